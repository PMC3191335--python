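"""Redundancy filtering for SSR-bearing sequence sets.

Two criteria produce a non-redundant, flank-bearing set:

(i)  sequences identical to, or exact substrings of, another sequence are
     clustered (transitive closure) and only the longest member kept;
(ii) sequences composed entirely of repeat motif, with no flanking base on
     either side, are discarded — their uniqueness cannot be established
     and no primer can be placed.

Clustering is deterministic exact/containment matching on the given
strand; inexact (mismatched) homologs are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .detect import SSRLocus
from .sequence_io import ESTRecord


@dataclass
class RedundancyReport:
    n_input: int
    n_kept: int
    n_dropped_duplicate: int = 0
    n_dropped_flankless: int = 0
    clusters: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_input == (
            self.n_kept + self.n_dropped_duplicate + self.n_dropped_flankless
        ), "redundancy counts do not reconcile"

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_dropped_duplicate": self.n_dropped_duplicate,
            "n_dropped_flankless": self.n_dropped_flankless,
            "clusters": [
                {"representative": rep, "members": members}
                for rep, members in self.clusters
            ],
        }


def combine_reports(first: RedundancyReport, second: RedundancyReport) -> RedundancyReport:
    """Chain two filtering stages into one reconciled report."""
    assert first.n_kept == second.n_input
    return RedundancyReport(
        n_input=first.n_input,
        n_kept=second.n_kept,
        n_dropped_duplicate=first.n_dropped_duplicate + second.n_dropped_duplicate,
        n_dropped_flankless=first.n_dropped_flankless + second.n_dropped_flankless,
        clusters=first.clusters + second.clusters,
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def deduplicate(
    records: Sequence[ESTRecord],
) -> tuple[list[ESTRecord], RedundancyReport]:
    """Cluster identical/contained sequences; keep the longest of each cluster.

    Ties on length are broken by input order (first wins); kept records
    preserve input order.
    """
    n = len(records)
    uf = _UnionFind(n)
    order = sorted(range(n), key=lambda i: -len(records[i].sequence))
    for a_pos, ia in enumerate(order):
        sa = records[ia].sequence
        for ib in order[a_pos + 1 :]:
            sb = records[ib].sequence  # len(sb) <= len(sa)
            if uf.find(ia) == uf.find(ib):
                continue
            if sb and sb in sa:
                uf.union(ia, ib)

    members: dict[int, list[int]] = {}
    for i in range(n):
        members.setdefault(uf.find(i), []).append(i)

    kept_idx: set[int] = set()
    clusters: list[tuple[str, list[str]]] = []
    for group in members.values():
        best = min(group, key=lambda i: (-len(records[i].sequence), i))
        kept_idx.add(best)
        if len(group) > 1:
            clusters.append(
                (records[best].seq_id, [records[i].seq_id for i in sorted(group)])
            )
    kept = [records[i] for i in range(n) if i in kept_idx]
    report = RedundancyReport(
        n_input=n,
        n_kept=len(kept),
        n_dropped_duplicate=n - len(kept),
        clusters=sorted(clusters),
    )
    return kept, report


def _covers_fully(length: int, loci: Sequence[SSRLocus]) -> bool:
    spans = sorted((l.start, l.end) for l in loci)
    covered_to = 0  # 1-based position up to which the union reaches
    for start, end in spans:
        if start > covered_to + 1:
            return False
        covered_to = max(covered_to, end)
    return covered_to >= length


def drop_flankless(
    records: Sequence[ESTRecord],
    loci_by_seq: Mapping[str, Sequence[SSRLocus]],
) -> tuple[list[ESTRecord], RedundancyReport]:
    """Discard records whose detected repeat spans cover the whole sequence.

    A record with no detected loci is kept: the rule applies only to
    repeat-composed sequences (including compound repeats with no flanks).
    """
    kept: list[ESTRecord] = []
    dropped = 0
    for rec in records:
        loci = loci_by_seq.get(rec.seq_id, ())
        if loci and _covers_fully(rec.length, loci):
            dropped += 1
        else:
            kept.append(rec)
    report = RedundancyReport(
        n_input=len(records), n_kept=len(kept), n_dropped_flankless=dropped
    )
    return kept, report
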