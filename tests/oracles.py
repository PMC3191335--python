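"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive O(n^2)-style enumeration, distinct from the
library's scanning algorithms.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp_oracle(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def primitive_brute(motif: str) -> str:
    """Smallest repeating unit by trying every divisor length."""
    for d in range(1, len(motif)):
        if len(motif) % d == 0:
            unit = motif[:d]
            if unit * (len(motif) // d) == motif:
                return unit
    return motif


def brute_force_ssrs(
    seq: str, min_period: int = 2, max_period: int = 6, min_repeats: int = 5
) -> set[tuple]:
    """Every maximal perfect repeat, by greedy extension from every start.

    Returns a set of (start, end, motif, period, repeat_count) with
    1-based inclusive coordinates, primitive motifs only, deduplicated on
    (start, end) keeping the smallest period.
    """
    n = len(seq)
    hits: dict[tuple[int, int], tuple] = {}
    for period in range(min_period, max_period + 1):
        for start in range(n):
            motif = seq[start : start + period]
            if len(motif) < period or any(c not in _COMP for c in motif):
                continue
            if primitive_brute(motif) != motif:
                continue
            # left-maximality: previous base must not continue the phase
            if start > 0 and seq[start - 1] in _COMP and seq[start - 1] == motif[-1]:
                continue
            k = 0
            while (
                start + k < n
                and seq[start + k] in _COMP
                and seq[start + k] == motif[k % period]
            ):
                k += 1
            count = k // period
            if count >= min_repeats:
                key = (start + 1, start + count * period)
                prev = hits.get(key)
                if prev is None or prev[3] > period:
                    hits[key] = (key[0], key[1], motif, period, count)
    return set(hits.values())


def longest_complementary_stretch(fw: str, rv: str) -> int:
    """Longest ungapped antiparallel complementary stretch, as the longest
    common substring of fw and revcomp(rv), by substring-set enumeration."""
    target = revcomp_oracle(rv)
    best = 0
    for length in range(1, min(len(fw), len(target)) + 1):
        subs = {fw[i : i + length] for i in range(len(fw) - length + 1)}
        if any(target[j : j + length] in subs for j in range(len(target) - length + 1)):
            best = length
        else:
            break
    return best


def three_prime_stretch(fw: str, rv: str) -> int:
    """Longest complementary stretch anchored at the 3' end of either primer,
    by explicit window comparison."""
    best = 0
    for a, b in ((fw, rv), (rv, fw)):
        for length in range(1, min(len(a), len(b)) + 1):
            suffix = a[-length:]
            for j in range(len(b) - length + 1):
                if suffix == revcomp_oracle(b[j : j + length]):
                    best = max(best, length)
                    break
    return best
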