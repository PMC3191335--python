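import io

import numpy as np
import pytest

from estssr import (
    DetectionConfig,
    ESTRecord,
    SimParams,
    find_perfect_ssrs,
    mine_records,
    plant_ssr,
    simulate_est_set,
    verify_locus,
    write_fasta,
)
from estssr.preprocess import composition_stats


def as_tuples(loci):
    return {(l.seq_id, l.start, l.end, l.motif, l.repeat_count) for l in loci}


def test_same_seed_gives_byte_identical_fasta():
    params = SimParams(n_sequences=60, seed=42)
    out = []
    for _ in range(2):
        records, _truth = simulate_est_set(params)
        buf = io.StringIO()
        write_fasta(records, buf)
        out.append(buf.getvalue())
    assert out[0] == out[1]


def test_null_model_plants_nothing():
    params = SimParams(n_sequences=50, seed=5, ssr_rate=0.0)
    _records, truth = simulate_est_set(params)
    assert truth.planted_loci == [] and truth.per_class_counts == {}


def test_planted_loci_verify_by_construction():
    params = SimParams(n_sequences=120, seed=9, ssr_rate=0.2, tail_rate=0.0)
    records, truth = simulate_est_set(params)
    by_id = {r.seq_id: r for r in records}
    assert truth.planted_loci
    for p in truth.planted_loci:
        rec = by_id[p.seq_id]
        # perfect repeat at the stated coordinates, detector not involved
        assert rec.sequence[p.start - 1 : p.end] == p.motif * p.repeat_count
        assert verify_locus(rec, p.as_locus())


def test_detector_recovers_every_planted_locus_exactly():
    params = SimParams(n_sequences=300, seed=13)
    records, truth = simulate_est_set(params)
    result = mine_records(records, design=False)
    detected = as_tuples(result.loci)
    planted = {(p.seq_id, p.start, p.end, p.motif, p.repeat_count)
               for p in truth.planted_loci}
    assert planted <= detected
    assert detected == as_tuples(truth.all_expected_loci)


def test_redundancy_corruptions_are_removed_as_planted():
    params = SimParams(n_sequences=250, seed=17)
    records, truth = simulate_est_set(params)
    result = mine_records(records, design=False)
    n_extra = len(truth.duplicate_pairs)
    assert result.redundancy.n_dropped_duplicate == n_extra
    assert result.redundancy.n_dropped_flankless == len(truth.flankless_ids)
    kept_ids = {r.seq_id for r in result.records_kept}
    assert not kept_ids & {d for _, d, _ in truth.duplicate_pairs}
    assert not kept_ids & set(truth.flankless_ids)


def test_composition_matches_base_probs():
    params = SimParams(n_sequences=300, seed=23, ssr_rate=0.0, tail_rate=0.0)
    records, _ = simulate_est_set(params)
    stats = composition_stats(records)
    n = stats.total_bases
    assert n >= 1e5
    p = 0.56
    se = 100 * np.sqrt(p * (1 - p) / n)
    assert abs(stats.pct_AT - 56.0) <= 3 * se + 0.05  # 0.05 for reporting rounding


def test_plant_ssr_inserts_exactly_one_maximal_run():
    rng = np.random.default_rng(1)
    bg = "G" * 60
    seq = plant_ssr(bg, "AT", 5, 30, rng)
    assert seq.count("AT" * 5) == 1
    assert "AT" * 6 not in seq


def test_plant_ssr_breaks_extending_neighbors():
    rng = np.random.default_rng(2)
    # background base right before the insertion point would extend (AC)5
    bg = "G" * 20 + "C" + "G" * 20
    seq = plant_ssr(bg, "AC", 5, 21, rng)
    rec = ESTRecord("x", seq)
    locus = next(l for l in find_perfect_ssrs(rec) if l.motif in ("AC", "CA"))
    assert locus.repeat_count == 5


def test_plant_ssr_flank_rule():
    with pytest.raises(ValueError):
        plant_ssr("ACGT", "CA", 5, 0)
    with pytest.raises(ValueError):
        plant_ssr("ACGT", "ATAT", 3, 2)  # non-primitive motif


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        SimParams(n_sequences=10, seed=1, dup_rate=0.6, containment_rate=0.5)
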