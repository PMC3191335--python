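import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estssr import (
    ESTRecord,
    PrimerConstraints,
    SSRLocus,
    complementarity_scores,
    design_primers,
    find_perfect_ssrs,
    gc_percent,
    melting_temperature,
    revcomp,
)
from oracles import longest_complementary_stretch, three_prime_stretch

dna = st.text(alphabet="ACGT", min_size=4, max_size=25)


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 50.0), ("GGCC", 100.0), ("AGTTCCGCCACATCCATTC", 52.6), ("AAAA", 0.0)],
)
def test_gc_percent(seq, expected):
    assert gc_percent(seq) == expected


def test_gc_percent_rejects_empty_and_n():
    with pytest.raises(ValueError):
        gc_percent("")
    with pytest.raises(ValueError):
        gc_percent("ACGNT")


def test_wallace_rule_closed_form():
    # 10 A/T and 10 G/C: 2*10 + 4*10
    assert melting_temperature("ATATATATATGCGCGCGCGC", method="wallace") == 60.0


def test_published_marker_tm_reproduced():
    # classic nearest-neighbor conditions reproduce the published 60.9
    assert abs(melting_temperature("AGTTCCGCCACATCCATTC") - 60.9) <= 3.0


@pytest.mark.parametrize("method", ["breslauer", "santalucia", "wallace"])
@given(seq=st.text(alphabet="ACGT", min_size=8, max_size=30))
def test_tm_duplex_symmetry(method, seq):
    # a duplex has one Tm: a primer and its reverse complement agree
    assert melting_temperature(seq, method=method) == pytest.approx(
        melting_temperature(revcomp(seq), method=method), abs=1e-6
    )


def test_tm_rejects_short_or_ambiguous():
    with pytest.raises(ValueError):
        melting_temperature("ACGTACG")
    with pytest.raises(ValueError):
        melting_temperature("ACGTNACGT")


def test_santalucia_matches_biopython_reference():
    from Bio.SeqUtils import MeltingTemp as mt

    seq = "AGTTCCGCCACATCCATTC"
    ours = melting_temperature(seq, method="santalucia")
    ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=25, dnac2=25)
    assert ours == pytest.approx(ref, abs=1e-9)


@pytest.mark.parametrize(
    "fw,rv,any_min",
    [("AAAA", "TTTT", 4), ("ACGT", "ACGT", 2)],
)
def test_complementarity_examples(fw, rv, any_min):
    any_comp, _ = complementarity_scores(fw, rv)
    assert any_comp >= any_min


def test_no_dimer_means_score_at_most_one():
    any_comp, _ = complementarity_scores("AAAA", "CCCC")
    assert any_comp <= 1


@given(dna, dna)
@settings(max_examples=150)
def test_complementarity_agrees_with_substring_oracle(fw, rv):
    any_comp, three = complementarity_scores(fw, rv)
    assert any_comp == longest_complementary_stretch(fw, rv)
    assert three == three_prime_stretch(fw, rv)


def _template(seed=11, motif="CA", count=15, flank=150):
    from conftest import random_dna
    from estssr.simulate import plant_ssr

    rng = np.random.default_rng(seed)
    bg = random_dna(rng, 2 * flank)
    seq = plant_ssr(bg, motif, count, flank, rng)
    rec = ESTRecord("tmpl", seq)
    loci = find_perfect_ssrs(rec)
    locus = next(l for l in loci if l.repeat_count == count and l.motif in (motif, motif[::-1]))
    return rec, locus, loci


def validate_candidate(rec, cand, constraints, exclusion):
    """Independent re-check of every constraint from raw sequences."""
    c = constraints
    s = rec.sequence
    fw_tpl = s[cand.fw_start - 1 : cand.fw_start - 1 + len(cand.fw_seq)]
    rv_tpl = s[cand.rv_end - len(cand.rv_seq) : cand.rv_end]
    assert fw_tpl == cand.fw_seq
    assert revcomp(rv_tpl) == cand.rv_seq
    for seq in (cand.fw_seq, cand.rv_seq):
        assert c.len_min <= len(seq) <= c.len_max
        assert c.gc_min <= gc_percent(seq) <= c.gc_max
        assert c.tm_min - 1 <= melting_temperature(seq, method=c.tm_method) <= c.tm_max + 1
        any_self, three_self = complementarity_scores(seq, seq)
        assert any_self <= c.max_self_comp and three_self <= c.max_3prime_comp
    any_pair, three_pair = complementarity_scores(cand.fw_seq, cand.rv_seq)
    assert any_pair <= c.max_self_comp and three_pair <= c.max_3prime_comp
    assert c.product_min <= cand.product_size <= c.product_max
    assert cand.product_size == cand.rv_end - cand.fw_start + 1
    fw_span = set(range(cand.fw_start, cand.fw_start + len(cand.fw_seq)))
    rv_span = set(range(cand.rv_end - len(cand.rv_seq) + 1, cand.rv_end + 1))
    for locus in exclusion:
        span = set(range(locus.start, locus.end + 1))
        assert not (fw_span & span) and not (rv_span & span)


def test_design_yields_valid_candidates_on_synthetic_template():
    rec, locus, loci = _template()
    constraints = PrimerConstraints()
    result = design_primers(rec, locus, constraints, exclusion_loci=loci)
    assert result.candidates, "expected at least one primer pair"
    for cand in result.candidates:
        validate_candidate(rec, cand, constraints, loci)
    penalties = [c.penalty for c in result.candidates]
    assert penalties == sorted(penalties)


def test_insufficient_flank_reported():
    rec = ESTRecord("x", "GATCG" + "CA" * 15 + "CGATC")
    locus = find_perfect_ssrs(rec)[0]
    result = design_primers(rec, locus)
    assert result.candidates == [] and result.failure_reason == "insufficient flank"


def test_product_size_coordinate_arithmetic():
    rec, locus, loci = _template()
    result = design_primers(rec, locus, exclusion_loci=loci)
    cand = result.best
    assert cand.product_size == cand.rv_end - cand.fw_start + 1


def test_locus_outside_record_errors():
    rec = ESTRecord("x", "ACGT" * 30)
    bad = SSRLocus("x", "CA", 2, 5, 115, 124)  # beyond the 120-base record
    with pytest.raises(ValueError):
        design_primers(rec, bad)


def test_tightening_constraints_is_monotone():
    rec, locus, loci = _template()
    base = PrimerConstraints()
    n_base = len(design_primers(rec, locus, base, exclusion_loci=loci).candidates)
    tighter = [
        PrimerConstraints(len_min=20),
        PrimerConstraints(len_max=24),
        PrimerConstraints(tm_min=57.0),
        PrimerConstraints(tm_max=59.0),
        PrimerConstraints(product_min=150),
        PrimerConstraints(product_max=250),
        PrimerConstraints(gc_min=40.0),
        PrimerConstraints(gc_max=60.0),
        PrimerConstraints(max_self_comp=5),
        PrimerConstraints(max_3prime_comp=2),
    ]
    for constraints in tighter:
        n = len(design_primers(rec, locus, constraints, exclusion_loci=loci).candidates)
        assert n <= n_base


def test_design_is_deterministic():
    rec, locus, loci = _template()
    a = design_primers(rec, locus, exclusion_loci=loci)
    b = design_primers(rec, locus, exclusion_loci=loci)
    assert a.candidates == b.candidates
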