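from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from estssr import (
    DetectionConfig,
    ESTRecord,
    classify_motif,
    find_perfect_ssrs,
    parse_ssr_notation,
    primitive_motif,
    revcomp,
    verify_locus,
)
from oracles import brute_force_ssrs, primitive_brute


def as_tuples(loci):
    return {(l.start, l.end, l.motif, l.period, l.repeat_count) for l in loci}


@pytest.mark.parametrize(
    "motif,expected",
    [("ATAT", "AT"), ("ACG", "ACG"), ("AAAAAA", "A"), ("ACACAC", "AC"), ("A", "A")],
)
def test_primitive_motif_examples(motif, expected):
    assert primitive_motif(motif) == expected


def test_primitive_motif_rejects_n():
    with pytest.raises(ValueError):
        primitive_motif("AN")


def test_primitive_motif_agrees_with_divisor_oracle():
    for length in range(1, 7):
        for chars in product("ACGT", repeat=length):
            motif = "".join(chars)
            assert primitive_motif(motif) == primitive_brute(motif)


@pytest.mark.parametrize(
    "motif,label,period_class",
    [
        ("GA", "CT/GA", "di"),
        ("AG", "AG/TC", "di"),
        ("CT", "CT/GA", "di"),
        ("TTC", "TTC", "tri"),
        ("TTTA", "TTTA", "tetra"),
        ("AATTG", "AATTG", "penta"),
        ("A", "A", "mono"),
    ],
)
def test_classify_motif(motif, label, period_class):
    mc = classify_motif(motif)
    assert (mc.class_label, mc.period_class) == (label, period_class)


def test_classify_motif_rejects_non_primitive():
    with pytest.raises(ValueError):
        classify_motif("ATAT")


def test_exactly_six_dinucleotide_classes():
    labels = {
        classify_motif(a + b).class_label
        for a in "ACGT"
        for b in "ACGT"
        if a != b
    }
    assert labels == {"AC/TG", "AG/TC", "AT/TA", "CA/GT", "CG/GC", "CT/GA"}


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACGTACG", set()),
        ("GGACACACACACATT", {(3, 12, "AC", 2, 5)}),
        ("TTGCAGAGAGAGGCTT", set()),  # four copies fall below the threshold
        ("CCTCTCTCTCTCTCTCTCTCTCTCTCTCTCTCTCC", {(2, 33, "CT", 2, 16)}),
        (
            "ATATATATATNATATATATAT",  # N breaks perfection; both sides rescanned
            {(1, 10, "AT", 2, 5), (12, 21, "AT", 2, 5)},
        ),
        ("", set()),
    ],
)
def test_detection_examples(seq, expected):
    loci = find_perfect_ssrs(ESTRecord("s", seq))
    assert as_tuples(loci) == expected


def test_trailing_partial_unit_excluded():
    # (AC)5 followed by a lone A: complete units only
    loci = find_perfect_ssrs(ESTRecord("s", "GGACACACACACATT"))
    assert loci[0].end == 12 and loci[0].repeat_count == 5


def test_leading_partial_unit_anchors_at_first_complete_copy():
    # run TATATATATAT: anchored at the leftmost complete unit, motif "TA"
    loci = find_perfect_ssrs(ESTRecord("s", "CCTATATATATATGG"))
    assert as_tuples(loci) == {(3, 12, "TA", 2, 5)}


def test_every_locus_reverifies():
    rec = ESTRecord("s", "GGACACACACACATTTTCTTCTTCTTCTTCGG")
    for locus in find_perfect_ssrs(rec, DetectionConfig(min_repeats=5)):
        assert verify_locus(rec, locus)


def test_mononucleotide_detection_behind_config():
    rec = ESTRecord("s", "GGCAAAAAAATGC")
    assert find_perfect_ssrs(rec) == []
    loci = find_perfect_ssrs(rec, DetectionConfig(min_period=1, min_repeats=5))
    assert {(l.motif, l.repeat_count) for l in loci} == {("A", 7)}


def test_strand_asymmetry_maps_to_complement_motif():
    # scanning is single-strand: the reverse complement reports the
    # complementary motif (same repeat count), not the same label
    seq = "GGACACACACACATT"
    fwd = find_perfect_ssrs(ESTRecord("s", seq))[0]
    rev = find_perfect_ssrs(ESTRecord("s", revcomp(seq)))[0]
    assert fwd.motif == "AC" and rev.motif == "TG"
    assert rev.repeat_count == fwd.repeat_count == 5


@given(
    st.text(alphabet="ACGTN", min_size=0, max_size=120),
    st.sampled_from([2, 5]),
)
@settings(max_examples=300)
def test_detector_equals_brute_force_oracle(seq, min_repeats):
    config = DetectionConfig(min_period=2, max_period=6, min_repeats=min_repeats)
    rec = ESTRecord("s", seq)
    assert as_tuples(find_perfect_ssrs(rec, config)) == brute_force_ssrs(
        seq, 2, 6, min_repeats
    )


@given(st.text(alphabet="AC", min_size=10, max_size=80))
def test_no_duplicate_spans_and_all_verify(seq):
    rec = ESTRecord("s", seq)
    loci = find_perfect_ssrs(rec)
    spans = [(l.start, l.end) for l in loci]
    assert len(spans) == len(set(spans))
    assert all(verify_locus(rec, l) for l in loci)


@pytest.mark.parametrize(
    "text,motif,count", [("(CA)15", "CA", 15), ("(TTTA)8", "TTTA", 8)]
)
def test_parse_ssr_notation(text, motif, count):
    assert parse_ssr_notation(text) == (motif, count)


def test_parse_ssr_notation_rejects_garbage():
    with pytest.raises(ValueError):
        parse_ssr_notation("CA15")
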