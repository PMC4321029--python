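"""Cytogenetic coordinate parsing, ordering and interval algebra.

The brute-force oracle enumerates discrete band indices on a synthetic map
with a fixed number of bands per subdivision and re-derives intersection and
boundary-keeping subtraction from set operations.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from f1screen.cytoband import (
    BandParseError,
    BandRange,
    CytoBand,
    band_le,
    band_lt,
    intersect,
    overlaps,
    parse_band,
    parse_breakpoint_range,
    parse_deficiency,
)

# ---------------------------------------------------------------- oracle ---

BANDS_PER_SUBDIVISION = 12  # synthetic map resolution for the oracle


def band_index(b: CytoBand) -> int:
    """Position of a concrete band on the synthetic discrete map."""
    assert b.letter is not None and b.band is not None
    return ((b.division - 21) * 6 + "ABCDEF".index(b.letter)) * BANDS_PER_SUBDIVISION + (
        b.band - 1
    )


def range_set(r: BandRange) -> set:
    return set(range(band_index(r.lo), band_index(r.hi) + 1))


def oracle_subtract(a: BandRange, b: BandRange) -> set:
    """Closed set difference, then re-extend each piece one band into ``b``
    where it abuts it — the breakpoint band itself is never exonerated."""
    a_set, b_set = range_set(a), range_set(b)
    remaining = a_set - b_set
    lo_b, hi_b = band_index(b.lo), band_index(b.hi)
    if lo_b - 1 in remaining and lo_b in a_set:
        remaining.add(lo_b)
    if hi_b + 1 in remaining and hi_b in a_set:
        remaining.add(hi_b)
    return remaining


def concrete_bands(chromosome=2):
    lo_div, hi_div = (21, 60) if chromosome == 2 else (61, 100)
    return st.builds(
        CytoBand,
        division=st.integers(lo_div, hi_div),
        letter=st.sampled_from("ABCDEF"),
        band=st.integers(1, BANDS_PER_SUBDIVISION),
    )


def concrete_ranges(chromosome=2):
    return st.tuples(concrete_bands(chromosome), concrete_bands(chromosome)).map(
        lambda ab: BandRange(*sorted(ab, key=CytoBand.sort_key))
    )


# --------------------------------------------------------------- parsing ---


@pytest.mark.parametrize(
    "text, division, letter, band, arm",
    [
        ("46C7", 46, "C", 7, "2R"),
        ("61A", 61, "A", None, "3L"),
        ("21E2", 21, "E", 2, "2L"),
        ("99D3", 99, "D", 3, "3R"),
    ],
)
def test_parse_band(text, division, letter, band, arm):
    b = parse_band(text)
    assert (b.division, b.letter, b.band, b.arm) == (division, letter, band, arm)
    assert str(b) == text  # round-trips through formatting


def test_parse_telomere_sentinel():
    t = parse_band("3Rt")
    assert t.telomere and t.arm == "3R" and str(t) == "3Rt"
    # outranks every concrete band of its arm
    assert band_lt(parse_band("100F12"), t)


@pytest.mark.parametrize("bad", ["", "46G1", "12A", "101A", "C7", "46C0", "4 6C"])
def test_parse_band_rejects_malformed(bad):
    with pytest.raises(BandParseError):
        parse_band(bad)


@pytest.mark.parametrize(
    "text, lo, hi",
    [
        ("49C1-4", "49C1", "49C4"),
        ("46C9-46C11", "46C9", "46C11"),
        ("50C23-D2", "50C23", "50D2"),
        ("85E7-F1", "85E7", "85F1"),
        ("77B-C", "77B", "77C"),
        ("45DE3", "45D", "45E3"),
        ("46C7", "46C7", "46C7"),
    ],
)
def test_parse_breakpoint_range(text, lo, hi):
    r = parse_breakpoint_range(text)
    assert (str(r.lo), str(r.hi)) == (lo, hi)


def test_parse_breakpoint_range_rejects_descending():
    with pytest.raises(BandParseError):
        parse_breakpoint_range("49C4-1")


def test_parse_deficiency_subdivision_expansion():
    # a letter-only proximal breakpoint spans its whole subdivision
    d = parse_deficiency("Df(2R)X1", "46C;47A1")
    assert band_lt(d.proximal.lo, parse_band("46C1"))
    assert band_lt(parse_band("46C11"), d.proximal.hi)
    assert str(d.distal.lo) == "47A1"
    assert d.minimal is not None


def test_parse_deficiency_degenerate_single_subdivision():
    d = parse_deficiency("Df(2R)M41A4", "41A;41A")
    assert d.maximal.lo.division == 41
    assert d.minimal is None  # nothing certainly deleted


@pytest.mark.parametrize(
    "bp", ["47A1;46C1", "46C", "46C;61A", "bogus;46C"]
)
def test_parse_deficiency_rejects(bp):
    with pytest.raises((BandParseError, ValueError)):
        parse_deficiency("X", bp)


def test_fixture_breakpoints_all_parse_and_roundtrip(screen_df, submap_cases):
    texts = [
        bp for bp in screen_df["breakpoints"] if bp not in ("N/A", "NA")
    ]
    assert len(texts) == 148
    for text in texts:
        d = parse_deficiency("x", text)
        # canonical formatting reparses to the identical interval
        canonical = f"{d.proximal};{d.distal}"
        d2 = parse_deficiency("x", canonical)
        assert (d2.proximal, d2.distal) == (d.proximal, d.distal)
    for case in submap_cases.values():
        assert case.parent.maximal is not None


# -------------------------------------------------------------- ordering ---


def test_band_order_examples():
    assert band_le(parse_band("46C1"), parse_band("46C7"))
    assert band_le(parse_band("46C7"), parse_band("47A1"))
    assert not band_le(parse_band("47A1"), parse_band("46C7"))


def test_band_order_matches_manual_genomic_sort():
    chr2 = ["21E2", "23C1", "25F3", "35B4", "41A", "46C", "46C7", "47A1",
            "49C1", "50D1", "54B16", "57B19", "60F1"]
    chr3 = ["61A", "64C", "70C2", "77B", "83C1", "95D7", "99D3", "3Rt"]
    for expected in (chr2, chr3):
        parsed = [parse_band(t) for t in expected]
        resorted = sorted(parsed, key=CytoBand.sort_key)
        assert [str(b) for b in resorted] == expected


def test_cross_chromosome_comparison_is_error():
    with pytest.raises(ValueError):
        band_le(parse_band("46C7"), parse_band("61A"))


@settings(derandomize=True, max_examples=200)
@given(a=concrete_bands(), b=concrete_bands(), c=concrete_bands())
def test_band_order_is_total(a, b, c):
    assert band_le(a, b) or band_le(b, a)
    if band_le(a, b) and band_le(b, a):
        assert a.sort_key() == b.sort_key()  # antisymmetry
    if band_le(a, b) and band_le(b, c):
        assert band_le(a, c)  # transitivity


# ------------------------------------------------------ interval algebra ---


def _df(name, bp):
    return parse_deficiency(name, bp)


def test_overlap_examples():
    x1 = _df("Df(2R)X1", "46C;47A1")
    assert overlaps(x1, _df("Df(2R)BSC298", "46B2;46C7"))
    assert not overlaps(x1, _df("Df(2R)vg-C", "49B2;49E2"))
    assert overlaps(x1, x1)
    # different chromosomes: no, but not an error
    assert not overlaps(x1, _df("Df(3L)emc-E12", "61A;61D3"))


def test_intersection_refines_to_46C1_46C7():
    x1 = _df("Df(2R)X1", "46C;47A1")
    bsc152 = _df("Df(2R)BSC152", "46C1;46D7")
    bsc298 = _df("Df(2R)BSC298", "46B2;46C7")
    first = intersect(x1, bsc152)
    assert (str(first.lo), str(first.hi)) == ("46C1", "46D7")
    final = first.intersect(bsc298.maximal)
    assert (str(final.lo), str(final.hi)) == ("46C1", "46C7")
    assert intersect(x1, _df("Df(2R)vg-C", "49B2;49E2")) is None


def test_subtract_keeps_uncertain_boundary_band():
    js17 = _df("Df(2L)JS17", "23C1-2;23E1-2").maximal
    cut = _df("Df(2L)Exel7015", "23C5;23E3").minimal
    pieces = js17.subtract(cut)
    assert [str(p) for p in pieces] == ["23C1-23C5"]


def test_subtract_self_is_empty_and_interior_cut_leaves_flanks():
    r = parse_breakpoint_range("46C1-46C11")
    assert r.subtract(r) == []
    pieces = r.subtract(parse_breakpoint_range("46C5-46C7"))
    assert [str(p) for p in pieces] == ["46C1-46C5", "46C7-46C11"]


@settings(derandomize=True, max_examples=300)
@given(a=concrete_ranges(), b=concrete_ranges())
def test_intersect_matches_enumeration_oracle(a, b):
    got = a.intersect(b)
    expected = range_set(a) & range_set(b)
    if got is None:
        assert expected == set()
    else:
        assert range_set(got) == expected


@settings(derandomize=True, max_examples=300)
@given(a=concrete_ranges(), b=concrete_ranges())
def test_subtract_matches_enumeration_oracle(a, b):
    got = a.subtract(b)
    assert set().union(*(range_set(p) for p in got), set()) == oracle_subtract(a, b)
    # pieces come out proximal -> distal
    idx = [band_index(p.lo) for p in got]
    assert idx == sorted(idx)


def test_minimal_extent_within_maximal(screen_df):
    for bp in screen_df["breakpoints"]:
        if bp in ("N/A", "NA"):
            continue
        d = parse_deficiency("x", bp)
        if d.minimal is not None:
            assert band_le(d.maximal.lo, d.minimal.lo)
            assert band_le(d.minimal.hi, d.maximal.hi)
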