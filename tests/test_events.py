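import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spliceoscope.core_io import GeneModelSet, JunctionTable, Transcript, junction_key
from spliceoscope.events import (
    SpliceEvent,
    compute_psi,
    enumerate_events,
    intronic_read_fraction,
    make_ir_event,
)


def _toy_models(strand="+"):
    """Three-exon coding gene: exons 100-200, 400-500, 800-1000."""
    t = Transcript("T1", "G1", "chr1", strand, [(100, 200), (400, 500), (800, 1000)],
                   150, 850)
    return GeneModelSet({"G1": ("chr1", strand)}, {"T1": t})


def _table(rows, boundaries=None):
    df = pd.DataFrame(rows, columns=["chrom", "intron_start", "intron_end",
                                     "strand", "sample_id", "count"])
    bdf = None
    if boundaries:
        bdf = pd.DataFrame(boundaries, columns=["boundary_id", "sample_id", "count"])
    return JunctionTable(df, bdf)


def test_skip_junction_yields_cassette_event():
    """An observed exon-2-skipping junction gives one cassette event."""
    models = _toy_models()
    table = _table([("chr1", 201, 399, "+", "s1", 10),
                    ("chr1", 501, 799, "+", "s1", 12),
                    ("chr1", 201, 799, "+", "s1", 8)])
    evs = enumerate_events(models, table)
    cass = [e for e in evs if e.etype == "cassette_exon"]
    assert len(cass) == 1
    assert cass[0].exon == (400, 500)
    assert cass[0].inclusion == (junction_key("chr1", 201, 799, "+"),)
    assert set(cass[0].exclusion) == {junction_key("chr1", 201, 399, "+"),
                                      junction_key("chr1", 501, 799, "+")}


@pytest.mark.parametrize("strand", ["+", "-"])
def test_acceptor_21nt_upstream_is_alt_3ss_offset_minus21(strand):
    """An acceptor 21 nt upstream of the annotated one (same donor) gives
    an alt 3'SS event with signed offset -21 on either strand."""
    models = _toy_models(strand)
    if strand == "+":
        novel = ("chr1", 201, 399 - 21, "+")     # acceptor at intron end
    else:
        novel = ("chr1", 501 + 21, 799, "-")     # acceptor at intron start
    table = _table([novel + ("s1", 9)])
    evs = enumerate_events(models, table)
    assert len(evs) == 1 and evs[0].etype == "alt_3ss"
    assert evs[0].offset == -21


def test_acceptor_600nt_upstream_is_not_an_event():
    """Alternative splice sites are limited to 500 nt from annotated ones."""
    t = Transcript("T1", "G1", "chr1", "+", [(100, 200), (1000, 1100)])
    models = GeneModelSet({"G1": ("chr1", "+")}, {"T1": t})
    table = _table([("chr1", 201, 999 - 600, "+", "s1", 9)])
    assert enumerate_events(models, table) == []


def test_donor_shift_is_alt_5ss_with_positive_offset():
    models = _toy_models()
    table = _table([("chr1", 201 + 15, 399, "+", "s1", 9)])
    evs = enumerate_events(models, table)
    assert len(evs) == 1 and evs[0].etype == "alt_5ss"
    assert evs[0].offset == 15


def test_junction_on_unknown_chromosome_is_skipped():
    models = _toy_models()
    table = _table([("chrUn", 201, 399, "+", "s1", 9)])
    assert enumerate_events(models, table) == []


def test_mutually_exclusive_pair_merged():
    """Two adjacent skippable exons never joined by a junction collapse
    into one mutually_exclusive event."""
    t = Transcript("T1", "G1", "chr1", "+",
                   [(100, 200), (400, 500), (700, 800), (1000, 1100)])
    models = GeneModelSet({"G1": ("chr1", "+")}, {"T1": t})
    rows = [("chr1", 201, 399, "+", "s1", 10),   # flank junctions observed
            ("chr1", 801, 999, "+", "s1", 10),
            ("chr1", 201, 699, "+", "s1", 6),    # skip exon 2 (use exon 3)
            ("chr1", 501, 999, "+", "s1", 7)]    # skip exon 3 (use exon 2)
    evs = enumerate_events(models, _table(rows))
    mxe = [e for e in evs if e.etype == "mutually_exclusive"]
    assert len(mxe) == 1
    assert not any(e.etype == "cassette_exon" for e in evs)
    # with the middle junction observed, they stay two cassette events
    rows.append(("chr1", 501, 699, "+", "s1", 3))
    evs2 = enumerate_events(models, _table(rows))
    assert sum(e.etype == "cassette_exon" for e in evs2) == 2


def test_enumeration_order_independent_of_samples():
    models = _toy_models()
    rows = [("chr1", 201, 799, "+", "s1", 8), ("chr1", 201, 399, "+", "s1", 4),
            ("chr1", 501, 799, "+", "s1", 4)]
    swapped = [r[:4] + ("s2",) + r[5:] for r in rows][::-1]
    e1 = enumerate_events(models, _table(rows))
    e2 = enumerate_events(models, _table(swapped + rows))
    assert [e.event_id for e in e1] == [e.event_id for e in e2]


def test_enumeration_superset_of_planted(small_reference, small_events):
    """On simulator output every planted event is enumerated (100% recall)."""
    planted = {s.event.event_id for s in small_reference.sites}
    enumerated = {e.event_id for e in small_events}
    assert planted <= enumerated


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------


def _psi_of(inclusion, exclusion, min_reads=5):
    models = _toy_models()
    ev = SpliceEvent("e1", "alt_3ss", "chr1", "+", "G1", "T1",
                     (junction_key("chr1", 201, 378, "+"),),
                     (junction_key("chr1", 201, 399, "+"),),
                     offset=-21, intron=(201, 399), alt_intron=(201, 378))
    table = _table([("chr1", 201, 378, "+", "s1", inclusion),
                    ("chr1", 201, 399, "+", "s1", exclusion)])
    return compute_psi([ev], table, min_reads=min_reads).psi.iloc[0, 0]


def test_psi_arithmetic():
    assert _psi_of(30, 70) == pytest.approx(30.0)


def test_psi_undefined_below_read_threshold():
    """inclusion 2 + exclusion 2 = 4 < 5 leaves PSI undefined."""
    assert np.isnan(_psi_of(2, 2))
    assert _psi_of(2, 3) == pytest.approx(40.0)


def test_intron_retention_psi_uses_boundary_mean():
    """IR PSI = 100 * mean(boundaries) / (mean + spliced): 10,20 vs 85 -> 15."""
    models = _toy_models()
    ev = make_ir_event(models.transcripts["T1"], 0)
    b_l, b_r = ev.inclusion
    table = _table([("chr1", 201, 399, "+", "s1", 85)],
                   boundaries=[(b_l, "s1", 10), (b_r, "s1", 20)])
    psi = compute_psi([ev], table)
    assert psi.psi.iloc[0, 0] == pytest.approx(15.0)


def test_missing_evidence_counts_as_zero():
    models = _toy_models()
    ev = SpliceEvent("e1", "alt_3ss", "chr1", "+", "G1", "T1",
                     (junction_key("chr1", 201, 378, "+"),),
                     (junction_key("chr1", 201, 399, "+"),),
                     offset=-21, intron=(201, 399), alt_intron=(201, 378))
    table = _table([("chr1", 201, 399, "+", "s1", 50)])
    psi = compute_psi([ev], table)
    assert psi.psi.iloc[0, 0] == pytest.approx(0.0)


@given(st.integers(min_value=2, max_value=50))
def test_psi_scale_invariance(k):
    """Multiplying all counts of a sample by k leaves defined PSI values
    unchanged (definedness may only grow)."""
    base = _psi_of(3, 4)
    scaled = _psi_of(3 * k, 4 * k)
    assert scaled == pytest.approx(base)


def test_intronic_read_fraction():
    cov = pd.DataFrame({
        "region_id": ["r"] * 6,
        "region_class": ["exonic", "intronic"] * 3,
        "sample_id": ["a", "a", "b", "b", "c", "c"],
        "count": [900, 100, 500, 0, 0, 0],
    })
    frac = intronic_read_fraction(cov)
    assert frac["a"] == pytest.approx(0.1)
    assert frac["b"] == pytest.approx(0.0)
    assert np.isnan(frac["c"])


def test_ir_coverage_depletion_recovered(small_study):
    """The planted global intron-coverage depletion (factor 0.8 in SF3B1
    carriers) is recovered from the coverage summary within 10%."""
    table, _, sheet, _ = small_study
    frac = intronic_read_fraction(table.coverage)
    mut = frac[sheet.samples_with_mutation("SF3B1")].mean()
    ctrl = frac[sheet.control_samples()].mean()
    assert mut / ctrl == pytest.approx(0.8, rel=0.10)


def test_event_invariants_enforced():
    with pytest.raises(ValueError, match="offset"):
        SpliceEvent("e", "alt_3ss", "chr1", "+", "G", "T",
                    ("a",), ("b",), offset=-600)
    with pytest.raises(ValueError, match="overlap"):
        SpliceEvent("e", "cassette_exon", "chr1", "+", "G", "T",
                    ("a",), ("a",))
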