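"""Completeness, microbial-identity and heme-motif filters."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cypminer.filters import (
    REASON_INCOMPLETE,
    REASON_MICROBIAL,
    REASON_NO_MOTIF,
    filter_cascade,
    find_heme_motifs,
    is_complete,
    passes_microbial_identity,
)
from cypminer.sequence_io import ProteinRecord, ReferenceEntry, ReferencePanel

from oracles import enumerate_motifs


def _rec(rid, seq, **kw):
    return ProteinRecord(record_id=rid, sequence=seq, **kw)


# --- completeness ----------------------------------------------------------


def test_explicit_flags_decide_completeness():
    assert is_complete(_rec("a", "WKT", complete=True))  # flag wins over sequence
    assert not is_complete(_rec("b", "MKT", complete=False, stop_seen=True))


def test_unknown_flag_falls_back_to_sequence_evidence():
    assert is_complete(_rec("a", "MKTAY", complete=None, stop_seen=True))
    assert not is_complete(_rec("b", "KTAYM", complete=None, stop_seen=True))
    assert not is_complete(_rec("c", "MKTAY", complete=None, stop_seen=False))


# --- motif scanner ---------------------------------------------------------


def test_canonical_motif_typical_spacers():
    (hit,) = find_heme_motifs("FGGGSHLCVG")
    assert (hit.n, hit.m, hit.bridge, hit.axial) == (2, 3, "G", "C")
    assert hit.canonical and hit.matched == "FGGGSHLCVG"


def test_canonical_motif_boundary_spacers():
    hits = [h for h in find_heme_motifs("FAAAAAGAAAAAACLG") if h.canonical]
    assert len(hits) == 1
    assert (hits[0].n, hits[0].m) == (5, 6)


def test_axial_tyrosine_is_near_miss_not_canonical():
    hits = find_heme_motifs("FGGGSHLYVG")
    assert [h.canonical for h in hits] == [False]
    assert hits[0].axial == "Y"


def test_overlapping_spacer_variants_all_reported():
    # two cysteines compatible with the same F via different (n, m) spacers
    seq = "FAAGGAACAGACAG"
    combos = {(h.n, h.m) for h in find_heme_motifs(seq) if h.canonical}
    assert {(2, 3), (3, 6)} <= combos


@given(st.text(alphabet="FGACYLSX", min_size=1, max_size=60))
def test_motif_scanner_matches_bruteforce_enumeration(seq):
    got_canon = {(h.start, h.n, h.m) for h in find_heme_motifs(seq) if h.canonical}
    got_near = {(h.start, h.n, h.m) for h in find_heme_motifs(seq) if not h.canonical}
    exp_canon, exp_near = enumerate_motifs(seq)
    assert got_canon == set(exp_canon)
    assert got_near == set(exp_near)


# --- microbial identity ----------------------------------------------------


def _panel_one(seq, microbial=True):
    return ReferencePanel(
        entries=[
            ReferenceEntry(
                ref_id="ref1", sequence=seq, family="CYP107", subfamily="A",
                is_microbial=microbial,
            )
        ]
    )


def test_identical_to_microbial_reference_passes():
    seq = "MKTAYIAKQRMKTAYIAKQR"
    ok, ref, ident = passes_microbial_identity(_rec("q", seq), _panel_one(seq))
    assert ok and ref == "ref1" and ident == 100.0


def test_exactly_twenty_percent_is_inclusive():
    # 2 identities out of 10 columns; I/V mismatches keep the alignment
    # ungapped and full-length, so identity is exactly 20.0
    query = _rec("q", "MK" + "I" * 8)
    ok, _, ident = passes_microbial_identity(query, _panel_one("MK" + "V" * 8))
    assert ident == pytest.approx(20.0)
    assert ok


def test_below_twenty_percent_fails():
    query = _rec("q", "M" + "I" * 9)
    ok, _, ident = passes_microbial_identity(query, _panel_one("M" + "V" * 9))
    assert ident == pytest.approx(10.0)
    assert not ok


def test_panel_without_microbial_entries_is_an_error():
    with pytest.raises(ValueError):
        passes_microbial_identity(_rec("q", "MKT"), _panel_one("MKT", microbial=False))


# --- cascade ---------------------------------------------------------------


def test_cascade_order_and_reasons(small_dataset):
    ref = small_dataset.panel.entries[0]
    good = _rec("good", ref.sequence, complete=True)
    partial = _rec("partial", ref.sequence, complete=False)
    motif_free = _rec(
        "motifless",
        ref.sequence.replace("C", "Y"),  # destroys the axial cysteine
        complete=True,
    )
    rng = np.random.default_rng(13)
    unrelated = _rec(
        "unrelated",
        "M" + "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 399)),
        complete=True,
    )
    reports = {
        r.record_id: r
        for r in filter_cascade([good, partial, motif_free, unrelated], small_dataset.panel)
    }
    assert reports["good"].kept and reports["good"].reason is None
    assert reports["partial"].reason == REASON_INCOMPLETE
    assert reports["motifless"].reason == REASON_NO_MOTIF
    assert reports["unrelated"].reason == REASON_MICROBIAL


def test_near_misses_surfaced_for_motif_failures(small_dataset):
    ref = small_dataset.panel.entries[0]
    mutated = ref.sequence.replace("C", "Y")
    (report,) = filter_cascade(
        [_rec("m", mutated, complete=True)], small_dataset.panel
    )
    assert report.reason == REASON_NO_MOTIF
    assert any(h.axial == "Y" for h in report.near_misses)


def test_kept_records_have_canonical_axial_cysteine(small_dataset):
    records = [
        ProteinRecord(r.record_id, r.sequence, r.site, True, True)
        for r in small_dataset.records
    ]
    reports = filter_cascade(records, small_dataset.panel)
    assert len(reports) == len(records)  # reports partition the input
    for rep in reports:
        if rep.kept:
            assert rep.motif_hits
            assert all(h.canonical and h.axial == "C" for h in rep.motif_hits)
        else:
            assert rep.reason in (REASON_INCOMPLETE, REASON_MICROBIAL, REASON_NO_MOTIF)


def test_cascade_rejections_match_generator_truth(small_dataset):
    """Per-stage rejection reasons equal the synthetic ground truth."""
    truth = small_dataset.truth.set_index("record_id")
    reports = {
        r.record_id: r for r in filter_cascade(small_dataset.records, small_dataset.panel)
    }
    for rid, row in truth.iterrows():
        if row.category == "incomplete":
            assert reports[rid].reason == REASON_INCOMPLETE
        elif row.category in ("known-subfamily", "new-subfamily", "new-family"):
            assert reports[rid].kept
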