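"""Generator determinism, identity bands, and truth-table fidelity."""

import filecmp

import numpy as np
import pytest

from cypminer.filters import find_heme_motifs
from cypminer.pairwise import global_align
from cypminer.screening import dereplicate
from cypminer.synthetic import (
    GenerationError,
    SyntheticConfig,
    generate,
    mutate_to_identity,
    write_synthetic_dataset,
)

from conftest import SMALL_CONFIG
from oracles import (
    blosum62_fn,
    enumerate_motifs,
    identity_from_columns,
    semiglobal_align,
)

_score = blosum62_fn()


def _oracle_identity(a, b):
    _, cols = semiglobal_align(a, b, _score)
    return identity_from_columns(cols, len(a), len(b))


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = SyntheticConfig(
        seed=9, n_families=2, subfamilies_per_family=2, ref_length=(100, 130),
        n_known_subfamily=2, n_new_subfamily=1, n_new_family=1, n_decoy=1,
        n_incomplete=1, n_duplicate=1,
    )
    a = write_synthetic_dataset(generate(cfg), tmp_path / "a")
    b = write_synthetic_dataset(generate(cfg), tmp_path / "b")
    for name in a:
        assert filecmp.cmp(a[name], b[name], shallow=False), name


def test_references_all_start_with_m_and_carry_one_motif(small_dataset):
    for entry in small_dataset.panel:
        assert entry.sequence.startswith("M")
        canonical = [h for h in find_heme_motifs(entry.sequence) if h.canonical]
        assert len(canonical) == 1
        # motif sits in the C-terminal third
        assert canonical[0].start >= len(entry.sequence) // 3


def test_cross_family_reference_identities_below_cutoff(small_dataset):
    """All cross-family pairwise identities verified by the independent DP
    oracle, not just by the generator's own aligner."""
    entries = list(small_dataset.panel)
    for i, a in enumerate(entries):
        for b in entries[i + 1 :]:
            if a.family == b.family:
                continue
            assert _oracle_identity(a.sequence, b.sequence) < 35.0


def test_within_family_subfamilies_in_band(small_dataset):
    cfg = SMALL_CONFIG
    by_family = {}
    for e in small_dataset.panel:
        by_family.setdefault(e.family, []).append(e)
    for family, members in by_family.items():
        founder = next(e for e in members if e.subfamily == "A")
        for other in members:
            if other.ref_id == founder.ref_id:
                continue
            ident = _oracle_identity(founder.sequence, other.sequence)
            assert cfg.band_new_subfamily[0] <= ident <= cfg.band_new_subfamily[1]


def test_generator_identities_agree_with_dp_oracle(small_dataset):
    """Truth-table identities match the brute-force oracle within 0.5 points."""
    panel = {e.ref_id: e.sequence for e in small_dataset.panel}
    recs = {r.record_id: r.sequence for r in small_dataset.records}
    checked = 0
    for row in small_dataset.truth.itertuples():
        if row.category not in ("known-subfamily", "new-subfamily", "new-family"):
            continue
        oracle = _oracle_identity(recs[row.record_id], panel[row.source])
        assert oracle == pytest.approx(row.realized_identity, abs=0.5)
        checked += 1
    assert checked >= 5


def test_realized_identities_inside_configured_bands(small_dataset):
    cfg = SMALL_CONFIG
    bands = {
        "known-subfamily": cfg.band_known,
        "new-subfamily": cfg.band_new_subfamily,
        "new-family": cfg.band_new_family,
    }
    for row in small_dataset.truth.itertuples():
        band = bands.get(row.category)
        if band is None:
            continue
        assert band[0] <= row.realized_identity <= band[1], row.record_id


def test_decoys_carry_no_canonical_motif(small_dataset):
    decoys = small_dataset.truth.query("category == 'decoy'")["record_id"]
    recs = {r.record_id: r.sequence for r in small_dataset.records}
    for rid in decoys:
        canonical, _ = enumerate_motifs(recs[rid])
        assert canonical == []


def test_no_decoys_config_yields_all_motif_positive():
    cfg = SyntheticConfig(
        seed=9, n_families=2, subfamilies_per_family=1, ref_length=(100, 130),
        n_known_subfamily=2, n_new_subfamily=1, n_new_family=1, n_decoy=0,
        n_incomplete=0, n_duplicate=0,
    )
    ds = generate(cfg)
    assert ds.truth.has_motif.all()


def test_duplicates_merge_with_their_sources(small_dataset):
    clusters = dereplicate(small_dataset.records)
    cluster_of = {m: c.seed_id for c in clusters for m in c.member_ids}
    dups = small_dataset.truth.query("category == 'duplicate'")
    assert len(dups) > 0
    for row in dups.itertuples():
        assert cluster_of[row.record_id] == cluster_of[row.source]


def test_incomplete_queries_flagged_partial(small_dataset):
    recs = {r.record_id: r for r in small_dataset.records}
    partials = small_dataset.truth.query("category == 'incomplete'")["record_id"]
    for rid in partials:
        assert recs[rid].complete is False


def test_band_straddling_threshold_rejected():
    with pytest.raises(ValueError, match="straddles"):
        SyntheticConfig(band_new_subfamily=(38.0, 43.0))


def test_mutate_to_identity_reaches_band_and_protects_motif(small_dataset):
    entry = small_dataset.panel.entries[0]
    span = small_dataset.ref_motif_spans[entry.ref_id]
    rng = np.random.default_rng(31)
    near, ident = mutate_to_identity(entry.sequence, (98.0, 100.0), [span], rng)
    assert ident >= 98.0
    assert near[span[0] : span[1]] == entry.sequence[span[0] : span[1]]
    far, ident2 = mutate_to_identity(entry.sequence, (43.0, 52.0), [span], rng)
    assert 43.0 <= ident2 <= 52.0
    assert global_align(far, entry.sequence).identity_pct == pytest.approx(ident2)
    assert far[span[0] : span[1]] == entry.sequence[span[0] : span[1]]
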