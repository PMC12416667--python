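"""Family/subfamily threshold calls, name allocation, registry bookkeeping."""

import numpy as np
import pytest

from cypminer.nomenclature import (
    NOVELTY_KNOWN,
    NOVELTY_NEW_FAMILY,
    NOVELTY_NEW_SUBFAMILY,
    NameRegistry,
    RegistryError,
    Thresholds,
    best_reference_hit,
    classify_all,
    _panel_targets,
)
from cypminer.sequence_io import ProteinRecord, ReferenceEntry, ReferencePanel

AA = "ACDEFGHIKLMNPQRSTVWY"


def _panel(*entries):
    return ReferencePanel(
        entries=[
            ReferenceEntry(ref_id=r, sequence=s, family=f, subfamily=sub)
            for r, s, f, sub in entries
        ]
    )


def _rec(rid, seq):
    return ProteinRecord(record_id=rid, sequence=seq, site="s1")


def _seq_with_identity(base: str, n_matches: int) -> str:
    """A sequence sharing exactly ``n_matches`` positions with ``base``.

    Mismatching positions use I<->V (a positive BLOSUM62 pair) so the
    optimal semi-global alignment stays ungapped and full length.
    """
    assert set(base[n_matches:]) == {"I"}
    return base[:n_matches] + "V" * (len(base) - n_matches)


BASE = "MKTAYRLEDWHQNS" + "I" * 26  # 40 residues, the I-tail is mutable


def test_exact_threshold_identities_fall_to_lower_category():
    panel = _panel(("ref", BASE, "CYP107", "PH"))
    cases = [
        (24, NOVELTY_KNOWN),          # 24/40 = 60% > 55
        (22, NOVELTY_NEW_SUBFAMILY),  # 55% exactly: strict
        (18, NOVELTY_NEW_SUBFAMILY),  # 45%
        (16, NOVELTY_NEW_FAMILY),     # 40% exactly: strict
        (14, NOVELTY_NEW_FAMILY),     # 35%
    ]
    for n_match, expected in cases:
        query = _rec(f"q{n_match}", _seq_with_identity(BASE, n_match))
        results, _, _ = classify_all([query], panel)
        assert results[0].novelty == expected, (n_match, results[0].identity_pct)


def test_known_subfamily_inherits_family_and_subfamily():
    panel = _panel(("ref", BASE, "CYP107", "PH"))
    query = _rec("q", _seq_with_identity(BASE, 30))  # 75%
    results, _, _ = classify_all([query], panel)
    (r,) = results
    assert (r.family, r.subfamily, r.allele) == ("CYP107", "PH", 1)
    assert r.name == "CYP107PH1"
    assert r.best_hit_id == "ref"


def test_new_subfamily_gets_next_free_letter():
    panel = _panel(("ref", BASE, "CYP107", "B"))
    query = _rec("q", _seq_with_identity(BASE, 20))  # 50%
    results, _, _ = classify_all([query], panel)
    (r,) = results
    assert r.family == "CYP107" and r.subfamily == "A"  # A unused, allocated first
    assert r.name == "CYP107A1"


def test_equidistant_references_tie_broken_lexicographically():
    panel = _panel(("refB", BASE, "CYP107", "PH"), ("refA", BASE, "CYP108", "A"))
    target, ident = best_reference_hit(BASE, _panel_targets(panel))
    assert ident == 100.0
    assert target.target_id == "refA"


def test_mutually_identical_novel_queries_share_new_family():
    panel = _panel(("ref", BASE, "CYP107", "A"))
    rng = np.random.default_rng(23)
    novel = "M" + "".join(AA[i] for i in rng.integers(0, 20, size=120))
    results, _, _ = classify_all([_rec("n1", novel), _rec("n2", novel)], panel)
    names = sorted(r.name for r in results)
    assert names == ["CYP9001A1", "CYP9001A2"]


def test_chained_queries_can_join_newly_created_groups(small_dataset):
    """Novelty categories recovered exactly on margin-banded synthetic data."""
    truth = small_dataset.truth.set_index("record_id")
    eligible = [
        r
        for r in small_dataset.records
        if truth.loc[r.record_id].category
        in (NOVELTY_KNOWN, NOVELTY_NEW_SUBFAMILY, NOVELTY_NEW_FAMILY)
    ]
    results, registry, summary = classify_all(eligible, small_dataset.panel)
    assert len(results) == len(eligible)
    for r in results:
        assert r.novelty == truth.loc[r.record_id].category
    assert summary.n_new_families == int((truth.category == NOVELTY_NEW_FAMILY).sum())


def test_query_order_does_not_change_categories_or_groups(small_dataset):
    truth = small_dataset.truth.set_index("record_id")
    eligible = [
        r
        for r in small_dataset.records
        if truth.loc[r.record_id].category
        in (NOVELTY_KNOWN, NOVELTY_NEW_SUBFAMILY, NOVELTY_NEW_FAMILY)
    ]
    first, _, _ = classify_all(eligible, small_dataset.panel)
    second, _, _ = classify_all(list(reversed(eligible)), small_dataset.panel)

    def partition(results):
        groups = {}
        for r in results:
            groups.setdefault(r.family, set()).add(r.record_id)
        return {frozenset(v) for v in groups.values()}

    assert {r.record_id: r.novelty for r in first} == {
        r.record_id: r.novelty for r in second
    }
    assert partition(first) == partition(second)


def test_near_threshold_queries_trigger_order_dependence_warning():
    panel = _panel(("ref", BASE, "CYP107", "PH"))
    query = _rec("edge", _seq_with_identity(BASE, 22))  # exactly 55%
    with pytest.warns(UserWarning, match="order-dependent.*edge"):
        classify_all([query], panel)


def test_empty_query_set_leaves_registry_unchanged():
    panel = _panel(("ref", BASE, "CYP107", "PH"))
    results, registry, summary = classify_all([], panel)
    assert results == [] and summary.n_classified == 0
    assert registry.family_numbers == [107]
    assert registry.subfamilies(107) == {"PH"}


# --- registry --------------------------------------------------------------


def test_novel_family_numbering_from_private_base():
    reg = NameRegistry(novel_family_base=9001)
    assert reg.next_family_number() == 9001
    assert reg.allocate(9001, "A") == "CYP9001A1"
    assert reg.next_family_number() == 9002


def test_subfamily_letters_extend_past_single_characters():
    reg = NameRegistry()
    import string

    for letter in string.ascii_uppercase:
        reg.allocate(107, letter)
    assert reg.next_subfamily_letters(107) == "AA"


def test_allele_numbers_increment_within_subfamily():
    reg = NameRegistry()
    assert reg.allocate(107, "PH") == "CYP107PH1"
    assert reg.allocate(107, "PH") == "CYP107PH2"
    assert reg.allocate(107, "PH") == "CYP107PH3"


def test_registry_roundtrips_through_json(tmp_path):
    reg = NameRegistry()
    reg.allocate(107, "PH")
    reg.allocate(9001, "A")
    path = tmp_path / "registry.json"
    reg.save(path)
    back = NameRegistry.load(path)
    assert back.to_dict() == reg.to_dict()
    assert back.allocate(107, "PH") == "CYP107PH2"


def test_corrupted_registry_raises_on_duplicate_allocation():
    reg = NameRegistry()
    reg.allocate(107, "A")
    reg._next_allele[(107, "A")] = 1  # simulate corruption
    with pytest.raises(RegistryError):
        reg.allocate(107, "A")


def test_threshold_validation():
    with pytest.raises(ValueError):
        Thresholds(family_min=60, subfamily_min=55)
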