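"""Synthetic reference panels and query sets with known ground truth.

Real metagenome-derived protein catalogues are far too large (and too
unlabelled) to test a mining pipeline against, so this module generates the
statistical structure the analysis assumes, with every property controlled:

* a reference panel organized into families and subfamilies whose pairwise
  identities respect the 40%/55% nomenclature thresholds (families mutually
  below 35% identity, subfamilies within a family in the 43-52% band);
* query proteins per category — members of known subfamilies (62-90%
  identity to a reference), founders of new subfamilies (43-52%), founders
  of new families (remote homologs at 28-35%: related enough to survive an
  alignment screen, below 40% to everything named), non-P450 decoys,
  truncated (incomplete) sequences, and exact/partial duplicates for
  dereplication;
* a truth table recording each query's category, source, realized identity
  (measured with the package's own aligner at generation time), motif
  content, completeness and site label.

Identity bands deliberately keep at least 3 points of margin from the 40 and
55 cut-offs so category recovery is well-posed; the :data:`ADVERSARIAL_BANDS`
preset instead generates near-threshold cases to exercise the
order-dependence warning. All randomness flows from one integer seed through
numpy's Generator, so a fixed seed gives byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .filters import find_heme_motifs
from .pairwise import AlignParams, DEFAULT_PARAMS, global_align
from .sequence_io import (
    ProteinRecord,
    ReferenceEntry,
    ReferencePanel,
    write_protein_fasta,
    write_reference_panel,
)

#: 20 canonical residues; uniform composition for random sequences.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CATEGORY_KNOWN = "known-subfamily"
CATEGORY_NEW_SUBFAMILY = "new-subfamily"
CATEGORY_NEW_FAMILY = "new-family"
CATEGORY_DECOY = "decoy"
CATEGORY_INCOMPLETE = "incomplete"
CATEGORY_DUPLICATE = "duplicate"

TRUTH_COLUMNS = [
    "record_id",
    "category",
    "source",
    "realized_identity",
    "has_motif",
    "is_complete",
    "site",
]

#: near-threshold bands for sensitivity (order-dependence) experiments
ADVERSARIAL_BANDS = {"known": (56.0, 60.0), "new_subfamily": (41.0, 44.0)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the package's study conditions."""

    seed: int = 17
    n_families: int = 4
    subfamilies_per_family: int = 2
    ref_length: tuple[int, int] = (380, 480)
    n_known_subfamily: int = 12
    n_new_subfamily: int = 8
    n_new_family: int = 6
    n_decoy: int = 6
    n_incomplete: int = 4
    n_duplicate: int = 6
    band_known: tuple[float, float] = (62.0, 90.0)
    band_new_subfamily: tuple[float, float] = (43.0, 52.0)
    #: new-family queries are remote homologs: related enough to pass the
    #: screen, but below the 40% family threshold to everything named
    band_new_family: tuple[float, float] = (28.0, 35.0)
    max_new_family_identity: float = 35.0
    family_number_base: int = 501
    sites: tuple[str, ...] = (
        "Armutlu",
        "Balya",
        "Gomec",
        "Hisaralan",
        "Lake Acigol",
        "Tuz Golu",
    )

    def __post_init__(self) -> None:
        for lo, hi in (self.band_known, self.band_new_subfamily, self.band_new_family):
            if lo > hi:
                raise ValueError("band bounds out of order")
            for cut in (40.0, 55.0):
                if lo <= cut <= hi:
                    raise ValueError(f"band ({lo}, {hi}) straddles the {cut}% threshold")


@dataclass
class SyntheticDataset:
    panel: ReferencePanel
    records: list[ProteinRecord]
    truth: pd.DataFrame
    ref_motif_spans: dict[str, tuple[int, int]]


class GenerationError(RuntimeError):
    """Raised when a configuration cannot be satisfied in bounded retries."""


# ---------------------------------------------------------------------------
# primitive generators


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.integers(0, len(AMINO_ACIDS), size=length - 1)
    return "M" + "".join(AMINO_ACIDS[i] for i in body)


def _random_motif(rng: np.random.Generator) -> str:
    n = int(rng.integers(2, 6))
    m = int(rng.integers(3, 7))
    spacer = lambda k: "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=k))
    bridge = "GA"[int(rng.integers(0, 2))]
    return f"F{spacer(n)}{bridge}{spacer(m)}C{spacer(1)}G"


def _count_canonical(seq: str) -> int:
    return sum(1 for h in find_heme_motifs(seq) if h.canonical)


def _protein_with_one_motif(
    rng: np.random.Generator, length: int, max_attempts: int = 200
) -> tuple[str, tuple[int, int]]:
    """A random protein with exactly one canonical motif, in its C-terminal
    third. Returns the sequence and the motif span (0-based half-open)."""
    for _ in range(max_attempts):
        backbone = _random_protein(rng, length)
        motif = _random_motif(rng)
        lo = max(1, 2 * length // 3)
        hi = length - len(motif)
        if hi <= lo:
            raise GenerationError("reference length too short for motif placement")
        pos = int(rng.integers(lo, hi + 1))
        seq = backbone[:pos] + motif + backbone[pos + len(motif) :]
        if _count_canonical(seq) == 1:
            return seq, (pos, pos + len(motif))
    raise GenerationError("could not place exactly one canonical motif")


def _protein_without_motif(
    rng: np.random.Generator, length: int, max_attempts: int = 200
) -> str:
    for _ in range(max_attempts):
        seq = _random_protein(rng, length)
        if _count_canonical(seq) == 0:
            return seq
    raise GenerationError("could not generate a motif-free decoy")


# ---------------------------------------------------------------------------
# identity-controlled mutation


def _apply_indels(
    sequence: str,
    protected: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    n_indels: int,
) -> tuple[str, list[tuple[int, int]]]:
    """Apply up to n short (<=3 residue) indels outside protected spans,
    shifting the spans accordingly."""
    seq = sequence
    spans = [tuple(s) for s in protected]
    for _ in range(n_indels):
        size = int(rng.integers(1, 4))
        deletion = bool(rng.integers(0, 2))
        for _ in range(50):
            pos = int(rng.integers(1, len(seq) - size))
            window = (pos, pos + (size if deletion else 0))
            if all(window[1] <= s or window[0] >= e for s, e in spans):
                break
        else:
            continue
        if deletion:
            seq = seq[:pos] + seq[pos + size :]
            spans = [
                (s - size, e - size) if s >= pos + size else (s, e) for s, e in spans
            ]
        else:
            insert = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=size))
            seq = seq[:pos] + insert + seq[pos:]
            spans = [(s + size, e + size) if s >= pos else (s, e) for s, e in spans]
    return seq, spans


def mutate_to_identity(
    sequence: str,
    band: tuple[float, float],
    protected: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    n_indels: int = 0,
    params: AlignParams = DEFAULT_PARAMS,
    max_attempts: int = 8,
) -> tuple[str, float]:
    """Mutate ``sequence`` until its semi-global identity to the original
    falls in ``band``.

    Substitutions are applied outside the protected spans (position 0 is
    always protected); the number of substituted positions is found by
    binary search on the measured identity. Optional short indels are
    applied first. Returns ``(mutant, realized_identity)``.
    """
    lo, hi = band
    for _ in range(max_attempts):
        seq, spans = _apply_indels(sequence, protected, rng, n_indels)
        blocked = {0}
        for s, e in spans:
            blocked.update(range(s, e))
        mutable = np.array([i for i in range(len(seq)) if i not in blocked])
        order = mutable[rng.permutation(len(mutable))]
        offsets = rng.integers(1, 20, size=len(order))  # replacement != original
        replacements = [
            AMINO_ACIDS[(AMINO_ACIDS.index(seq[p]) + o) % 20]
            for p, o in zip(order, offsets)
        ]

        def variant(k: int) -> str:
            arr = list(seq)
            for p, r in zip(order[:k], replacements[:k]):
                arr[p] = r
            return "".join(arr)

        low_k, high_k = 0, len(order)
        while low_k <= high_k:
            k = (low_k + high_k) // 2
            mutant = variant(k)
            ident = global_align(mutant, sequence, params).identity_pct
            if ident > hi:
                low_k = k + 1
            elif ident < lo:
                high_k = k - 1
            else:
                return mutant, ident
    raise GenerationError(f"identity band {band} not reached in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# panel and query-set construction


def _max_identity(seq: str, others: Sequence[str], params: AlignParams) -> float:
    if not others:
        return 0.0
    return max(global_align(seq, o, params).identity_pct for o in others)


def make_reference_panel(
    config: SyntheticConfig, params: AlignParams = DEFAULT_PARAMS
) -> tuple[ReferencePanel, dict[str, tuple[int, int]]]:
    """Build the labelled panel plus the motif span of each reference.

    Family founders are mutually below ``max_new_family_identity``; extra
    subfamilies are identity-controlled mutants of their founder inside the
    new-subfamily band. Offending draws are resampled a bounded number of
    times.
    """
    rng = np.random.default_rng(config.seed)
    entries: list[ReferenceEntry] = []
    motif_spans: dict[str, tuple[int, int]] = {}
    accepted: list[tuple[str, str]] = []  # (family, sequence) of every reference so far
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for fam_idx in range(config.n_families):
        family = f"CYP{config.family_number_base + fam_idx}"
        length = int(rng.integers(config.ref_length[0], config.ref_length[1] + 1))
        founder = None
        for _ in range(50):
            seq, span = _protein_with_one_motif(rng, length)
            foreign = [s for _, s in accepted]
            if _max_identity(seq, foreign, params) < config.max_new_family_identity:
                founder, founder_span = seq, span
                break
        if founder is None:
            raise GenerationError("could not separate family founders")
        fam_refs = [(f"{family}A_ref", founder, founder_span, "A")]
        for sub_idx in range(1, config.subfamilies_per_family):
            sub = letters[sub_idx]
            for _ in range(50):
                mutant, _ident = mutate_to_identity(
                    founder,
                    config.band_new_subfamily,
                    [founder_span],
                    rng,
                    n_indels=int(rng.integers(0, 3)),
                    params=params,
                )
                foreign = [s for fam, s in accepted if fam != family]
                if (
                    _count_canonical(mutant) == 1
                    and _max_identity(mutant, foreign, params)
                    < config.max_new_family_identity
                ):
                    hit = next(h for h in find_heme_motifs(mutant) if h.canonical)
                    fam_refs.append(
                        (f"{family}{sub}_ref", mutant, (hit.start, hit.start + len(hit.matched)), sub)
                    )
                    break
            else:
                raise GenerationError("could not carve a subfamily reference")
        accepted.extend((family, seq) for _, seq, _, _ in fam_refs)
        for ref_id, seq, span, sub in fam_refs:
            entries.append(
                ReferenceEntry(
                    ref_id=ref_id,
                    sequence=seq,
                    family=family,
                    subfamily=sub,
                    is_microbial=True,
                )
            )
            motif_spans[ref_id] = span
    return ReferencePanel(entries=entries), motif_spans


def _derive_query(
    ref: ReferenceEntry,
    span: tuple[int, int],
    band: tuple[float, float],
    panel: ReferencePanel,
    rng: np.random.Generator,
    params: AlignParams,
    require_band_overall: bool,
    n_indels: int,
    max_attempts: int = 30,
) -> tuple[str, float]:
    """Mutant of a reference whose *best* panel identity behaves correctly.

    For new-subfamily queries (``require_band_overall``) the maximum identity
    over the whole panel must itself lie inside the band; for known-subfamily
    queries the best hit must simply stay in the source family.
    """
    others = [e for e in panel if e.ref_id != ref.ref_id]
    for _ in range(max_attempts):
        # aim at a narrow sub-band so realized identities spread over the band
        if band[1] - band[0] > 4:
            centre = rng.uniform(band[0] + 2, band[1] - 2)
            target = (max(band[0], centre - 2), min(band[1], centre + 2))
        else:
            target = band
        mutant, ident = mutate_to_identity(
            ref.sequence, target, [span], rng, n_indels=n_indels, params=params
        )
        if _count_canonical(mutant) < 1:
            continue
        other_best = _max_identity(mutant, [e.sequence for e in others], params)
        if require_band_overall:
            if other_best <= ident and band[0] <= max(ident, other_best) <= band[1]:
                return mutant, ident
        else:
            best_entry = max(
                panel,
                key=lambda e: global_align(mutant, e.sequence, params).identity_pct,
            )
            if best_entry.family == ref.family:
                return mutant, ident
    raise GenerationError("could not derive a query inside its identity band")


def make_query_set(
    panel: ReferencePanel,
    motif_spans: dict[str, tuple[int, int]],
    config: SyntheticConfig,
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate the query records and their truth table."""
    rng = np.random.default_rng(config.seed + 1)
    refs = sorted(panel, key=lambda e: e.ref_id)
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    site_cycle = 0

    def next_site() -> str:
        nonlocal site_cycle
        site = config.sites[site_cycle % len(config.sites)]
        site_cycle += 1
        return site

    def add(record_id, sequence, category, source, ident, complete_flag, site=None):
        site = site or next_site()
        records.append(
            ProteinRecord(
                record_id=record_id,
                sequence=sequence,
                site=site,
                complete=complete_flag,
                stop_seen=bool(complete_flag),
            )
        )
        truth_rows.append(
            {
                "record_id": record_id,
                "category": category,
                "source": source,
                "realized_identity": round(ident, 2) if ident == ident else ident,
                "has_motif": _count_canonical(sequence) > 0,
                "is_complete": bool(complete_flag),
                "site": site,
            }
        )

    for i in range(config.n_known_subfamily):
        ref = refs[i % len(refs)]
        seq, ident = _derive_query(
            ref, motif_spans[ref.ref_id], config.band_known, panel, rng, params,
            require_band_overall=False, n_indels=int(rng.integers(0, 2)),
        )
        add(f"q_known_{i:02d}", seq, CATEGORY_KNOWN, ref.ref_id, ident, True)

    for i in range(config.n_new_subfamily):
        ref = refs[i % len(refs)]
        seq, ident = _derive_query(
            ref, motif_spans[ref.ref_id], config.band_new_subfamily, panel, rng, params,
            require_band_overall=True, n_indels=int(rng.integers(0, 3)),
        )
        add(f"q_newsub_{i:02d}", seq, CATEGORY_NEW_SUBFAMILY, ref.ref_id, ident, True)

    new_family_seqs: list[str] = []
    for i in range(config.n_new_family):
        ref = refs[i % len(refs)]
        for _ in range(50):
            seq, ident = mutate_to_identity(
                ref.sequence,
                config.band_new_family,
                [motif_spans[ref.ref_id]],
                rng,
                n_indels=int(rng.integers(0, 3)),
                params=params,
            )
            all_named = [e.sequence for e in refs] + new_family_seqs
            if (
                _count_canonical(seq) >= 1
                and _max_identity(seq, all_named, params) <= config.max_new_family_identity
            ):
                break
        else:
            raise GenerationError("could not isolate a new-family query")
        new_family_seqs.append(seq)
        add(f"q_newfam_{i:02d}", seq, CATEGORY_NEW_FAMILY, ref.ref_id, ident, True)

    for i in range(config.n_decoy):
        length = int(rng.integers(config.ref_length[0], config.ref_length[1] + 1))
        seq = _protein_without_motif(rng, length)
        add(f"q_decoy_{i:02d}", seq, CATEGORY_DECOY, "", float("nan"), True)

    for i in range(config.n_incomplete):
        ref = refs[i % len(refs)]
        seq, ident = _derive_query(
            ref, motif_spans[ref.ref_id], config.band_known, panel, rng, params,
            require_band_overall=False, n_indels=0,
        )
        if i % 2 == 0:
            # drop the N-terminus (start lost)
            cut = int(rng.integers(20, max(21, len(seq) // 5)))
            truncated = seq[cut:]
        else:
            # cut ahead of the motif (heme region lost)
            hit = next(h for h in find_heme_motifs(seq) if h.canonical)
            truncated = seq[: hit.start]
        add(f"q_partial_{i:02d}", truncated, CATEGORY_INCOMPLETE, ref.ref_id, ident, False)

    # duplicates reference the already-generated eligible queries
    eligible = [r for r in records if r.record_id.startswith(("q_known", "q_newsub", "q_newfam"))]
    for i in range(config.n_duplicate):
        src = eligible[i % len(eligible)]
        if i % 2 == 0:
            dup_seq = src.sequence
        else:
            keep = int(np.ceil(0.85 * src.length))
            dup_seq = src.sequence[:keep]
        add(f"zdup_{i:02d}", dup_seq, CATEGORY_DUPLICATE, src.record_id, 100.0, True,
            site=src.site)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return records, truth


def generate(
    config: SyntheticConfig = SyntheticConfig(), params: AlignParams = DEFAULT_PARAMS
) -> SyntheticDataset:
    """Generate the full dataset (panel + queries + truth) for a config."""
    panel, spans = make_reference_panel(config, params)
    records, truth = make_query_set(panel, spans, config, params)
    return SyntheticDataset(panel=panel, records=records, truth=truth, ref_motif_spans=spans)


def write_synthetic_dataset(
    dataset: SyntheticDataset, out_dir: str | Path
) -> dict[str, Path]:
    """Write the dataset in exactly the formats :mod:`cypminer.sequence_io`
    reads, plus the truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "queries": out / "queries.fasta",
        "metadata": out / "metadata.tsv",
        "panel_fasta": out / "panel.fasta",
        "panel_labels": out / "panel_labels.tsv",
        "truth": out / "truth.tsv",
    }
    write_protein_fasta(dataset.records, paths["queries"], paths["metadata"])
    write_reference_panel(dataset.panel, paths["panel_fasta"], paths["panel_labels"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
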