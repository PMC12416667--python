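"""Post-screen filter cascade: completeness, microbial identity, heme motif.

The cascade reproduces the filtering logic applied between P450 candidate
discovery and classification: only theoretically complete ORFs are kept, a
candidate must reach at least 20% identity to a microbial reference P450, and
it must contain the consensus heme-binding motif

    F(x)n G/A (x)m C x G      with n in 2..5 and m in 3..6,

whose cysteine is the axial heme ligand. Windows matching everything except
the axial cysteine are reported as near-misses (natural Cys substitutions,
e.g. Cys->Tyr, are known but are never counted as canonical motifs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .pairwise import AlignParams, DEFAULT_PARAMS, global_align
from .sequence_io import ProteinRecord, ReferencePanel

logger = logging.getLogger(__name__)

REASON_INCOMPLETE = "incomplete"
REASON_MICROBIAL = "below-20%-microbial-identity"
REASON_NO_MOTIF = "no-heme-motif"

#: Cascade order; first failure is recorded.
STAGES = (REASON_INCOMPLETE, REASON_MICROBIAL, REASON_NO_MOTIF)


@dataclass(frozen=True)
class MotifHit:
    """One heme-motif window. ``start`` is the 0-based position of the F."""

    start: int
    n: int
    m: int
    bridge: str
    axial: str
    matched: str
    canonical: bool


@dataclass(frozen=True)
class FilterConfig:
    n_range: tuple[int, int] = (2, 5)
    m_range: tuple[int, int] = (3, 6)
    min_microbial_identity: float = 20.0
    min_microbial_coverage: float = 50.0


@dataclass(frozen=True)
class FilterReport:
    record_id: str
    kept: bool
    reason: Optional[str]
    motif_hits: tuple[MotifHit, ...] = ()
    near_misses: tuple[MotifHit, ...] = ()
    best_microbial_ref: Optional[str] = None
    best_microbial_identity: Optional[float] = None


def is_complete(record: ProteinRecord) -> bool:
    """Completeness of the underlying ORF.

    An explicit gene-caller flag wins; with no evidence we fall back to the
    sequence itself: initial methionine plus a stop marker seen at ingest.
    """
    if record.complete is not None:
        return record.complete
    return record.sequence.startswith("M") and record.stop_seen


def find_heme_motifs(
    sequence: str,
    n_range: tuple[int, int] = (2, 5),
    m_range: tuple[int, int] = (3, 6),
) -> list[MotifHit]:
    """All windows matching F(x)n G/A (x)m C x G for any (n, m) in range.

    Canonical hits have C at the axial position; near-misses match every
    fixed position except the axial one. Overlapping windows with different
    spacers are all reported.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    hits: list[MotifHit] = []
    length = len(sequence)
    for i, ch in enumerate(sequence):
        if ch != "F":
            continue
        for n in range(n_range[0], n_range[1] + 1):
            bridge_pos = i + n + 1
            if bridge_pos >= length or sequence[bridge_pos] not in "GA":
                continue
            for m in range(m_range[0], m_range[1] + 1):
                g_pos = i + n + m + 4
                if g_pos >= length or sequence[g_pos] != "G":
                    continue
                axial = sequence[i + n + m + 2]
                hits.append(
                    MotifHit(
                        start=i,
                        n=n,
                        m=m,
                        bridge=sequence[bridge_pos],
                        axial=axial,
                        matched=sequence[i : g_pos + 1],
                        canonical=axial == "C",
                    )
                )
    return hits


def passes_microbial_identity(
    record: ProteinRecord,
    panel: ReferencePanel,
    params: AlignParams = DEFAULT_PARAMS,
    min_identity: float = 20.0,
    min_coverage: float = 50.0,
) -> tuple[bool, Optional[str], Optional[float]]:
    """Best semi-global identity against microbial panel entries.

    Passes iff the best identity is >= ``min_identity`` (inclusive — "at
    least 20%") with both coverages >= ``min_coverage``. Returns
    ``(passed, best_ref_id, best_identity)``; the best hit is reported even
    when it fails.
    """
    microbial = panel.microbial()
    if not microbial:
        raise ValueError("panel has no microbial entries")
    best_id = None
    best_ref = None
    best_pass = False
    for entry in sorted(microbial, key=lambda e: e.ref_id):
        res = global_align(record.sequence, entry.sequence, params)
        ok = (
            res.identity_pct >= min_identity
            and res.query_coverage_pct >= min_coverage
            and res.subject_coverage_pct >= min_coverage
        )
        if best_id is None or res.identity_pct > best_id:
            best_id, best_ref, best_pass = res.identity_pct, entry.ref_id, ok
        elif res.identity_pct == best_id and ok and not best_pass:
            best_ref, best_pass = entry.ref_id, ok
    return best_pass, best_ref, best_id


def filter_cascade(
    records: Iterable[ProteinRecord],
    panel: ReferencePanel,
    config: FilterConfig = FilterConfig(),
    params: AlignParams = DEFAULT_PARAMS,
) -> list[FilterReport]:
    """Apply completeness -> microbial identity -> motif, in that order.

    The first failing stage is recorded as the rejection reason; per-stage
    counts are logged so the funnel shape of a run is machine-readable.
    """
    reports: list[FilterReport] = []
    counts = {stage: 0 for stage in STAGES}
    kept = 0
    for record in records:
        if not is_complete(record):
            counts[REASON_INCOMPLETE] += 1
            reports.append(
                FilterReport(record_id=record.record_id, kept=False, reason=REASON_INCOMPLETE)
            )
            continue
        ok, ref, ident = passes_microbial_identity(
            record,
            panel,
            params,
            min_identity=config.min_microbial_identity,
            min_coverage=config.min_microbial_coverage,
        )
        if not ok:
            counts[REASON_MICROBIAL] += 1
            reports.append(
                FilterReport(
                    record_id=record.record_id,
                    kept=False,
                    reason=REASON_MICROBIAL,
                    best_microbial_ref=ref,
                    best_microbial_identity=ident,
                )
            )
            continue
        motifs = find_heme_motifs(record.sequence, config.n_range, config.m_range)
        canonical = tuple(h for h in motifs if h.canonical)
        near = tuple(h for h in motifs if not h.canonical)
        if not canonical:
            counts[REASON_NO_MOTIF] += 1
            reports.append(
                FilterReport(
                    record_id=record.record_id,
                    kept=False,
                    reason=REASON_NO_MOTIF,
                    near_misses=near,
                    best_microbial_ref=ref,
                    best_microbial_identity=ident,
                )
            )
            continue
        kept += 1
        reports.append(
            FilterReport(
                record_id=record.record_id,
                kept=True,
                reason=None,
                motif_hits=canonical,
                near_misses=near,
                best_microbial_ref=ref,
                best_microbial_identity=ident,
            )
        )
    logger.info(
        "filter cascade: kept=%d incomplete=%d below-identity=%d no-motif=%d",
        kept,
        counts[REASON_INCOMPLETE],
        counts[REASON_MICROBIAL],
        counts[REASON_NO_MOTIF],
    )
    return reports
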