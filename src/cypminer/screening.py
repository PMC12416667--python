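"""Dereplication and reference-panel screening of candidate proteins.

Dereplication collapses redundant proteins greedily, longest first: a record
joins an existing cluster iff a 100%-identity local alignment to the cluster
seed covers at least 80% of the record's own length. A 100%-identity local
alignment can contain no gap columns (a gap column would drop identity below
100), so the maximal such alignment is the longest common substring, which is
what we compute. X (unknown residue) matches nothing.

Screening aligns every record locally against every panel entry and applies
blastp-style thresholds (E-value, query/subject coverage, identity over the
local span).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .pairwise import AlignParams, DEFAULT_PARAMS, local_align
from .sequence_io import ProteinRecord, ReferencePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Cluster:
    """One dereplication cluster; the seed is a longest member."""

    seed_id: str
    member_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class ScreenThresholds:
    """Pass criteria of the reference screen (all must hold)."""

    max_evalue: float = 1e-5
    min_query_cover: float = 50.0
    min_subject_cover: float = 50.0
    min_identity: float = 15.0


@dataclass(frozen=True)
class ScreenHit:
    """Best reference hit for one record plus the pass/fail verdict."""

    record_id: str
    ref_id: Optional[str]
    identity_pct: Optional[float]
    query_coverage_pct: Optional[float]
    subject_coverage_pct: Optional[float]
    evalue: Optional[float]
    score: float
    passed: bool
    failed_criteria: tuple[str, ...] = ()


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact common substring; X never matches."""
    if not a or not b:
        return 0
    arr_a = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    x = ord("X")
    prev = np.zeros(arr_b.size, dtype=np.int32)
    best = 0
    for ca in arr_a:
        eq = (arr_b == ca) & (arr_b != x)
        cur = eq.astype(np.int32)
        cur[1:] += np.where(eq[1:], prev[:-1], 0)
        run = int(cur.max()) if cur.size else 0
        if run > best:
            best = run
        prev = cur
    return best


def dereplicate(
    records: Sequence[ProteinRecord],
    min_overlap_pct: float = 80.0,
    relative_to: str = "member",
) -> list[Cluster]:
    """Greedy longest-first clustering at 100% identity.

    ``relative_to`` selects the denominator of the overlap fraction: the
    joining record's own length (``"member"``, default) or the seed's
    (``"seed"``). Output order is deterministic: seeds by descending length,
    ties by record id.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if relative_to not in {"member", "seed"}:
        raise ValueError("relative_to must be 'member' or 'seed'")
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique")

    ordered = sorted(records, key=lambda r: (-r.length, r.record_id))
    seeds: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        placed = False
        for idx, seed in enumerate(seeds):
            overlap = longest_common_substring(rec.sequence, seed.sequence)
            denom = rec.length if relative_to == "member" else seed.length
            if 100.0 * overlap / denom >= min_overlap_pct:
                members[idx].append(rec.record_id)
                placed = True
                break
        if not placed:
            seeds.append(rec)
            members.append([rec.record_id])
    return [
        Cluster(seed_id=s.record_id, member_ids=tuple(m))
        for s, m in zip(seeds, members)
    ]


def _span_length(span: Optional[tuple[int, int]]) -> int:
    return 0 if span is None else span[1] - span[0]


def screen_candidates(
    records: Iterable[ProteinRecord],
    panel: ReferencePanel,
    params: AlignParams = DEFAULT_PARAMS,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[ScreenHit]:
    """Align each record locally to every panel entry and flag passes.

    The best hit per record has the lowest E-value (ties: highest identity,
    then longest aligned span, then lexicographic reference id). The E-value
    search space is query residues x total panel residues.
    """
    if len(panel) == 0:
        raise ValueError("reference panel must be non-empty")
    db = panel.total_residues
    hits: list[ScreenHit] = []
    for rec in records:
        best = None
        best_key = None
        for entry in panel:
            res = local_align(rec.sequence, entry.sequence, params, db_residues=db)
            if not res.is_hit:
                continue
            key = (
                res.evalue,
                -res.identity_pct,
                -_span_length(res.query_span),
                entry.ref_id,
            )
            if best_key is None or key < best_key:
                best, best_key = (entry, res), key
        if best is None:
            hits.append(
                ScreenHit(
                    record_id=rec.record_id,
                    ref_id=None,
                    identity_pct=None,
                    query_coverage_pct=None,
                    subject_coverage_pct=None,
                    evalue=None,
                    score=0.0,
                    passed=False,
                    failed_criteria=("no-alignment",),
                )
            )
            continue
        entry, res = best
        failed = []
        if res.evalue > thresholds.max_evalue:
            failed.append("evalue")
        if res.query_coverage_pct < thresholds.min_query_cover:
            failed.append("query-cover")
        if res.subject_coverage_pct < thresholds.min_subject_cover:
            failed.append("subject-cover")
        if res.identity_pct < thresholds.min_identity:
            failed.append("identity")
        hits.append(
            ScreenHit(
                record_id=rec.record_id,
                ref_id=entry.ref_id,
                identity_pct=res.identity_pct,
                query_coverage_pct=res.query_coverage_pct,
                subject_coverage_pct=res.subject_coverage_pct,
                evalue=res.evalue,
                score=res.score,
                passed=not failed,
                failed_criteria=tuple(failed),
            )
        )
    return hits
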