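"""Pairwise protein alignment: the computational core of every screening stage.

Two alignment flavours are exposed:

* :func:`global_align` — semi-global (terminal gaps free) alignment used for
  the nomenclature identity definition. CYP nomenclature compares
  near-full-length proteins, so terminal overhangs are neither penalized nor
  counted in the identity denominator.
* :func:`local_align` — Smith–Waterman local alignment with a Karlin–Altschul
  E-value, mirroring the semantics of a blastp-style reference screen
  (query/subject coverage, identity over the local span).

Semi-global percent identity is 100 x identical aligned pairs / denominator,
where the denominator is the number of aligned columns (internal gap columns
included, terminal overhangs excluded) or the length of the shorter sequence,
whichever is larger. Without the shorter-sequence floor the definition
degenerates for unrelated proteins: free terminal gaps make a tiny
perfect-match overlap the optimal alignment, which would read as 100%
identity. The floor leaves near-full-length comparisons (the nomenclature
use case) unchanged and matches the shorter-sequence convention of greedy
clustering tools. An X (unknown residue) never counts as identical.

Gap costs are affine with the BLAST convention: a gap of length k costs
open + k * extend (defaults 10 + k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from Bio.Align import PairwiseAligner, substitution_matrices


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring parameters.

    ``lam`` and ``k`` are the Karlin–Altschul constants for gapped BLOSUM62
    scoring used by :func:`evalue`.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class AlignmentResult:
    """Score, identity, coverage and span contract shared by all stages.

    Spans are 0-based half-open on the original (ungapped) sequences. For a
    local "no hit" (no positive-scoring cell) ``score`` is 0 and the identity,
    coverages and spans are ``None``.
    """

    score: float
    identity_pct: Optional[float]
    query_coverage_pct: Optional[float]
    subject_coverage_pct: Optional[float]
    query_span: Optional[tuple[int, int]]
    subject_span: Optional[tuple[int, int]]
    evalue: Optional[float] = None
    n_columns: int = 0
    n_identical: int = 0

    @property
    def is_hit(self) -> bool:
        return self.query_span is not None


@lru_cache(maxsize=8)
def _aligner(params: AlignParams, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # BLAST convention: first gapped residue costs open+extend.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    if mode == "global":
        aligner.mode = "global"
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    elif mode == "local":
        aligner.mode = "local"
    else:  # pragma: no cover - internal misuse
        raise ValueError(mode)
    return aligner


def _column_stats(row_a: str, row_b: str) -> tuple[int, int, int, int]:
    """Match/column counts and per-row residue counts over aligned columns.

    Terminal columns where either row is gapped are trimmed first; internal
    gap columns stay in the denominator. Returns
    ``(n_identical, n_columns, residues_a, residues_b)`` within the trimmed
    block.
    """
    start = 0
    end = len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    n_cols = end - start
    n_ident = 0
    res_a = 0
    res_b = 0
    for ca, cb in zip(row_a[start:end], row_b[start:end]):
        if ca != "-":
            res_a += 1
        if cb != "-":
            res_b += 1
        if ca == cb and ca != "-" and ca != "X":
            n_ident += 1
    return n_ident, n_cols, res_a, res_b


def global_align(
    a: str, b: str, params: AlignParams = DEFAULT_PARAMS
) -> AlignmentResult:
    """Optimal semi-global alignment of ``a`` (query) and ``b`` (subject).

    Terminal gaps are free and excluded from the identity denominator. With
    the symmetric default matrix the identity is symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    # canonical argument order: among co-optimal alignments the traceback is
    # deterministic but order-sensitive, so align the lexicographically
    # smaller sequence first and mirror the result — identity and coverages
    # are then exactly symmetric
    swapped = b < a
    if swapped:
        a, b = b, a
    aligner = _aligner(params, "global")
    aln = aligner.align(a, b)[0]
    row_a, row_b = aln[0], aln[1]
    n_ident, n_cols, res_a, res_b = _column_stats(row_a, row_b)
    if n_cols == 0:
        # Degenerate: optimal alignment is all terminal gaps (no overlap).
        return AlignmentResult(
            score=float(aln.score),
            identity_pct=0.0,
            query_coverage_pct=0.0,
            subject_coverage_pct=0.0,
            query_span=None,
            subject_span=None,
        )
    # Residues of each sequence falling before the trimmed block.
    lead_cols = 0
    while row_a[lead_cols] == "-" or row_b[lead_cols] == "-":
        lead_cols += 1
    a_start = sum(1 for c in row_a[:lead_cols] if c != "-")
    b_start = sum(1 for c in row_b[:lead_cols] if c != "-")
    a_span = (a_start, a_start + res_a)
    b_span = (b_start, b_start + res_b)
    if swapped:
        a, b = b, a
        a_span, b_span = b_span, a_span
        res_a, res_b = res_b, res_a
    denom = max(n_cols, min(len(a), len(b)))
    return AlignmentResult(
        score=float(aln.score),
        identity_pct=100.0 * n_ident / denom,
        query_coverage_pct=100.0 * res_a / len(a),
        subject_coverage_pct=100.0 * res_b / len(b),
        query_span=a_span,
        subject_span=b_span,
        n_columns=n_cols,
        n_identical=n_ident,
    )


NO_HIT = AlignmentResult(
    score=0.0,
    identity_pct=None,
    query_coverage_pct=None,
    subject_coverage_pct=None,
    query_span=None,
    subject_span=None,
)


def local_align(
    a: str,
    b: str,
    params: AlignParams = DEFAULT_PARAMS,
    db_residues: Optional[int] = None,
) -> AlignmentResult:
    """Optimal local (Smith–Waterman) alignment with an attached E-value.

    ``db_residues`` sets the database size n of the E-value search space
    (defaults to ``len(b)``). If no positive-scoring cell exists the result
    is the "no hit" sentinel (score 0, undefined identity).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(params, "local")
    score = aligner.score(a, b)
    if score <= 0:
        return NO_HIT
    aln = aligner.align(a, b)[0]
    row_a, row_b = aln[0], aln[1]
    n_ident, n_cols, res_a, res_b = _column_stats(row_a, row_b)
    coords = aln.coordinates
    a_span = (int(coords[0][0]), int(coords[0][-1]))
    b_span = (int(coords[1][0]), int(coords[1][-1]))
    n = db_residues if db_residues is not None else len(b)
    return AlignmentResult(
        score=float(aln.score),
        identity_pct=100.0 * n_ident / n_cols if n_cols else None,
        query_coverage_pct=100.0 * (a_span[1] - a_span[0]) / len(a),
        subject_coverage_pct=100.0 * (b_span[1] - b_span[0]) / len(b),
        query_span=a_span,
        subject_span=b_span,
        evalue=evalue(float(aln.score), len(a), n, params),
        n_columns=n_cols,
        n_identical=n_ident,
    )


def evalue(
    score: float, m: int, n: int, params: AlignParams = DEFAULT_PARAMS
) -> float:
    """Karlin–Altschul expectation value E = K * m * n * exp(-lambda * S).

    Strictly decreasing in the score and linear in the search space m*n.
    """
    if score < 0:
        raise ValueError("score must be non-negative")
    if m < 1 or n < 1:
        raise ValueError("search-space sizes must be >= 1")
    return params.k * m * n * math.exp(-params.lam * score)


def identity_pct(a: str, b: str, params: AlignParams = DEFAULT_PARAMS) -> float:
    """Semi-global percent identity between two sequences (the nomenclature
    definition)."""
    return global_align(a, b, params).identity_pct
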