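"""Per-site summary statistics and community-profile helpers.

The central per-site quantity is the P450 diversity percentage,

    diversity_pct = 100 * n_families / n_P450s,

printed half-up to one decimal: 100% means every P450 at the site belongs to
a distinct family. The family-by-site count matrix has one row per family and
one column per site; its column sums equal the per-site P450 counts.

Relative abundance and Shannon diversity operate on non-negative coverage
values per lineage, as produced by read-coverage community profilers.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy


@dataclass(frozen=True)
class SiteSummary:
    site: str
    condition: str
    n_p450: int
    n_families: int
    n_subfamilies: int
    dominant_families: tuple[str, ...]
    diversity_pct: float
    diversity_raw: float


def diversity_percentage(n_p450: int, n_families: int) -> float:
    """100 x families / P450s, half-up rounded to one decimal."""
    if n_p450 < 1:
        raise ValueError("diversity percentage undefined for zero P450s")
    if not (1 <= n_families <= n_p450):
        raise ValueError("need 1 <= n_families <= n_p450")
    raw = Decimal(100) * Decimal(n_families) / Decimal(n_p450)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def dominant_families(counts: Mapping[str, int]) -> list[str]:
    """All families attaining the maximum count, sorted; ties are kept."""
    if not counts:
        return []
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    top = max(counts.values())
    return sorted(f for f, v in counts.items() if v == top)


def summarize_sites(
    classifications: Sequence["object"],
    site_conditions: Optional[Mapping[str, str]] = None,
) -> tuple[list[SiteSummary], pd.DataFrame, dict]:
    """One summary per site, the family-by-site matrix, and overall totals.

    ``classifications`` are objects with ``site``, ``family`` and
    ``subfamily`` attributes (the nomenclature results). Overall family and
    subfamily totals count distinct groups across all sites, not the sum of
    per-site counts — a family present at two sites counts once.
    """
    site_conditions = dict(site_conditions or {})
    rows = [
        {"site": c.site, "family": c.family, "subfamily": (c.family, c.subfamily)}
        for c in classifications
    ]
    df = pd.DataFrame(rows, columns=["site", "family", "subfamily"])
    summaries: list[SiteSummary] = []
    for site, group in sorted(df.groupby("site"), key=lambda kv: kv[0]) if len(df) else []:
        counts = group["family"].value_counts().to_dict()
        n = len(group)
        n_fam = group["family"].nunique()
        n_sub = group["subfamily"].nunique()
        summaries.append(
            SiteSummary(
                site=site,
                condition=site_conditions.get(site, ""),
                n_p450=n,
                n_families=n_fam,
                n_subfamilies=n_sub,
                dominant_families=tuple(dominant_families(counts)),
                diversity_pct=diversity_percentage(n, n_fam),
                diversity_raw=100.0 * n_fam / n,
            )
        )
    if len(df):
        matrix = pd.crosstab(df["family"], df["site"])
        matrix = matrix.sort_index(axis=0).sort_index(axis=1)
        matrix.index.name = "family"
        matrix.columns.name = None
    else:
        matrix = pd.DataFrame(dtype=int)
        matrix.index.name = "family"
    overall = {
        "n_p450": len(df),
        "n_families": df["family"].nunique() if len(df) else 0,
        "n_subfamilies": df["subfamily"].nunique() if len(df) else 0,
    }
    return summaries, matrix, overall


def relative_abundance(coverages: Iterable[float]) -> np.ndarray:
    """Normalize coverages to proportions (order preserved, sums to 1)."""
    values = np.asarray(list(coverages), dtype=float)
    if values.size == 0 or np.any(values < 0):
        raise ValueError("coverages must be non-empty and non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero coverages have no relative abundance")
    return values / total


def shannon(coverages: Iterable[float], base: Optional[float] = None) -> float:
    """Shannon diversity H = -sum(p ln p) after internal normalization.

    Natural log by default (the ecology convention); zero coverages
    contribute nothing. Invariant to rescaling by a positive constant.
    """
    p = relative_abundance(coverages)
    return float(_scipy_entropy(p, base=base))
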