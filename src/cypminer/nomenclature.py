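"""CYP family/subfamily assignment and name allocation.

Classification follows the P450 nomenclature convention: a protein sharing
more than 55% identity with a named P450 joins its subfamily, more than 40%
joins its family (with a new subfamily letter), and at or below 40% to every
named P450 it founds a new family. Both cut-offs are strict: identity exactly
at a threshold falls to the lower category. Identity is the semi-global
percent identity from :mod:`cypminer.pairwise`, the single definition used
across the package.

Queries are classified sequentially (longest first) against the reference
panel plus all previously classified queries, so co-novel sequences can share
a newly founded family. Near a threshold this chaining makes group membership
order-dependent; queries whose best identity lies within a small margin of a
cut-off are collected and surfaced as a warning rather than silently placed.

Novel family numbers come from a private base (default 9001) so that locally
allocated names can never collide with committee-assigned ones.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .pairwise import AlignParams, DEFAULT_PARAMS, global_align
from .sequence_io import ProteinRecord, ReferencePanel

logger = logging.getLogger(__name__)

NOVELTY_KNOWN = "known-subfamily"
NOVELTY_NEW_SUBFAMILY = "new-subfamily"
NOVELTY_NEW_FAMILY = "new-family"


@dataclass(frozen=True)
class Thresholds:
    """Strict identity cut-offs (%) for family and subfamily membership."""

    family_min: float = 40.0
    subfamily_min: float = 55.0
    #: queries within this margin of a cut-off trigger the order-dependence warning
    warn_margin: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.family_min < self.subfamily_min < 100):
            raise ValueError("need 0 < family_min < subfamily_min < 100")


@dataclass(frozen=True)
class ClassificationResult:
    record_id: str
    site: str
    family: str
    subfamily: str
    allele: int
    name: str
    novelty: str
    best_hit_id: str
    identity_pct: float
    near_threshold: bool = False


def _letters_sequence():
    """Subfamily letters in allocation order: A..Z, AA..AZ, BA.."""
    from itertools import count, product
    import string

    for width in count(1):
        for combo in product(string.ascii_uppercase, repeat=width):
            yield "".join(combo)


class RegistryError(RuntimeError):
    pass


class NameRegistry:
    """Bookkeeping of allocated CYP names.

    Tracks used family numbers, per-family subfamily letters, and per
    (family, subfamily) allele counters. Names are never reused; the registry
    serializes to JSON and reloads losslessly.
    """

    def __init__(self, novel_family_base: int = 9001) -> None:
        self.novel_family_base = novel_family_base
        self._families: dict[int, set[str]] = {}
        self._next_allele: dict[tuple[int, str], int] = {}
        self._allocated: set[str] = set()

    # -- seeding -----------------------------------------------------------
    def register_panel(self, panel: ReferencePanel) -> None:
        for entry in panel:
            self._families.setdefault(entry.family_number, set()).add(entry.subfamily)

    # -- queries -----------------------------------------------------------
    @property
    def family_numbers(self) -> list[int]:
        return sorted(self._families)

    def subfamilies(self, family_number: int) -> set[str]:
        return set(self._families.get(family_number, set()))

    # -- allocation --------------------------------------------------------
    def next_family_number(self) -> int:
        num = self.novel_family_base
        while num in self._families:
            num += 1
        return num

    def next_subfamily_letters(self, family_number: int) -> str:
        used = self._families.get(family_number, set())
        for letters in _letters_sequence():
            if letters not in used:
                return letters

    def allocate(self, family_number: int, subfamily: str) -> str:
        """Reserve and return the next full name in (family, subfamily)."""
        self._families.setdefault(family_number, set()).add(subfamily)
        key = (family_number, subfamily)
        allele = self._next_allele.get(key, 1)
        self._next_allele[key] = allele + 1
        name = f"CYP{family_number}{subfamily}{allele}"
        if name in self._allocated:
            raise RegistryError(f"duplicate allocation of {name}")
        self._allocated.add(name)
        return name

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "novel_family_base": self.novel_family_base,
            "families": {str(k): sorted(v) for k, v in self._families.items()},
            "next_allele": {f"{k[0]}:{k[1]}": v for k, v in self._next_allele.items()},
            "allocated": sorted(self._allocated),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "NameRegistry":
        reg = cls(novel_family_base=data["novel_family_base"])
        reg._families = {int(k): set(v) for k, v in data["families"].items()}
        reg._next_allele = {
            (int(k.split(":")[0]), k.split(":")[1]): v
            for k, v in data["next_allele"].items()
        }
        reg._allocated = set(data["allocated"])
        return reg

    @classmethod
    def load(cls, path: str | Path) -> "NameRegistry":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class _Target:
    """A comparison target: a panel entry or a previously classified query."""

    target_id: str
    sequence: str
    family_number: int
    family: str
    subfamily: str


def _panel_targets(panel: ReferencePanel) -> list[_Target]:
    return [
        _Target(e.ref_id, e.sequence, e.family_number, e.family, e.subfamily)
        for e in panel
    ]


def best_reference_hit(
    query_sequence: str,
    targets: Sequence[_Target],
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[_Target, float]:
    """Maximum semi-global identity over all targets.

    Ties are broken by higher query coverage, then lexicographic target id
    (ties are logged).
    """
    if not targets:
        raise ValueError("no comparison targets")
    scored = []
    for target in targets:
        res = global_align(query_sequence, target.sequence, params)
        scored.append(((-res.identity_pct, -res.query_coverage_pct, target.target_id), target, res))
    scored.sort(key=lambda item: item[0])
    best_key, best_target, best_res = scored[0]
    tied = [t.target_id for k, t, _ in scored[1:] if k[:2] == best_key[:2]]
    if tied:
        logger.info(
            "best-hit tie at identity %.2f broken lexicographically among %s",
            best_res.identity_pct,
            sorted(tied + [best_target.target_id]),
        )
    return best_target, best_res.identity_pct


def classify(
    query: ProteinRecord,
    targets: Sequence[_Target],
    thresholds: Thresholds = Thresholds(),
    registry: Optional[NameRegistry] = None,
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[ClassificationResult, _Target]:
    """Classify one query and allocate its name.

    Returns the result plus the target entry representing this query for
    subsequent chained classification.
    """
    if registry is None:
        registry = NameRegistry()
    target, ident = best_reference_hit(query.sequence, targets, params)
    near = (
        abs(ident - thresholds.family_min) <= thresholds.warn_margin
        or abs(ident - thresholds.subfamily_min) <= thresholds.warn_margin
    )
    if ident > thresholds.subfamily_min:
        novelty = NOVELTY_KNOWN
        fam_num, family, subfamily = target.family_number, target.family, target.subfamily
    elif ident > thresholds.family_min:
        novelty = NOVELTY_NEW_SUBFAMILY
        fam_num, family = target.family_number, target.family
        subfamily = registry.next_subfamily_letters(fam_num)
    else:
        novelty = NOVELTY_NEW_FAMILY
        fam_num = registry.next_family_number()
        family = f"CYP{fam_num}"
        subfamily = "A"
    name = registry.allocate(fam_num, subfamily)
    allele = int(name[len(f"CYP{fam_num}{subfamily}"):])
    result = ClassificationResult(
        record_id=query.record_id,
        site=query.site,
        family=family,
        subfamily=subfamily,
        allele=allele,
        name=name,
        novelty=novelty,
        best_hit_id=target.target_id,
        identity_pct=ident,
        near_threshold=near,
    )
    return result, _Target(query.record_id, query.sequence, fam_num, family, subfamily)


@dataclass
class ClassificationSummary:
    n_classified: int
    n_families: int
    n_subfamilies: int
    n_new_families: int
    n_new_subfamilies: int
    near_threshold_records: list[str] = field(default_factory=list)


def classify_all(
    queries: Sequence[ProteinRecord],
    panel: ReferencePanel,
    thresholds: Thresholds = Thresholds(),
    params: AlignParams = DEFAULT_PARAMS,
    registry: Optional[NameRegistry] = None,
) -> tuple[list[ClassificationResult], NameRegistry, ClassificationSummary]:
    """Sequential classification of all queries with registry growth.

    Queries are processed in deterministic order (descending length, then
    record id); each classified query becomes a comparison target for later
    ones, so mutually similar novel sequences land in the same new group.
    """
    if registry is None:
        registry = NameRegistry()
    registry.register_panel(panel)
    targets = _panel_targets(panel)
    ordered = sorted(queries, key=lambda r: (-r.length, r.record_id))
    results: list[ClassificationResult] = []
    for query in ordered:
        result, new_target = classify(query, targets, thresholds, registry, params)
        results.append(result)
        targets.append(new_target)
    near = [r.record_id for r in results if r.near_threshold]
    if near:
        warnings.warn(
            "group membership may be order-dependent: best identity within "
            f"{thresholds.warn_margin} points of a threshold for records {sorted(near)}",
            stacklevel=2,
        )
    summary = ClassificationSummary(
        n_classified=len(results),
        n_families=len({r.family for r in results}),
        n_subfamilies=len({(r.family, r.subfamily) for r in results}),
        n_new_families=len({r.family for r in results if r.novelty == NOVELTY_NEW_FAMILY}),
        n_new_subfamilies=len(
            {(r.family, r.subfamily) for r in results if r.novelty == NOVELTY_NEW_SUBFAMILY}
        ),
        near_threshold_records=sorted(near),
    )
    return results, registry, summary
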