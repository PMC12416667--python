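"""End-to-end orchestration: dereplicate -> screen -> filter -> classify -> summarize.

The run writes every intermediate table, a name registry, and a JSON manifest
whose per-stage counts form the discovery funnel

    input -> dereplicated -> screen-passed -> complete -> >=20% microbial
          -> motif-positive (= classified)

Counts are non-increasing along the cascade, and re-running with the same
config and seed reproduces every table byte for byte (the manifest's
timestamp is the only run-specific value).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .filters import FilterConfig, FilterReport, filter_cascade
from .nomenclature import NameRegistry, Thresholds, classify_all
from .pairwise import AlignParams
from .screening import ScreenThresholds, dereplicate, screen_candidates
from .sequence_io import (
    ProteinRecord,
    ReferencePanel,
    read_protein_fasta,
    read_reference_panel,
    write_results,
)
from .summarize import summarize_sites
from .synthetic import SyntheticConfig, generate, write_synthetic_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; echoed verbatim into the manifest."""

    out_dir: str
    queries: Optional[str] = None
    metadata: Optional[str] = None
    panel_fasta: Optional[str] = None
    panel_labels: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    seed: int = 17
    derep_min_overlap: float = 80.0
    derep_relative_to: str = "member"
    align: AlignParams = field(default_factory=AlignParams)
    screen: ScreenThresholds = field(default_factory=ScreenThresholds)
    filters: FilterConfig = field(default_factory=FilterConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    novel_family_base: int = 9001
    site_conditions: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if data.get("synthetic") is not None and not isinstance(
            data["synthetic"], SyntheticConfig
        ):
            syn = dict(data["synthetic"])
            for key in ("ref_length", "band_known", "band_new_subfamily", "sites"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            data["synthetic"] = SyntheticConfig(**syn)
        for key, typ in (
            ("align", AlignParams),
            ("screen", ScreenThresholds),
            ("filters", FilterConfig),
            ("thresholds", Thresholds),
        ):
            if key in data and not isinstance(data[key], typ):
                sub = dict(data[key])
                for tkey in ("n_range", "m_range"):
                    if tkey in sub:
                        sub[tkey] = tuple(sub[tkey])
                data[key] = typ(**sub)
        return cls(**data)


@dataclass
class RunResult:
    out_dir: Path
    manifest: dict
    classifications: list
    summaries: list


class PipelineError(RuntimeError):
    pass


def _load_inputs(
    config: RunConfig, out: Path
) -> tuple[list[ProteinRecord], ReferencePanel]:
    if config.synthetic is not None:
        syn = config.synthetic
        if config.seed is not None:
            from dataclasses import replace

            syn = replace(syn, seed=config.seed)
        dataset = generate(syn)
        write_synthetic_dataset(dataset, out / "inputs")
        return dataset.records, dataset.panel
    if not (config.queries and config.panel_fasta and config.panel_labels):
        raise PipelineError(
            "either a synthetic preset or queries + panel paths are required"
        )
    records = read_protein_fasta(config.queries, config.metadata)
    panel = read_reference_panel(config.panel_fasta, config.panel_labels)
    return records, panel


def _write_clusters(clusters, path: Path) -> None:
    rows = [
        {"seed_id": c.seed_id, "size": c.size, "member_ids": ";".join(c.member_ids)}
        for c in clusters
    ]
    pd.DataFrame(rows, columns=["seed_id", "size", "member_ids"]).to_csv(
        path, sep="\t", index=False
    )


def _write_screen_report(hits, path: Path) -> None:
    rows = [
        {
            "record_id": h.record_id,
            "ref_id": h.ref_id or "",
            "identity_pct": "" if h.identity_pct is None else f"{h.identity_pct:.2f}",
            "query_cover_pct": ""
            if h.query_coverage_pct is None
            else f"{h.query_coverage_pct:.2f}",
            "subject_cover_pct": ""
            if h.subject_coverage_pct is None
            else f"{h.subject_coverage_pct:.2f}",
            "evalue": "" if h.evalue is None else f"{h.evalue:.3e}",
            "passed": str(h.passed).lower(),
            "failed_criteria": ";".join(h.failed_criteria),
        }
        for h in hits
    ]
    cols = [
        "record_id",
        "ref_id",
        "identity_pct",
        "query_cover_pct",
        "subject_cover_pct",
        "evalue",
        "passed",
        "failed_criteria",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def _write_filter_report(reports: list[FilterReport], path: Path) -> None:
    rows = []
    for r in reports:
        motifs = ";".join(f"{h.start}:n{h.n}:m{h.m}" for h in r.motif_hits)
        near = ";".join(f"{h.start}:axial={h.axial}" for h in r.near_misses)
        rows.append(
            {
                "record_id": r.record_id,
                "kept": str(r.kept).lower(),
                "reason": r.reason or "",
                "motif_hits": motifs,
                "near_misses": near,
                "best_microbial_ref": r.best_microbial_ref or "",
                "best_microbial_identity": ""
                if r.best_microbial_identity is None
                else f"{r.best_microbial_identity:.2f}",
            }
        )
    cols = [
        "record_id",
        "kept",
        "reason",
        "motif_hits",
        "near_misses",
        "best_microbial_ref",
        "best_microbial_identity",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all outputs under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, panel = _load_inputs(config, out)
    logger.info("loaded %d records, %d panel entries", len(records), len(panel))

    by_id = {r.record_id: r for r in records}

    if records:
        clusters = dereplicate(
            records, config.derep_min_overlap, config.derep_relative_to
        )
    else:
        clusters = []
    _write_clusters(clusters, out / "clusters.tsv")
    seeds = [by_id[c.seed_id] for c in clusters]
    logger.info("dereplicated %d records into %d clusters", len(records), len(clusters))

    hits = screen_candidates(seeds, panel, config.align, config.screen) if seeds else []
    _write_screen_report(hits, out / "screen_report.tsv")
    passed_ids = {h.record_id for h in hits if h.passed}
    survivors = [r for r in seeds if r.record_id in passed_ids]
    logger.info("screen passed %d of %d cluster seeds", len(survivors), len(seeds))

    reports = filter_cascade(survivors, panel, config.filters, config.align) if survivors else []
    _write_filter_report(reports, out / "filter_report.tsv")
    kept_ids = {r.record_id for r in reports if r.kept}
    kept = [r for r in survivors if r.record_id in kept_ids]

    registry = NameRegistry(novel_family_base=config.novel_family_base)
    results, registry, summary = classify_all(
        kept, panel, config.thresholds, config.align, registry
    )
    registry.save(out / "registry.json")

    summaries, matrix, overall = summarize_sites(results, config.site_conditions)
    write_results(results, summaries, matrix, out)

    n_incomplete = sum(1 for r in reports if r.reason == "incomplete")
    n_below = sum(1 for r in reports if r.reason == "below-20%-microbial-identity")
    counts = {
        "input": len(records),
        "dereplicated": len(clusters),
        "screen_passed": len(survivors),
        "complete": len(survivors) - n_incomplete,
        "microbial_identity": len(survivors) - n_incomplete - n_below,
        "motif_positive": len(kept),
        "classified": len(results),
    }
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "counts": counts,
        "classification_summary": {
            "n_classified": summary.n_classified,
            "n_families": summary.n_families,
            "n_subfamilies": summary.n_subfamilies,
            "n_new_families": summary.n_new_families,
            "n_new_subfamilies": summary.n_new_subfamilies,
            "near_threshold_records": summary.near_threshold_records,
        },
        "overall": overall,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for stage, count in counts.items():
        logger.info("funnel %s=%d", stage, count)
    return RunResult(out_dir=out, manifest=manifest, classifications=results, summaries=summaries)
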