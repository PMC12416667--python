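"""Protein FASTA / TSV input-output and the canonical in-memory record model.

All tabular output is UTF-8 TSV with a fixed column order and rows sorted by
record identifier, so repeated runs are diff-stable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical amino-acid alphabet plus X (unknown residue).
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Gene-caller partial flag meaning "both start and stop codon present".
COMPLETE_FLAG = "00"

_FAMILY_RE = re.compile(r"^CYP(\d+)$")
_SUBFAMILY_RE = re.compile(r"^[A-Z]{1,2}$")

CLASSIFICATION_COLUMNS = [
    "record_id",
    "site",
    "family",
    "subfamily",
    "allele",
    "name",
    "novelty",
    "best_hit",
    "identity_pct",
]

SUMMARY_COLUMNS = [
    "site",
    "condition",
    "n_p450",
    "n_families",
    "n_subfamilies",
    "dominant_families",
    "diversity_pct",
]


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA entries, labels, or metadata."""


def normalize_sequence(raw: str, record_id: str = "?") -> tuple[str, bool]:
    """Uppercase a protein sequence and strip a single trailing stop marker.

    Returns ``(sequence, stop_seen)``. Raises :class:`SequenceFormatError` for
    an empty sequence or any residue outside the 20 canonical letters plus X.
    """
    seq = raw.strip().upper()
    stop_seen = False
    if seq.endswith("*"):
        seq = seq[:-1]
        stop_seen = True
    if not seq:
        raise SequenceFormatError(f"record {record_id!r}: empty sequence")
    for pos, ch in enumerate(seq):
        if ch not in ALLOWED_RESIDUES:
            raise SequenceFormatError(
                f"record {record_id!r}: illegal residue {ch!r} at position {pos}"
            )
    return seq, stop_seen


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate protein with its provenance.

    ``complete`` is tri-state: ``True`` (gene caller saw start and stop),
    ``False`` (explicitly partial), ``None`` (no evidence). ``stop_seen``
    records whether a trailing ``*`` was stripped on ingest.
    """

    record_id: str
    sequence: str
    site: str = "unknown"
    complete: Optional[bool] = None
    stop_seen: bool = False

    def __post_init__(self) -> None:
        if not self.record_id:
            raise SequenceFormatError("record_id must be non-empty")
        if not self.sequence:
            raise SequenceFormatError(f"record {self.record_id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def x_fraction(self) -> float:
        return self.sequence.count("X") / len(self.sequence)

    @property
    def high_x(self) -> bool:
        """More than 10% unknown residues — kept, but flagged."""
        return self.x_fraction > 0.10


@dataclass(frozen=True)
class ReferenceEntry:
    """A labelled known P450 used for screening and classification."""

    ref_id: str
    sequence: str
    family: str
    subfamily: str
    is_microbial: bool = True

    def __post_init__(self) -> None:
        if not _FAMILY_RE.match(self.family):
            raise SequenceFormatError(
                f"reference {self.ref_id!r}: family {self.family!r} must match CYP<number>"
            )
        if not _SUBFAMILY_RE.match(self.subfamily):
            raise SequenceFormatError(
                f"reference {self.ref_id!r}: subfamily {self.subfamily!r} must be 1-2 uppercase letters"
            )

    @property
    def family_number(self) -> int:
        return int(_FAMILY_RE.match(self.family).group(1))


@dataclass
class ReferencePanel:
    """An indexed collection of labelled reference P450s."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.ref_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SequenceFormatError(f"duplicate reference ids: {sorted(dupes)}")
        self._by_id = {e.ref_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, ref_id: str) -> ReferenceEntry:
        return self._by_id[ref_id]

    @property
    def total_residues(self) -> int:
        return sum(len(e.sequence) for e in self.entries)

    def microbial(self) -> list[ReferenceEntry]:
        return [e for e in self.entries if e.is_microbial]


def _parse_partial_flag(flag: object) -> Optional[bool]:
    if flag is None or (isinstance(flag, float) and pd.isna(flag)):
        return None
    text = str(flag).strip()
    if not text or text.lower() in {"nan", "na", "unknown"}:
        return None
    return text == COMPLETE_FLAG


def read_protein_fasta(
    path: str | Path, metadata: str | Path | None = None
) -> list[ProteinRecord]:
    """Read candidate proteins, joining optional per-record metadata by id.

    The metadata TSV carries ``record_id``, ``site`` and ``partial_flag``
    columns (``partial_flag == "00"`` means a complete ORF). Records without a
    metadata row get ``site="unknown"`` and unknown completeness.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: Mapping[str, tuple[str, Optional[bool]]] = {}
    if metadata is not None:
        table = pd.read_csv(metadata, sep="\t", dtype=str)
        required = {"record_id", "site", "partial_flag"}
        if not required.issubset(table.columns):
            raise SequenceFormatError(
                f"metadata must have columns {sorted(required)}, got {list(table.columns)}"
            )
        meta = {
            row.record_id: (row.site, _parse_partial_flag(row.partial_flag))
            for row in table.itertuples()
        }

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    duplicates: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            duplicates.add(rid)
            continue
        seen.add(rid)
        seq, stop_seen = normalize_sequence(str(entry.seq), rid)
        site, complete = meta.get(rid, ("unknown", None))
        records.append(
            ProteinRecord(
                record_id=rid,
                sequence=seq,
                site=site,
                complete=complete,
                stop_seen=stop_seen,
            )
        )
    if duplicates:
        raise SequenceFormatError(f"duplicate record ids: {sorted(duplicates)}")
    if not records:
        logger.warning("no sequences found in %s", path)
    for rec in records:
        if rec.high_x:
            logger.warning(
                "record %s has %.0f%% unknown residues", rec.record_id, 100 * rec.x_fraction
            )
    return records


def write_protein_fasta(
    records: Iterable[ProteinRecord],
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write records as FASTA plus, optionally, the metadata TSV."""
    records = list(records)
    seqs = [SeqRecord(Seq(r.sequence), id=r.record_id, description="") for r in records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    if metadata_path is not None:
        rows = []
        for r in records:
            if r.complete is None:
                flag = ""
            else:
                flag = COMPLETE_FLAG if r.complete else "10"
            rows.append({"record_id": r.record_id, "site": r.site, "partial_flag": flag})
        pd.DataFrame(rows, columns=["record_id", "site", "partial_flag"]).to_csv(
            metadata_path, sep="\t", index=False
        )


def read_reference_panel(fasta: str | Path, labels: str | Path) -> ReferencePanel:
    """Read a labelled reference panel (FASTA + label TSV).

    The label table has columns ``ref_id``, ``family``, ``subfamily``,
    ``is_microbial``. Every FASTA entry must be labelled.
    """
    table = pd.read_csv(labels, sep="\t", dtype=str)
    required = {"ref_id", "family", "subfamily", "is_microbial"}
    if not required.issubset(table.columns):
        raise SequenceFormatError(
            f"label table must have columns {sorted(required)}, got {list(table.columns)}"
        )
    label_map = {
        row.ref_id: (row.family, row.subfamily, str(row.is_microbial).strip().lower() in {"true", "1", "yes"})
        for row in table.itertuples()
    }
    entries = []
    for entry in SeqIO.parse(str(fasta), "fasta"):
        if entry.id not in label_map:
            raise SequenceFormatError(f"reference {entry.id!r} has no label row")
        seq, _ = normalize_sequence(str(entry.seq), entry.id)
        family, subfamily, is_microbial = label_map[entry.id]
        entries.append(
            ReferenceEntry(
                ref_id=entry.id,
                sequence=seq,
                family=family,
                subfamily=subfamily,
                is_microbial=is_microbial,
            )
        )
    return ReferencePanel(entries=entries)


def write_reference_panel(
    panel: ReferencePanel, fasta: str | Path, labels: str | Path
) -> None:
    seqs = [SeqRecord(Seq(e.sequence), id=e.ref_id, description="") for e in panel]
    SeqIO.write(seqs, str(fasta), "fasta")
    rows = [
        {
            "ref_id": e.ref_id,
            "family": e.family,
            "subfamily": e.subfamily,
            "is_microbial": str(e.is_microbial).lower(),
        }
        for e in panel
    ]
    pd.DataFrame(rows, columns=["ref_id", "family", "subfamily", "is_microbial"]).to_csv(
        labels, sep="\t", index=False
    )


def write_results(
    classifications: Sequence["object"],
    summaries: Sequence["object"],
    matrix: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the classification table, per-site summary, and family-by-site matrix.

    ``classifications`` and ``summaries`` are the dataclasses produced by the
    nomenclature and site-summary stages; only their public fields are used.
    Returns the written paths keyed by table name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cls_rows = [
        {
            "record_id": c.record_id,
            "site": c.site,
            "family": c.family,
            "subfamily": c.subfamily,
            "allele": c.allele,
            "name": c.name,
            "novelty": c.novelty,
            "best_hit": c.best_hit_id,
            "identity_pct": f"{c.identity_pct:.2f}",
        }
        for c in classifications
    ]
    cls_df = pd.DataFrame(cls_rows, columns=CLASSIFICATION_COLUMNS)
    cls_df = cls_df.sort_values("record_id") if len(cls_df) else cls_df
    cls_path = out / "classifications.tsv"
    cls_df.to_csv(cls_path, sep="\t", index=False)

    sum_rows = [
        {
            "site": s.site,
            "condition": s.condition,
            "n_p450": s.n_p450,
            "n_families": s.n_families,
            "n_subfamilies": s.n_subfamilies,
            "dominant_families": ";".join(s.dominant_families),
            "diversity_pct": f"{s.diversity_pct:.1f}",
        }
        for s in summaries
    ]
    sum_df = pd.DataFrame(sum_rows, columns=SUMMARY_COLUMNS)
    sum_path = out / "site_summary.tsv"
    sum_df.to_csv(sum_path, sep="\t", index=False)

    mat_path = out / "family_site_matrix.tsv"
    matrix.to_csv(mat_path, sep="\t", index_label="family")

    return {"classifications": cls_path, "site_summary": sum_path, "matrix": mat_path}


def read_classification_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"record_id": str, "site": str})
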