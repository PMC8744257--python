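"""Data model and readers/writers for the tabular inputs of the pipeline.

The pipeline consumes plain delimited text: a spectral-count matrix
(proteins x samples), a sample design table, protein annotations (length,
Mitocarta membership, MTS interval), peptide identifications, upstream
enrichment exports (SAINT-style fold change / FDR columns) and APEX-seq-like
mRNA tables.  All coordinates are 1-based inclusive amino-acid positions,
matching protein residue numbering used by MTS annotations.

Delimiters are auto-detected among tab and comma (supplementary tables ship
in both dialects) and can be forced with ``sep=``.  Missing count cells are
rejected rather than imputed: in spectral counting, absence and zero are
different statements and the caller must be explicit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AnnotationGapError,
    DesignMismatchError,
    DuplicateKeyError,
    EmptyInputError,
    InvariantError,
    SchemaError,
)

CONDITIONS = ("bait", "control")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    """One purification sample: bait or control, with replicate index."""

    sample_id: str
    condition: str
    replicate: int
    timepoint: Optional[str] = None
    cell_context: Optional[str] = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise InvariantError(
                f"sample {self.sample_id!r}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if int(self.replicate) < 1:
            raise InvariantError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


class SampleDesign:
    """Ordered collection of :class:`Sample` records with uniqueness checks."""

    def __init__(self, samples: Sequence[Sample]):
        samples = list(samples)
        if not samples:
            raise EmptyInputError("sample design is empty")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateKeyError(f"duplicate sample ids in design: {dupes}")
        seen = set()
        for s in samples:
            key = (s.condition, s.timepoint, s.replicate)
            if key in seen:
                raise InvariantError(
                    f"replicate {s.replicate} duplicated within group "
                    f"({s.condition}, timepoint={s.timepoint})"
                )
            seen.add(key)
        self.samples = samples

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(self, condition: str | None = None, timepoint: str | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if condition is not None and s.condition != condition:
                continue
            if timepoint is not None and s.timepoint != timepoint:
                continue
            out.append(s.sample_id)
        return out

    def bait_ids(self, timepoint: str | None = None) -> list[str]:
        return self.subset("bait", timepoint)

    def control_ids(self, timepoint: str | None = None) -> list[str]:
        return self.subset("control", timepoint)

    def require_contrast(self, timepoint: str | None = None) -> tuple[list[str], list[str]]:
        """Bait and control sample ids; errors if either side is empty."""
        bait, ctrl = self.bait_ids(timepoint), self.control_ids(timepoint)
        if not bait or not ctrl:
            raise DesignMismatchError(
                f"enrichment contrast needs >=1 bait and >=1 control sample "
                f"(timepoint={timepoint}): got {len(bait)} bait / {len(ctrl)} control"
            )
        return bait, ctrl

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.samples])


@dataclass
class CountMatrix:
    """Nonnegative integer spectral counts, proteins x samples."""

    protein_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise InvariantError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if self.counts.size and (
            not np.issubdtype(self.counts.dtype, np.integer)
            or (self.counts < 0).any()
        ):
            raise InvariantError("spectral counts must be nonnegative integers")
        for label, values in (("protein", self.protein_ids), ("sample", self.sample_ids)):
            if len(set(values)) != len(values):
                dupes = sorted({v for v in values if values.count(v) > 1})
                raise DuplicateKeyError(f"duplicate {label} ids: {dupes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.protein_ids, columns=self.sample_ids)

    def columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Count sub-matrix for the given samples (in the given order)."""
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise DesignMismatchError(f"samples not in count matrix: {missing}")
        return self.counts[:, [idx[s] for s in sample_ids]]


@dataclass(frozen=True)
class ProteinAnnotation:
    """Per-protein annotation: length, Mitocarta flag, MTS interval."""

    protein_id: str
    gene_symbol: str
    length_aa: int
    is_mitochondrial: bool = False
    mts_interval: Optional[tuple[int, int]] = None
    is_mito_encoded: bool = False

    def __post_init__(self):
        if self.length_aa <= 0:
            raise InvariantError(f"{self.protein_id}: length_aa must be positive")
        if self.mts_interval is not None:
            start, end = self.mts_interval
            if not (1 <= start <= end <= self.length_aa):
                raise InvariantError(
                    f"{self.protein_id}: MTS interval [{start},{end}] outside "
                    f"protein of length {self.length_aa}"
                )
            if self.is_mito_encoded:
                raise InvariantError(
                    f"{self.protein_id}: mito-encoded proteins carry no MTS"
                )

    @property
    def has_mts(self) -> bool:
        return self.mts_interval is not None


@dataclass(frozen=True)
class PeptideHit:
    """One identified peptide located on its parent protein (1-based, inclusive)."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise InvariantError(
                f"{self.protein_id}: invalid peptide interval [{self.start},{self.end}]"
            )


@dataclass
class ExternalEnrichmentTable:
    """Upstream enrichment export (SAINT-style): fold change + FDR per protein."""

    frame: pd.DataFrame  # columns: protein_id, fold_change, fdr [+ extras]

    def __post_init__(self):
        need = {"protein_id", "fold_change", "fdr"}
        missing = need - set(self.frame.columns)
        if missing:
            raise SchemaError(f"external table missing columns: {sorted(missing)}")
        f = self.frame
        if f["protein_id"].duplicated().any():
            dupes = sorted(f.loc[f["protein_id"].duplicated(), "protein_id"])
            raise DuplicateKeyError(f"duplicate protein ids in external table: {dupes}")
        if (f["fold_change"] <= 0).any():
            raise InvariantError("external fold_change values must be > 0")
        if ((f["fdr"] < 0) | (f["fdr"] > 1)).any():
            raise InvariantError("external fdr values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _read_table(path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    if sep is None:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, dtype={0: str})
    if frame.empty:
        raise EmptyInputError(f"{path} contains a header but no rows")
    return frame


def _apply_column_map(frame: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    # column_map: canonical name -> name used in the file
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    return frame


def read_design(path, sep: str | None = None) -> SampleDesign:
    """Read a sample design table (sample_id, condition, replicate, ...)."""
    frame = _read_table(path, sep)
    missing = {"sample_id", "condition", "replicate"} - set(frame.columns)
    if missing:
        raise SchemaError(f"design table missing columns: {sorted(missing)}")
    samples = []
    for _, row in frame.iterrows():
        samples.append(
            Sample(
                sample_id=str(row["sample_id"]),
                condition=str(row["condition"]),
                replicate=int(row["replicate"]),
                timepoint=_opt_str(row.get("timepoint")),
                cell_context=_opt_str(row.get("cell_context")),
            )
        )
    return SampleDesign(samples)


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_counts(path, design: SampleDesign, sep: str | None = None,
                protein_col: str | None = None) -> CountMatrix:
    """Read a spectral-count matrix and validate it against a design.

    The first column (or ``protein_col``) holds protein accessions; the
    remaining columns are matched by name to the design's sample ids.  Cells
    must be nonnegative integers; missing cells are rejected, not imputed.
    """
    frame = _read_table(path, sep)
    protein_col = protein_col or frame.columns[0]
    if protein_col not in frame.columns:
        raise SchemaError(f"protein column {protein_col!r} not found")
    proteins = frame[protein_col].astype(str).tolist()
    missing = [s for s in design.sample_ids if s not in frame.columns]
    if missing:
        raise DesignMismatchError(f"count table lacks design samples: {missing}")
    sub = frame[design.sample_ids]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise InvariantError(
            f"missing count cells in rows {bad}; spectral counts must be explicit "
            "(write 0 for not-observed only if that is what you mean)"
        )
    values = sub.to_numpy()
    rounded = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(rounded)) or not np.all(rounded == np.floor(rounded)):
        raise InvariantError("non-integer spectral count encountered")
    counts = rounded.astype(np.int64)
    if (counts < 0).any():
        raise InvariantError("negative spectral count encountered")
    return CountMatrix(proteins, list(design.sample_ids), counts)


def read_annotations(path, sep: str | None = None,
                     column_map: Mapping[str, str] | None = None) -> list[ProteinAnnotation]:
    """Read a protein annotation table.

    Required columns: protein_id, gene_symbol, length_aa.  Optional:
    mts_start/mts_end, is_mitochondrial, is_mito_encoded (missing optional
    fields default to absent/false).
    """
    frame = _apply_column_map(_read_table(path, sep), column_map)
    missing = {"protein_id", "gene_symbol", "length_aa"} - set(frame.columns)
    if missing:
        raise SchemaError(f"annotation table missing columns: {sorted(missing)}")
    if frame["protein_id"].duplicated().any():
        dupes = sorted(frame.loc[frame["protein_id"].duplicated(), "protein_id"])
        raise DuplicateKeyError(f"duplicate protein ids in annotations: {dupes}")
    out = []
    for _, row in frame.iterrows():
        mts = None
        start, end = row.get("mts_start"), row.get("mts_end")
        if start is not None and end is not None and not (pd.isna(start) or pd.isna(end)):
            mts = (int(start), int(end))
        out.append(
            ProteinAnnotation(
                protein_id=str(row["protein_id"]),
                gene_symbol=str(row["gene_symbol"]),
                length_aa=int(row["length_aa"]),
                is_mitochondrial=_as_bool(row.get("is_mitochondrial")),
                mts_interval=mts,
                is_mito_encoded=_as_bool(row.get("is_mito_encoded")),
            )
        )
    return out


def _as_bool(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1", "yes", "t"}


def read_peptides(path, sep: str | None = None,
                  annotations: Iterable[ProteinAnnotation] | None = None) -> list[PeptideHit]:
    """Read a peptide table (protein_id, start, end); optionally validate
    coordinates against annotated protein lengths."""
    frame = _read_table(path, sep)
    missing = {"protein_id", "start", "end"} - set(frame.columns)
    if missing:
        raise SchemaError(f"peptide table missing columns: {sorted(missing)}")
    hits = [
        PeptideHit(str(r["protein_id"]), int(r["start"]), int(r["end"]))
        for _, r in frame.iterrows()
    ]
    if annotations is not None:
        lengths = {a.protein_id: a.length_aa for a in annotations}
        for h in hits:
            if h.protein_id in lengths and h.end > lengths[h.protein_id]:
                raise InvariantError(
                    f"{h.protein_id}: peptide end {h.end} beyond protein "
                    f"length {lengths[h.protein_id]}"
                )
    return hits


def read_external_table(path, sep: str | None = None,
                        column_map: Mapping[str, str] | None = None) -> ExternalEnrichmentTable:
    """Read an upstream enrichment export; ``column_map`` maps canonical
    names (protein_id, fold_change, fdr) to the file's column names, since
    supplementary exports vary in their headers."""
    frame = _apply_column_map(_read_table(path, sep), column_map)
    frame["protein_id"] = frame["protein_id"].astype(str)
    return ExternalEnrichmentTable(frame)


def read_omm_table(path, sep: str | None = None,
                   column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an APEX-seq-style mRNA table with gene, log2_fc, fdr columns."""
    frame = _apply_column_map(_read_table(path, sep), column_map)
    missing = {"gene", "log2_fc", "fdr"} - set(frame.columns)
    if missing:
        raise SchemaError(f"mRNA table missing columns: {sorted(missing)}")
    frame["gene"] = frame["gene"].astype(str)
    return frame


def read_fasta_lengths(path) -> dict[str, int]:
    """Protein lengths (residue counts) from a FASTA file, keyed by accession."""
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise DuplicateKeyError(f"duplicate FASTA accession: {record.id}")
        lengths[record.id] = len(str(record.seq).replace(" ", "").replace("\n", ""))
    return lengths


# ---------------------------------------------------------------------------
# Writing — TSV with header, deterministic row order (sorted by protein_id)
# ---------------------------------------------------------------------------

def write_counts(matrix: CountMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "protein_id"
    frame.sort_index().to_csv(path, sep="\t")


def write_design(design: SampleDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def write_annotations(annotations: Iterable[ProteinAnnotation], path) -> None:
    rows = []
    for a in annotations:
        start, end = a.mts_interval if a.mts_interval else ("", "")
        rows.append(
            dict(protein_id=a.protein_id, gene_symbol=a.gene_symbol,
                 length_aa=a.length_aa, is_mitochondrial=a.is_mitochondrial,
                 mts_start=start, mts_end=end, is_mito_encoded=a.is_mito_encoded)
        )
    pd.DataFrame(rows).sort_values("protein_id").to_csv(path, sep="\t", index=False)


def write_peptides(hits: Iterable[PeptideHit], path) -> None:
    frame = pd.DataFrame([dataclasses.asdict(h) for h in hits])
    frame.sort_values(["protein_id", "start", "end"]).to_csv(path, sep="\t", index=False)


def write_table(frame: pd.DataFrame, path, sort_by: str | None = "protein_id") -> None:
    out = frame
    if sort_by and sort_by in frame.columns:
        out = frame.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def annotation_index(annotations: Iterable[ProteinAnnotation]) -> dict[str, ProteinAnnotation]:
    index = {}
    for a in annotations:
        if a.protein_id in index:
            raise DuplicateKeyError(f"duplicate annotation for {a.protein_id}")
        index[a.protein_id] = a
    return index


def require_lengths(protein_ids: Sequence[str],
                    annotations: Mapping[str, ProteinAnnotation]) -> np.ndarray:
    """Lengths for the given proteins; raises listing ids with no length."""
    missing = [p for p in protein_ids if p not in annotations]
    if missing:
        raise AnnotationGapError(
            f"{len(missing)} proteins lack a length annotation", missing_ids=missing
        )
    return np.array([annotations[p].length_aa for p in protein_ids], dtype=float)
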