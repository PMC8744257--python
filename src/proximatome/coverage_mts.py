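"""Peptide-coverage analysis against mitochondrial targeting sequences.

Nucleus-encoded mitochondrial proteins carry an N-terminal targeting
sequence (MTS) that is cleaved on import.  If a protein pool detected by
mass spectrometry were the cytosolic precursor, peptides mapping inside the
MTS would appear; if the pool is the matured, imported form, coverage starts
downstream of the MTS.  This module merges peptide intervals per protein and
reports whether the annotated MTS region is covered.

"MTS covered" is operationalized as at least ``min_overlap`` amino acids of
intersection between the merged coverage and the annotated MTS interval
(default 1, the strictest falsifiable reading).  Peptides count once
regardless of spectral count: coverage is a positional statement, not a
quantitative one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import InvariantError
from .io_model import PeptideHit, ProteinAnnotation


@dataclass
class CoverageReport:
    """Merged coverage of one protein and its overlap with the MTS."""

    protein_id: str
    merged_intervals: list[tuple[int, int]]
    coverage_fraction: float
    mts_overlap_aa: Optional[int]      # None when the protein has no MTS
    mts_covered: Optional[bool]        # None = not applicable (no MTS)
    first_covered_residue: Optional[int]


def merge_coverage(peptides: Iterable[PeptideHit]) -> list[tuple[int, int]]:
    """Union of peptide intervals; overlapping or adjacent (gap 0) merge."""
    intervals = sorted((p.start, p.end) for p in peptides)
    merged: list[tuple[int, int]] = []
    for start, end in intervals:
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def covered_length(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(end - start + 1 for start, end in intervals)


def interval_overlap(intervals: Sequence[tuple[int, int]],
                     target: tuple[int, int]) -> int:
    """Total amino acids of intersection between intervals and target."""
    t_start, t_end = target
    return sum(
        max(0, min(end, t_end) - max(start, t_start) + 1)
        for start, end in intervals
    )


def mts_overlap_report(protein_id: str, peptides: Iterable[PeptideHit],
                       annotation: ProteinAnnotation,
                       min_overlap: int = 1) -> CoverageReport:
    """Coverage report for one protein, including MTS overlap if annotated."""
    peptides = [p for p in peptides if p.protein_id == protein_id]
    for p in peptides:
        if p.end > annotation.length_aa:
            raise InvariantError(
                f"{protein_id}: peptide [{p.start},{p.end}] beyond length "
                f"{annotation.length_aa}"
            )
    merged = merge_coverage(peptides)
    fraction = covered_length(merged) / annotation.length_aa
    if annotation.mts_interval is None:
        overlap, covered = None, None
    else:
        overlap = interval_overlap(merged, annotation.mts_interval)
        covered = overlap >= min_overlap
    return CoverageReport(
        protein_id=protein_id,
        merged_intervals=merged,
        coverage_fraction=fraction,
        mts_overlap_aa=overlap,
        mts_covered=covered,
        first_covered_residue=merged[0][0] if merged else None,
    )


def coverage_table(peptides: Iterable[PeptideHit],
                   annotations: Mapping[str, ProteinAnnotation],
                   min_overlap: int = 1,
                   protein_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """One CoverageReport row per protein, intervals serialized "s-e;s-e"."""
    by_protein: dict[str, list[PeptideHit]] = {}
    for p in peptides:
        by_protein.setdefault(p.protein_id, []).append(p)
    ids = list(protein_ids) if protein_ids is not None else sorted(
        set(by_protein) & set(annotations)
    )
    rows = []
    for pid in ids:
        report = mts_overlap_report(
            pid, by_protein.get(pid, []), annotations[pid], min_overlap
        )
        rows.append(
            {
                "protein_id": pid,
                "merged_intervals": ";".join(
                    f"{s}-{e}" for s, e in report.merged_intervals
                ),
                "coverage_fraction": report.coverage_fraction,
                "mts_overlap_aa": report.mts_overlap_aa,
                "mts_covered": report.mts_covered,
                "first_covered_residue": report.first_covered_residue,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "merged_intervals", "coverage_fraction",
                 "mts_overlap_aa", "mts_covered", "first_covered_residue"],
    )
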