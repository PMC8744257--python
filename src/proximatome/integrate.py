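"""Set-level integration of enriched lists with annotation sources.

Covers three recurring steps: filtering an APEX-seq-style outer-membrane
mRNA table to the significantly and positively enriched genes (FDR < 0.1 and
log2FC > 0, both strict), overlap statistics between two gene/protein sets
(intersection size, percent overlap, Jaccard), and tagging a set's members
with annotation flags (Mitocarta membership, Uniprot MTS, mitochondrial
genome encoding).

Identifier matching is case-normalized exact string equality; cross-species
or symbol/accession mismatches are resolved with an explicit user-supplied
synonym map, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptyInputError, InvariantError, SchemaError
from .io_model import ProteinAnnotation


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols or accessions."""

    name: str
    members: frozenset[str]
    provenance: str = ""

    def __post_init__(self):
        if not self.name:
            raise InvariantError("gene set needs a non-empty name")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


def _normalize(members: Iterable[str],
               synonyms: Mapping[str, str] | None = None) -> frozenset[str]:
    synonyms = {k.upper(): v.upper() for k, v in (synonyms or {}).items()}
    out = set()
    for m in members:
        key = str(m).strip().upper()
        out.add(synonyms.get(key, key))
    return frozenset(out)


def make_gene_set(name: str, members: Iterable[str], provenance: str = "",
                  synonyms: Mapping[str, str] | None = None) -> GeneSet:
    return GeneSet(name, _normalize(members, synonyms), provenance)


def filter_omm_table(table: pd.DataFrame, fdr_max: float = 0.1,
                     log2fc_min: float = 0.0, name: str = "omm_mrnas") -> GeneSet:
    """Genes with fdr < fdr_max and log2_fc > log2fc_min (both strict)."""
    missing = {"gene", "log2_fc", "fdr"} - set(table.columns)
    if missing:
        raise SchemaError(f"mRNA table missing columns: {sorted(missing)}")
    keep = table[(table["fdr"] < fdr_max) & (table["log2_fc"] > log2fc_min)]
    return make_gene_set(
        name, keep["gene"].astype(str),
        provenance=f"fdr<{fdr_max}, log2_fc>{log2fc_min}",
    )


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_intersection: int
    overlap_percent: float          # denominator = smaller set
    overlap_percent_of_a: float     # both denominators reported to avoid ambiguity
    overlap_percent_of_b: float
    jaccard: float
    intersection: list[str] = field(default_factory=list)


def set_overlap(a: GeneSet, b: GeneSet,
                synonyms: Mapping[str, str] | None = None) -> OverlapResult:
    """Overlap statistics; overlap_percent uses the smaller set as denominator."""
    if not a.members or not b.members:
        raise EmptyInputError("set overlap requires two non-empty sets")
    mem_a = _normalize(a.members, synonyms)
    mem_b = _normalize(b.members, synonyms)
    inter = mem_a & mem_b
    union = mem_a | mem_b
    return OverlapResult(
        n_a=len(mem_a),
        n_b=len(mem_b),
        n_intersection=len(inter),
        overlap_percent=100.0 * len(inter) / min(len(mem_a), len(mem_b)),
        overlap_percent_of_a=100.0 * len(inter) / len(mem_a),
        overlap_percent_of_b=100.0 * len(inter) / len(mem_b),
        jaccard=len(inter) / len(union),
        intersection=sorted(inter),
    )


def annotate_sets(gene_set: GeneSet,
                  annotations: Iterable[ProteinAnnotation] | Mapping[str, ProteinAnnotation]
                  ) -> tuple[pd.DataFrame, dict]:
    """Per-member annotation flags and summary counts.

    Members are matched against annotation accessions and gene symbols
    (case-insensitive).  Uncovered members are listed as unannotated and
    contribute only to n_total.  Summary: (n_total, n_mitochondrial,
    n_with_mts, n_mito_encoded) plus the unannotated list.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.protein_id: a for a in annotations}
    lookup: dict[str, ProteinAnnotation] = {}
    for ann in annotations.values():
        lookup.setdefault(ann.protein_id.upper(), ann)
        lookup.setdefault(ann.gene_symbol.upper(), ann)
    rows, unannotated = [], []
    for member in sorted(gene_set.members):
        ann = lookup.get(member.upper())
        if ann is None:
            unannotated.append(member)
            rows.append(dict(member=member, annotated=False,
                             is_mitochondrial=False, has_mts=False,
                             is_mito_encoded=False))
        else:
            rows.append(dict(member=member, annotated=True,
                             is_mitochondrial=ann.is_mitochondrial,
                             has_mts=ann.has_mts,
                             is_mito_encoded=ann.is_mito_encoded))
    frame = pd.DataFrame(
        rows, columns=["member", "annotated", "is_mitochondrial",
                       "has_mts", "is_mito_encoded"],
    )
    summary = {
        "n_total": int(len(frame)),
        "n_mitochondrial": int(frame["is_mitochondrial"].sum()) if len(frame) else 0,
        "n_with_mts": int(frame["has_mts"].sum()) if len(frame) else 0,
        "n_mito_encoded": int(frame["is_mito_encoded"].sum()) if len(frame) else 0,
        "unannotated": unannotated,
    }
    return frame, summary
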