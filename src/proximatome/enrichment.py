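"""Bait-over-control enrichment from spectral counts.

A protein is called enriched in the bait purification when its pseudocounted
fold change exceeds ``fc_min`` and its FDR falls below ``fdr_max`` (defaults
FC > 2, FDR < 0.1, both strict).  Fold change is

    FC = (mean bait SpC + alpha) / (mean control SpC + alpha)

with pseudocount ``alpha`` (default 1) keeping FC finite when the control is
empty.  Confidence comes from one of three backends:

``external``
    pass-through of an upstream scorer's fold-change/FDR columns (e.g. a
    SAINT-style export), used when reproducing published selections;
``binomial``
    an exact one-sided binomial tail on the split of total spectra between
    bait and control libraries: with K_b bait and K_c control spectra and
    library weight w = n_bait/(n_bait + n_control), p = P(X >= K_b) for
    X ~ Binomial(K_b + K_c, w);
``permutation``
    the empirical one-sided p of the observed fold change against fold
    changes from every distinct reassignment of bait/control labels.

Internal backends feed Benjamini-Hochberg to produce an FDR.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    InsufficientPermutationsError,
    UndefinedRatioError,
    ValidationError,
)
from .io_model import CountMatrix, ExternalEnrichmentTable, SampleDesign

RECORD_COLUMNS = [
    "protein_id", "mean_bait", "mean_control", "fold_change", "log2_fc",
    "p_value", "fdr", "enriched",
]


def compute_fold_change(matrix: CountMatrix, design: SampleDesign,
                        pseudocount: float = 1.0,
                        timepoint: str | None = None) -> pd.DataFrame:
    """Per-protein bait and control means and pseudocounted fold change.

    Returns a frame with columns protein_id, mean_bait, mean_control,
    fold_change, log2_fc.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be nonnegative")
    bait_ids, control_ids = design.require_contrast(timepoint)
    mean_bait = matrix.columns(bait_ids).mean(axis=1)
    mean_control = matrix.columns(control_ids).mean(axis=1)
    if pseudocount == 0 and (mean_control == 0).any():
        raise UndefinedRatioError(
            "zero control mean with pseudocount 0; pass a positive pseudocount"
        )
    fc = (mean_bait + pseudocount) / (mean_control + pseudocount)
    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "mean_bait": mean_bait,
            "mean_control": mean_control,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
        }
    )


def binomial_p(k_bait: np.ndarray, k_control: np.ndarray,
               n_bait: int, n_control: int) -> np.ndarray:
    """Exact one-sided tail P(X >= K_b), X ~ Binomial(K_b+K_c, w).

    w = n_bait / (n_bait + n_control) weights for unequal library numbers.
    K_b = K_c = 0 gives p = 1 (no evidence).
    """
    k_bait = np.asarray(k_bait, dtype=np.int64)
    k_control = np.asarray(k_control, dtype=np.int64)
    w = n_bait / (n_bait + n_control)
    total = k_bait + k_control
    # sf(k-1) = P(X >= k); clip handles K_b = 0 -> p = 1 exactly
    return np.where(total == 0, 1.0, stats.binom.sf(k_bait - 1, total, w))


def permutation_p(matrix: CountMatrix, design: SampleDesign,
                  pseudocount: float = 1.0,
                  timepoint: str | None = None) -> np.ndarray:
    """Empirical one-sided p of the observed FC over all distinct
    bait/control label reassignments (the identity included)."""
    bait_ids, control_ids = design.require_contrast(timepoint)
    all_ids = bait_ids + control_ids
    n_total, n_bait = len(all_ids), len(bait_ids)
    if n_total < 4:
        raise InsufficientPermutationsError(
            f"permutation backend needs >= 4 samples, got {n_total}"
        )
    n_perm = comb(n_total, n_bait)
    if n_perm < 100:
        warnings.warn(
            f"only {n_perm} distinct label reassignments; p-value granularity "
            f"is limited to 1/{n_perm}",
            stacklevel=2,
        )
    counts = matrix.columns(all_ids).astype(float)
    observed = _fc_for_split(counts, tuple(range(n_bait)), pseudocount)
    n_ge = np.zeros(len(matrix.protein_ids), dtype=np.int64)
    for bait_idx in combinations(range(n_total), n_bait):
        fc = _fc_for_split(counts, bait_idx, pseudocount)
        n_ge += fc >= observed - 1e-12
    return n_ge / n_perm


def _fc_for_split(counts: np.ndarray, bait_idx: tuple[int, ...],
                  pseudocount: float) -> np.ndarray:
    mask = np.zeros(counts.shape[1], dtype=bool)
    mask[list(bait_idx)] = True
    return (counts[:, mask].mean(axis=1) + pseudocount) / (
        counts[:, ~mask].mean(axis=1) + pseudocount
    )


def score_enrichment(matrix: CountMatrix, design: SampleDesign,
                     backend: str = "binomial",
                     external: ExternalEnrichmentTable | None = None,
                     pseudocount: float = 1.0,
                     timepoint: str | None = None) -> pd.Series:
    """Per-protein p-value under the chosen backend (indexed by protein_id).

    ``external`` pass-through returns the export's FDR column as the
    "p-value" slot only if the export carries one; normally external tables
    enter via :func:`records_from_external` which keeps their FDR as FDR.
    """
    if backend == "binomial":
        bait_ids, control_ids = design.require_contrast(timepoint)
        k_b = matrix.columns(bait_ids).sum(axis=1)
        k_c = matrix.columns(control_ids).sum(axis=1)
        p = binomial_p(k_b, k_c, len(bait_ids), len(control_ids))
    elif backend == "permutation":
        p = permutation_p(matrix, design, pseudocount, timepoint)
    elif backend == "external":
        if external is None:
            raise ValidationError("backend='external' requires an external table")
        frame = external.frame.set_index("protein_id")
        col = "p_value" if "p_value" in frame.columns else "fdr"
        return frame[col].reindex(matrix.protein_ids)
    else:
        raise ValidationError(f"unknown backend {backend!r}")
    return pd.Series(p, index=matrix.protein_ids, name="p_value")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_records(matrix: CountMatrix, design: SampleDesign,
                  backend: str = "binomial",
                  external: ExternalEnrichmentTable | None = None,
                  pseudocount: float = 1.0,
                  fc_min: float = 2.0, fdr_max: float = 0.1,
                  timepoint: str | None = None) -> pd.DataFrame:
    """Full enrichment table: FC, p, FDR and the enriched flag.

    With internal backends the FDR is BH on backend p-values.  With
    ``backend='external'`` the export's fold change and FDR are consumed
    as-is (the upstream scorer's own FDR, e.g. SAINT BFDR, is not re-derived).
    """
    if backend == "external":
        if external is None:
            raise ValidationError("backend='external' requires an external table")
        return records_from_external(external, fc_min=fc_min, fdr_max=fdr_max)
    records = compute_fold_change(matrix, design, pseudocount, timepoint)
    p = score_enrichment(matrix, design, backend, external, pseudocount, timepoint)
    records["p_value"] = p.to_numpy()
    records["fdr"] = adjust_bh(records["p_value"])
    records["enriched"] = (records["fold_change"] > fc_min) & (records["fdr"] < fdr_max)
    return records[RECORD_COLUMNS]


def records_from_external(table: ExternalEnrichmentTable,
                          fc_min: float = 2.0, fdr_max: float = 0.1) -> pd.DataFrame:
    """Enrichment records carrying an upstream scorer's FC/FDR columns."""
    f = table.frame
    records = pd.DataFrame(
        {
            "protein_id": f["protein_id"].astype(str),
            "mean_bait": f.get("mean_bait", np.nan),
            "mean_control": f.get("mean_control", np.nan),
            "fold_change": f["fold_change"].astype(float),
            "log2_fc": np.log2(f["fold_change"].astype(float)),
            "p_value": f.get("p_value", np.nan),
            "fdr": f["fdr"].astype(float),
        }
    )
    records["enriched"] = (records["fold_change"] > fc_min) & (records["fdr"] < fdr_max)
    return records[RECORD_COLUMNS]


def filter_enriched(records: pd.DataFrame,
                    fc_min: float = 2.0, fdr_max: float = 0.1) -> pd.DataFrame:
    """Enriched subset: FC > fc_min and FDR < fdr_max, both strict.

    Output is sorted by descending fold change, ties broken by protein_id.
    """
    for col in ("fold_change", "fdr"):
        if col not in records.columns:
            raise ValidationError(f"records lack column {col!r}")
    keep = records[(records["fold_change"] > fc_min) & (records["fdr"] < fdr_max)]
    return (
        keep.sort_values(["fold_change", "protein_id"],
                         ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
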