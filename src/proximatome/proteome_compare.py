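"""Length-normalized abundance and paired proteome comparison.

Spectral counts scale with protein length, so per-protein abundance is the
mean spectral count over replicates divided by the protein length in amino
acids (a spectral abundance factor).  Abundances are z-scored over the
declared protein universe (all proteins detected in that sample by default)
with the sample (n-1) standard deviation, and two proteomes are compared on
the z scale: Pearson and Spearman correlation over shared proteins plus a
count of discordant proteins (|z_a - z_b| > 2).  Proteins detected in only
one proteome are listed, never silently dropped.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDistributionError, InsufficientOverlapError
from .io_model import CountMatrix, ProteinAnnotation, require_lengths


def saf_abundance(matrix: CountMatrix, sample_ids: Sequence[str],
                  annotations: Mapping[str, ProteinAnnotation]) -> pd.DataFrame:
    """Mean spectral count over the given replicates, divided by length.

    Returns a frame with protein_id, mean_spc, abundance.  Raises listing
    the offending ids if any protein lacks a length annotation.
    """
    lengths = require_lengths(matrix.protein_ids, annotations)
    mean_spc = matrix.columns(sample_ids).mean(axis=1)
    return pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "mean_spc": mean_spc,
            "abundance": mean_spc / lengths,
        }
    )


def zscore_profile(profiles: pd.DataFrame) -> pd.DataFrame:
    """z = (A - mean A) / sd(A) over the profile's protein universe (ddof=1)."""
    a = profiles["abundance"].to_numpy(dtype=float)
    if len(a) < 2 or np.std(a, ddof=1) == 0:
        raise DegenerateDistributionError(
            "z-scoring needs >= 2 proteins with nonidentical abundances"
        )
    out = profiles.copy()
    out["z"] = (a - a.mean()) / np.std(a, ddof=1)
    return out


def compare_proteomes(profile_a: pd.DataFrame, profile_b: pd.DataFrame,
                      annotations: Mapping[str, ProteinAnnotation] | None = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Pair two z-scored profiles on shared proteins.

    Returns the paired table (protein_id, z_a, z_b, delta_z,
    is_mitochondrial) and a concordance summary: Pearson and Spearman
    correlation of z, the number of proteins with |z_a - z_b| > 2, and the
    ids detected in only one proteome.
    """
    for profile in (profile_a, profile_b):
        if "z" not in profile.columns:
            raise DegenerateDistributionError(
                "profiles must be z-scored first (zscore_profile)"
            )
    a = profile_a.set_index("protein_id")["z"]
    b = profile_b.set_index("protein_id")["z"]
    shared = sorted(set(a.index) & set(b.index))
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"need >= 3 shared proteins, got {len(shared)}"
        )
    paired = pd.DataFrame(
        {
            "protein_id": shared,
            "z_a": a.loc[shared].to_numpy(),
            "z_b": b.loc[shared].to_numpy(),
        }
    )
    paired["delta_z"] = paired["z_a"] - paired["z_b"]
    if annotations is not None:
        paired["is_mitochondrial"] = [
            annotations[p].is_mitochondrial if p in annotations else False
            for p in shared
        ]
    pearson = stats.pearsonr(paired["z_a"], paired["z_b"]).statistic
    spearman = stats.spearmanr(paired["z_a"], paired["z_b"]).statistic
    summary = {
        "n_shared": len(shared),
        "pearson": float(pearson),
        "spearman": float(spearman),
        "n_outliers": int((paired["delta_z"].abs() > 2).sum()),
        "only_a": sorted(set(a.index) - set(b.index)),
        "only_b": sorted(set(b.index) - set(a.index)),
    }
    return paired, summary


def node_attributes(records: pd.DataFrame, profiles: pd.DataFrame,
                    annotations: Mapping[str, ProteinAnnotation]) -> pd.DataFrame:
    """Node-attribute table for external network-visualization tools:
    protein_id, log2_fc, abundance, is_mitochondrial, has_mts."""
    merged = records[["protein_id", "log2_fc"]].merge(
        profiles[["protein_id", "abundance"]], on="protein_id", how="left"
    )
    merged["is_mitochondrial"] = [
        annotations[p].is_mitochondrial if p in annotations else False
        for p in merged["protein_id"]
    ]
    merged["has_mts"] = [
        annotations[p].has_mts if p in annotations else False
        for p in merged["protein_id"]
    ]
    return merged.sort_values("protein_id", kind="mergesort").reset_index(drop=True)
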