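"""Two-timepoint classification of enriched proteins.

After proximity labeling for a short (e.g. 30 min) and a long (e.g. 16 h)
duration, each protein enriched at both time points gets an FC-variation
ratio R = FC_late / FC_early.  Proteins with R below a threshold (default
0.5) show decreasing relative enrichment over time — the signature of stable
interactors that are labeled once and then diluted by accumulating
background — and form group 1.  Proteins with R at or above the threshold
(stable or increasing enrichment) form group 2; in the CLUH system this
group captures high-flux mitochondrial precursor substrates that are
continuously synthesized, labeled and imported.

The ratio direction is fixed as late over early so that "reduced enrichment
over time" reads as R < 1.  The boundary is inclusive on the group-2 side
(R = threshold -> group 2).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ValidationError
from .io_model import ProteinAnnotation

GROUP1 = "group1"
GROUP2 = "group2"


def fc_variation(fc_early, fc_late):
    """FC-variation ratio R = fc_late / fc_early (scalar or array)."""
    fc_early = np.asarray(fc_early, dtype=float)
    fc_late = np.asarray(fc_late, dtype=float)
    if np.any(fc_early <= 0) or np.any(fc_late <= 0):
        raise ValidationError("fold changes must be strictly positive")
    ratio = fc_late / fc_early
    return float(ratio) if ratio.ndim == 0 else ratio


def pair_timepoints(early: pd.DataFrame, late: pd.DataFrame,
                    enriched_only: bool = True
                    ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Join early/late enrichment records on protein_id.

    Returns (paired frame with fc_early/fc_late, ids enriched only early,
    ids enriched only late).  Proteins enriched at a single time point
    cannot receive a ratio and are listed, not classified.
    """
    def _side(records, suffix):
        r = records
        if enriched_only and "enriched" in r.columns:
            r = r[r["enriched"].astype(bool)]
        return r[["protein_id", "fold_change"]].rename(
            columns={"fold_change": f"fc_{suffix}"}
        )

    e, l = _side(early, "early"), _side(late, "late")
    paired = e.merge(l, on="protein_id", how="inner")
    only_early = sorted(set(e["protein_id"]) - set(paired["protein_id"]))
    only_late = sorted(set(l["protein_id"]) - set(paired["protein_id"]))
    return paired.reset_index(drop=True), only_early, only_late


def classify_groups(records: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Attach the FC-variation ratio and group label to paired records.

    ratio < threshold -> group1; ratio >= threshold -> group2.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    out = records.copy()
    out["ratio"] = fc_variation(out["fc_early"].to_numpy(), out["fc_late"].to_numpy())
    out["group"] = np.where(out["ratio"] < threshold, GROUP1, GROUP2)
    return out


def group_composition(records: pd.DataFrame,
                      annotations: Iterable[ProteinAnnotation] | Mapping[str, ProteinAnnotation],
                      flag: str = "is_mitochondrial") -> dict:
    """Group sizes and the split of annotated (e.g. mitochondrial) proteins.

    For each group reports its size, the number of flag-true members and the
    share (percent, one-decimal rounding) of all flag-true classified
    proteins that fall in that group.  Protein ids with no annotation entry
    are treated as flag-false and listed under ``unannotated``.
    """
    if records.empty:
        raise EmptyInputError("no classified records to summarize")
    if not isinstance(annotations, Mapping):
        annotations = {a.protein_id: a for a in annotations}
    flags = records["protein_id"].map(
        lambda p: bool(getattr(annotations[p], flag)) if p in annotations else False
    )
    unannotated = sorted(
        p for p in records["protein_id"] if p not in annotations
    )
    n_flag_total = int(flags.sum())
    summary: dict = {"n_total": int(len(records)),
                     "n_annotated_true": n_flag_total,
                     "unannotated": unannotated,
                     "groups": {}}
    for group in (GROUP1, GROUP2):
        in_group = records["group"] == group
        n_flag = int((flags & in_group).sum())
        share = 100.0 * n_flag / n_flag_total if n_flag_total else 0.0
        summary["groups"][group] = {
            "size": int(in_group.sum()),
            "n_annotated_true": n_flag,
            "share_percent": round(share, 1),
        }
    return summary
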