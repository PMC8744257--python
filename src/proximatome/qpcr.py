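"""qPCR-derived statistics: 2^-ddCT, RIP percent-of-input, decay curves.

All computations work on cycle-threshold (CT) values and assume perfect
two-fold amplification per cycle (no efficiency calibration).  Replicates
are averaged on the CT scale before differencing — equivalent to a
geometric mean of quantities and invariant to a global machine-baseline
shift of all CT values.

Three quantities:

* **2^-ddCT** relative expression: dCT = CT_target - CT_reference within each
  condition, ddCT = dCT_test - dCT_calibrator, relative quantity 2^-ddCT.
* **% of input** for RNA immunoprecipitation or subcellular fractions:
  a fraction f of the input lysate (default 1%) is carried through in
  parallel, so recovery = 100 * f * 2^(CT_input - CT_IP); optionally
  normalized to a reference target as a ratio of percent-input values.
* **mRNA decay** after transcription arrest: remaining fraction at time t is
  2^-[(CT_tgt(t) - CT_ref(t)) - (CT_tgt(0) - CT_ref(0))], anchored at 1 for
  t = 0, with an optional log-linear fit giving half-life = ln 2 / rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import (
    AnchorError,
    MissingNormalizerError,
    SchemaError,
    ValidationError,
)

TABLE_COLUMNS = ["target", "sample", "role", "timepoint", "replicate", "ct"]


def validate_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = {"target", "sample", "replicate", "ct"} - set(table.columns)
    if missing:
        raise SchemaError(f"qPCR table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValidationError("CT values must be positive cycle numbers")
    return table


def mean_ct(table: pd.DataFrame, target: str, sample: str) -> float:
    """Replicate-mean CT for one (target, sample); replicates averaged on
    the CT scale (geometric mean of quantities)."""
    rows = table[(table["target"] == target) & (table["sample"] == sample)]
    if rows.empty:
        raise MissingNormalizerError(
            f"no CT rows for target {target!r} in sample {sample!r}"
        )
    return float(rows["ct"].mean())


def ddct(ct_target_test: float, ct_ref_test: float,
         ct_target_calib: float, ct_ref_calib: float) -> float:
    """Relative quantity 2^-ddCT of target in test vs calibrator condition."""
    delta_test = ct_target_test - ct_ref_test
    delta_calib = ct_target_calib - ct_ref_calib
    return float(2.0 ** (-(delta_test - delta_calib)))


def ddct_from_table(table: pd.DataFrame, target: str, reference: str,
                    test_sample: str, calibrator_sample: str) -> float:
    """2^-ddCT from a long-format CT table, averaging replicates first."""
    validate_qpcr_table(table)
    return ddct(
        mean_ct(table, target, test_sample),
        mean_ct(table, reference, test_sample),
        mean_ct(table, target, calibrator_sample),
        mean_ct(table, reference, calibrator_sample),
    )


@dataclass
class EnrichmentFraction:
    """Recovery of a target relative to the (diluted) input sample."""

    target: str
    percent_input: float
    normalized_percent_input: Optional[float]
    input_fraction: float


def percent_input(ct_ip: float, ct_input: float, input_fraction: float = 0.01,
                  reference: Optional[tuple[float, float]] = None,
                  target: str = "") -> EnrichmentFraction:
    """% of input = 100 * f * 2^(CT_input - CT_IP).

    ``input_fraction`` f is the share of lysate set aside as input (1% in
    the standard protocol); the correction accounts for that dilution.
    ``reference`` = (ct_ip, ct_input) of a reference target yields
    normalized_percent_input as the ratio of the two recoveries.
    """
    if not 0 < input_fraction <= 1:
        raise ValidationError("input_fraction must lie in (0, 1]")
    pct = 100.0 * input_fraction * 2.0 ** (ct_input - ct_ip)
    normalized = None
    if reference is not None:
        ref_pct = 100.0 * input_fraction * 2.0 ** (reference[1] - reference[0])
        normalized = pct / ref_pct
    return EnrichmentFraction(target, pct, normalized, input_fraction)


def percent_input_from_table(table: pd.DataFrame, target: str,
                             ip_sample: str, input_sample: str,
                             input_fraction: float = 0.01,
                             reference: Optional[str] = None) -> EnrichmentFraction:
    validate_qpcr_table(table)
    ref = None
    if reference is not None:
        ref = (mean_ct(table, reference, ip_sample),
               mean_ct(table, reference, input_sample))
    return percent_input(
        mean_ct(table, target, ip_sample),
        mean_ct(table, target, input_sample),
        input_fraction, ref, target=target,
    )


@dataclass
class DecayFit:
    """Log-linear decay fit: remaining = exp(-rate * t)."""

    rate_per_hour: float
    half_life_hours: float
    no_decay: bool


def decay_curve(ct_target: Mapping[float, float], ct_ref: Mapping[float, float],
                t0: float = 0.0) -> pd.DataFrame:
    """Remaining fraction per timepoint, normalized to reference and t0.

    ``ct_target`` and ``ct_ref`` map timepoint (hours) to replicate-mean CT.
    remaining(t) = 2^-[(dCT(t)) - (dCT(t0))] with dCT = CT_target - CT_ref;
    remaining(t0) = 1 by construction.
    """
    if t0 not in ct_target or t0 not in ct_ref:
        raise AnchorError(f"t0 = {t0} missing from target or reference CTs")
    times = sorted(set(ct_target) & set(ct_ref))
    d0 = ct_target[t0] - ct_ref[t0]
    rows = [
        {"time": t, "remaining": 2.0 ** (-((ct_target[t] - ct_ref[t]) - d0))}
        for t in times
    ]
    return pd.DataFrame(rows)


def fit_half_life(curve: pd.DataFrame) -> DecayFit:
    """Least-squares slope of ln(remaining) vs time, through the t=0 anchor.

    The model ln(remaining) = -rate * t has no intercept because the curve
    is normalized to 1 at t = 0.  A nonpositive fitted rate is flagged as
    "no decay" with infinite half-life.
    """
    t = curve["time"].to_numpy(dtype=float)
    r = curve["remaining"].to_numpy(dtype=float)
    if (r <= 0).any():
        raise ValidationError("remaining fractions must be positive to fit decay")
    mask = t > 0
    if not mask.any():
        raise AnchorError("need at least one timepoint after t = 0 to fit decay")
    log_r = np.log(r[mask])
    slope = float(np.sum(t[mask] * log_r) / np.sum(t[mask] ** 2))
    rate = -slope
    if rate <= 0:
        return DecayFit(rate_per_hour=rate, half_life_hours=float("inf"), no_decay=True)
    return DecayFit(rate_per_hour=rate, half_life_hours=float(np.log(2) / rate),
                    no_decay=False)


def decay_from_table(table: pd.DataFrame, target: str, reference: str,
                     t0: str | float = 0.0) -> tuple[pd.DataFrame, DecayFit]:
    """Decay curve and half-life fit from a long-format CT table.

    Timepoints are read from the ``timepoint`` column and parsed as hours
    (plain numbers, or strings like "4h" / "30min").
    """
    validate_qpcr_table(table)
    if "timepoint" not in table.columns:
        raise SchemaError("decay analysis needs a 'timepoint' column")

    def _curve(tgt: str) -> dict[float, float]:
        rows = table[table["target"] == tgt]
        return {
            parse_timepoint(tp): float(grp["ct"].mean())
            for tp, grp in rows.groupby("timepoint")
        }

    t0_hours = parse_timepoint(t0)
    curve = decay_curve(_curve(target), _curve(reference), t0=t0_hours)
    return curve, fit_half_life(curve)


def parse_timepoint(label) -> float:
    """Parse a timepoint label to hours: 4, "4", "4h", "30min", "16 h"."""
    if isinstance(label, (int, float)) and not isinstance(label, bool):
        return float(label)
    s = str(label).strip().lower().replace(" ", "")
    for suffix, factor in (("min", 1 / 60), ("h", 1.0)):
        if s.endswith(suffix):
            return float(s[: -len(suffix)]) * factor
    return float(s)
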