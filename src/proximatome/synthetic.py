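"""Synthetic datasets with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a proximity-labeling
spectral-count experiment: bait and control purifications in triplicate,
negative-binomial counts (overdispersed relative to Poisson, as spectral
counts are), and three planted protein classes —

``background``
    nonspecific contaminants, true fold change 1 at both labeling durations;
``stable_interactor``
    proteins stably bound to the bait: strongly enriched at the short
    labeling time, with a late/early FC-variation ratio drawn below the 0.5
    group boundary (LogNormal(log 0.2, 0.2)) — labeled once, then diluted
    by accumulating background signal;
``transient_flux``
    high-flux substrates (mostly mitochondrial precursors): enriched at both
    times with ratio drawn at or above the boundary (LogNormal(log 1.2,
    0.2)) — continuously synthesized, labeled and imported.

Counts are NegBinomial with mean = baseline_mean * true FC on the bait side
and baseline_mean on the control side; ``nb_dispersion`` is the gamma shape
r (variance = m + m^2/r; the Poisson limit is recovered as r -> inf).
All draws go through one ``numpy.random.Generator`` seeded from the config,
so outputs are bit-identical for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .io_model import (
    CountMatrix,
    PeptideHit,
    ProteinAnnotation,
    Sample,
    SampleDesign,
)

CLASSES = ("background", "stable_interactor", "transient_flux")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic interactome.

    Defaults mirror the experimental design being emulated: 3 bait + 3
    control replicates, a control-side mean of 10 spectra per protein,
    mild overdispersion, an 8-fold stable-interactor enrichment, and
    late/early ratio distributions placed on either side of the 0.5 group
    boundary.
    """

    n_proteins: int = 500
    class_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    baseline_mean: float = 10.0
    nb_dispersion: float = 10.0
    effect_fc_stable: float = 8.0
    effect_fc_flux_early: float = 4.0
    effect_fc_flux_late: float = 5.0
    n_replicates: int = 3
    protein_length_range: tuple[int, int] = (100, 1000)
    mts_length_range: tuple[int, int] = (15, 60)
    mito_fraction_among_flux: float = 0.9
    mito_fraction_among_stable: float = 0.05
    ratio_logmean_stable: float = float(np.log(0.2))
    ratio_logmean_flux: float = float(np.log(1.2))
    ratio_logsd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.class_fractions, dtype=float)
        if len(f) != 3 or np.any(f < 0) or np.any(f > 1) or abs(f.sum() - 1) > 1e-9:
            raise ConfigError(
                "class_fractions must be three values in [0,1] summing to 1"
            )
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigError("baseline_mean and nb_dispersion must be > 0")
        for name in ("effect_fc_stable", "effect_fc_flux_early", "effect_fc_flux_late"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ConfigError("n_proteins and n_replicates must be >= 1")
        if not 0 <= self.mito_fraction_among_flux <= 1:
            raise ConfigError("mito_fraction_among_flux must lie in [0,1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _nb_counts(rng: np.random.Generator, mean, dispersion: float, size) -> np.ndarray:
    """NegBinomial(mean m, shape r): var = m + m^2/r."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if not np.isfinite(dispersion):
        return rng.poisson(mean).astype(np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_proteins
    counts = np.floor(np.asarray(config.class_fractions) * n).astype(int)
    # distribute the rounding remainder to the largest fractions
    remainder = n - counts.sum()
    order = np.argsort(config.class_fractions)[::-1]
    for i in range(remainder):
        counts[order[i % 3]] += 1
    classes = np.repeat(np.array(CLASSES), counts)
    rng.shuffle(classes)
    return classes


def _make_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ground truth: class, true FC at both timepoints, annotation fields."""
    n = config.n_proteins
    classes = _assign_classes(config, rng)
    width = len(str(n))
    protein_ids = [f"SYN{i:0{width}d}" for i in range(1, n + 1)]
    lengths = rng.integers(config.protein_length_range[0],
                           config.protein_length_range[1] + 1, size=n)

    fc_early = np.ones(n)
    ratio = np.ones(n)
    stable = classes == "stable_interactor"
    flux = classes == "transient_flux"
    fc_early[stable] = config.effect_fc_stable
    fc_early[flux] = config.effect_fc_flux_early
    ratio[stable] = rng.lognormal(config.ratio_logmean_stable,
                                  config.ratio_logsd, stable.sum())
    ratio[flux] = rng.lognormal(config.ratio_logmean_flux,
                                config.ratio_logsd, flux.sum())
    fc_late = fc_early * ratio

    is_mito = np.zeros(n, dtype=bool)
    is_mito[flux] = rng.random(flux.sum()) < config.mito_fraction_among_flux
    is_mito[stable] = rng.random(stable.sum()) < config.mito_fraction_among_stable

    mts_start = np.where(is_mito, 1, 0)
    mts_len = rng.integers(config.mts_length_range[0],
                           config.mts_length_range[1] + 1, size=n)
    mts_end = np.where(is_mito, np.minimum(mts_len, lengths), 0)

    return pd.DataFrame(
        {
            "protein_id": protein_ids,
            "true_class": classes,
            "true_fc_early": fc_early,
            "true_fc_late": fc_late,
            "true_ratio": ratio,
            "is_mitochondrial": is_mito,
            "length_aa": lengths,
            "mts_start": mts_start,
            "mts_end": mts_end,
        }
    )


def _truth_annotations(truth: pd.DataFrame) -> list[ProteinAnnotation]:
    out = []
    for _, row in truth.iterrows():
        mts = None
        if row["mts_start"] > 0:
            mts = (int(row["mts_start"]), int(row["mts_end"]))
        out.append(
            ProteinAnnotation(
                protein_id=row["protein_id"],
                gene_symbol=row["protein_id"],
                length_aa=int(row["length_aa"]),
                is_mitochondrial=bool(row["is_mitochondrial"]),
                mts_interval=mts,
            )
        )
    return out


def _design(config: SimulationConfig, timepoint: str | None) -> SampleDesign:
    tag = f"_{timepoint}" if timepoint else ""
    samples = [
        Sample(f"bait{tag}_{r}", "bait", r, timepoint)
        for r in range(1, config.n_replicates + 1)
    ] + [
        Sample(f"control{tag}_{r}", "control", r, timepoint)
        for r in range(1, config.n_replicates + 1)
    ]
    return SampleDesign(samples)


def _counts_for(config: SimulationConfig, rng: np.random.Generator,
                truth: pd.DataFrame, fc_column: str,
                design: SampleDesign) -> CountMatrix:
    n, m = len(truth), config.n_replicates
    bait_mean = config.baseline_mean * truth[fc_column].to_numpy()[:, None]
    bait = _nb_counts(rng, bait_mean, config.nb_dispersion, (n, m))
    ctrl = _nb_counts(rng, config.baseline_mean, config.nb_dispersion, (n, m))
    return CountMatrix(list(truth["protein_id"]), design.sample_ids,
                       np.hstack([bait, ctrl]))


def simulate_dataset(config: SimulationConfig, timepoint: str = "early"
                     ) -> tuple[CountMatrix, SampleDesign, list[ProteinAnnotation], pd.DataFrame]:
    """One bait-vs-control dataset at a single labeling duration.

    ``timepoint`` selects which planted FC drives the bait means ("early"
    or "late").  Returns (counts, design, annotations, ground truth).
    """
    if timepoint not in ("early", "late"):
        raise ConfigError("timepoint must be 'early' or 'late'")
    rng = config.rng()
    truth = _make_truth(config, rng)
    design = _design(config, None)
    matrix = _counts_for(config, rng, truth, f"true_fc_{timepoint}", design)
    return matrix, design, _truth_annotations(truth), truth


def simulate_timecourse_dataset(config: SimulationConfig
                                ) -> tuple[tuple[CountMatrix, SampleDesign],
                                           tuple[CountMatrix, SampleDesign],
                                           list[ProteinAnnotation], pd.DataFrame]:
    """Early and late labeling datasets sharing one ground truth.

    The late bait mean is baseline * early FC * planted ratio, so the drawn
    per-protein ratio — not a fixed late anchor — defines the true group.
    """
    rng = config.rng()
    truth = _make_truth(config, rng)
    design_early = _design(config, "early")
    design_late = _design(config, "late")
    early = _counts_for(config, rng, truth, "true_fc_early", design_early)
    late = _counts_for(config, rng, truth, "true_fc_late", design_late)
    return (early, design_early), (late, design_late), _truth_annotations(truth), truth


def simulate_peptides(annotations: Sequence[ProteinAnnotation],
                      mode: str = "mature_only",
                      peptides_per_protein: int = 20,
                      peptide_length: int = 10,
                      seed: int | np.random.Generator = 0) -> list[PeptideHit]:
    """Peptides sampled per protein, uniform over allowed start positions.

    ``mature_only`` emulates detection of the matured (MTS-cleaved) protein
    pool: starts are drawn from (mts_end + 1) .. (L - len + 1) so the MTS
    region is never covered.  ``full_length`` draws from 1 .. (L - len + 1).
    Proteins shorter than the peptide length are skipped with a warning.
    """
    if mode not in ("mature_only", "full_length"):
        raise ConfigError("mode must be 'mature_only' or 'full_length'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits: list[PeptideHit] = []
    for ann in annotations:
        last_start = ann.length_aa - peptide_length + 1
        first_start = 1
        if mode == "mature_only" and ann.mts_interval is not None:
            first_start = ann.mts_interval[1] + 1
        if last_start < first_start:
            warnings.warn(
                f"{ann.protein_id}: protein too short for length-{peptide_length} "
                "peptides in this mode; skipped",
                stacklevel=2,
            )
            continue
        starts = rng.integers(first_start, last_start + 1, size=peptides_per_protein)
        hits.extend(
            PeptideHit(ann.protein_id, int(s), int(s) + peptide_length - 1)
            for s in starts
        )
    return hits


def simulate_qpcr_plate(true_quantities: Mapping[tuple[str, str], float],
                        ct_noise_sd: float = 0.0,
                        n_replicates: int = 3,
                        baseline_ct: float = 20.0,
                        roles: Mapping[str, str] | None = None,
                        timepoints: Mapping[str, object] | None = None,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """CT table from true relative quantities.

    ``true_quantities`` maps (target, sample) to a positive quantity;
    CT = baseline_ct - log2(quantity) + Normal(0, ct_noise_sd), so at zero
    noise every downstream qPCR statistic recovers the planted ratios
    exactly.  ``roles`` / ``timepoints`` optionally fill those columns per
    sample.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for (target, sample), quantity in true_quantities.items():
        if quantity <= 0:
            raise ValidationError(
                f"quantity for ({target}, {sample}) must be positive"
            )
        base = baseline_ct - np.log2(quantity)
        for rep in range(1, n_replicates + 1):
            ct = base + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
            rows.append(
                {
                    "target": target,
                    "sample": sample,
                    "role": (roles or {}).get(sample, ""),
                    "timepoint": (timepoints or {}).get(sample, ""),
                    "replicate": rep,
                    "ct": float(ct),
                }
            )
    return pd.DataFrame(rows)
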