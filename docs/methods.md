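# Methods

## The analysis problem

Proximity labeling (BioID/TurboID) fuses a promiscuous biotin ligase to a
bait protein; proteins within labeling range are biotinylated in vivo,
captured on streptavidin and identified by LC-MS/MS. The quantitative
questions this package answers are:

1. which proteins are *enriched* in the bait purification over a control
   purification, from label-free spectral counts;
2. which enriched proteins behave as *stable interactors* versus
   *high-flux transient substrates* when the labeling duration is varied;
3. whether the detected protein pool is the matured (post-import) or the
   precursor form of mitochondrial proteins, read off peptide coverage
   against the annotated N-terminal targeting sequence (MTS);
4. how two proteomes compare on a length-normalized abundance scale; and
5. companion qPCR statistics (relative expression, RIP recovery, mRNA
   decay) for the RNA side of the same biology.

## Enrichment model

For protein *i* with mean bait spectral count `b_i` and mean control count
`c_i` over replicates, the fold change is

    FC_i = (b_i + α) / (c_i + α)

with pseudocount α = 1 by default. α keeps FC finite and interpretable when
the control is empty; it is configurable, and α = 0 is rejected whenever a
control mean is zero. A protein is called enriched when FC > 2 **and**
FDR < 0.1, both strict inequalities.

Confidence backends:

* **external** — a published upstream scorer's fold-change and FDR columns
  (e.g. a SAINT export) are consumed as-is. That scorer's Bayesian model is
  deliberately not re-derived here; when reproducing published selections
  this is the backend to use.
* **binomial** — an exact one-sided tail test on how total spectra split
  between libraries: with `K_b` summed bait and `K_c` summed control
  spectra and library weight `w = n_bait/(n_bait+n_control)`, the p-value
  is `P(X ≥ K_b)` for `X ~ Binomial(K_b+K_c, w)`. `K_b = K_c = 0` gives
  p = 1. This assumes counts are exchangeable spectra; overdispersion makes
  it anticonservative per protein, which is why the null false-positive
  property below is checked on the *filtered* output (the FC > 2 gate and
  BH across proteins absorb the inflation).
* **permutation** — the empirical one-sided p of the observed FC among the
  FCs from **all** `C(n, n_bait)` distinct bait/control label
  reassignments (identity included, so p ≥ 1/#reassignments). Requires at
  least four samples; a warning is emitted below 100 reassignments (3v3
  gives 20, so the smallest achievable p is 0.05).

Internal backends are corrected across proteins by Benjamini–Hochberg
(statsmodels `fdr_bh`). The FDR of the external backend is whatever the
upstream scorer reported.

## Time-course classification

With enrichment measured at a short and a long labeling duration, each
protein enriched at **both** time points receives the FC-variation ratio

    R = FC_late / FC_early.

`R < 0.5` defines group 1, `R ≥ 0.5` group 2 (boundary inclusive on the
group-2 side). The direction is fixed as late/early so that "reduced
enrichment over time" reads `R < 1`: a stable interactor is labeled early
and saturates, so its enrichment *relative to the accumulating background*
falls; a continuously synthesized, labeled and imported substrate keeps or
increases its relative enrichment. Proteins enriched at a single time point
cannot receive a ratio; they are listed separately, never silently dropped
and never classified. Group shares of an annotation flag (e.g. Mitocarta
membership) are reported as raw counts plus percentages rounded to one
decimal, so either rounding convention of a published share can be checked
against the counts.

## Length-normalized abundance and proteome comparison

Per-protein abundance is `A = mean SpC / L` (spectral abundance factor),
with the mean over the declared replicate subset and `L` the protein length
in amino acids; no control subtraction enters the abundance (the control
enters via FC). z-scores use the sample (n−1) standard deviation over the
universe of all proteins detected in that sample — the universe is
configurable but defaults to all detected, and no log-transform is applied
before z-scoring. Two proteomes are compared on the z scale (Pearson +
Spearman over shared proteins, plus a |Δz| > 2 outlier count). A z-scale
comparison resolves a planted fold change only when that change exceeds the
z-equivalent of measurement noise on the most abundant proteins; the
package's power check therefore uses a narrow abundance spread (log-sd 0.1,
5% noise), and users should not expect 2-fold changes of minor proteins to
be visible in heavy-tailed whole-proteome profiles.

## Peptide coverage vs MTS

Peptide intervals (1-based, inclusive) are unioned per protein; overlapping
*and adjacent* (gap 0) intervals merge. "The MTS region is covered" is
operationalized as ≥ `min_overlap` amino acids (default 1 — the strictest
falsifiable reading) of intersection between merged coverage and the
annotated MTS interval. Peptides count once regardless of spectral count.
Proteins without an MTS annotation report "not applicable" rather than
false. For uniformly sampled length-ℓ peptides on an L-residue protein, a
peptide overlaps an N-terminal MTS `[1, m]` iff its start is ≤ m (the start
range is clipped at 1), so the per-protein detection probability with k
peptides is exactly `1 − (1 − m/(L−ℓ+1))^k`; the Monte-Carlo check uses
this clipped closed form.

## qPCR statistics

Replicates are always averaged on the CT scale first (geometric mean of
quantities), making every statistic invariant to a global CT shift:

* relative expression `2^−ΔΔCT` with ΔCT = CT_target − CT_reference per
  condition and ΔΔCT = ΔCT_test − ΔCT_calibrator;
* RIP / fraction recovery `% of input = 100 · f · 2^(CT_input − CT_IP)`
  where `f` is the input dilution (default 0.01 for a 1% input aliquot);
  the published protocols do not print this formula, so the standard
  adjusted-input convention is adopted and `f` is configurable; reference
  normalization is the ratio of two percent-input values, with the raw
  value always reported alongside;
* decay after transcription arrest: `remaining(t) = 2^−[ΔCT(t) − ΔCT(0)]`,
  anchored at 1 for t = 0; the half-life comes from a no-intercept least
  squares of ln(remaining) on t (the anchor forces the intercept), with a
  nonpositive rate flagged "no decay" (infinite half-life) rather than
  reported as a negative half-life.

Amplification-efficiency calibration and melt-curve QC are out of scope;
perfect doubling per cycle is assumed throughout.

## Synthetic data generator

The generator emulates the statistical structure of the experiments, not
their biochemistry. Study conditions (defaults of `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 500 | proteins per dataset |
| `class_fractions` | (0.8, 0.1, 0.1) | background / stable / flux split |
| `baseline_mean` | 10 | control-side NB mean (spectra/protein) |
| `nb_dispersion` | 10 | NB shape r; var = m + m²/r (≈2× Poisson at m=10); Poisson is the r → ∞ limit |
| `effect_fc_stable` | 8 | stable-interactor FC at the short labeling |
| `effect_fc_flux_early` / `_late` | 4 / 5 | flux-class FC anchors |
| `n_replicates` | 3 | bait and control replicates each |
| ratio draws | LogNormal(log 0.2, 0.2) / LogNormal(log 1.2, 0.2) | late/early ratio for stable vs flux |
| `mito_fraction_among_flux` | 0.9 | mitochondrial annotation rate in the flux class |
| `mito_fraction_among_stable` | 0.05 | occasional mitochondrial stable/background annotation |

Bait counts are NB(mean = baseline × true FC), control counts
NB(baseline); in the two-timepoint generator the late FC is the early FC
times a per-protein drawn ratio, so the drawn ratio — not the late anchor —
is the ground-truth group. The two ratio distributions sit on either side
of the 0.5 boundary with a gap that makes recovery targets meaningful but
not trivial. All draws flow through a single `numpy.random.Generator`
seeded from the config, so outputs are bit-identical per seed.

What the generator does **not** emulate: peptide detectability and
ionization efficiency, protein-length-dependent count rates, correlated
contaminant structure (CRAPome-style frequent flyers), biotinylation
kinetics, and inter-replicate batch effects. Passing recovery tests on this
generator therefore demonstrates the statistical machinery is correct under
the declared noise model, not that real interactomes will separate as
cleanly.

Peptide simulation: `mature_only` draws peptide starts uniformly downstream
of the MTS (the matured, import-cleaved pool — MTS coverage is impossible
by construction), `full_length` uniformly over the whole sequence. qPCR
simulation writes CT = baseline − log2(quantity) + N(0, sd), so zero-noise
plates round-trip every qPCR statistic exactly.

## Numerical choices and degenerate inputs

* Strict inequalities at every published threshold (FC > 2, FDR < 0.1,
  log2FC > 0, ratio < 0.5), with the ratio boundary itself falling in
  group 2.
* Filter output ordering: descending FC, ties broken by protein id
  (stable sort), so outputs are byte-reproducible.
* Missing count cells are rejected, never imputed as zero; absence and
  zero are different statements in spectral counting.
* Set overlap reports the smaller-set percentage **and** both one-sided
  percentages plus Jaccard, because published overlap figures do not always
  state their denominator.
* Zero-variance abundance vectors, empty record lists, missing t0 anchors,
  sub-4-sample permutation designs and invalid thresholds all raise typed
  errors rather than producing NaN.

## Problem sizes

The self-contained test and acceptance computations use 500-protein
datasets (200 for the null false-positive rate, 100 seeds for each recovery
rate), 1000 proteins for coverage Monte Carlo, and 1000 simulations for
qPCR noise coverage — sizes at which the binomial and Monte-Carlo standard
errors are far below the margins being asserted.

## Known limitations

* The internal binomial backend is a pragmatic count-split test, not a
  reimplementation of any published interaction scorer; reproducing a
  published selection requires the original export via `backend=external`.
* Percent rounding to one decimal can make group shares sum to 99.9 or
  100.1; raw counts are always emitted alongside.
* Cross-species or symbol/accession identifier reconciliation is the
  user's responsibility through an explicit synonym map.
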