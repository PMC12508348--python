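# Methods

## Signal model

A voxel's magnitude signal on a multi-b, multi-TE spin-echo acquisition is
modeled as a nonnegative mixture of mono-exponential decays over a
discretized diffusivity–relaxation plane:

    s(b, TE) = Σ_j Σ_k f(D_j, T2_k) · exp(−b·D_j·10⁻³) · exp(−TE/T2_k)

with D in µm²/ms, b in s/mm², T2 and TE in ms (the 10⁻³ makes b·D
dimensionless; it is applied only inside kernel construction).  The default
acquisition is the 35-frame protocol — b ∈ {0, 50, 100, 200, 400, 800,
1500} s/mm² crossed with TE ∈ {77, 90, 110, 130, 150} ms — stored TE-major
(five echo-time blocks, b fastest), matching five successive EPI scans
each sweeping the full b ladder.

The spectral plane is a 30 × 30 grid over D ∈ [0.01, 5] µm²/ms and
T2 ∈ [1, 150] ms.  Node placement is geometric (log-spaced) on both axes:
multi-exponential kernels discriminate decay rates on a ratio scale, so
log spacing spends resolution where the data carry information.  Linear
spacing is available via the `spacing` option.  Range endpoints are pinned
exactly to the configured limits.

## Spectrum inversion

Each voxel's spectrum solves

    min_{f ≥ 0}  ‖K·f − s‖² + λ‖f‖²

by nonnegative least squares on the λ-augmented system (√λ·I stacked under
K).  The penalty is zeroth-order (identity) Tikhonov; λ defaults to 0.01
and is exposed everywhere.  An L-curve selector (`select_lambda`) picks the
candidate closest to the utopia point of the log-residual vs log-norm
trade-off; it can select an endpoint, which matters for noiseless data
where the smallest λ is correct.  It is not on by default — a per-voxel
ladder multiplies cost by the ladder length and rarely moves ROI-level
fractions.

Magnitude noise is Rician; the fit is nevertheless least squares on
magnitudes, as is standard for this family of tools.  Voxels with
identically-zero or negative signals are flagged and excluded from ROI
averages rather than silently dropped.

### Resolution limits (what recovery tests show)

The inverse problem has 35 measurements and 900 unknowns: the
zero-residual set is a high-dimensional polytope and the λ → 0 NNLS
solution is a sparse vertex, not the generating spectrum.  Two practical
consequences, both quantified by the phantom analyses:

* **Short-T2 visibility.** With TE ≥ 77 ms, nodes below T2 ≈ 15 ms
  contribute < 0.3 % of their weight to the signal.  Under noise they act
  as high-gain sinks: NNLS parks large weights there to absorb small
  residuals, and normalization then counts that phantom mass fully.
* **Peak merging.** Two compartments sharing T2 and separated ≈ 3× in D
  (0.6 vs 2.0 µm²/ms) merge, at SNR ≈ 50, into one hump centered near
  their geometric mean (≈ 1.1 µm²/ms).  Because the tumor-cell/stroma
  boundary sits at D = 1, the merged mass lands preferentially on the
  stroma side: ROI-mean V_B is biased low by roughly 5–15 points and V_D
  high by a similar amount across the λ range, for Rician or Gaussian
  noise alike.  An oracle fit restricted to the five generating decay
  pairs recovers fractions to ≤ 3 points at the same SNR, so this is an
  estimator resolution limit, not an information void; sharper estimators
  (reweighted penalties, greedy pursuit) were evaluated and trade this
  bias for worse ones.

Tests therefore distinguish exact properties (single-peak localization,
solver equivalence with an independent bounded-variable QP reference,
conservation) from recovery properties, whose tolerances reflect the
measured resolution of the prescribed estimator.

## Compartment analysis

Normalized spectra are integrated over five rectangles of the plane:
A (T2 < 40 ms, D < 4), B (40 ≤ T2 ≤ 140, D < 1), C (T2 > 140, D < 4),
D (40 ≤ T2 ≤ 140, 1 ≤ D < 4), E (D ≥ 4, any T2) — interpreted as normal
tissue, tumor cells, necrosis, tumor-associated stroma, and capillary
perfusion respectively.  Boundaries are half-open and evaluated in a fixed
order (E first, then A, C, B, D) so every node belongs to exactly one
region and fractions conserve to 100 % by construction.  On the default
log grid only one T2 node exceeds 140 ms, so V_C is intrinsically
coarse — consistent with the sub-percent group means reported for it.
Patient-level fractions are unweighted means over all successfully fitted
voxels in the ROI, across slices.

## Conventional maps

ADC uses exactly the b = 0/800 s/mm² pair at TE = 77 ms:
ADC = ln(s₀/s₈₀₀)/0.8.  T2 comes from ordinary least squares of ln s on TE
at b = 0; nonpositive samples are dropped and non-decaying fits are
flagged invalid rather than raising.  Both are deliberately
single-exponential: on mixed voxels they land between the generating
component values, which is the voxel-averaging effect that motivates the
spectral decomposition.

## Synthetic data

**Phantoms.**  Each voxel draws compartment fractions from a Dirichlet
distribution whose mean is a tissue preset and whose common concentration
is least-squares matched to the preset's reported standard deviations
(exact per-compartment SDs are not representable by a single Dirichlet
concentration); a jitter-free mode uses the preset means directly.  The
presets are the three published group summaries — normal tongue
(75.6/1.4/0.1/2.6/20.4 % ± 8.0/1.4/0.2/3.5/7.5), node-negative tumor
(47.9/17.4/0.4/16.2/18.0 % ± 20.8/11.8/0.5/10.0/10.3) and node-positive
tumor (30.3/28.9/0.6/24.6/15.5 % ± 14.8/10.9/0.7/10.0/5.5).  Mass sits on
the grid node nearest each compartment's representative (D, T2):
A (0.8, 25), B (0.6, 80), C (1.5, 148), D (2.0, 80), E (4.5, 100),
approximately centered in their regions and configurable.  Noise is
Rician — two independent Gaussian channels of width σ = s(b=0, TE=77)/SNR
per voxel, magnitude taken.  Voxels are independent; real tumors have
spatial correlation, partial-volume geometry, and broad (non-delta)
spectral peaks, so passing phantom tests demonstrates algorithmic
correctness, not clinical accuracy.  The synthetic mixtures also do not
reproduce the published ADC/T2 group means (e.g. the normal-tissue ADC of
the five-delta mixture is ≈ 1.9 rather than 1.47 µm²/ms): the anchors were
chosen to center compartments, not to calibrate conventional maps.

**Cohorts.**  Covariates are drawn at the published frequencies and
moments of the 57-patient cohort (e.g. 70 % advanced cT, DOI 1.5 ± 0.9 cm);
compartment fractions come from the prevalence-weighted pooled tumor
preset; the binary outcome is Bernoulli with
logit = β₀ + ln(1.079)·V_B + ln(3.394)·DOI, the published independent
predictors.  β₀ defaults to the value that makes the risk at the covariate
means equal the study prevalence 34/57 — the one quantity the outcome
model needs that the study does not print.  V_B and DOI are drawn
independently (their reported correlation is 0.31); the collinearity
reproduction therefore uses the printed correlation directly rather than
the generator.

## Statistics

* Two-group comparisons gate on Shapiro–Wilk at α = 0.05 per group:
  both normal → Welch t; otherwise Mann–Whitney U (two-sided,
  tie-corrected).  Categorical tables use Pearson χ² without continuity
  correction — the choice that reproduces the published cT stage p = 0.015
  (Yates would not).  Constant samples are treated as non-normal.
* Interobserver agreement is ICC(2,1): two-way random effects, absolute
  agreement, single measurement — the standard form for two readers rating
  all subjects — banded poor < 0.4 ≤ fair < 0.6 ≤ good ≤ 0.75 < excellent.
* Associations: Pearson for continuous pairs, point-biserial (Pearson on
  {0,1} coding) for mixed pairs, φ from the 2×2 table for binary pairs.
* Logistic regression is maximum likelihood with Wald 95 % intervals
  (z = 1.959964).  For a single binary predictor the fitted OR equals the
  2×2 cross-product ratio exactly, which is how the seven published
  univariate odds ratios are reproduced from the printed contingency
  tables.  Multivariate entry requires univariate p < 0.05; backward
  elimination removes terms at p ≥ 0.05 (the study does not state its
  selection path; this is the conventional default).  Separation falls
  back to a flagged gradient fit so downstream scores stay finite.
  VIF is 1/(1−R²) from regressing each predictor on the others.
* ROC: trapezoidal AUC over all observed thresholds (equal to the
  normalized Mann–Whitney U, asserted as an identity), DeLong variance for
  the CI, cutoff by Youden's J with ties broken toward higher specificity.
  The study prints cutoffs without naming a criterion; Youden is assumed.
* The nomogram scales each variable's axis by |coef|·range-width, with the
  widest axis spanning 100 points and negative coefficients counted from
  the range maximum so points are always risk-increasing; the total maps
  affinely back to the linear predictor, making the round-trip exact to
  machine precision.  Calibration uses decile bins of predicted risk with
  bootstrap refits for optimism correction; empty bins merge with their
  neighbor.

## Problem sizes and defaults

Phantom analyses use 5×5×2 blocks (50 voxels) per preset and a 10×10×2
block (200 voxels) for the noisy-recovery check; cohort analyses use
n = 57 (study-sized) and n = 1000 (parameter recovery, replicated for
bias estimation).  Default λ = 0.01; SNR 50 for noisy phantoms; all
generators take explicit seeds and are bit-reproducible.

## Known limitations

* Per-voxel fraction maps inherit the V_B/V_D merging bias described
  above; group *differences* remain monotone in the generating truth, but
  absolute fractions at realistic SNR should be read with ±10-point
  caution for the low-D tumor compartment.
* No spatial regularization, Rician-likelihood fitting, or data-driven
  compartment discovery; boundaries are fixed inputs.
* The cohort generator models covariates independently except through the
  outcome; correlation structure among predictors is not emulated.
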