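# drcsi

Diffusion-relaxation correlation spectroscopic imaging (DR-CSI) analysis
for tumor characterization and lymph-node-metastasis risk modelling.

Conventional diffusion MRI summarizes each voxel with a single apparent
diffusion coefficient (ADC), and multi-echo imaging with a single T2 —
both blur over the sub-voxel mixture of tissue components that actually
determines tumor behavior.  DR-CSI instead acquires signals over a grid of
diffusion weightings and echo times (here 7 b-values × 5 echo times = 35
frames) and inverts each voxel into a two-dimensional spectrum
f(D, T2) over diffusivity and transverse relaxation:

    s(b, TE) = Σ_j Σ_k f(D_j, T2_k) · e^(−b·D_j) · e^(−TE/T2_k),  f ≥ 0

solved by Tikhonov-regularized nonnegative least squares on a 30×30
log-spaced (D, T2) grid.  Normalized spectra are integrated over five
rectangular compartments — A (normal tissue), B (tumor cells),
C (necrosis), D (tumor-associated stroma), E (capillary perfusion) —
giving volume fractions V_A…V_E per voxel and per ROI.  A cohort-level
layer implements the statistics such a study reports: normality-gated
group tests, ICC agreement, correlation coefficients, univariate and
multivariate logistic regression with odds ratios and Wald intervals,
VIF, ROC with Youden cutoffs and DeLong intervals, a combined V_B + DOI
(depth-of-invasion) model, a points-based nomogram, and bootstrap
calibration.  Because patient-level data for this kind of study are
withheld, a synthetic-data module generates phantoms and cohorts with the
published group structure so every stage is testable end to end.

Audience: imaging scientists prototyping diffusion-relaxation analyses,
and methodologists reproducing the statistical pipeline of
imaging-biomarker studies.

## Worked example

```python
import numpy as np
from drcsi import (build_kernel, build_spectral_grid, default_acquisition,
                   fit_volume, roi_fractions, PRESETS, PhantomSpec, make_phantom)

kernel = build_kernel(default_acquisition(), build_spectral_grid())
spec = PhantomSpec(shape=(5, 5, 2), preset=PRESETS["CLNM_pos"], snr=50.0, seed=7)
volume, mask, truth = make_phantom(spec, kernel)          # 50 voxels, 35 frames
smap = fit_volume(volume, mask, kernel, lam=0.01)         # per-voxel spectra
roi = roi_fractions(smap, kernel.spectral)
print({k: round(v, 1) for k, v in roi.as_dict().items()})
```

prints

```
{'A': 19.3, 'B': 26.1, 'C': 2.2, 'D': 39.1, 'E': 13.2}
```

— the recovered ROI-mean volume fractions (percent, summing to 100) for a
simulated node-positive tumor whose generating voxel-mean fractions were
A 30.2 / B 29.1 / C 0.7 / D 27.2 / E 12.9.  The deviation on A, B and D
is the documented resolution limit of the per-voxel inversion at this
noise level (see `docs/methods.md`); C and E recover within a couple of
points, and noiseless single-component voxels recover exactly.

The same pipeline is scriptable from the shell:

```
drcsi simulate-phantom --preset CLNM_pos --seed 7 --out-dir phantom
drcsi fit --signal phantom/signal.nii.gz --mask phantom/mask.nii.gz --out-dir spectra
drcsi segment --spectra-dir spectra --out fractions.csv
drcsi simulate-cohort --n 57 --seed 1 --out cohort.csv
drcsi stats --cohort cohort.csv --out-dir stats
drcsi predict --cohort cohort.csv --out-dir predict
```

The numbered drivers under `analysis/` run the full study-shaped analysis
(phantom simulation → spectral fitting → compartment recovery →
conventional maps → cohort simulation → statistics → prediction model)
and write their tables under `results/`.

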