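#!/usr/bin/env python
"""Fit D–T2 spectra on the simulated phantoms and compare recovered
compartment fractions with the generator's ground truth.

Writes results/phantom_recovery.csv: per phantom, the true and recovered
ROI-mean V_A…V_E (percent) and their differences.  The recovery error is
the empirical resolution limit of the regularized per-voxel inversion:
noiseless errors reflect the non-uniqueness of the 35-measurement inverse
problem, noisy errors add the B/D peak-merging bias discussed in the
methods note.
"""

from pathlib import Path

import pandas as pd

from drcsi.compartments import COMPARTMENTS, roi_fractions
from drcsi.grids import build_kernel, build_spectral_grid, default_acquisition
from drcsi.inversion import fit_volume
from drcsi.io import read_mask, read_signal_volume

ROOT = Path(__file__).resolve().parents[1] / "results"
LAMBDA = 0.01


def main() -> None:
    acq = default_acquisition()
    grid = build_spectral_grid()
    kernel = build_kernel(acq, grid)
    rows = []
    for phantom_dir in sorted((ROOT / "phantoms").iterdir()):
        volume = read_signal_volume(phantom_dir / "signal.nii.gz", acq)
        mask = read_mask(phantom_dir / "mask.nii.gz")
        truth = pd.read_csv(phantom_dir / "truth.csv")
        smap = fit_volume(volume, mask, kernel, LAMBDA)
        roi = roi_fractions(smap, grid).as_dict()
        row = {"phantom": phantom_dir.name, "n_voxels": smap.n_fitted}
        for comp in COMPARTMENTS:
            true = truth[f"V_{comp}"].mean()
            row[f"true_V_{comp}"] = round(true, 2)
            row[f"recovered_V_{comp}"] = round(roi[comp], 2)
            row[f"error_V_{comp}"] = round(roi[comp] - true, 2)
        rows.append(row)
        worst = max(abs(row[f"error_V_{c}"]) for c in COMPARTMENTS)
        print(f"{phantom_dir.name:22s} max |error| = {worst:5.2f} points")
    out = ROOT / "phantom_recovery.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"-> {out}")


if __name__ == "__main__":
    main()
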