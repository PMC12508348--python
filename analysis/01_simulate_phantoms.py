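#!/usr/bin/env python
"""Simulate multi-(b, TE) phantoms for the three tissue groups.

One 5×5×2 block per preset (normal tongue, node-negative tumor,
node-positive tumor), noiseless and at SNR 50, written as NIfTI with
ground-truth fraction tables under results/phantoms/.
"""

from pathlib import Path

import numpy as np

from drcsi.grids import build_kernel, build_spectral_grid, default_acquisition
from drcsi.io import PipelineConfig, write_manifest, write_mask, write_signal_volume
from drcsi.synthetic import PRESETS, PhantomSpec, make_phantom

OUT = Path(__file__).resolve().parents[1] / "results" / "phantoms"
SEED = 7
SHAPE = (5, 5, 2)


def main() -> None:
    kernel = build_kernel(default_acquisition(), build_spectral_grid())
    for preset in PRESETS:
        for label, snr in [("noiseless", np.inf), ("snr50", 50.0)]:
            spec = PhantomSpec(SHAPE, PRESETS[preset], snr=snr, seed=SEED)
            volume, mask, truth = make_phantom(spec, kernel)
            out = OUT / f"{preset}_{label}"
            out.mkdir(parents=True, exist_ok=True)
            write_signal_volume(out / "signal.nii.gz", volume, kernel.acquisition)
            write_mask(out / "mask.nii.gz", mask)
            truth.to_csv(out / "truth.csv", index=False)
            write_manifest(
                out / "manifest.json",
                "simulate-phantom",
                PipelineConfig(seed=SEED, snr=snr if np.isfinite(snr) else float("inf")),
                {"preset": preset, "shape": list(SHAPE)},
            )
            print(f"{preset:9s} {label:9s}: {volume.shape} -> {out}")


if __name__ == "__main__":
    main()
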