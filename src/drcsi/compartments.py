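"""Partition of the D–T2 plane into compartments A–E and volume fractions.

The normalized spectrum is integrated over five rectangular regions of
the (D, T2) plane, each associated with a tissue component:

* A — short T2 (< 40 ms), low-to-medium diffusivity: normal tissue
* B — intermediate T2 (40–140 ms), low diffusivity (< 1 µm²/ms): tumor cells
* C — long T2 (> 140 ms), low-to-intermediate diffusivity: necrosis
* D — intermediate T2, intermediate diffusivity (1–4 µm²/ms): tumor stroma
* E — high diffusivity (≥ 4 µm²/ms), any T2: capillary perfusion

Boundaries are half-open so the partition is exhaustive and exclusive:
E takes precedence at D = 4; T2 = 40 and T2 = 140 belong to the
intermediate band.  Fractions are percentages summing to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inversion import SpectrumMap, VoxelSpectrum
from .grids import SpectralGrid

__all__ = [
    "CompartmentBounds",
    "CompartmentFractions",
    "COMPARTMENTS",
    "label_nodes",
    "segment_spectrum",
    "roi_fractions",
]

COMPARTMENTS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class CompartmentBounds:
    """Boundary lines of the five-region partition (ms and µm²/ms)."""

    t2_short_max: float = 40.0
    t2_long_min: float = 140.0
    d_low_max: float = 1.0
    d_high_min: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.t2_short_max < self.t2_long_min):
            raise ValueError("need 0 < t2_short_max < t2_long_min")
        if not (0 < self.d_low_max < self.d_high_min):
            raise ValueError("need 0 < d_low_max < d_high_min")


@dataclass(frozen=True)
class CompartmentFractions:
    """Volume fractions V_A…V_E in percent; conserved to 100."""

    V_A: float
    V_B: float
    V_C: float
    V_D: float
    V_E: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < -1e-9) or np.any(vals > 100 + 1e-9):
            raise ValueError("fractions must lie in [0, 100]")
        if abs(vals.sum() - 100.0) > 1e-6:
            raise ValueError(f"fractions must sum to 100, got {vals.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.V_A, self.V_B, self.V_C, self.V_D, self.V_E])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(COMPARTMENTS, self.as_array().tolist()))


def label_nodes(grid: SpectralGrid, bounds: CompartmentBounds | None = None) -> np.ndarray:
    """Compartment index (0..4 for A..E) of every (D, T2) node, shape (n_D, n_T2).

    Decision order per node: E if D ≥ d_high_min; else A if T2 < t2_short_max;
    else C if T2 > t2_long_min; else B if D < d_low_max; else D.
    """
    bounds = bounds or CompartmentBounds()
    d = np.asarray(grid.d_nodes)[:, None]
    t2 = np.asarray(grid.t2_nodes)[None, :]
    labels = np.full(grid.shape, 3, dtype=int)  # default: compartment D
    labels[np.broadcast_to(t2 > bounds.t2_long_min, grid.shape)] = 2
    labels[np.broadcast_to(t2 < bounds.t2_short_max, grid.shape)] = 0
    inter = (t2 >= bounds.t2_short_max) & (t2 <= bounds.t2_long_min)
    b_region = np.broadcast_to(inter, grid.shape) & np.broadcast_to(
        d < bounds.d_low_max, grid.shape
    )
    labels[b_region] = 1
    labels[np.broadcast_to(d >= bounds.d_high_min, grid.shape)] = 4
    return labels


def segment_spectrum(
    spec: VoxelSpectrum, grid: SpectralGrid, bounds: CompartmentBounds | None = None
) -> CompartmentFractions:
    """Integrate a normalized spectrum over the five regions, in percent."""
    if not spec.normalized:
        raise ValueError("segment_spectrum requires a normalized spectrum")
    if spec.grid_shape != grid.shape:
        raise ValueError("spectrum grid shape does not match the spectral grid")
    labels = label_nodes(grid, bounds)
    plane = spec.as_plane()
    sums = np.array([plane[labels == i].sum() for i in range(5)])
    sums = 100.0 * sums
    # pin the float sum to exactly 100 by adjusting the largest entry
    sums[np.argmax(sums)] += 100.0 - sums.sum()
    return CompartmentFractions(*sums.tolist())


def roi_fractions(
    spectrum_map: SpectrumMap,
    grid: SpectralGrid,
    bounds: CompartmentBounds | None = None,
) -> CompartmentFractions:
    """Patient-level fractions: unweighted mean over successfully fitted voxels."""
    if spectrum_map.n_fitted == 0:
        raise ValueError("no successfully fitted voxels in ROI")
    per_voxel = np.array(
        [
            segment_spectrum(spec, grid, bounds).as_array()
            for spec in spectrum_map.spectra.values()
        ]
    )
    mean = per_voxel.mean(axis=0)
    mean[np.argmax(mean)] += 100.0 - mean.sum()
    return CompartmentFractions(*mean.tolist())
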