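"""Conventional ADC and T2 maps from the same multi-(b, TE) acquisition.

ADC comes from the two-point log ratio at b = 0 and 800 s/mm² at the
shortest echo time; T2 from an ordinary least-squares line through
ln(signal) vs TE at b = 0.  Both are the single-exponential summaries the
spectral analysis is compared against, and both inherit its voxel-averaging
blind spot by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import AcquisitionGrid

__all__ = ["ScalarMap", "compute_adc", "compute_t2", "adc_map", "t2_map"]

ADC_B_PAIR = (0.0, 800.0)  # s/mm²


@dataclass
class ScalarMap:
    """3-D parameter map with a validity mask; units: µm²/ms (ADC) or ms (T2)."""

    values: np.ndarray
    valid: np.ndarray
    units: str

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask must share a shape")


def compute_adc(s0: float, s800: float, b_high: float = ADC_B_PAIR[1]) -> float:
    """Two-point ADC in µm²/ms: ln(s0/s_b) / (b · 10⁻³).

    Returns NaN (invalid) for nonpositive intensities or non-decaying pairs.
    """
    if s0 <= 0 or s800 <= 0 or s800 >= s0:
        return float("nan")
    return float(np.log(s0 / s800) / (b_high * 1e-3))


def compute_t2(signals: np.ndarray, echo_times: np.ndarray) -> float:
    """T2 in ms from the OLS slope of ln(signal) on TE; NaN when undefined.

    Nonpositive samples are dropped; at least two positive samples and a
    strictly negative slope are required.
    """
    s = np.asarray(signals, dtype=float).ravel()
    te = np.asarray(echo_times, dtype=float).ravel()
    if s.size != te.size:
        raise ValueError("signals and echo_times must have equal length")
    keep = s > 0
    if keep.sum() < 2:
        return float("nan")
    slope = np.polyfit(te[keep], np.log(s[keep]), 1)[0]
    if not np.isfinite(slope) or slope >= 0:
        return float("nan")
    return float(-1.0 / slope)


def _frame_index(acq: AcquisitionGrid, b: float, te: float) -> int:
    return acq.pairs().index((b, te))


def adc_map(volume: np.ndarray, mask: np.ndarray, acq: AcquisitionGrid) -> ScalarMap:
    """Voxel-wise two-point ADC at the shortest TE; invalid voxels masked out."""
    te0 = acq.echo_times[0]
    i0 = _frame_index(acq, ADC_B_PAIR[0], te0)
    i800 = _frame_index(acq, ADC_B_PAIR[1], te0)
    values = np.full(mask.shape, np.nan)
    for x, y, z in np.argwhere(mask):
        values[x, y, z] = compute_adc(volume[x, y, z, i0], volume[x, y, z, i800])
    return ScalarMap(values=values, valid=np.isfinite(values), units="um^2/ms")


def t2_map(volume: np.ndarray, mask: np.ndarray, acq: AcquisitionGrid) -> ScalarMap:
    """Voxel-wise mono-exponential T2 from the b = 0 frame at every TE."""
    idx = [_frame_index(acq, 0.0, te) for te in acq.echo_times]
    te = np.asarray(acq.echo_times)
    values = np.full(mask.shape, np.nan)
    for x, y, z in np.argwhere(mask):
        values[x, y, z] = compute_t2(volume[x, y, z, idx], te)
    return ScalarMap(values=values, valid=np.isfinite(values), units="ms")
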