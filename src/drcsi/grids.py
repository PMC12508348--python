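"""Acquisition and spectral grids, and the forward (dictionary) kernel.

The measurement space is the Cartesian product of diffusion weightings
(b-values, s/mm²) and echo times (TE, ms); the default protocol acquires
7 b-values at each of 5 echo times, 35 frames total, ordered TE-major
(5 successive scans, each sweeping the full b-ladder at one TE).

The spectral domain is a discretized (D, T2) plane.  Units are fixed
package-wide: D in µm²/ms, b in s/mm², T2 and TE in ms.  The product
b·D then carries a factor 10⁻³ to become dimensionless; that conversion
lives only inside kernel construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionGrid",
    "SpectralGrid",
    "Kernel",
    "default_acquisition",
    "build_spectral_grid",
    "build_kernel",
    "cached_kernel",
]

#: (s/mm²)·(µm²/ms) → dimensionless exponent
B_D_UNIT = 1e-3

DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1500.0)
DEFAULT_ECHO_TIMES = (77.0, 90.0, 110.0, 130.0, 150.0)
DEFAULT_D_RANGE = (0.01, 5.0)
DEFAULT_T2_RANGE = (1.0, 150.0)
DEFAULT_N_NODES = 30


def _strictly_increasing(x: np.ndarray) -> bool:
    return bool(np.all(np.diff(x) > 0))


@dataclass(frozen=True)
class AcquisitionGrid:
    """Ordered b-value and echo-time lists defining the measurement space."""

    b_values: tuple[float, ...]
    echo_times: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        te = np.asarray(self.echo_times, dtype=float)
        if b.size == 0 or te.size == 0:
            raise ValueError("b_values and echo_times must be non-empty")
        if not _strictly_increasing(b) and b.size > 1:
            raise ValueError("b_values must be strictly increasing")
        if b[0] < 0:
            raise ValueError("b_values must start at >= 0")
        if (te.size > 1 and not _strictly_increasing(te)) or np.any(te <= 0):
            raise ValueError("echo_times must be strictly increasing and > 0")

    @property
    def n_measurements(self) -> int:
        return len(self.b_values) * len(self.echo_times)

    def pairs(self) -> list[tuple[float, float]]:
        """(b, TE) per frame, TE-major: 1 block per echo time, b fastest."""
        return [(b, te) for te in self.echo_times for b in self.b_values]

    def to_dict(self) -> dict:
        return {"b_values": list(self.b_values), "echo_times": list(self.echo_times)}

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGrid":
        return cls(tuple(d["b_values"]), tuple(d["echo_times"]))


@dataclass(frozen=True)
class SpectralGrid:
    """Discretized (D, T2) plane; node lists are strictly increasing."""

    d_nodes: tuple[float, ...]
    t2_nodes: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, nodes in (("d_nodes", self.d_nodes), ("t2_nodes", self.t2_nodes)):
            arr = np.asarray(nodes, dtype=float)
            if arr.size < 2:
                raise ValueError(f"{name} needs at least 2 nodes")
            if np.any(arr <= 0) or not _strictly_increasing(arr):
                raise ValueError(f"{name} must be positive and strictly increasing")

    @property
    def n_nodes(self) -> int:
        return len(self.d_nodes) * len(self.t2_nodes)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.d_nodes), len(self.t2_nodes))

    def node_pairs(self) -> list[tuple[float, float]]:
        """(D, T2) per kernel column, D-major (T2 fastest)."""
        return [(d, t2) for d in self.d_nodes for t2 in self.t2_nodes]

    def nearest_node(self, d: float, t2: float) -> tuple[int, int]:
        i = int(np.argmin(np.abs(np.asarray(self.d_nodes) - d)))
        j = int(np.argmin(np.abs(np.asarray(self.t2_nodes) - t2)))
        return i, j

    def to_dict(self) -> dict:
        return {"d_nodes": list(self.d_nodes), "t2_nodes": list(self.t2_nodes)}

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralGrid":
        return cls(tuple(d["d_nodes"]), tuple(d["t2_nodes"]))


@dataclass(frozen=True)
class Kernel:
    """Forward matrix mapping spectra (columns) to measured signals (rows).

    matrix[row, col] = exp(-b·D·10⁻³) · exp(-TE/T2) for the row's (b, TE)
    pair (TE-major order) and the column's (D, T2) node (D-major order).
    """

    matrix: np.ndarray = field(repr=False)
    acquisition: AcquisitionGrid
    spectral: SpectralGrid

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (self.acquisition.n_measurements, self.spectral.n_nodes):
            raise ValueError("kernel shape inconsistent with grids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def forward(self, weights: np.ndarray) -> np.ndarray:
        """Synthesize the signal s = K·f for spectrum weights f."""
        return self.matrix @ np.asarray(weights, dtype=float).ravel()


def default_acquisition() -> AcquisitionGrid:
    """The 35-frame protocol: 7 b-values crossed with 5 echo times."""
    return AcquisitionGrid(DEFAULT_B_VALUES, DEFAULT_ECHO_TIMES)


def build_spectral_grid(
    n_d: int = DEFAULT_N_NODES,
    n_t2: int = DEFAULT_N_NODES,
    d_range: tuple[float, float] = DEFAULT_D_RANGE,
    t2_range: tuple[float, float] = DEFAULT_T2_RANGE,
    spacing: str = "log",
) -> SpectralGrid:
    """Place spectral nodes on the (D, T2) plane with exact range endpoints.

    Logarithmic spacing is the default: multi-exponential decays resolve
    components on a ratio scale, so geometric node placement spends
    resolution where the kernel actually distinguishes decay rates.
    """
    if n_d < 2 or n_t2 < 2:
        raise ValueError("need at least 2 nodes per axis")
    for lo, hi in (d_range, t2_range):
        if not (hi > lo > 0 if spacing == "log" else hi > lo):
            raise ValueError(f"invalid range ({lo}, {hi}) for spacing={spacing!r}")
    if spacing == "log":
        d_nodes = np.geomspace(d_range[0], d_range[1], n_d)
        t2_nodes = np.geomspace(t2_range[0], t2_range[1], n_t2)
    elif spacing == "linear":
        d_nodes = np.linspace(d_range[0], d_range[1], n_d)
        t2_nodes = np.linspace(t2_range[0], t2_range[1], n_t2)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    # endpoints must equal the configured limits exactly
    d_nodes[0], d_nodes[-1] = d_range
    t2_nodes[0], t2_nodes[-1] = t2_range
    return SpectralGrid(tuple(d_nodes), tuple(t2_nodes))


def build_kernel(acq: AcquisitionGrid, grid: SpectralGrid) -> Kernel:
    """Evaluate the double-exponential dictionary on the two grids."""
    b = np.array([p[0] for p in acq.pairs()])[:, None]
    te = np.array([p[1] for p in acq.pairs()])[:, None]
    d = np.array([p[0] for p in grid.node_pairs()])[None, :]
    t2 = np.array([p[1] for p in grid.node_pairs()])[None, :]
    matrix = np.exp(-b * d * B_D_UNIT) * np.exp(-te / t2)
    return Kernel(matrix=matrix, acquisition=acq, spectral=grid)


def _grid_hash(acq: AcquisitionGrid, grid: SpectralGrid) -> str:
    payload = json.dumps([acq.to_dict(), grid.to_dict()], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cached_kernel(acq: AcquisitionGrid, grid: SpectralGrid, cache_dir: str | Path) -> Kernel:
    """Build the kernel, memoizing the matrix to an .npy file keyed by grid hash."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"kernel_{_grid_hash(acq, grid)}.npy"
    if path.exists():
        matrix = np.load(path)
        return Kernel(matrix=matrix, acquisition=acq, spectral=grid)
    kernel = build_kernel(acq, grid)
    np.save(path, kernel.matrix)
    return kernel
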