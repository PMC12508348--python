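"""NIfTI / CSV / JSON I/O, pipeline configuration, and run manifests.

Conventions (enforced here, assumed everywhere else):

* signal volumes are NIfTI-1, (X, Y, Z, M) with M = n_b × n_TE frames in
  TE-major order (one block per echo time, b-value fastest); a JSON
  sidecar records the grids and frame ordering;
* masks are uint8 {0, 1} NIfTI-1 volumes on the same voxel grid;
* tabular data are UTF-8 comma-separated with a mandatory header;
* every pipeline artifact gets a manifest (inputs, config hash, seed,
  package version) so it can be regenerated from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .compartments import CompartmentBounds
from .grids import AcquisitionGrid, SpectralGrid, build_spectral_grid, default_acquisition
from .inversion import DEFAULT_LAMBDA

__all__ = [
    "PipelineConfig",
    "FrameLayoutError",
    "read_signal_volume",
    "write_signal_volume",
    "read_mask",
    "write_mask",
    "write_scalar_map",
    "write_manifest",
]


class FrameLayoutError(ValueError):
    """4-D input does not match the expected (b, TE) frame layout."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated bundle of every knob the pipeline stages read."""

    acquisition: AcquisitionGrid = field(default_factory=default_acquisition)
    spectral: SpectralGrid = field(default_factory=build_spectral_grid)
    regularization: float = DEFAULT_LAMBDA
    bounds: CompartmentBounds = field(default_factory=CompartmentBounds)
    snr: float = float("inf")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regularization < 0:
            raise ValueError("regularization must be nonnegative")
        if not self.snr > 0:
            raise ValueError("snr must be positive")

    def to_dict(self) -> dict:
        return {
            "acquisition": self.acquisition.to_dict(),
            "spectral": self.spectral.to_dict(),
            "regularization": self.regularization,
            "bounds": asdict(self.bounds),
            "snr": self.snr if np.isfinite(self.snr) else "inf",
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            acquisition=AcquisitionGrid.from_dict(d["acquisition"]),
            spectral=SpectralGrid.from_dict(d["spectral"]),
            regularization=float(d["regularization"]),
            bounds=CompartmentBounds(**d["bounds"]),
            snr=float("inf") if d["snr"] == "inf" else float(d["snr"]),
            seed=int(d["seed"]),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_signal_volume(
    path: str | Path, volume: np.ndarray, acq: AcquisitionGrid, affine=None
) -> None:
    """Write a 4-D signal volume with its frame-ordering sidecar."""
    path = Path(path)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), path)
    sidecar = {
        "frame_order": "te_major",
        "acquisition": acq.to_dict(),
        "frames": [{"b": b, "te": te} for b, te in acq.pairs()],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def read_signal_volume(path: str | Path, acq: AcquisitionGrid) -> np.ndarray:
    """Load a 4-D signal volume, checking (and if needed restoring) frame order.

    The frame count must equal the acquisition's measurement count.  If a
    JSON sidecar is present its per-frame (b, TE) list is compared against
    the expected TE-major layout and frames are permuted into it.
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    expected = acq.n_measurements
    if data.ndim != 4 or data.shape[-1] != expected:
        got = data.shape[-1] if data.ndim == 4 else None
        raise FrameLayoutError(
            f"expected a 4-D volume with {expected} frames "
            f"(TE-major: {len(acq.echo_times)} echo-time blocks × "
            f"{len(acq.b_values)} b-values), got shape {data.shape} ({got} frames)"
        )
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frames = [(f["b"], f["te"]) for f in meta.get("frames", [])]
        expected_pairs = acq.pairs()
        if frames and frames != expected_pairs:
            try:
                perm = [frames.index(p) for p in expected_pairs]
            except ValueError as exc:
                raise FrameLayoutError(
                    f"sidecar frames do not cover the expected (b, TE) pairs: {exc}"
                ) from exc
            data = data[..., perm]
    return data


def write_mask(path: str | Path, mask: np.ndarray, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    data = np.asarray(nib.load(Path(path)).dataobj)
    return (data > 0).astype(np.uint8)


def write_scalar_map(path: str | Path, values: np.ndarray, units: str, affine=None) -> None:
    """3-D parameter map; units recorded in the NIfTI descrip field."""
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    img.header["descrip"] = f"units={units}".encode()
    nib.save(img, Path(path))


def write_manifest(path: str | Path, stage: str, config: PipelineConfig, inputs: dict) -> dict:
    """Record what produced an artifact: stage, inputs, config hash, seed."""
    from . import __version__

    manifest = {
        "stage": stage,
        "inputs": inputs,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
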