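"""File formats: 32-bit float multi-page TIFF for volumes and projection
stacks, JSON for geometry, parameters and experiment configuration.

A projection stack on disk is a pair of files: ``<stem>.tiff`` with one
page per projection angle, and a ``<stem>.json`` geometry sidecar with the
keys ``source_to_center_mm``, ``center_to_detector_mm``,
``detector_pixel_size_mm``, ``n_voxels``, ``voxel_size_mm``,
``angles_rad``.  Volumes are stored one z-slice per page.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .geometry import ConeBeamGeometry, ProjectionStack, VoxelVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_projection_stack",
    "read_projection_stack",
    "ExperimentConfig",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(path: str | Path, vol: VoxelVolume) -> None:
    tifffile.imwrite(Path(path), vol.values.astype(np.float32))


def read_volume(path: str | Path, voxel_size: float = 1.0) -> VoxelVolume:
    arr = tifffile.imread(Path(path))
    if not np.issubdtype(arr.dtype, np.floating):
        raise TypeError(f"{path}: expected float pixels, found {arr.dtype}")
    return VoxelVolume(np.asarray(arr, dtype=np.float64), voxel_size)


def write_projection_stack(path: str | Path, proj: ProjectionStack) -> None:
    """Write the stack as float32 TIFF plus its geometry sidecar."""
    path = Path(path)
    tifffile.imwrite(path, proj.values.astype(np.float32))
    proj.geometry.to_json(_sidecar(path))


def read_projection_stack(path: str | Path) -> tuple[ProjectionStack, ConeBeamGeometry]:
    """Load a projection stack and validate it against its sidecar."""
    path = Path(path)
    side = _sidecar(path)
    if not path.exists():
        raise FileNotFoundError(f"projection stack not found: {path}")
    if not side.exists():
        raise FileNotFoundError(
            f"missing geometry sidecar: expected {side} next to {path.name}"
        )
    geom = ConeBeamGeometry.from_json(side)
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.floating):
        raise TypeError(f"{path}: expected float pixels, found {arr.dtype}")
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.shape[0] != geom.n_angles:
        raise ValueError(
            f"{path}: {arr.shape[0]} pages but sidecar lists "
            f"{geom.n_angles} angles"
        )
    return ProjectionStack(arr, geom), geom


@dataclass
class ExperimentConfig:
    """Resolved settings of one simulate/train/reconstruct run.

    Written next to every run's outputs so experiments are reproducible
    from the directory alone.
    """

    n_voxels: int = 64
    n_angles: int = 32
    cone_angle_deg: float = 10.0
    phantom_family: str = "fourshape"
    phantom_seed: int = 0
    noise_i0: float | None = 256.0
    noise_seed: int = 0
    n_hidden: int = 4
    n_train: int = 1_000_000
    n_val: int = 1_000_000
    lma_lambda0: float = 1e-2
    lma_max_epochs: int = 500
    lma_patience: int = 100
    lma_damping: str = "identity"
    metrics: tuple = ("tse", "ssim")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["metrics"] = list(self.metrics)
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        d = json.loads(Path(path).read_text())
        d["metrics"] = tuple(d.get("metrics", ("tse", "ssim")))
        return cls(**d)
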