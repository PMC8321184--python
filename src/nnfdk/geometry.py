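"""Circular cone-beam scan geometry and the basic array containers.

The scanning setup is the classic circular cone-beam trajectory: a point
source and a flat panel detector rotate (equivalently, the object rotates)
about a fixed vertical axis.  The reconstruction volume is an ``N**3`` cube
of attenuation values, the detector an ``N x N`` pixel grid, and ``Na``
projections are taken at increasing rotation angles, so the data vector has
``Na * N * N`` entries.

Conventions
-----------
* World coordinates are in millimetres, centred on the rotation axis; the
  rotation axis is ``z``; sample points sit at cell centres.
* At angle ``beta`` the source is at ``D_so * (cos b, sin b, 0)`` and the
  detector centre at ``-D_od * (cos b, sin b, 0)``.  Detector columns run
  along the transaxial direction ``u = (-sin b, cos b, 0)``, rows along the
  axial direction ``v = (0, 0, 1)``; ``u = v = 0`` at the detector centre.
* Attenuation values are stored in 1/cm; geometric lengths in mm.  The
  forward projector converts path lengths to cm so that line integrals are
  the dimensionless ``-ln(I/I0)`` of Beer-Lambert.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConeBeamGeometry",
    "VoxelVolume",
    "ProjectionStack",
    "default_geometry",
]

#: mm -> cm, applied wherever a geometric length multiplies an attenuation.
MM_TO_CM = 0.1


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Description of one circular cone-beam scan.

    Parameters
    ----------
    source_to_center:
        Distance from the X-ray source to the rotation axis (mm), > 0.
    center_to_detector:
        Distance from the rotation axis to the detector plane (mm), >= 0.
    n_voxels:
        Side length ``N`` of the ``N**3`` reconstruction volume; the
        detector is ``N x N`` pixels.
    voxel_size:
        Isotropic voxel pitch (mm).
    detector_pixel_size:
        Isotropic detector pixel pitch (mm).
    angles:
        Rotation angles in radians, strictly increasing within ``[0, 2*pi)``.
    """

    source_to_center: float
    center_to_detector: float
    n_voxels: int
    voxel_size: float
    detector_pixel_size: float
    angles: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "angles", np.ascontiguousarray(self.angles, dtype=np.float64)
        )
        if self.source_to_center <= 0:
            raise ValueError("source_to_center must be > 0")
        if self.center_to_detector < 0:
            raise ValueError("center_to_detector must be >= 0")
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if self.voxel_size <= 0 or self.detector_pixel_size <= 0:
            raise ValueError("voxel and detector pixel sizes must be > 0")
        a = self.angles
        if a.ndim != 1 or a.size == 0:
            raise ValueError("angles must be a non-empty 1-D sequence")
        if np.any(a < 0) or np.any(a >= 2 * np.pi):
            raise ValueError("angles must lie in [0, 2*pi)")
        if a.size > 1 and np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        # The magnified volume must fit on the detector, otherwise every
        # projection is truncated and FDK is meaningless.
        extent_needed = self.magnification * self.n_voxels * self.voxel_size
        extent_have = self.n_voxels * self.detector_pixel_size
        if extent_needed > extent_have * (1 + 1e-9):
            raise ValueError(
                "detector does not cover the projected volume: "
                f"need {extent_needed:.3f} mm, have {extent_have:.3f} mm"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def detector_pixels(self) -> tuple[int, int]:
        """Detector grid as (rows, cols); rows are axial, cols transaxial."""
        return (self.n_voxels, self.n_voxels)

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @property
    def magnification(self) -> float:
        """(source-to-detector) / (source-to-axis) distance ratio."""
        return (self.source_to_center + self.center_to_detector) / self.source_to_center

    @property
    def source_to_detector(self) -> float:
        return self.source_to_center + self.center_to_detector

    @property
    def virtual_pixel_size(self) -> float:
        """Detector pitch rescaled to the plane through the rotation axis."""
        return self.detector_pixel_size / self.magnification

    @property
    def cone_angle(self) -> float:
        """Full axial cone opening angle (radians) subtended by the detector."""
        half = 0.5 * self.n_voxels * self.virtual_pixel_size
        return 2.0 * math.atan2(half, self.source_to_center)

    def volume_shape(self) -> tuple[int, int, int]:
        n = self.n_voxels
        return (n, n, n)

    def projection_shape(self) -> tuple[int, int, int]:
        return (self.n_angles, *self.detector_pixels)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "source_to_center_mm": float(self.source_to_center),
            "center_to_detector_mm": float(self.center_to_detector),
            "detector_pixel_size_mm": float(self.detector_pixel_size),
            "n_voxels": int(self.n_voxels),
            "voxel_size_mm": float(self.voxel_size),
            "angles_rad": [float(a) for a in self.angles],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConeBeamGeometry":
        return cls(
            source_to_center=d["source_to_center_mm"],
            center_to_detector=d["center_to_detector_mm"],
            n_voxels=d["n_voxels"],
            voxel_size=d["voxel_size_mm"],
            detector_pixel_size=d["detector_pixel_size_mm"],
            angles=np.asarray(d["angles_rad"], dtype=np.float64),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConeBeamGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_angles(self, angles: np.ndarray) -> "ConeBeamGeometry":
        return ConeBeamGeometry(
            source_to_center=self.source_to_center,
            center_to_detector=self.center_to_detector,
            n_voxels=self.n_voxels,
            voxel_size=self.voxel_size,
            detector_pixel_size=self.detector_pixel_size,
            angles=angles,
        )


def equidistant_angles(n_angles: int) -> np.ndarray:
    """``n_angles`` equally spaced rotation angles over the full circle."""
    return np.arange(n_angles, dtype=np.float64) * (2.0 * np.pi / n_angles)


def default_geometry(
    n_voxels: int,
    n_angles: int,
    *,
    cone_angle_deg: float = 10.0,
    physical_size_mm: float = 100.0,
    magnification: float = 2.0,
) -> ConeBeamGeometry:
    """Convenience constructor for a desk-scale scan of a 10 cm cube.

    The source distance is chosen so the volume subtends the requested full
    cone angle, and the detector pitch equals ``magnification * voxel_size``
    so the magnified volume exactly fills the ``N x N`` detector.
    """
    if cone_angle_deg <= 0 or cone_angle_deg >= 120:
        raise ValueError("cone_angle_deg must be in (0, 120)")
    s = physical_size_mm / n_voxels
    half = 0.5 * physical_size_mm
    d_so = half / math.tan(math.radians(cone_angle_deg) / 2.0)
    return ConeBeamGeometry(
        source_to_center=d_so,
        center_to_detector=d_so * (magnification - 1.0),
        n_voxels=n_voxels,
        voxel_size=s,
        detector_pixel_size=magnification * s,
        angles=equidistant_angles(n_angles),
    )


@dataclass
class VoxelVolume:
    """An ``N**3`` grid of attenuation samples (1/cm) with its voxel pitch (mm)."""

    values: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError("volume must be a cubic 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_geometry(self, geom: ConeBeamGeometry) -> None:
        if self.values.shape != geom.volume_shape():
            raise ValueError(
                f"volume shape {self.values.shape} does not match geometry "
                f"{geom.volume_shape()}"
            )


@dataclass
class ProjectionStack:
    """Stack of ``Na`` cone-beam projections (line integrals, dimensionless)."""

    values: np.ndarray
    geometry: ConeBeamGeometry

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("projection stack must be a 3-D array")
        if self.values.shape != self.geometry.projection_shape():
            raise ValueError(
                f"projection shape {self.values.shape} does not match geometry "
                f"{self.geometry.projection_shape()}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projections contain non-finite values")

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]
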