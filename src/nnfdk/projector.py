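"""Forward and backprojection operators for the circular cone-beam geometry.

The reconstruction problem is the linear system ``W x = y`` with ``W`` the
discretized cone-beam transform.  This module provides:

``forward_project``
    The physics forward model ``W``: ray-driven integration with trilinear
    sampling, returning Beer-Lambert line integrals (volume in 1/cm, paths
    converted to cm, so ``exp(-y)`` is a transmitted fraction).
``backproject``
    ``W^T``-style voxel-driven backprojection with bilinear detector
    interpolation.  It is the exact transpose of ``forward_project_matched``
    (a pixel splatting operator), and only an approximate transpose of
    ``forward_project`` -- the two discretizations differ, as is usual for
    ray-driven/voxel-driven pairs.  Iterative methods therefore use the
    matched pair.
``fdk_weighted_backproject``
    The backprojection used inside FDK: same interpolation, plus the
    Feldkamp ``(D/(D+s))**2`` distance weight and the angular-step and
    detector-pitch normalization of the inversion formula.

A backend registry lets an external (e.g. GPU) projector replace the native
kernels; everything in-tree runs against ``"native"``.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .geometry import MM_TO_CM, ConeBeamGeometry, ProjectionStack, VoxelVolume

__all__ = [
    "forward_project",
    "forward_project_matched",
    "backproject",
    "fdk_weighted_backproject",
    "register_backend",
    "use_backend",
    "active_backend",
]

#: Ray-marching step as a fraction of the voxel pitch.  0.5 keeps the
#: integration error well below the trilinear interpolation error.
RAY_STEP_FRACTION = 0.5


class NativeBackend:
    """CPU projector pair built on the numba kernels."""

    name = "native"

    def forward(self, vol: np.ndarray, geom: ConeBeamGeometry) -> np.ndarray:
        out = np.zeros(geom.projection_shape(), dtype=np.float64)
        rows, cols = geom.detector_pixels
        _kernels.forward_kernel(
            np.ascontiguousarray(vol, dtype=np.float64),
            geom.voxel_size,
            geom.angles,
            rows,
            cols,
            geom.detector_pixel_size,
            geom.source_to_center,
            geom.center_to_detector,
            RAY_STEP_FRACTION,
            out,
        )
        out *= MM_TO_CM  # path lengths mm -> cm
        return out

    def forward_matched(self, vol: np.ndarray, geom: ConeBeamGeometry) -> np.ndarray:
        out = np.zeros(geom.projection_shape(), dtype=np.float64)
        _kernels.splat_forward_kernel(
            np.ascontiguousarray(vol, dtype=np.float64),
            geom.angles,
            geom.n_voxels,
            geom.voxel_size,
            geom.detector_pixel_size,
            geom.source_to_center,
            geom.center_to_detector,
            geom.voxel_size * MM_TO_CM,
            out,
        )
        return out

    def backproject(self, proj: np.ndarray, geom: ConeBeamGeometry) -> np.ndarray:
        out = np.zeros(geom.volume_shape(), dtype=np.float64)
        _kernels.backproject_kernel(
            np.ascontiguousarray(proj, dtype=np.float64),
            geom.angles,
            geom.n_voxels,
            geom.voxel_size,
            geom.detector_pixel_size,
            geom.source_to_center,
            geom.center_to_detector,
            False,
            geom.voxel_size * MM_TO_CM,
            out,
        )
        return out

    def fdk_backproject(self, proj: np.ndarray, geom: ConeBeamGeometry) -> np.ndarray:
        out = np.zeros(geom.volume_shape(), dtype=np.float64)
        # Angular step 2*pi/Na, the half from the redundant full circle, and
        # the virtual detector pitch (in cm, matching the filter's 1/cm^2
        # scale and the 1/cm attenuation unit) are folded in here so learned
        # filters stay comparable across Na.
        scale = (
            (2.0 * np.pi / geom.n_angles)
            * 0.5
            * geom.virtual_pixel_size
            * MM_TO_CM
        )
        _kernels.backproject_kernel(
            np.ascontiguousarray(proj, dtype=np.float64),
            geom.angles,
            geom.n_voxels,
            geom.voxel_size,
            geom.detector_pixel_size,
            geom.source_to_center,
            geom.center_to_detector,
            True,
            scale,
            out,
        )
        return out


_BACKENDS: dict[str, object] = {"native": NativeBackend()}
_ACTIVE = "native"


def register_backend(backend) -> None:
    """Register a projector backend exposing the NativeBackend interface."""
    _BACKENDS[backend.name] = backend


def use_backend(name: str) -> None:
    global _ACTIVE
    if name not in _BACKENDS:
        raise KeyError(f"unknown projector backend {name!r}")
    _ACTIVE = name


def active_backend():
    return _BACKENDS[_ACTIVE]


def forward_project(vol: VoxelVolume, geom: ConeBeamGeometry) -> ProjectionStack:
    """Apply the cone-beam transform ``W`` to a volume.

    Returns dimensionless line integrals (attenuation in 1/cm times path
    length in cm); linear in ``vol``.
    """
    vol.check_geometry(geom)
    return ProjectionStack(active_backend().forward(vol.values, geom), geom)


def forward_project_matched(vol: VoxelVolume, geom: ConeBeamGeometry) -> ProjectionStack:
    """Pixel-splatting forward projector, exact transpose of ``backproject``."""
    vol.check_geometry(geom)
    return ProjectionStack(active_backend().forward_matched(vol.values, geom), geom)


def backproject(proj: ProjectionStack, geom: ConeBeamGeometry) -> VoxelVolume:
    """Plain backprojection ``W^T y`` (no distance weight, no FDK scaling)."""
    _check_proj(proj, geom)
    return VoxelVolume(active_backend().backproject(proj.values, geom), geom.voxel_size)


def fdk_weighted_backproject(proj: ProjectionStack, geom: ConeBeamGeometry) -> VoxelVolume:
    """Feldkamp distance-weighted backprojection with FDK normalization."""
    _check_proj(proj, geom)
    return VoxelVolume(active_backend().fdk_backproject(proj.values, geom), geom.voxel_size)


def _check_proj(proj: ProjectionStack, geom: ConeBeamGeometry) -> None:
    if proj.values.shape != geom.projection_shape():
        raise ValueError(
            f"projection shape {proj.values.shape} does not match geometry "
            f"{geom.projection_shape()}"
        )
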