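"""SIRT with a nonnegativity constraint (SIRT+).

The simultaneous iterative reconstruction technique update

    x <- max(0, x + C W^T R (y - W x))

with ``R`` and ``C`` the diagonal inverse row and column sums of ``W``
(zero where a ray or voxel is never hit).  It uses the matched
(adjoint-consistent) projector pair -- the pixel-splatting forward and the
voxel-driven backprojector -- because SIRT's convergence theory assumes
``W^T`` is the true transpose; the FDK-weighted backprojector is not used
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ConeBeamGeometry, ProjectionStack, VoxelVolume
from .projector import backproject, forward_project_matched

__all__ = ["SIRTState", "sirt_plus", "sirt_iterations"]


@dataclass
class SIRTState:
    """Final iterate with the normalization fields and residual history."""

    volume: VoxelVolume
    row_inv: np.ndarray
    col_inv: np.ndarray
    n_iter: int
    residual_norms: list


def sirt_iterations(forward, transpose, y, x0, n_iter, nonneg=True, eps=1e-12):
    """Generic SIRT loop over callables ``forward(x)`` / ``transpose(y)``.

    Factored out so tiny explicit systems can exercise the exact update
    rule; returns ``(x, residual_norms, row_inv, col_inv)``.
    """
    row_sum = forward(np.ones_like(x0))
    col_sum = transpose(np.ones_like(y))
    row_inv = np.where(row_sum > eps, 1.0 / np.maximum(row_sum, eps), 0.0)
    col_inv = np.where(col_sum > eps, 1.0 / np.maximum(col_sum, eps), 0.0)
    x = x0.copy()
    norms = []
    for _ in range(n_iter):
        res = y - forward(x)
        norms.append(float(np.linalg.norm(res)))
        x = x + col_inv * transpose(row_inv * res)
        if nonneg:
            np.maximum(x, 0.0, out=x)
    norms.append(float(np.linalg.norm(y - forward(x))))
    return x, norms, row_inv, col_inv


def sirt_plus(
    proj: ProjectionStack,
    geom: ConeBeamGeometry,
    n_iter: int = 200,
    nonneg: bool = True,
    return_state: bool = False,
):
    """Run ``n_iter`` SIRT(+) iterations from a zero initial volume.

    Typical iteration counts are 200 for low-angle/high-dose problems and
    20 for low-dose ones.  Returns the final ``VoxelVolume`` (and the full
    ``SIRTState`` when ``return_state`` is set).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if proj.values.shape != geom.projection_shape():
        raise ValueError("projection stack does not match geometry")

    def fwd(x):
        return forward_project_matched(VoxelVolume(x, geom.voxel_size), geom).values

    def bwd(y):
        return backproject(ProjectionStack(y, geom), geom).values

    x0 = np.zeros(geom.volume_shape())
    x, norms, row_inv, col_inv = sirt_iterations(
        fwd, bwd, proj.values, x0, n_iter, nonneg=nonneg
    )
    vol = VoxelVolume(x, geom.voxel_size)
    if return_state:
        return SIRTState(vol, row_inv, col_inv, n_iter, norms)
    return vol
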