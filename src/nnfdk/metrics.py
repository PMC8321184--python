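"""Quantitative evaluation of reconstructions.

Three measure families:

* TSE (test-set error): half the mean squared difference between a
  reconstruction and a high-quality reference over a region of interest --
  the evaluation-side twin of the half-SSE training loss.
* SSIM with a uniform 19-pixel window (scikit-image defaults otherwise),
  computed per z-slice over the ROI bounding box and averaged.
* Segmentation overlap measures for binary masks: signed volume error,
  mislabeled-voxel fraction and the Dice coefficient.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .geometry import VoxelVolume

__all__ = ["tse", "ssim", "segmentation_metrics"]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, VoxelVolume) else np.asarray(x, dtype=np.float64)


def tse(x_r, x_hq, mask: np.ndarray) -> float:
    """Test-set error ``1 / (2 N_ROI) * || mask * (x_hq - x_r) ||^2``."""
    a, b = _values(x_r), _values(x_hq)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("reconstruction, reference and mask shapes must match")
    n_roi = int(np.count_nonzero(mask))
    if n_roi == 0:
        raise ValueError("empty ROI mask")
    diff = (b - a)[mask.astype(bool)]
    return float(diff @ diff) / (2.0 * n_roi)


def ssim(
    x_r,
    x_hq,
    mask: np.ndarray | None = None,
    win_size: int = 19,
) -> float:
    """Mean structural similarity, uniform window of ``win_size`` pixels.

    Computed slice-by-slice along z over the bounding box of ``mask`` (the
    full volume if no mask is given), averaging the per-pixel SSIM map over
    the masked voxels.  The dynamic range is taken from the reference.
    """
    a, b = _values(x_r), _values(x_hq)
    if a.shape != b.shape:
        raise ValueError("image shapes must match")
    if mask is not None and mask.shape != a.shape:
        raise ValueError("mask shape must match the images")
    if mask is not None:
        mask = mask.astype(bool)
        idx = np.where(mask)
        lo = [int(i.min()) for i in idx]
        hi = [int(i.max()) + 1 for i in idx]
        # grow the bounding box to at least the window size where possible
        for ax in range(3):
            short = win_size - (hi[ax] - lo[ax])
            if short > 0:
                lo[ax] = max(0, lo[ax] - (short + 1) // 2)
                hi[ax] = min(a.shape[ax], lo[ax] + max(win_size, hi[ax] - lo[ax]))
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        a, b, mask = a[box], b[box], mask[box]
    data_range = float(b.max() - b.min())
    if data_range == 0:
        data_range = 1.0
    if mask is None:
        # unmasked: the standard per-slice mean SSIM (window-cropped),
        # averaged over slices
        vals = [
            structural_similarity(
                b[z], a[z], win_size=win_size, gaussian_weights=False,
                data_range=data_range,
            )
            for z in range(a.shape[0])
        ]
        return float(np.mean(vals))
    total = 0.0
    weight = 0
    for z in range(a.shape[0]):
        _, smap = structural_similarity(
            b[z],
            a[z],
            win_size=win_size,
            gaussian_weights=False,
            data_range=data_range,
            full=True,
        )
        m = mask[z]
        total += float(smap[m].sum())
        weight += int(np.count_nonzero(m))
    if weight == 0:
        raise ValueError("mask selects no voxels")
    return total / weight


def segmentation_metrics(s_rec: np.ndarray, s_gs: np.ndarray):
    """Volume error, mislabeled fraction and Dice coefficient of two masks.

    ``Verr`` is signed, ``(|S_rec| - |S_gs|) / |S_gs|``; ``MLerr`` counts
    voxelwise absolute differences relative to ``|S_gs|``; ``DC`` is
    ``2 |S_rec & S_gs| / (|S_rec| + |S_gs|)``.
    """
    a = np.asarray(s_rec).astype(bool)
    b = np.asarray(s_gs).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes must match")
    n_gs = int(b.sum())
    if n_gs == 0:
        raise ValueError("empty gold-standard mask")
    n_rec = int(a.sum())
    verr = (n_rec - n_gs) / n_gs
    mlerr = int(np.count_nonzero(a != b)) / n_gs
    inter = int(np.count_nonzero(a & b))
    dc = 2.0 * inter / (n_rec + n_gs) if (n_rec + n_gs) else 1.0
    return verr, mlerr, dc
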