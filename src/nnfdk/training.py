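"""Training machinery for NN-FDK networks.

A training pair couples one voxel's feature vector -- its value in each of
the ``Ne`` FDK reconstructions with binned unit filters -- to the same
voxel in a high-quality reference reconstruction.  Pairs are drawn
uniformly without replacement from a region of interest (the thresholded
object support dilated by a buffer of roughly ``0.2 N`` voxels), with an
equal number of pairs per source dataset, and the squared-error loss

    L(theta, T) = 1/2 * sum_j (O_j - N_theta(Z_j))^2

is minimized with the Levenberg-Marquardt algorithm using the analytic
Jacobian of the network.  A damping step is accepted only if it reduces
the training loss; the validation loss of every accepted iterate is
tracked and the parameters returned are the (earliest) iterate with the
lowest validation loss, with early stopping after a configurable number of
epochs without validation improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.filters import threshold_otsu

from .binning import BinningOperator, expand_unit
from .fdk import apply_filter_1d, fdk, reweight
from .geometry import ConeBeamGeometry, ProjectionStack, VoxelVolume
from .network import NNFDKParams, network_forward, sigmoid
from .projector import fdk_weighted_backproject

__all__ = [
    "FeatureVolumes",
    "TrainingSet",
    "LMAConfig",
    "compute_feature_volumes",
    "roi_mask",
    "sample_pairs",
    "fit_input_scaling",
    "fit_target_scaling",
    "train_lma",
]


@dataclass
class FeatureVolumes:
    """The ``Ne`` FDK reconstructions with binned unit filters.

    ``volumes[j]`` is the reconstruction with the indicator filter of bin
    ``j``; the linear combination with coefficients ``h_e`` reproduces the
    FDK reconstruction with the expanded filter ``E h_e``.
    """

    volumes: np.ndarray  # (Ne, N, N, N)
    binning: BinningOperator
    voxel_size: float

    @property
    def ne(self) -> int:
        return self.volumes.shape[0]

    def rows(self, flat_indices: np.ndarray) -> np.ndarray:
        """Feature vectors (len Ne) for flat voxel indices."""
        flat = self.volumes.reshape(self.ne, -1)
        return flat[:, flat_indices].T


def compute_feature_volumes(
    proj: ProjectionStack, geom: ConeBeamGeometry, binning: BinningOperator
) -> FeatureVolumes:
    """One FDK reconstruction per binned unit filter.

    The reweighting is shared; each unit filter gets its own row filtering
    and weighted backprojection, exactly as ``fdk`` would compute it.
    """
    weighted = reweight(proj, geom)
    vols = np.empty((binning.ne, *geom.volume_shape()), dtype=np.float64)
    for j in range(binning.ne):
        filtered = apply_filter_1d(weighted, expand_unit(binning, j))
        vols[j] = fdk_weighted_backproject(filtered, geom).values
    return FeatureVolumes(vols, binning, geom.voxel_size)


def roi_mask(x_hq: VoxelVolume | np.ndarray, buffer_frac: float = 0.2) -> np.ndarray:
    """Object support (global Otsu threshold) dilated by ``buffer_frac * N``.

    The dilation is Euclidean: a voxel is in the mask if its distance to
    the thresholded object is at most ``round(buffer_frac * N)`` voxels.
    """
    values = x_hq.values if isinstance(x_hq, VoxelVolume) else np.asarray(x_hq, float)
    if np.ptp(values) == 0:
        raise ValueError("volume is constant; no object to build an ROI around")
    support = values > threshold_otsu(values)
    radius = int(round(buffer_frac * values.shape[0]))
    if radius == 0:
        return support
    dist = distance_transform_edt(~support)
    return dist <= radius


@dataclass
class TrainingSet:
    """Sampled (feature vector, target) pairs with their provenance."""

    inputs: np.ndarray  # (n, Ne)
    targets: np.ndarray  # (n,)
    dataset_ids: np.ndarray  # (n,)
    voxel_indices: np.ndarray  # (n,) flat indices into the source volume

    def __post_init__(self) -> None:
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=np.float64))
        self.targets = np.asarray(self.targets, dtype=np.float64).ravel()
        n = self.inputs.shape[0]
        if self.targets.shape != (n,):
            raise ValueError("inputs and targets disagree in length")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @staticmethod
    def concatenate(sets: list["TrainingSet"]) -> "TrainingSet":
        return TrainingSet(
            inputs=np.concatenate([s.inputs for s in sets]),
            targets=np.concatenate([s.targets for s in sets]),
            dataset_ids=np.concatenate([s.dataset_ids for s in sets]),
            voxel_indices=np.concatenate([s.voxel_indices for s in sets]),
        )


def _sample_one(features, target_values, mask, nt, nv, rng, dataset_id):
    flat_mask = np.flatnonzero(mask.ravel())
    if nt + nv > flat_mask.size:
        raise ValueError(
            f"ROI of dataset {dataset_id!r} has {flat_mask.size} voxels, "
            f"fewer than the {nt + nv} requested pairs"
        )
    chosen = rng.choice(flat_mask, size=nt + nv, replace=False)
    tgt = np.asarray(
        target_values.values if isinstance(target_values, VoxelVolume) else target_values
    ).ravel()

    def build(idx):
        return TrainingSet(
            inputs=features.rows(idx),
            targets=tgt[idx],
            dataset_ids=np.full(idx.size, dataset_id),
            voxel_indices=idx,
        )

    return build(chosen[:nt]), build(chosen[nt:])


def sample_pairs(
    features,
    x_hq_scaled,
    mask,
    nt: int,
    nv: int,
    rng_seed: int,
    dataset_id=0,
) -> tuple[TrainingSet, TrainingSet]:
    """Draw disjoint training/validation pairs uniformly from the ROI.

    Every pair is unique (sampling without replacement) and the training
    and validation sets are disjoint.  Passing lists of feature volumes,
    targets and masks draws an equal number of pairs from each dataset;
    ``nt`` and ``nv`` must then divide evenly.
    """
    rng = np.random.default_rng(rng_seed)
    if isinstance(features, (list, tuple)):
        n_ds = len(features)
        if nt % n_ds or nv % n_ds:
            raise ValueError(
                f"nt={nt} and nv={nv} must be divisible by the number of "
                f"datasets ({n_ds}) for an equal per-dataset split"
            )
        ids = dataset_id if isinstance(dataset_id, (list, tuple)) else range(n_ds)
        trains, vals = [], []
        for feat, tgt, msk, did in zip(features, x_hq_scaled, mask, ids):
            tr, va = _sample_one(feat, tgt, msk, nt // n_ds, nv // n_ds, rng, did)
            trains.append(tr)
            vals.append(va)
        return TrainingSet.concatenate(trains), TrainingSet.concatenate(vals)
    return _sample_one(features, x_hq_scaled, mask, nt, nv, rng, dataset_id)


def fit_input_scaling(inputs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (offset, scale) normalizing features to zero mean, unit sd."""
    inputs = np.asarray(inputs, dtype=np.float64)
    mu = inputs.mean(axis=0)
    sd = inputs.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def fit_target_scaling(
    values: np.ndarray, low: float = 0.05, high: float = 0.95
) -> tuple[float, float]:
    """Affine (offset, scale) mapping the value range into [low, high].

    Grey value g maps to ``(g - offset) / scale``; the sigmoid output is
    mapped back with ``out * scale + offset``.
    """
    values = np.asarray(values, dtype=np.float64)
    vmin, vmax = float(values.min()), float(values.max())
    span = vmax - vmin
    if span == 0:
        span = 1.0
    scale = span / (high - low)
    offset = vmin - low * scale
    return offset, scale


def scale_targets(values, offset: float, scale: float):
    return (np.asarray(values, dtype=np.float64) - offset) / scale


# ---------------------------------------------------------------------------
# Levenberg-Marquardt


@dataclass
class LMAConfig:
    """Classical Marquardt schedule; exposed because the exact variant is
    a free design choice (identity vs. Jacobian-diagonal damping)."""

    lambda0: float = 1e-2
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    max_epochs: int = 500
    patience: int = 100
    damping: str = "identity"  # or "diag"
    lambda_max: float = 1e12


def _pack(theta: NNFDKParams) -> np.ndarray:
    return np.concatenate(
        [
            theta.hidden_filters.ravel(),
            theta.hidden_biases,
            theta.output_weights,
            [theta.output_bias],
        ]
    )


def _unpack(vec: np.ndarray, theta: NNFDKParams) -> NNFDKParams:
    nh, ne = theta.nh, theta.ne
    i = nh * ne
    return replace(
        theta,
        hidden_filters=vec[:i].reshape(nh, ne).copy(),
        hidden_biases=vec[i : i + nh].copy(),
        output_weights=vec[i + nh : i + 2 * nh].copy(),
        output_bias=float(vec[i + 2 * nh]),
    )


def _forward_parts(vec, z, nh, ne):
    w = vec[: nh * ne].reshape(nh, ne)
    bh = vec[nh * ne : nh * ne + nh]
    xi = vec[nh * ne + nh : nh * ne + 2 * nh]
    bo = vec[nh * ne + 2 * nh]
    hidden = sigmoid(z @ w.T - bh)  # (n, Nh)
    out = sigmoid(hidden @ xi - bo)  # (n,)
    return hidden, out, xi


def model_residuals(vec, z, t, nh, ne):
    _, out, _ = _forward_parts(vec, z, nh, ne)
    return out - t


def model_jacobian(vec, z, nh, ne):
    """Analytic Jacobian d out_j / d theta_i, shape (n, (Ne+2)Nh + 1)."""
    hidden, out, xi = _forward_parts(vec, z, nh, ne)
    d_out = out * (1.0 - out)  # (n,)
    d_hidden = hidden * (1.0 - hidden)  # (n, Nh)
    n = z.shape[0]
    jac = np.empty((n, (ne + 2) * nh + 1))
    chain = d_out[:, None] * xi[None, :] * d_hidden  # (n, Nh)
    # hidden filter coefficients, laid out k-major like _pack
    jac[:, : nh * ne] = (chain[:, :, None] * z[:, None, :]).reshape(n, nh * ne)
    jac[:, nh * ne : nh * ne + nh] = -chain  # hidden biases
    jac[:, nh * ne + nh : nh * ne + 2 * nh] = d_out[:, None] * hidden  # xi
    jac[:, -1] = -d_out  # output bias
    return jac


@dataclass
class EpochRecord:
    epoch: int
    lam: float
    train_loss: float
    val_loss: float
    accepted: bool


def train_lma(
    theta0: NNFDKParams,
    train: TrainingSet,
    val: TrainingSet,
    config: LMAConfig | None = None,
) -> tuple[NNFDKParams, list[EpochRecord]]:
    """Levenberg-Marquardt minimization of the half-SSE loss.

    Solves ``(J^T J + lambda D) delta = J^T r`` per epoch with the analytic
    Jacobian; steps that do not reduce the training loss are rejected and
    raise the damping.  Returns the accepted iterate with the lowest
    validation loss seen (the initial parameters count, so the result is
    never worse on validation than ``theta0``) together with the per-epoch
    history.
    """
    cfg = config or LMAConfig()
    if cfg.damping not in ("identity", "diag"):
        raise ValueError("damping must be 'identity' or 'diag'")
    nh, ne = theta0.nh, theta0.ne
    zt, tt = train.inputs, train.targets
    zv, tv = val.inputs, val.targets

    vec = _pack(theta0)
    r = model_residuals(vec, zt, tt, nh, ne)
    loss = 0.5 * float(r @ r)
    if not np.isfinite(loss):
        raise ValueError("non-finite training loss at the initial parameters")
    rv = model_residuals(vec, zv, tv, nh, ne)
    val_loss = 0.5 * float(rv @ rv)

    best_vec = vec.copy()
    best_val = val_loss
    since_improve = 0
    lam = cfg.lambda0
    history = [EpochRecord(0, lam, loss, val_loss, True)]

    jac = model_jacobian(vec, zt, nh, ne)
    for epoch in range(1, cfg.max_epochs + 1):
        jtj = jac.T @ jac
        grad = jac.T @ r
        damp = np.eye(vec.size) if cfg.damping == "identity" else np.diag(
            np.maximum(np.diag(jtj), 1e-12)
        )
        try:
            delta = np.linalg.solve(jtj + lam * damp, grad)
        except np.linalg.LinAlgError:
            lam = min(lam * cfg.lambda_up, cfg.lambda_max)
            history.append(EpochRecord(epoch, lam, loss, val_loss, False))
            continue
        cand = vec - delta
        r_new = model_residuals(cand, zt, tt, nh, ne)
        loss_new = 0.5 * float(r_new @ r_new)
        if np.isfinite(loss_new) and loss_new < loss:
            vec, r, loss = cand, r_new, loss_new
            lam = max(lam * cfg.lambda_down, 1e-15)
            jac = model_jacobian(vec, zt, nh, ne)
            rv = model_residuals(vec, zv, tv, nh, ne)
            val_loss = 0.5 * float(rv @ rv)
            accepted = True
            if val_loss < best_val:  # strict: ties keep the earliest best
                best_val = val_loss
                best_vec = vec.copy()
                since_improve = 0
            else:
                since_improve += 1
        else:
            lam = min(lam * cfg.lambda_up, cfg.lambda_max)
            accepted = False
            since_improve += 1
        history.append(EpochRecord(epoch, lam, loss, val_loss, accepted))
        if since_improve >= cfg.patience:
            break
    return _unpack(best_vec, theta0), history
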