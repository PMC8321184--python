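"""The NN-FDK network and reconstruction algorithm.

The network ``N_theta`` is a two-layer perceptron acting on one voxel's
feature vector ``q`` (the voxel's value in each of the ``Ne`` FDK
reconstructions with binned unit filters):

    N_theta(q) = P_{xi, b_o}( [ P_{h_e^k, b_k}(q) ]_{k=1..Nh} ),
    P_{w, b}(eta) = sigmoid(eta . w - b).

Because FDK is bilinear in (data, filter), evaluating this network at every
voxel simultaneously is the same as running ``Nh`` FDK reconstructions with
the learned binned filters and combining them through sigmoids -- the
NN-FDK reconstruction algorithm.  This module holds the parameter set, both
evaluation routes, and their bookkeeping (scaling, serialization,
initialization, parameter counting).

Scaling conventions (stored in the parameter set):

* input scaling: each feature channel j is mapped ``(q_j - mu_j) / sd_j``
  before entering the hidden layer.  At reconstruction time the affine map
  is fused into the filters and biases (``h' = h / sd``,
  ``b' = b + mu . h'``) so the volume route and the voxel route agree
  exactly.
* target scaling: grey values are mapped affinely into (0, 1) for training
  (a sigmoid output cannot leave that interval) and the inverse map is
  applied to reconstructed volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import expit

from .binning import BinnedFilter, BinningOperator, expand
from .fdk import fdk
from .geometry import ConeBeamGeometry, ProjectionStack, VoxelVolume

__all__ = [
    "NNFDKParams",
    "sigmoid",
    "perceptron",
    "network_forward",
    "predict_grey",
    "count_params",
    "init_params",
    "nnfdk_reconstruct",
]


def sigmoid(t):
    """Numerically stable logistic function ``1 / (1 + exp(-t))``."""
    return expit(t)


def perceptron(eta: np.ndarray, xi: np.ndarray, b: float):
    """Single node: sigmoid of a weighted input sum minus a bias."""
    eta = np.asarray(eta, dtype=np.float64)
    xi = np.asarray(xi, dtype=np.float64)
    if eta.shape[-1] != xi.shape[0]:
        raise ValueError(f"input length {eta.shape[-1]} != weight length {xi.shape[0]}")
    return sigmoid(eta @ xi - b)


@dataclass
class NNFDKParams:
    """Full parameter set ``theta`` of the NN-FDK algorithm.

    ``hidden_filters`` holds the binned filter coefficients ``h_e^k`` as an
    (Nh, Ne) array; together with the hidden biases, output weights and
    output bias these are the trainable parameters.  The affine input and
    target scalings are fitted once from the training set and are part of
    the model, not of the optimization.
    """

    binning: BinningOperator
    hidden_filters: np.ndarray
    hidden_biases: np.ndarray
    output_weights: np.ndarray
    output_bias: float
    input_offset: np.ndarray
    input_scale: np.ndarray
    target_offset: float = 0.0
    target_scale: float = 1.0

    def __post_init__(self) -> None:
        ne = self.binning.ne
        self.hidden_filters = np.atleast_2d(
            np.asarray(self.hidden_filters, dtype=np.float64)
        )
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=np.float64).ravel()
        self.output_weights = np.asarray(self.output_weights, dtype=np.float64).ravel()
        self.input_offset = np.asarray(self.input_offset, dtype=np.float64).ravel()
        self.input_scale = np.asarray(self.input_scale, dtype=np.float64).ravel()
        nh = self.hidden_filters.shape[0]
        if nh < 1:
            raise ValueError("need at least one hidden node")
        if self.hidden_filters.shape != (nh, ne):
            raise ValueError("hidden_filters must have shape (Nh, Ne)")
        for name, arr, size in [
            ("hidden_biases", self.hidden_biases, nh),
            ("output_weights", self.output_weights, nh),
            ("input_offset", self.input_offset, ne),
            ("input_scale", self.input_scale, ne),
        ]:
            if arr.shape != (size,):
                raise ValueError(f"{name} must have length {size}")
        if np.any(self.input_scale <= 0):
            raise ValueError("input_scale entries must be > 0")
        if self.target_scale == 0:
            raise ValueError("target_scale must be nonzero")

    @property
    def nh(self) -> int:
        return self.hidden_filters.shape[0]

    @property
    def ne(self) -> int:
        return self.binning.ne

    @property
    def n_trainable(self) -> int:
        return count_params(self.nh, self.binning)

    # -- serialization (bit-exact: JSON shortest-roundtrip floats) ---------

    def to_dict(self) -> dict:
        return {
            "binning": self.binning.to_dict(),
            "hidden_filters": self.hidden_filters.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": float(self.output_bias),
            "input_offset": self.input_offset.tolist(),
            "input_scale": self.input_scale.tolist(),
            "target_offset": float(self.target_offset),
            "target_scale": float(self.target_scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NNFDKParams":
        return cls(
            binning=BinningOperator.from_dict(d["binning"]),
            hidden_filters=np.asarray(d["hidden_filters"], dtype=np.float64),
            hidden_biases=np.asarray(d["hidden_biases"], dtype=np.float64),
            output_weights=np.asarray(d["output_weights"], dtype=np.float64),
            output_bias=d["output_bias"],
            input_offset=np.asarray(d["input_offset"], dtype=np.float64),
            input_scale=np.asarray(d["input_scale"], dtype=np.float64),
            target_offset=d["target_offset"],
            target_scale=d["target_scale"],
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "NNFDKParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def count_params(nh: int, binning: BinningOperator) -> int:
    """Number of trainable parameters: ``(Ne + 2) * Nh + 1``.

    Per hidden node: Ne filter coefficients, one hidden bias and one output
    weight; plus the single output bias.
    """
    if nh < 1:
        raise ValueError("nh must be >= 1")
    return (binning.ne + 2) * nh + 1


def init_params(nh: int, binning: BinningOperator, rng_seed: int) -> NNFDKParams:
    """Reproducible random initialization (uniform in [-1, 1], b_o = 0)."""
    rng = np.random.default_rng(rng_seed)
    ne = binning.ne
    return NNFDKParams(
        binning=binning,
        hidden_filters=rng.uniform(-1.0, 1.0, size=(nh, ne)),
        hidden_biases=rng.uniform(-1.0, 1.0, size=nh),
        output_weights=rng.uniform(-1.0, 1.0, size=nh),
        output_bias=0.0,
        input_offset=np.zeros(ne),
        input_scale=np.ones(ne),
    )


def network_forward(q: np.ndarray, theta: NNFDKParams) -> np.ndarray:
    """Evaluate ``N_theta`` on already input-scaled feature vectors.

    ``q`` has shape (..., Ne); the result lies strictly in (0, 1).
    """
    q = np.asarray(q, dtype=np.float64)
    if q.shape[-1] != theta.ne:
        raise ValueError(f"feature length {q.shape[-1]} != Ne = {theta.ne}")
    hidden = sigmoid(q @ theta.hidden_filters.T - theta.hidden_biases)
    return sigmoid(hidden @ theta.output_weights - theta.output_bias)


def predict_grey(q_raw: np.ndarray, theta: NNFDKParams) -> np.ndarray:
    """Network prediction in grey values from raw (unscaled) features."""
    q = (np.asarray(q_raw, dtype=np.float64) - theta.input_offset) / theta.input_scale
    return network_forward(q, theta) * theta.target_scale + theta.target_offset


def fused_hidden_layer(theta: NNFDKParams) -> tuple[np.ndarray, np.ndarray]:
    """Hidden filters/biases with the input scaling folded in.

    Returns ``(H', b')`` such that ``sigmoid(q_raw @ H'.T - b')`` equals the
    hidden layer applied to the scaled features.
    """
    h_fused = theta.hidden_filters / theta.input_scale[np.newaxis, :]
    b_fused = theta.hidden_biases + h_fused @ theta.input_offset
    return h_fused, b_fused


def nnfdk_reconstruct(
    proj: ProjectionStack, theta: NNFDKParams, geom: ConeBeamGeometry
) -> VoxelVolume:
    """NN-FDK reconstruction: Nh FDK runs combined through sigmoids.

    Performs exactly ``Nh`` FDK evaluations with the (scaling-fused)
    expanded binned filters, applies the hidden sigmoids and the output
    perceptron voxelwise, and maps the result back to grey values.
    """
    if theta.binning.n != geom.n_voxels:
        raise ValueError("parameter binning does not match geometry size")
    h_fused, b_fused = fused_hidden_layer(theta)
    acc = None
    for k in range(theta.nh):
        vol_k = fdk(proj, expand(theta.binning, h_fused[k]), geom)
        hk = sigmoid(vol_k.values - b_fused[k])
        term = theta.output_weights[k] * hk
        acc = term if acc is None else acc + term
    out = sigmoid(acc - theta.output_bias)
    grey = out * theta.target_scale + theta.target_offset
    return VoxelVolume(grey, geom.voxel_size)
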