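"""End-to-end simulation experiments tying the modules together.

The canonical pipeline mirrors the simulated-data study design: generate
random Fourshape phantoms, simulate noisy low-quality scans, build
high-quality training targets with the dense-scan Hann-FDK recipe, train
an NN-FDK network on voxel pairs drawn from the region of interest of
several training datasets, and evaluate the trained network against
Hann-filtered FDK on fresh test phantoms by their test-set error (TSE)
against the ground-truth voxelization.

Desk-scale defaults (N = 64, 10 training datasets, 3 * 10^4 training and
validation pairs) keep a full experiment within a few minutes on one CPU;
all sizes are arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .binning import make_binning
from .fdk import fdk, standard_filter
from .geometry import ConeBeamGeometry, VoxelVolume, default_geometry
from .metrics import tse
from .network import NNFDKParams, init_params, nnfdk_reconstruct
from .phantoms import fourshape_random, make_hq_target, simulate_projections, voxelize
from .sirt import sirt_plus
from .training import (
    LMAConfig,
    TrainingSet,
    compute_feature_volumes,
    fit_input_scaling,
    fit_target_scaling,
    roi_mask,
    sample_pairs,
    scale_targets,
    train_lma,
)

__all__ = [
    "SimulatedDataset",
    "build_training_dataset",
    "train_from_datasets",
    "fourshape_noise_experiment",
]


@dataclass
class SimulatedDataset:
    """One simulated scan: phantom, noisy data, and the HQ training target."""

    spec: object
    ground_truth: VoxelVolume
    geometry: ConeBeamGeometry
    projections: object
    hq_target: VoxelVolume
    seed: int


def build_training_dataset(
    seed: int,
    n: int = 64,
    na: int = 32,
    i0: float | None = 256.0,
    cone_angle_deg: float = 10.0,
) -> SimulatedDataset:
    """Simulate one Fourshape dataset with its high-quality target."""
    spec = fourshape_random(seed)
    gt = voxelize(spec, n)
    geom = default_geometry(n, na, cone_angle_deg=cone_angle_deg)
    proj = simulate_projections(gt, geom, i0, rng_seed=seed + 1)
    hq = make_hq_target(spec, n, rng_seed=seed + 2, vol=gt)
    return SimulatedDataset(spec, gt, geom, proj, hq, seed)


def train_from_datasets(
    datasets: list,
    nh: int = 4,
    nt: int = 30_000,
    nv: int = 30_000,
    seed: int = 0,
    config: LMAConfig | None = None,
):
    """Train an NN-FDK network from simulated datasets.

    Feature volumes are computed per dataset, the ROI is taken from each
    HQ target, grey values are mapped into (0, 1) by a common affine
    target scaling, and the requested numbers of unique pairs are drawn
    equally from every dataset.  ``nt``/``nv`` are clipped to what the
    ROIs can supply.  Returns ``(params, history)``.
    """
    geom = datasets[0].geometry
    binning = make_binning(geom)
    features, targets, masks = [], [], []
    for ds in datasets:
        features.append(compute_feature_volumes(ds.projections, ds.geometry, binning))
        masks.append(roi_mask(ds.hq_target))
        targets.append(ds.hq_target.values)

    roi_sizes = [int(m.sum()) for m in masks]
    n_ds = len(datasets)
    per_ds_cap = min(roi_sizes) // 2
    nt = min(nt // n_ds, per_ds_cap - per_ds_cap // 4) * n_ds
    nv = min(nv // n_ds, per_ds_cap // 4) * n_ds

    t_off, t_scale = fit_target_scaling(
        np.concatenate([t[m] for t, m in zip(targets, masks)])
    )
    scaled = [scale_targets(t, t_off, t_scale) for t in targets]
    train, val = sample_pairs(
        features, scaled, masks, nt, nv, rng_seed=seed,
        dataset_id=[ds.seed for ds in datasets],
    )
    mu, sd = fit_input_scaling(train.inputs)

    def apply_scaling(ts: TrainingSet) -> TrainingSet:
        return TrainingSet(
            (ts.inputs - mu) / sd, ts.targets, ts.dataset_ids, ts.voxel_indices
        )

    theta0 = replace(
        init_params(nh, binning, rng_seed=seed + 1),
        input_offset=mu,
        input_scale=sd,
        target_offset=t_off,
        target_scale=t_scale,
    )
    params, history = train_lma(theta0, apply_scaling(train), apply_scaling(val), config)
    return params, history


def evaluate_on_phantom(
    params: NNFDKParams,
    seed: int,
    n: int = 64,
    na: int = 32,
    i0: float | None = 256.0,
    cone_angle_deg: float = 10.0,
) -> dict:
    """TSE of NN-FDK vs Hann-FDK on one fresh test phantom (vs ground truth)."""
    spec = fourshape_random(seed)
    gt = voxelize(spec, n)
    geom = default_geometry(n, na, cone_angle_deg=cone_angle_deg)
    proj = simulate_projections(gt, geom, i0, rng_seed=seed + 1)
    mask = roi_mask(gt)
    rec_nn = nnfdk_reconstruct(proj, params, geom)
    rec_fdk = fdk(proj, standard_filter("hann", geom), geom)
    return {
        "seed": seed,
        "tse_nnfdk": tse(rec_nn, gt, mask),
        "tse_fdk_hann": tse(rec_fdk, gt, mask),
    }


def fourshape_noise_experiment(
    seed: int = 0,
    n: int = 64,
    na: int = 32,
    i0: float = 256.0,
    n_train_datasets: int = 10,
    n_test: int = 10,
    nh: int = 4,
    nt: int = 30_000,
    nv: int = 30_000,
    sirt_iters: int = 0,
) -> dict:
    """The high-noise simulated-data comparison at desk scale.

    Trains one NN-FDK network on ``n_train_datasets`` random Fourshape
    datasets (N, Na, I0 as given), then evaluates NN-FDK against
    Hann-filtered FDK on ``n_test`` fresh random test phantoms.  If
    ``sirt_iters`` > 0, also runs SIRT+ on the first test problem and
    reports its residual history and minimum voxel value.
    """
    rng = np.random.default_rng(seed)
    train_seeds = [int(s) for s in rng.integers(0, 2**30, size=n_train_datasets)]
    test_seeds = [int(s) for s in rng.integers(0, 2**30, size=n_test)]
    datasets = [
        build_training_dataset(s, n=n, na=na, i0=i0) for s in train_seeds
    ]
    params, history = train_from_datasets(
        datasets, nh=nh, nt=nt, nv=nv, seed=seed + 1
    )
    results = [evaluate_on_phantom(params, s, n=n, na=na, i0=i0) for s in test_seeds]
    out = {
        "params": params,
        "history": history,
        "tests": results,
        "n_wins": sum(r["tse_nnfdk"] < r["tse_fdk_hann"] for r in results),
    }
    if sirt_iters > 0:
        spec = fourshape_random(test_seeds[0])
        gt = voxelize(spec, n)
        geom = default_geometry(n, na)
        proj = simulate_projections(gt, geom, i0, rng_seed=test_seeds[0] + 1)
        state = sirt_plus(proj, geom, n_iter=sirt_iters, return_state=True)
        out["sirt_residuals"] = state.residual_norms
        out["sirt_min_voxel"] = float(state.volume.values.min())
    return out
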