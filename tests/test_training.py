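"""Training machinery: feature volumes, ROI, pair sampling, LMA."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

import nnfdk as nf
from nnfdk.binning import expand_unit
from nnfdk.network import network_forward
from nnfdk.training import (
    LMAConfig,
    _pack,
    compute_feature_volumes,
    fit_input_scaling,
    fit_target_scaling,
    model_jacobian,
    model_residuals,
    scale_targets,
)


class TestFeatureVolumes:
    def test_unit_filter_volumes_match_direct_fdk(self, geom16, rng):
        proj = nf.ProjectionStack(rng.normal(size=geom16.projection_shape()), geom16)
        op = nf.make_binning(geom16)
        fv = compute_feature_volumes(proj, geom16, op)
        assert fv.ne == op.ne
        for j in (0, op.ne // 2, op.ne - 1):
            direct = nf.fdk(proj, expand_unit(op, j), geom16).values
            assert np.array_equal(fv.volumes[j], direct)

    def test_linear_combination_reproduces_fdk(self, geom16, rng):
        proj = nf.ProjectionStack(rng.normal(size=geom16.projection_shape()), geom16)
        op = nf.make_binning(geom16)
        fv = compute_feature_volumes(proj, geom16, op)
        he = rng.normal(size=op.ne)
        combined = np.tensordot(he, fv.volumes, axes=1)
        direct = nf.fdk(proj, nf.expand(op, he), geom16).values
        assert np.linalg.norm(combined - direct) / np.linalg.norm(direct) <= 1e-6

    def test_zero_projections_give_zero_features(self, geom16):
        proj = nf.ProjectionStack(np.zeros(geom16.projection_shape()), geom16)
        fv = compute_feature_volumes(proj, geom16, nf.make_binning(geom16))
        assert np.all(fv.volumes == 0)


class TestRoiMask:
    def _half_cube(self, n=32):
        vals = np.zeros((n, n, n))
        q = n // 4
        vals[q : 3 * q, q : 3 * q, q : 3 * q] = 1.0
        return vals

    def test_mask_matches_euclidean_dilation_oracle(self):
        """Mask equals the object dilated by a Euclidean ball of radius
        round(0.2 N) = 6 voxels (independent ball-structuring-element
        dilation as the oracle)."""
        vals = self._half_cube(32)
        mask = nf.roi_mask(nf.VoxelVolume(vals, 1.0), buffer_frac=0.2)
        r = 6
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = zz**2 + yy**2 + xx**2 <= r**2
        oracle = ndimage.binary_dilation(vals > 0.5, structure=ball)
        assert np.array_equal(mask, oracle)

    def test_mask_is_superset_of_object(self):
        vals = self._half_cube(32)
        mask = nf.roi_mask(nf.VoxelVolume(vals, 1.0))
        assert np.all(mask[vals > 0.5])

    def test_zero_buffer_equals_thresholded_support(self):
        vals = self._half_cube(32)
        mask = nf.roi_mask(nf.VoxelVolume(vals, 1.0), buffer_frac=0.0)
        assert np.array_equal(mask, vals > 0.5)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            nf.roi_mask(nf.VoxelVolume(np.ones((16, 16, 16)), 1.0))


def _fake_features(n, ne, seed, voxel_size=1.0):
    rng = np.random.default_rng(seed)
    return nf.FeatureVolumes(rng.normal(size=(ne, n, n, n)), nf.make_binning(8), voxel_size)


class TestSamplePairs:
    def test_unique_pairs_inside_mask(self):
        n = 16
        fv = _fake_features(n, 6, 0)
        target = np.arange(n**3, dtype=float).reshape(n, n, n)
        mask = np.zeros((n, n, n), bool)
        mask[4:12, 4:12, 4:12] = True
        train, val = nf.sample_pairs(fv, target, mask, 100, 50, rng_seed=3)
        assert len(train) == 100 and len(val) == 50
        both = np.concatenate([train.voxel_indices, val.voxel_indices])
        assert len(set(both.tolist())) == 150  # unique and disjoint
        assert mask.ravel()[both].all()
        # targets really are the masked voxel values
        assert np.array_equal(train.targets, target.ravel()[train.voxel_indices])

    def test_equal_split_across_datasets(self):
        n = 16
        fvs = [_fake_features(n, 6, s) for s in (1, 2)]
        targets = [np.random.default_rng(s).normal(size=(n, n, n)) for s in (1, 2)]
        masks = [np.ones((n, n, n), bool)] * 2
        train, val = nf.sample_pairs(
            fvs, targets, masks, 100, 20, rng_seed=0, dataset_id=["a", "b"]
        )
        assert (train.dataset_ids == "a").sum() == 50
        assert (train.dataset_ids == "b").sum() == 50
        assert (val.dataset_ids == "a").sum() == 10

    def test_deterministic_under_seed(self):
        n = 16
        fv = _fake_features(n, 6, 0)
        target = np.zeros((n, n, n))
        mask = np.ones((n, n, n), bool)
        t1, v1 = nf.sample_pairs(fv, target, mask, 64, 32, rng_seed=9)
        t2, v2 = nf.sample_pairs(fv, target, mask, 64, 32, rng_seed=9)
        assert np.array_equal(t1.voxel_indices, t2.voxel_indices)
        assert np.array_equal(v1.voxel_indices, v2.voxel_indices)

    def test_too_small_roi_rejected(self):
        n = 16
        fv = _fake_features(n, 6, 0)
        mask = np.zeros((n, n, n), bool)
        mask[0, 0, :10] = True
        with pytest.raises(ValueError):
            nf.sample_pairs(fv, np.zeros((n, n, n)), mask, 8, 8, rng_seed=0)


class TestScalings:
    def test_input_scaling_normalizes(self, rng):
        x = rng.normal(loc=3.0, scale=2.5, size=(500, 4))
        mu, sd = fit_input_scaling(x)
        z = (x - mu) / sd
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)

    def test_target_scaling_maps_range_into_unit_interval(self, rng):
        v = rng.normal(size=1000) * 7 - 3
        off, sc = fit_target_scaling(v)
        z = scale_targets(v, off, sc)
        assert z.min() == pytest.approx(0.05)
        assert z.max() == pytest.approx(0.95)


class TestLMA:
    def _planted(self, nh, ne_n, n_pairs, seed):
        op = nf.make_binning(ne_n)
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(n_pairs, op.ne))
        star = nf.init_params(nh, op, seed + 1)
        t = network_forward(z, star)
        return op, z, t, star

    def test_jacobian_matches_central_finite_differences(self):
        op, z, t, star = self._planted(2, 4, 40, 5)
        theta0 = nf.init_params(2, op, 77)
        vec = _pack(theta0)
        nh, ne = 2, op.ne
        jac = model_jacobian(vec, z, nh, ne)
        eps = 1e-6
        for i in range(vec.size):
            vp, vm = vec.copy(), vec.copy()
            vp[i] += eps
            vm[i] -= eps
            fd = (
                model_residuals(vp, z, t, nh, ne)
                - model_residuals(vm, z, t, nh, ne)
            ) / (2 * eps)
            scale = max(np.abs(jac[:, i]).max(), 1e-8)
            assert np.abs(fd - jac[:, i]).max() / scale <= 1e-5

    def test_planted_parameters_recovered(self):
        """Noiseless targets from a planted network: predictions match to
        MSE <= 1e-6 (Nh=2, Ne=5, 1e4 pairs)."""
        op, z, t, star = self._planted(2, 4, 10_000, 1)
        assert op.ne == 5
        theta0 = nf.init_params(2, op, 99)
        train = nf.TrainingSet(z[:8000], t[:8000], np.zeros(8000), np.arange(8000))
        val = nf.TrainingSet(z[8000:], t[8000:], np.zeros(2000), np.arange(2000))
        fit, _ = nf.train_lma(theta0, train, val)
        mse = float(np.mean((network_forward(z, fit) - t) ** 2))
        assert mse <= 1e-6

    def test_accepted_training_loss_non_increasing(self):
        op, z, t, _ = self._planted(2, 4, 2000, 3)
        theta0 = nf.init_params(2, op, 12)
        train = nf.TrainingSet(z[:1500], t[:1500], np.zeros(1500), np.arange(1500))
        val = nf.TrainingSet(z[1500:], t[1500:], np.zeros(500), np.arange(500))
        _, hist = nf.train_lma(theta0, train, val, LMAConfig(max_epochs=120))
        losses = [h.train_loss for h in hist if h.accepted]
        assert all(b <= a + 1e-15 for a, b in zip(losses, losses[1:]))

    def test_returned_params_never_worse_on_validation(self):
        op, z, t, _ = self._planted(2, 4, 1000, 8)
        theta0 = nf.init_params(2, op, 21)
        train = nf.TrainingSet(z[:700], t[:700], np.zeros(700), np.arange(700))
        val = nf.TrainingSet(z[700:], t[700:], np.zeros(300), np.arange(300))
        fit, hist = nf.train_lma(theta0, train, val, LMAConfig(max_epochs=50))
        r0 = network_forward(val.inputs, theta0) - val.targets
        rf = network_forward(val.inputs, fit) - val.targets
        assert 0.5 * float(rf @ rf) <= 0.5 * float(r0 @ r0) + 1e-15

    def test_converges_to_coordinatewise_grid_optimum(self):
        """After convergence on a tiny planted problem, sweeping each single
        parameter over a grid finds no lower training loss (grid-search
        oracle for local optimality)."""
        op, z, t, _ = self._planted(1, 4, 500, 4)
        theta0 = nf.init_params(1, op, 31)
        train = nf.TrainingSet(z, t, np.zeros(500), np.arange(500))
        fit, _ = nf.train_lma(theta0, train, train)
        vec = _pack(fit)
        nh, ne = 1, op.ne

        def loss(v):
            r = model_residuals(v, z, t, nh, ne)
            return 0.5 * float(r @ r)

        base = loss(vec)
        for i in range(vec.size):
            for step in np.linspace(-0.05, 0.05, 11):
                if step == 0:
                    continue
                v = vec.copy()
                v[i] += step
                assert loss(v) >= base - 1e-6

    def test_diag_damping_variant_also_converges(self):
        op, z, t, _ = self._planted(2, 4, 3000, 6)
        theta0 = nf.init_params(2, op, 14)
        train = nf.TrainingSet(z[:2500], t[:2500], np.zeros(2500), np.arange(2500))
        val = nf.TrainingSet(z[2500:], t[2500:], np.zeros(500), np.arange(500))
        fit, _ = nf.train_lma(theta0, train, val, LMAConfig(damping="diag"))
        mse = float(np.mean((network_forward(z, fit) - t) ** 2))
        assert mse <= 1e-5

    def test_nonfinite_initial_loss_rejected(self):
        op = nf.make_binning(4)
        theta0 = nf.init_params(1, op, 0)
        bad = nf.TrainingSet(
            np.full((10, op.ne), 1.0), np.full(10, np.nan), np.zeros(10), np.arange(10)
        )
        with pytest.raises(ValueError):
            nf.train_lma(theta0, bad, bad)
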