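"""Projector correctness: linearity, physical scale, adjointness, geometry."""

import numpy as np
import pytest
from scipy import ndimage

import nnfdk as nf
from nnfdk.geometry import MM_TO_CM
from nnfdk.projector import forward_project_matched

from conftest import random_volume


def siddon_oracle(vol, geom, step_frac=0.02):
    """Brute-force ray tracer: piecewise-constant voxels, very fine steps.

    Independent of the production kernel: numpy-only, nearest-cell
    sampling, explicit slab intersection per ray.
    """
    n = geom.n_voxels
    s = geom.voxel_size
    half = n * s / 2
    out = np.zeros(geom.projection_shape())
    for a, beta in enumerate(geom.angles):
        cb, sb = np.cos(beta), np.sin(beta)
        src = np.array([geom.source_to_center * cb, geom.source_to_center * sb, 0.0])
        for r in range(n):
            v = (r - (n - 1) / 2) * geom.detector_pixel_size
            for c in range(n):
                u = (c - (n - 1) / 2) * geom.detector_pixel_size
                pix = np.array(
                    [
                        -geom.center_to_detector * cb - u * sb,
                        -geom.center_to_detector * sb + u * cb,
                        v,
                    ]
                )
                d = pix - src
                length = np.linalg.norm(d)
                d /= length
                t0, t1 = 0.0, length
                ok = True
                for ax in range(3):
                    o, dd = src[ax], d[ax]
                    if abs(dd) < 1e-12:
                        if abs(o) > half:
                            ok = False
                            break
                    else:
                        ta, tb = (-half - o) / dd, (half - o) / dd
                        if ta > tb:
                            ta, tb = tb, ta
                        t0, t1 = max(t0, ta), min(t1, tb)
                if not ok or t1 <= t0:
                    continue
                dt = step_frac * s
                m = int(np.ceil((t1 - t0) / dt))
                dt = (t1 - t0) / m
                ts = t0 + (np.arange(m) + 0.5) * dt
                pts = src[None, :] + ts[:, None] * d[None, :]
                idx = np.floor(pts / s + n / 2).astype(int)
                valid = np.all((idx >= 0) & (idx < n), axis=1)
                ii = idx[valid]
                out[a, r, c] = vol.values[ii[:, 2], ii[:, 1], ii[:, 0]].sum() * dt * MM_TO_CM
    return out


class TestForwardProject:
    def test_zero_volume_gives_zero_projections(self, geom16):
        vol = nf.VoxelVolume(np.zeros(geom16.volume_shape()), geom16.voxel_size)
        assert np.all(nf.forward_project(vol, geom16).values == 0)

    def test_linearity(self, geom16):
        a = random_volume(geom16, seed=1)
        b = random_volume(geom16, seed=2)
        pa = nf.forward_project(a, geom16).values
        pb = nf.forward_project(b, geom16).values
        comb = nf.VoxelVolume(2.0 * a.values - 0.5 * b.values, geom16.voxel_size)
        pc = nf.forward_project(comb, geom16).values
        assert np.allclose(pc, 2.0 * pa - 0.5 * pb, rtol=1e-6, atol=1e-12)

    def test_central_ray_through_homogeneous_cube(self):
        """Central ray value equals mu * chord length through the cube."""
        n = 64
        geom = nf.default_geometry(n, 4, cone_angle_deg=10.0)
        s = geom.voxel_size
        c = (np.arange(n) - (n - 1) / 2) * s
        x, y, z = np.meshgrid(c, c, c, indexing="ij")
        side = 40 * s  # mm; faces fall on voxel-cell boundaries
        mu = 0.22
        inside = (np.abs(x) < side / 2) & (np.abs(y) < side / 2) & (np.abs(z) < side / 2)
        vol = nf.VoxelVolume(inside.astype(float).transpose(2, 1, 0) * mu, s)
        proj = nf.forward_project(vol, geom)
        expected = mu * side * MM_TO_CM
        assert proj.values[0, n // 2, n // 2] == pytest.approx(expected, rel=0.02)

    def test_single_voxel_blob_against_siddon_oracle(self):
        """A unit voxel projects to one blob per angle whose integral is the
        voxel volume times the magnification correction, consistent with a
        brute-force Siddon tracer."""
        geom = nf.default_geometry(8, 16, cone_angle_deg=10.0)
        vals = np.zeros((8, 8, 8))
        vals[4, 4, 4] = 1.0
        vol = nf.VoxelVolume(vals, geom.voxel_size)
        proj = nf.forward_project(vol, geom).values
        oracle = siddon_oracle(vol, geom)
        # paraxial expectation: s_cm * s^2 * m^2 per angle
        expected = (
            geom.voxel_size * MM_TO_CM * geom.voxel_size**2 * geom.magnification**2
        )
        pix_area = geom.detector_pixel_size**2
        for a in range(geom.n_angles):
            n_blobs = ndimage.label(proj[a] > 1e-3 * proj[a].max())[1]
            assert n_blobs == 1
            assert proj[a].sum() * pix_area == pytest.approx(expected, rel=0.10)
        # total footprint integral matches the independent tracer closely
        assert proj.sum() == pytest.approx(oracle.sum(), rel=0.04)

    def test_rotating_phantom_equals_shifting_angles(self):
        """Circular-trajectory symmetry: rotating the object by one angular
        step reproduces the projections of the previous angle."""
        n = 32
        base = nf.default_geometry(n, 24, cone_angle_deg=10.0)
        geom = base.with_angles(base.angles + np.radians(7.5))
        s = geom.voxel_size
        c = (np.arange(n) - (n - 1) / 2) * s
        zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
        sig, cx, cy = 12.0, 10.0, 3.0

        def blob(bx, by):
            return np.exp(-0.5 * ((xx - bx) ** 2 + (yy - by) ** 2 + zz**2) / sig**2)

        db = geom.angles[1] - geom.angles[0]
        bxr = np.cos(db) * cx - np.sin(db) * cy
        byr = np.sin(db) * cx + np.cos(db) * cy
        p1 = nf.forward_project(nf.VoxelVolume(blob(cx, cy), s), geom).values
        p2 = nf.forward_project(nf.VoxelVolume(blob(bxr, byr), s), geom).values
        rel = np.linalg.norm(p2[1:] - p1[:-1]) / np.linalg.norm(p1[:-1])
        assert rel <= 1e-3


class TestBackproject:
    def test_zero_projections_give_zero_volume(self, geom16):
        proj = nf.ProjectionStack(np.zeros(geom16.projection_shape()), geom16)
        assert np.all(nf.backproject(proj, geom16).values == 0)
        assert np.all(nf.fdk_weighted_backproject(proj, geom16).values == 0)

    def test_linearity(self, geom16, rng):
        pa = nf.ProjectionStack(rng.normal(size=geom16.projection_shape()), geom16)
        pb = nf.ProjectionStack(rng.normal(size=geom16.projection_shape()), geom16)
        for op in (nf.backproject, nf.fdk_weighted_backproject):
            va = op(pa, geom16).values
            vb = op(pb, geom16).values
            comb = nf.ProjectionStack(3.0 * pa.values + 0.25 * pb.values, geom16)
            assert np.allclose(op(comb, geom16).values, 3 * va + 0.25 * vb,
                               rtol=1e-6, atol=1e-12)

    def test_matched_adjoint_identity(self, geom8, rng):
        """<Wx, y> == <x, W^T y> for the matched splat/voxel-driven pair."""
        for _ in range(5):
            x = random_volume(geom8, seed=rng.integers(1 << 30))
            y = rng.normal(size=geom8.projection_shape())
            wx = forward_project_matched(x, geom8).values
            wty = nf.backproject(nf.ProjectionStack(y, geom8), geom8).values
            err = abs((wx * y).sum() - (x.values * wty).sum())
            assert err / (np.linalg.norm(wx) * np.linalg.norm(y)) <= 1e-3

    def test_single_pixel_backprojects_onto_its_ray(self, geom16):
        """A lone detector pixel may only touch voxels whose projection falls
        in that pixel's bilinear neighbourhood."""
        y = np.zeros(geom16.projection_shape())
        a0, r0, c0 = 3, 9, 5
        y[a0, r0, c0] = 1.0
        vol = nf.backproject(nf.ProjectionStack(y, geom16), geom16).values
        nz = np.argwhere(vol != 0)
        assert nz.size > 0
        beta = geom16.angles[a0]
        cb, sb = np.cos(beta), np.sin(beta)
        n = geom16.n_voxels
        for iz, iy, ix in nz:
            x = (ix - (n - 1) / 2) * geom16.voxel_size
            yy = (iy - (n - 1) / 2) * geom16.voxel_size
            z = (iz - (n - 1) / 2) * geom16.voxel_size
            ratio = geom16.source_to_center / (geom16.source_to_center - (x * cb + yy * sb))
            u = (-x * sb + yy * cb) * ratio * geom16.magnification
            v = z * ratio * geom16.magnification
            fc = u / geom16.detector_pixel_size + (n - 1) / 2
            fr = v / geom16.detector_pixel_size + (n - 1) / 2
            assert abs(fc - c0) < 1.0 and abs(fr - r0) < 1.0

    def test_fdk_weight_field_matches_geometry(self):
        """FDK backprojection equals the plain one times the independently
        computed (D/(D+s))^2 distance-weight field, per angle."""
        n = 16
        geom = nf.default_geometry(n, 1, cone_angle_deg=20.0).with_angles(
            np.array([0.7])
        )
        rng = np.random.default_rng(3)
        y = nf.ProjectionStack(rng.normal(size=geom.projection_shape()), geom)
        plain = nf.backproject(y, geom).values
        weighted = nf.fdk_weighted_backproject(y, geom).values
        # independent weight field from the geometry definition
        c = (np.arange(n) - (n - 1) / 2) * geom.voxel_size
        zz, yy, xx = np.meshgrid(c, c, c, indexing="ij")
        beta = geom.angles[0]
        s_ax = -(xx * np.cos(beta) + yy * np.sin(beta))
        wfield = (geom.source_to_center / (geom.source_to_center + s_ax)) ** 2
        norm = (
            (2 * np.pi / geom.n_angles) * 0.5 * geom.virtual_pixel_size * MM_TO_CM
        ) / (geom.voxel_size * MM_TO_CM)
        sel = np.abs(plain) > 1e-9
        assert np.allclose(weighted[sel], plain[sel] * wfield[sel] * norm, rtol=1e-9)

    def test_fdk_weight_is_one_at_rotation_center(self):
        """s = 0 at the rotation axis, so the distance weight is exactly 1."""
        n = 17  # odd: a voxel sits exactly on the axis
        geom = nf.ConeBeamGeometry(
            source_to_center=300.0,
            center_to_detector=300.0,
            n_voxels=n,
            voxel_size=100.0 / n,
            detector_pixel_size=2 * 100.0 / n,
            angles=np.array([1.1]),
        )
        rng = np.random.default_rng(4)
        y = nf.ProjectionStack(rng.normal(size=geom.projection_shape()), geom)
        plain = nf.backproject(y, geom).values
        weighted = nf.fdk_weighted_backproject(y, geom).values
        norm = (2 * np.pi) * 0.5 * geom.virtual_pixel_size / geom.voxel_size
        mid = n // 2
        assert weighted[mid, mid, mid] == pytest.approx(
            plain[mid, mid, mid] * norm, rel=1e-12
        )
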