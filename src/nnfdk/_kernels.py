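"""Numba kernels for the native cone-beam projector pair.

Three discretizations live here:

* a ray-driven forward projector (trilinear sampling along each source to
  detector-pixel ray, fixed sub-voxel step),
* a voxel-driven backprojector with bilinear detector interpolation,
  optionally carrying the Feldkamp ``(D/(D+s))**2`` distance weight,
* a pixel-driven "splat" forward projector that is the exact transpose of
  the unweighted voxel-driven backprojector (used for adjoint tests and for
  the SIRT iteration, which needs a matched operator pair).

All kernels loop one angle at a time so projection-space layouts stay
(angle, row, col) with rows axial and columns transaxial.
"""

import math

import numba
import numpy as np

_SIG_CACHE = dict(cache=True, fastmath=True)


@numba.njit(**_SIG_CACHE)
def _trilinear(vol, n, fx, fy, fz):
    """Sample ``vol`` at fractional voxel coordinates, zero outside."""
    if fx <= -1.0 or fx >= n or fy <= -1.0 or fy >= n or fz <= -1.0 or fz >= n:
        return 0.0
    ix = int(math.floor(fx))
    iy = int(math.floor(fy))
    iz = int(math.floor(fz))
    wx = fx - ix
    wy = fy - iy
    wz = fz - iz
    acc = 0.0
    for dz in range(2):
        z = iz + dz
        if z < 0 or z >= n:
            continue
        cz = wz if dz == 1 else 1.0 - wz
        for dy in range(2):
            y = iy + dy
            if y < 0 or y >= n:
                continue
            cy = wy if dy == 1 else 1.0 - wy
            for dx in range(2):
                x = ix + dx
                if x < 0 or x >= n:
                    continue
                cx = wx if dx == 1 else 1.0 - wx
                acc += cz * cy * cx * vol[z, y, x]
    return acc


@numba.njit(**_SIG_CACHE)
def forward_kernel(vol, voxel_size, angles, n_rows, n_cols, pixel_size,
                   d_so, d_od, step_frac, out):
    """Ray-driven line integrals; ``out`` has shape (Na, rows, cols).

    Integrals are in units of (volume value) * mm; the caller rescales.
    """
    n = vol.shape[0]
    half = 0.5 * n * voxel_size
    inv_s = 1.0 / voxel_size
    off = 0.5 * (n - 1)
    step = step_frac * voxel_size
    for a in range(angles.shape[0]):
        cb = math.cos(angles[a])
        sb = math.sin(angles[a])
        sx = d_so * cb
        sy = d_so * sb
        for r in range(n_rows):
            v = (r - 0.5 * (n_rows - 1)) * pixel_size
            for c in range(n_cols):
                u = (c - 0.5 * (n_cols - 1)) * pixel_size
                px = -d_od * cb - u * sb
                py = -d_od * sb + u * cb
                pz = v
                dx = px - sx
                dy = py - sy
                dz = pz  # source z is 0
                norm = math.sqrt(dx * dx + dy * dy + dz * dz)
                dx /= norm
                dy /= norm
                dz /= norm
                # slab intersection with the cube [-half, half]^3
                t0 = 0.0
                t1 = norm
                ok = True
                for axis in range(3):
                    if axis == 0:
                        o = sx
                        d = dx
                    elif axis == 1:
                        o = sy
                        d = dy
                    else:
                        o = 0.0
                        d = dz
                    if abs(d) < 1e-12:
                        if o < -half or o > half:
                            ok = False
                            break
                    else:
                        ta = (-half - o) / d
                        tb = (half - o) / d
                        if ta > tb:
                            ta, tb = tb, ta
                        if ta > t0:
                            t0 = ta
                        if tb < t1:
                            t1 = tb
                if not ok or t1 <= t0:
                    out[a, r, c] = 0.0
                    continue
                n_steps = int(math.ceil((t1 - t0) / step))
                if n_steps < 1:
                    n_steps = 1
                dt = (t1 - t0) / n_steps
                t = t0 + 0.5 * dt
                acc = 0.0
                for _ in range(n_steps):
                    x = sx + t * dx
                    y = sy + t * dy
                    z = t * dz
                    acc += _trilinear(vol, n,
                                      x * inv_s + off,
                                      y * inv_s + off,
                                      z * inv_s + off)
                    t += dt
                out[a, r, c] = acc * dt


@numba.njit(**_SIG_CACHE)
def backproject_kernel(proj, angles, n, voxel_size, pixel_size,
                       d_so, d_od, weighted, scale, out):
    """Voxel-driven backprojection with bilinear detector interpolation.

    ``weighted`` toggles the Feldkamp distance weight ``(D/(D+s))**2`` with
    ``s`` the voxel coordinate along the source-to-detector axis.  ``scale``
    multiplies every contribution (physical normalization lives there).
    """
    n_rows = proj.shape[1]
    n_cols = proj.shape[2]
    mag = (d_so + d_od) / d_so
    off = 0.5 * (n - 1)
    inv_p = 1.0 / pixel_size
    for a in range(angles.shape[0]):
        cb = math.cos(angles[a])
        sb = math.sin(angles[a])
        for iz in range(n):
            z = (iz - off) * voxel_size
            for iy in range(n):
                y = (iy - off) * voxel_size
                for ix in range(n):
                    x = (ix - off) * voxel_size
                    s_ax = -(x * cb + y * sb)
                    denom = d_so + s_ax
                    if denom <= 1e-9:
                        continue
                    ratio = d_so / denom
                    # virtual detector coordinates, then physical pixels
                    u = (-x * sb + y * cb) * ratio * mag
                    v = z * ratio * mag
                    fc = u * inv_p + 0.5 * (n_cols - 1)
                    fr = v * inv_p + 0.5 * (n_rows - 1)
                    if fc <= -1.0 or fc >= n_cols or fr <= -1.0 or fr >= n_rows:
                        continue
                    ic = int(math.floor(fc))
                    ir = int(math.floor(fr))
                    wc = fc - ic
                    wr = fr - ir
                    val = 0.0
                    for dr in range(2):
                        rr = ir + dr
                        if rr < 0 or rr >= n_rows:
                            continue
                        cr = wr if dr == 1 else 1.0 - wr
                        for dc in range(2):
                            cc = ic + dc
                            if cc < 0 or cc >= n_cols:
                                continue
                            cw = wc if dc == 1 else 1.0 - wc
                            val += cr * cw * proj[a, rr, cc]
                    if weighted:
                        val *= ratio * ratio
                    out[iz, iy, ix] += scale * val


@numba.njit(**_SIG_CACHE)
def splat_forward_kernel(vol, angles, n, voxel_size, pixel_size,
                         d_so, d_od, scale, out):
    """Exact transpose of the unweighted ``backproject_kernel``."""
    n_rows = out.shape[1]
    n_cols = out.shape[2]
    mag = (d_so + d_od) / d_so
    off = 0.5 * (n - 1)
    inv_p = 1.0 / pixel_size
    for a in range(angles.shape[0]):
        cb = math.cos(angles[a])
        sb = math.sin(angles[a])
        for iz in range(n):
            z = (iz - off) * voxel_size
            for iy in range(n):
                y = (iy - off) * voxel_size
                for ix in range(n):
                    x = (ix - off) * voxel_size
                    val = vol[iz, iy, ix]
                    if val == 0.0:
                        continue
                    s_ax = -(x * cb + y * sb)
                    denom = d_so + s_ax
                    if denom <= 1e-9:
                        continue
                    ratio = d_so / denom
                    u = (-x * sb + y * cb) * ratio * mag
                    v = z * ratio * mag
                    fc = u * inv_p + 0.5 * (n_cols - 1)
                    fr = v * inv_p + 0.5 * (n_rows - 1)
                    if fc <= -1.0 or fc >= n_cols or fr <= -1.0 or fr >= n_rows:
                        continue
                    ic = int(math.floor(fc))
                    ir = int(math.floor(fr))
                    wc = fc - ic
                    wr = fr - ir
                    sval = scale * val
                    for dr in range(2):
                        rr = ir + dr
                        if rr < 0 or rr >= n_rows:
                            continue
                        cr = wr if dr == 1 else 1.0 - wr
                        for dc in range(2):
                            cc = ic + dc
                            if cc < 0 or cc >= n_cols:
                                continue
                            cw = wc if dc == 1 else 1.0 - wc
                            out[a, rr, cc] += cr * cw * sval
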