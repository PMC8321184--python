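"""Phantom families and cone-beam data simulation.

Two families of geometric phantoms drive the simulation studies:

* *Fourshape*: three random occurrences of each of four primitive types --
  an ellipsoid, a cuboid, a Gaussian blob and a Siemens star (an 8-spoke
  resolution target), with randomized centres, sizes, orientations and
  intensities.
* *Random Defrise*: a stack of flat, non-overlapping disks along the
  rotation axis, the classic probe for cone-angle artifacts; the standard
  variant has equispaced equal-intensity disks symmetric about the
  midplane.

Phantoms are defined on the unit cube and scaled to a 10 cm physical cube;
a relative intensity of 1 corresponds to an attenuation of 0.22 1/cm
(common plastics at ~40 keV).  Projection data follow Beer-Lambert
statistics: detected counts are Poisson with mean ``I0 * exp(-line
integral)``, and the measured value is ``-ln(max(counts, 1) / I0)`` (the
clamp keeps fully absorbed rays finite).

The high-quality training target is the reconstruction recipe used
throughout: 1500 projection angles, low noise (I0 = 2**20), a small
(0.6 degree) cone angle, reconstructed by FDK with a Hann filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fdk import fdk, standard_filter
from .geometry import ConeBeamGeometry, ProjectionStack, VoxelVolume, default_geometry
from .projector import forward_project

__all__ = [
    "Primitive",
    "PhantomSpec",
    "fourshape_random",
    "defrise_random",
    "defrise_standard",
    "voxelize",
    "simulate_projections",
    "make_hq_target",
]

#: Attenuation (1/cm) that a relative intensity of 1 maps to.
MU_PLASTIC = 0.22
#: Physical phantom cube edge (mm).
CUBE_MM = 100.0

KINDS = ("ellipsoid", "cuboid", "gaussian_blob", "siemens_star", "disk")


@dataclass
class Primitive:
    """One geometric primitive in unit-cube coordinates ([-0.5, 0.5]^3).

    ``size`` is interpreted per kind: semi-axes (ellipsoid), half-edges
    (cuboid), standard deviations (gaussian_blob), or
    (radius, radius, half-thickness) for disks and Siemens stars.
    """

    kind: str
    center: np.ndarray
    size: np.ndarray
    orientation: np.ndarray  # 3x3 rotation, world -> primitive frame is R.T
    intensity: float
    spokes: int = 8  # Siemens star only

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        self.center = np.asarray(self.center, dtype=np.float64)
        self.size = np.asarray(self.size, dtype=np.float64)
        self.orientation = np.asarray(self.orientation, dtype=np.float64)

    def bounding_radius(self) -> float:
        if self.kind == "gaussian_blob":
            return 3.0 * float(np.max(self.size))
        if self.kind in ("disk", "siemens_star"):
            return float(np.hypot(self.size[0], self.size[2]))
        return float(np.linalg.norm(self.size))

    def bounding_extents(self) -> np.ndarray:
        """Axis-aligned half-extents of the primitive in world coordinates."""
        r = self.orientation  # primitive -> world
        a = self.size
        if self.kind == "gaussian_blob":
            a = 3.0 * a
        if self.kind == "cuboid":
            return np.abs(r) @ a
        if self.kind in ("disk", "siemens_star"):
            normal = r[:, 2]
            return a[0] * np.sqrt(np.maximum(1.0 - normal**2, 0.0)) + a[2] * np.abs(
                normal
            )
        # ellipsoid / blob: support function of an ellipsoid along each axis
        return np.sqrt(((r * a[np.newaxis, :]) ** 2).sum(axis=1))

    def evaluate(self, pts: np.ndarray) -> np.ndarray:
        """Relative intensity contribution at points of shape (..., 3)."""
        q = (pts - self.center) @ self.orientation  # into primitive frame
        a = self.size
        if self.kind == "ellipsoid":
            inside = (q[..., 0] / a[0]) ** 2 + (q[..., 1] / a[1]) ** 2 + (
                q[..., 2] / a[2]
            ) ** 2 <= 1.0
            return self.intensity * inside
        if self.kind == "cuboid":
            inside = (
                (np.abs(q[..., 0]) <= a[0])
                & (np.abs(q[..., 1]) <= a[1])
                & (np.abs(q[..., 2]) <= a[2])
            )
            return self.intensity * inside
        if self.kind == "gaussian_blob":
            r2 = (q[..., 0] / a[0]) ** 2 + (q[..., 1] / a[1]) ** 2 + (
                q[..., 2] / a[2]
            ) ** 2
            return self.intensity * np.exp(-0.5 * r2)
        # disk / siemens_star: flat cylinder of radius a[0], half-height a[2]
        rad2 = q[..., 0] ** 2 + q[..., 1] ** 2
        inside = (rad2 <= a[0] ** 2) & (np.abs(q[..., 2]) <= a[2])
        if self.kind == "siemens_star":
            phi = np.arctan2(q[..., 1], q[..., 0])
            inside = inside & (np.sin(self.spokes * phi) > 0)
        return self.intensity * inside

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "center": self.center.tolist(),
            "size": self.size.tolist(),
            "orientation": self.orientation.tolist(),
            "intensity": float(self.intensity),
            "spokes": int(self.spokes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Primitive":
        return cls(
            kind=d["kind"],
            center=np.asarray(d["center"]),
            size=np.asarray(d["size"]),
            orientation=np.asarray(d["orientation"]),
            intensity=d["intensity"],
            spokes=d.get("spokes", 8),
        )


@dataclass
class PhantomSpec:
    """A phantom as a list of primitives plus a family label."""

    primitives: list
    family: str = "custom"

    def __post_init__(self) -> None:
        for p in self.primitives:
            if np.any(np.abs(p.center) + p.bounding_extents() > 0.5 + 1e-9):
                raise ValueError("primitive extends outside the unit cube")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "primitives": [p.to_dict() for p in self.primitives],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            primitives=[Primitive.from_dict(p) for p in d["primitives"]],
            family=d["family"],
        )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via a random unit quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


#: Randomization ranges for the Fourshape family (relative to cube width).
SIZE_RANGE = (0.05, 0.3)
INTENSITY_RANGE = (0.5, 1.5)


def fourshape_random(rng_seed: int, n_each: int = 3) -> PhantomSpec:
    """Random Fourshape phantom: ``n_each`` of each of the four kinds.

    Sizes are uniform in [0.05, 0.3] of the cube width, intensities in
    [0.5, 1.5], orientations uniform over rotations, centres uniform
    subject to the primitive staying inside the unit cube.
    """
    rng = np.random.default_rng(rng_seed)
    prims = []
    for kind in ("ellipsoid", "cuboid", "gaussian_blob", "siemens_star"):
        for _ in range(n_each):
            for _attempt in range(200):
                if kind in ("ellipsoid", "cuboid"):
                    size = rng.uniform(*SIZE_RANGE, size=3) * 0.5
                elif kind == "gaussian_blob":
                    size = np.full(3, rng.uniform(*SIZE_RANGE) * 0.25)
                else:  # siemens_star: radius and a thin height
                    radius = rng.uniform(*SIZE_RANGE)
                    size = np.array([radius, radius, rng.uniform(0.02, 0.06)])
                rot = _random_rotation(rng)
                intensity = rng.uniform(*INTENSITY_RANGE)
                p = Primitive(kind, np.zeros(3), size, rot, intensity)
                bound = p.bounding_radius()
                if bound >= 0.5:
                    continue
                p.center = rng.uniform(-(0.5 - bound), 0.5 - bound, size=3)
                prims.append(p)
                break
            else:  # pragma: no cover - ranges guarantee placement
                raise RuntimeError("could not place primitive inside the cube")
    return PhantomSpec(prims, family="fourshape")


def defrise_standard(n_disks: int = 7) -> PhantomSpec:
    """Equispaced equal-intensity Defrise disks, symmetric about z = 0."""
    centers = np.linspace(-0.35, 0.35, n_disks)
    prims = [
        Primitive(
            "disk",
            np.array([0.0, 0.0, z]),
            np.array([0.35, 0.35, 0.02]),
            np.eye(3),
            1.0,
        )
        for z in centers
    ]
    return PhantomSpec(prims, family="defrise")


def defrise_random(
    rng_seed: int, n_disks: int = 7, max_retries: int = 200
) -> PhantomSpec:
    """Random Defrise variant: varied intensity/size/tilt, non-overlapping.

    Disks are placed bottom-up along z with a positive gap between the
    axial slabs that bound consecutive (possibly tilted) disks.
    """
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_retries):
        prims = []
        z = -0.45
        ok = True
        for _i in range(n_disks):
            radius = rng.uniform(0.2, 0.3)
            half_th = rng.uniform(0.01, 0.02)
            tilt = math.radians(rng.uniform(0.0, 3.0))
            phi = rng.uniform(0.0, 2 * np.pi)
            ct, st = math.cos(tilt), math.sin(tilt)
            cp, sp = math.cos(phi), math.sin(phi)
            # tilt about a random in-plane axis
            rot = np.array(
                [[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]]
            ) @ np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])
            slab = radius * st + half_th  # axial half-extent of the tilted disk
            gap = rng.uniform(0.02, 0.06)
            zc = z + gap + slab
            if zc + slab > 0.45:
                ok = False
                break
            p = Primitive(
                "disk",
                np.array([0.0, 0.0, zc]),
                np.array([radius, radius, half_th]),
                rot,
                rng.uniform(*INTENSITY_RANGE),
            )
            if np.any(np.abs(p.center) + p.bounding_extents() > 0.5):
                ok = False
                break
            prims.append(p)
            z = zc + slab
        if ok and len(prims) == n_disks:
            return PhantomSpec(prims, family="defrise")
    raise RuntimeError("could not place non-overlapping Defrise disks")


def rotate_spec(spec: PhantomSpec, angle: float) -> PhantomSpec:
    """Rotate a phantom about the z (rotation) axis by ``angle`` radians."""
    c, s = math.cos(angle), math.sin(angle)
    rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    prims = [
        Primitive(
            p.kind, rz @ p.center, p.size.copy(), rz @ p.orientation,
            p.intensity, p.spokes,
        )
        for p in spec.primitives
    ]
    return PhantomSpec(prims, family=spec.family)


def voxelize(spec: PhantomSpec, n: int, supersample: int = 2) -> VoxelVolume:
    """Sample a phantom on an ``n**3`` grid (values in 1/cm).

    Partial-volume effects are handled by ``supersample``-fold subdivision
    of each voxel and averaging.  A relative intensity of 1 maps to
    0.22 1/cm and the cube spans 10 cm, so ``voxel_size = 100 / n`` mm.
    """
    if n < 16:
        raise ValueError("voxelize requires N >= 16")
    m = n * supersample
    coords = (np.arange(m) + 0.5) / m - 0.5
    values = np.zeros((m, m, m), dtype=np.float64)
    for p in spec.primitives:
        bound = p.bounding_radius()
        sel = [
            np.flatnonzero(np.abs(coords - p.center[ax]) <= bound + 1.0 / m)
            for ax in (0, 1, 2)  # x, y, z
        ]
        if any(s.size == 0 for s in sel):
            continue
        xs, ys, zs = (coords[s] for s in sel)
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        pts = np.stack([xx, yy, zz], axis=-1)  # (nz, ny, nx, 3), xyz order
        values[np.ix_(sel[2], sel[1], sel[0])] += p.evaluate(pts)
    if supersample > 1:
        values = values.reshape(n, supersample, n, supersample, n, supersample).mean(
            axis=(1, 3, 5)
        )
    return VoxelVolume(values * MU_PLASTIC, voxel_size=CUBE_MM / n)


def simulate_projections(
    vol: VoxelVolume,
    geom: ConeBeamGeometry,
    i0: float | None,
    rng_seed: int | None = None,
) -> ProjectionStack:
    """Forward project and, if ``i0`` is given, apply Beer-Lambert Poisson noise.

    Detected counts are ``Poisson(i0 * exp(-ybar))`` per detector sample;
    the returned value is ``-ln(max(counts, 1) / i0)``.  ``i0=None`` gives
    the noiseless line integrals.
    """
    clean = forward_project(vol, geom)
    if i0 is None:
        return clean
    rng = np.random.default_rng(rng_seed)
    counts = rng.poisson(i0 * np.exp(-clean.values))
    y = -np.log(np.maximum(counts, 1) / i0)
    return ProjectionStack(y, geom)


#: High-quality target recipe: many angles, low noise, small cone angle.
HQ_N_ANGLES = 1500
HQ_I0 = 2**20
HQ_CONE_ANGLE_DEG = 0.6


def make_hq_target(
    spec: PhantomSpec,
    n: int,
    rng_seed: int,
    vol: VoxelVolume | None = None,
) -> VoxelVolume:
    """High-quality reference reconstruction used as the training target.

    Simulates a dense scan (1500 angles, I0 = 2**20, 0.6 degree cone) of
    the phantom and reconstructs it with Hann-filtered FDK.  ``vol`` may
    pass an existing voxelization of ``spec`` to avoid recomputing it.
    """
    if vol is None:
        vol = voxelize(spec, n)
    geom = default_geometry(n, HQ_N_ANGLES, cone_angle_deg=HQ_CONE_ANGLE_DEG)
    proj = simulate_projections(vol, geom, HQ_I0, rng_seed)
    return fdk(proj, standard_filter("hann", geom), geom)
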