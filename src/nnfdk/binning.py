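"""Exponential binning of 1-D reconstruction filters.

A length-``2N`` spatial filter is parametrized by ``Ne ~ log2(N)``
coefficients: taps are grouped into radial bins around the filter centre
whose widths grow exponentially (1, 1, 1, 1, 2, 4, 8, ...), and the two
mirror-image bins at equal distance from the centre share one coefficient,
since FBP-type filters are symmetric.  The expansion ``h = E h_e`` is the
piecewise-constant map assigning each tap its bin's coefficient; ``E`` has
0/1 indicator columns and full column rank, so bin-averaging is an exact
left inverse.

With this scheme an N = 1024 geometry has Ne = 13 bins, which together
with four hidden nodes gives the 61 trainable network parameters of the
headline configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fdk import Filter1D
from .geometry import ConeBeamGeometry

__all__ = [
    "BinningOperator",
    "BinnedFilter",
    "make_binning",
    "expand",
    "bin_average",
]


@dataclass(frozen=True)
class BinningOperator:
    """Map between ``Ne`` bin coefficients and ``2N`` filter taps."""

    n: int
    boundaries: tuple
    """Radial bin edges ``b_0 = 0 < b_1 < ... < b_Ne``; bin j covers taps
    whose distance r from the filter centre satisfies b_j <= r < b_{j+1}."""

    def __post_init__(self) -> None:
        b = tuple(int(x) for x in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        if b[0] != 0 or any(x >= y1 for x, y1 in zip(b, b[1:])) or b[-1] != self.n + 1:
            raise ValueError("invalid bin boundaries")

    @property
    def ne(self) -> int:
        return len(self.boundaries) - 1

    @property
    def bin_index(self) -> np.ndarray:
        """Bin id for each of the 2N tap positions (centre tap at index N)."""
        radius = np.abs(np.arange(2 * self.n) - self.n)
        return np.searchsorted(np.asarray(self.boundaries), radius, side="right") - 1

    def to_dict(self) -> dict:
        return {"n": self.n, "boundaries": list(self.boundaries)}

    @classmethod
    def from_dict(cls, d: dict) -> "BinningOperator":
        return cls(n=d["n"], boundaries=tuple(d["boundaries"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "BinningOperator":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class BinnedFilter:
    """Coefficient vector ``h_e`` of length ``Ne``."""

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.ascontiguousarray(self.coefficients, dtype=np.float64)
        if self.coefficients.ndim != 1:
            raise ValueError("coefficients must be 1-D")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


def make_binning(geom: ConeBeamGeometry | int) -> BinningOperator:
    """Construct the exponential binning for filter length ``2N``.

    Radial widths follow 1, 1, 1, 1, 2, 4, 8, ... doubling after the four
    innermost unit bins; the last bin is truncated so the bins exactly
    partition radii 0..N (taps run over offsets -N..N-1 from the centre).
    """
    n = geom if isinstance(geom, (int, np.integer)) else geom.n_voxels
    n = int(n)
    if n < 4:
        raise ValueError("binning requires N >= 4")
    edges = [0, 1, 2, 3, 4]
    width = 2
    while edges[-1] < n + 1:
        edges.append(min(edges[-1] + width, n + 1))
        width *= 2
    return BinningOperator(n=n, boundaries=tuple(edges))


def expand(op: BinningOperator, he: BinnedFilter | np.ndarray) -> Filter1D:
    """Expand bin coefficients to a piecewise-constant length-2N filter."""
    coeff = he.coefficients if isinstance(he, BinnedFilter) else np.asarray(he, float)
    if coeff.shape != (op.ne,):
        raise ValueError(f"expected {op.ne} coefficients, got {coeff.shape}")
    return Filter1D(coeff[op.bin_index], name="binned")


def expand_unit(op: BinningOperator, j: int) -> Filter1D:
    """Indicator filter of bin ``j`` (expansion of the j-th unit vector)."""
    e = np.zeros(op.ne)
    e[j] = 1.0
    return expand(op, e)


def bin_average(op: BinningOperator, h: Filter1D | np.ndarray) -> BinnedFilter:
    """Per-bin mean of the taps: the exact left inverse of ``expand``."""
    taps = h.taps if isinstance(h, Filter1D) else np.asarray(h, float)
    if taps.shape != (2 * op.n,):
        raise ValueError(f"expected {2 * op.n} taps, got {taps.shape}")
    idx = op.bin_index
    sums = np.bincount(idx, weights=taps, minlength=op.ne)
    counts = np.bincount(idx, minlength=op.ne)
    return BinnedFilter(sums / counts)
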