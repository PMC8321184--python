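"""The FDK direct inversion: cosine reweighting, row-wise 1D filtering,
distance-weighted backprojection.

``FDK(y, h) = B_w( h * r(y) )`` with ``r`` the cosine reweighting that
makes cone-beam data behave approximately like fan-beam data, ``h`` a 1-D
spatial filter of length ``2N`` convolved along each detector row, and
``B_w`` the Feldkamp weighted backprojection.  The whole map is bilinear in
``(y, h)``, which is what makes the learned-filter network equivalence
possible.

Filters are kept in the spatial domain (the exponential binning of learned
filters is defined on spatial taps).  The standard ramp (Ram-Lak) filter
uses the closed-form band-limited taps; the Hann filter apodizes the ramp's
frequency response with a Hann window.  Tap units are 1/cm^2 at the virtual
detector pitch; together with the pitch and angular-step factors folded
into the backprojection this makes FDK of noiseless data approximate the
attenuation in 1/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .geometry import MM_TO_CM, ConeBeamGeometry, ProjectionStack, VoxelVolume
from .projector import fdk_weighted_backproject

__all__ = ["Filter1D", "reweight", "apply_filter_1d", "standard_filter", "fdk"]


@dataclass
class Filter1D:
    """Spatial-domain 1-D filter of length ``2N`` with its centre at tap N."""

    taps: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.taps = np.ascontiguousarray(self.taps, dtype=np.float64)
        if self.taps.ndim != 1:
            raise ValueError("filter taps must be 1-D")
        if not np.all(np.isfinite(self.taps)):
            raise ValueError("filter taps must be finite")

    def __len__(self) -> int:
        return self.taps.size

    def to_json(self, path) -> None:
        """Write the taps as a plain JSON array (with the name as metadata)."""
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps({"name": self.name, "taps": self.taps.tolist()}))

    @classmethod
    def from_json(cls, path) -> "Filter1D":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["taps"], dtype=np.float64), name=d.get("name", "custom"))

    def check_geometry(self, geom: ConeBeamGeometry) -> None:
        if self.taps.size != 2 * geom.n_voxels:
            raise ValueError(
                f"filter length {self.taps.size} != 2N = {2 * geom.n_voxels}"
            )


def detector_coordinates(geom: ConeBeamGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Physical (u, v) coordinates (mm) of detector pixel centres."""
    rows, cols = geom.detector_pixels
    u = (np.arange(cols) - 0.5 * (cols - 1)) * geom.detector_pixel_size
    v = (np.arange(rows) - 0.5 * (rows - 1)) * geom.detector_pixel_size
    return u, v


def reweight(proj: ProjectionStack, geom: ConeBeamGeometry) -> ProjectionStack:
    """Cosine weighting ``D / sqrt(D^2 + u^2 + v^2)`` per detector sample.

    ``D`` is the source-to-detector distance and (u, v) are physical
    coordinates from the detector centre, so the weight is the cosine of
    the angle between each ray and the central ray; it is 1 at the centre
    and decreases radially.
    """
    _check(proj, geom)
    u, v = detector_coordinates(geom)
    d = geom.source_to_detector
    w = d / np.sqrt(d * d + u[np.newaxis, :] ** 2 + v[:, np.newaxis] ** 2)
    return ProjectionStack(proj.values * w[np.newaxis, :, :], geom)


def apply_filter_1d(proj: ProjectionStack, h: Filter1D) -> ProjectionStack:
    """Convolve every detector row (fixed angle and v) with ``h``.

    Zero-padded FFT convolution; with a row of length N and 2N taps the
    padded length is 3N-1, and the output window is centred on the filter's
    middle tap so a unit impulse at tap N reproduces the input.
    """
    n = proj.values.shape[2]
    if h.taps.size != 2 * n:
        raise ValueError(f"filter length {h.taps.size} != 2N = {2 * n}")
    full = fftconvolve(proj.values, h.taps[np.newaxis, np.newaxis, :], axes=2)
    out = full[:, :, n : n + n]
    return ProjectionStack(np.ascontiguousarray(out), proj.geometry)


def _ramlak_taps(n: int, du_cm: float) -> np.ndarray:
    """Band-limited ramp kernel samples at pitch ``du_cm`` (length 2n)."""
    offsets = np.arange(-n, n)
    taps = np.zeros(2 * n, dtype=np.float64)
    taps[n] = 1.0 / (4.0 * du_cm * du_cm)
    odd = offsets % 2 != 0
    taps[odd] = -1.0 / (np.pi * np.pi * offsets[odd].astype(float) ** 2 * du_cm * du_cm)
    return taps


def standard_filter(name: str, geom: ConeBeamGeometry) -> Filter1D:
    """Build a standard FBP filter ("ram-lak" or "hann") for this geometry.

    The taps are sampled at the virtual detector pitch (detector pitch
    divided by magnification, converted to cm).  The Hann variant is the
    ramp apodized in the frequency domain by a Hann window that reaches
    zero at the Nyquist frequency.
    """
    n = geom.n_voxels
    du_cm = geom.virtual_pixel_size * MM_TO_CM
    key = name.lower().replace("_", "-")
    if key == "ram-lak":
        return Filter1D(_ramlak_taps(n, du_cm), name="ram-lak")
    if key == "hann":
        ramp = _ramlak_taps(n, du_cm)
        spectrum = np.fft.fft(np.fft.ifftshift(ramp))
        k = np.fft.fftfreq(2 * n) * 2 * n  # integer frequency index, |k| <= n
        window = 0.5 * (1.0 + np.cos(np.pi * k / n))
        taps = np.fft.fftshift(np.fft.ifft(spectrum * window).real)
        return Filter1D(taps, name="hann")
    raise ValueError(f"unknown filter name {name!r} (expected 'ram-lak' or 'hann')")


def fdk(proj: ProjectionStack, h: Filter1D, geom: ConeBeamGeometry) -> VoxelVolume:
    """Full FDK reconstruction with filter ``h``; bilinear in ``(proj, h)``."""
    _check(proj, geom)
    h.check_geometry(geom)
    return fdk_weighted_backproject(apply_filter_1d(reweight(proj, geom), h), geom)


def _check(proj: ProjectionStack, geom: ConeBeamGeometry) -> None:
    if proj.values.shape != geom.projection_shape():
        raise ValueError(
            f"projection shape {proj.values.shape} does not match geometry "
            f"{geom.projection_shape()}"
        )
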