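"""Phase phantoms: test wavefronts expressed as optical path difference maps.

A :class:`PhaseMap` is a square grid of either optical path difference (nm) or
phase (radians) with its physical extent attached.  OPD is the natural unit
for transparent specimens because it is wavelength independent; conversion to
phase at a given wavelength is ``phi = 2*pi*OPD/lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PhaseMap",
    "make_sinusoid_phantom",
    "make_disc_phantom",
    "make_cell_phantom",
]

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseMap:
    """A 2D wavefront sample with physical metadata.

    values : square 2D array, OPD in nm or phase in radians per ``unit``.
    extent_mm : physical side length of the field.
    unit : ``"opd_nm"`` or ``"phase_rad"``.
    """

    values: np.ndarray
    extent_mm: float
    unit: str = "opd_nm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("PhaseMap values must be a square 2D grid")
        if self.values.shape[0] < 8:
            raise ValueError("PhaseMap grid must be at least 8x8")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PhaseMap values must be finite")
        if self.unit not in ("opd_nm", "phase_rad"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def pixel_size_mm(self) -> float:
        return self.extent_mm / self.n_pixels

    def to_phase_rad(self, wavelength_nm: float) -> "PhaseMap":
        if self.unit == "phase_rad":
            return self
        return replace(self, values=TWO_PI * self.values / wavelength_nm, unit="phase_rad")

    def to_opd_nm(self, wavelength_nm: float) -> "PhaseMap":
        if self.unit == "opd_nm":
            return self
        return replace(self, values=self.values * wavelength_nm / TWO_PI, unit="opd_nm")

    def peak_to_valley(self) -> float:
        return float(self.values.max() - self.values.min())


def make_sinusoid_phantom(
    period_px: float,
    amplitude: float,
    n_pixels: int,
    *,
    extent_mm: float = 7.066,
    unit: str = "phase_rad",
) -> PhaseMap:
    """One-dimensional sinusoid ``W(x, y) = A * sin(2*pi*x / period)``.

    The classic probe for shearing sensitivity: shearing it by ``s`` scales
    its amplitude by ``2*sin(pi*s/period)``.
    """
    if period_px < 2:
        raise ValueError("period_px below 2 pixels would alias")
    x = np.arange(n_pixels, dtype=np.float64)
    row = amplitude * np.sin(TWO_PI * x / period_px)
    return PhaseMap(np.broadcast_to(row, (n_pixels, n_pixels)).copy(), extent_mm, unit)


def make_disc_phantom(
    diameter_um: float,
    depth_nm: float,
    refractive_index: float,
    n_pixels: int,
    extent_um: float,
    *,
    edge_px: float = 1.0,
) -> PhaseMap:
    """Etched circular target: a disc of reduced optical thickness.

    Etching removes substrate of index ``n``, so the OPD inside the centred
    disc is ``-depth * (n - 1)`` relative to the background (negative: less
    glass).  ``edge_px`` linearly ramps the edge over about one pixel to keep
    the pixelized boundary mild.
    """
    if diameter_um >= extent_um:
        raise ValueError("disc diameter must be smaller than the field extent")
    if refractive_index <= 1.0:
        raise ValueError("refractive index must exceed 1")
    c = (n_pixels - 1) / 2.0
    y, x = np.mgrid[0:n_pixels, 0:n_pixels]
    px_um = extent_um / n_pixels
    r = np.hypot(x - c, y - c) * px_um
    radius = diameter_um / 2.0
    opd = depth_nm * (refractive_index - 1.0)
    if edge_px > 0:
        half_edge = 0.5 * edge_px * px_um
        frac = np.clip((radius + half_edge - r) / (2.0 * half_edge), 0.0, 1.0)
    else:
        frac = (r <= radius).astype(np.float64)
    return PhaseMap(-opd * frac, extent_um * 1e-3, "opd_nm")


def make_cell_phantom(
    n_blobs: int,
    opd_range_nm: tuple[float, float],
    seed: int,
    *,
    n_pixels: int = 501,
    extent_mm: float = 7.066,
    blob_width_range: tuple[float, float] = (0.04, 0.10),
) -> PhaseMap:
    """Smooth band-limited cell-like field: Gaussian domes and torus shells.

    A reproducible stand-in for fields of red blood cells: each blob is either
    a dome or a biconcave-looking ring, with its width drawn from
    ``blob_width_range`` (as a fraction of the field side).  The summed map is
    rescaled so its maximum falls in the upper half of ``opd_range_nm``.
    """
    if n_blobs < 0:
        raise ValueError("n_blobs must be non-negative")
    lo, hi = opd_range_nm
    if hi < lo:
        raise ValueError("opd_range_nm must be an increasing interval")
    values = np.zeros((n_pixels, n_pixels))
    if n_blobs == 0 or hi == 0:
        return PhaseMap(values, extent_mm, "opd_nm")
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:n_pixels, 0:n_pixels] / n_pixels
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0.15, 0.85, size=2)
        w = rng.uniform(*blob_width_range)
        r2 = ((x - cx) ** 2 + (y - cy) ** 2) / w**2
        dome = np.exp(-0.5 * r2)
        if rng.random() < 0.4:  # torus: dome with a depressed centre
            dome = dome * (0.35 + 0.65 * r2) * np.exp(-0.25 * r2)
        values += rng.uniform(0.5, 1.0) * dome
    peak = rng.uniform(lo + 0.5 * (hi - lo), hi)
    values *= peak / values.max()
    return PhaseMap(values, extent_mm, "opd_nm")
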