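"""Spectral sensitivity of single- and dual-shear quadriwave interferometry.

Relative to an interferometer with an external reference, a shearing
interferometer measures the spectrum of the wavefront through the transfer
magnitudes ``2|sin(pi*s*u)|``; its per-frequency amplitude sensitivity is

    sigma(u, v)  = 2 * sqrt(sin^2(pi*s*u) + sin^2(pi*s*v))

and for two shears, accounting for the sqrt(2) shot-noise cost of splitting
the beam,

    sigma'(u, v) = sqrt(2) * sqrt(sin^2(pi*s*u) + sin^2(pi*s*v)
                                 + sin^2(pi*s'*u) + sin^2(pi*s'*v)).

The measurement uncertainty scales as ``1/sigma``.  A good shear pair makes
``sigma'`` flat over the sampled band, i.e. minimizes its standard deviation
over the frequency grid; the minimizing off-diagonal pairs sit in two valleys
flanking the equal-shear diagonal of the (beta, beta') SD map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantoms import PhaseMap

__all__ = [
    "SensitivityMap",
    "sigma_single",
    "sigma_dual",
    "uncertainty_ratio",
    "count_zero_bins",
    "sd_map",
    "optimize_shear_pair",
    "estimate_offset",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class SensitivityMap:
    """Sensitivity on a centred frequency grid, with the generating ratios."""

    values: np.ndarray
    betas: tuple[float, ...]
    extent_mm: float

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    def freq_axis_cyc_mm(self) -> np.ndarray:
        n = self.n_pixels
        return (np.arange(n) - n // 2) / self.extent_mm


def _centered_freqs(n_pixels: int, extent_mm: float) -> tuple[np.ndarray, np.ndarray]:
    k = np.arange(n_pixels) - n_pixels // 2
    f = k / extent_mm
    return f[None, :], f[:, None]  # u along axis 1, v along axis 0


def _check_beta(beta: float) -> None:
    if not 0.0 < beta < 0.5:
        raise ValueError("shear ratio must lie in (0, 0.5)")


def sigma_single(beta: float, extent_mm: float = 7.066, n_pixels: int = 501) -> SensitivityMap:
    """Single-shear sensitivity ``sigma`` on the centred grid; range [0, 2*sqrt(2)]."""
    _check_beta(beta)
    s = beta * extent_mm
    u, v = _centered_freqs(n_pixels, extent_mm)
    values = 2.0 * np.sqrt(np.sin(np.pi * s * u) ** 2 + np.sin(np.pi * s * v) ** 2)
    return SensitivityMap(values, (beta,), extent_mm)


def sigma_dual(
    beta_a: float,
    beta_b: float,
    extent_mm: float = 7.066,
    n_pixels: int = 501,
) -> SensitivityMap:
    """Dual-shear sensitivity ``sigma'`` on the centred grid; range [0, 4]."""
    _check_beta(beta_a)
    _check_beta(beta_b)
    sa, sb = beta_a * extent_mm, beta_b * extent_mm
    u, v = _centered_freqs(n_pixels, extent_mm)
    values = _SQRT2 * np.sqrt(
        np.sin(np.pi * sa * u) ** 2
        + np.sin(np.pi * sa * v) ** 2
        + np.sin(np.pi * sb * u) ** 2
        + np.sin(np.pi * sb * v) ** 2
    )
    return SensitivityMap(values, (beta_a, beta_b), extent_mm)


def uncertainty_ratio(u: float, v: float, s: float) -> float:
    """Uncertainty relative to an externally referenced interferometer: 1/sigma.

    Infinite (flagged as ``inf``) on the blind lattice ``u = m/s, v = n/s``.
    """
    sigma = 2.0 * np.sqrt(np.sin(np.pi * s * u) ** 2 + np.sin(np.pi * s * v) ** 2)
    if sigma < 1e-9:  # on (or numerically on) the blind lattice
        return float("inf")
    return 1.0 / sigma


def count_zero_bins(sens: SensitivityMap, *, threshold: float = 1e-9) -> int:
    """Number of grid bins whose sensitivity falls below ``threshold``."""
    return int(np.count_nonzero(sens.values < threshold))


def _transfer_1d(beta: float, extent_mm: float, n_pixels: int) -> np.ndarray:
    k = np.arange(n_pixels) - n_pixels // 2
    return np.sin(np.pi * beta * k) ** 2  # s*u = beta*extent * k/extent = beta*k


def sd_map(
    beta_range: tuple[float, float] = (0.01, 0.03),
    n_steps: int = 101,
    extent_mm: float = 7.066,
    n_pixels: int = 501,
    *,
    include_dc: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard deviation of ``sigma'`` over the frequency grid per shear pair.

    Returns ``(betas, sd)`` where ``sd[i, j]`` is the population SD of
    ``sigma'(beta_i, beta_j)`` over all ``n_pixels**2`` bins.  ``sigma'`` is
    separable in u and v, so each pair costs one outer sum over two 1D
    transfer vectors rather than a full 2D rebuild.
    """
    lo, hi = min(beta_range), max(beta_range)
    _check_beta(lo)
    _check_beta(hi)
    betas = np.linspace(lo, hi, n_steps)
    g = np.stack([_transfer_1d(b, extent_mm, n_pixels) for b in betas])
    sd = np.empty((n_steps, n_steps))
    for i in range(n_steps):
        for j in range(i, n_steps):
            axis = g[i] + g[j]
            sig = _SQRT2 * np.sqrt(axis[:, None] + axis[None, :])
            if not include_dc:
                sig = sig[sig > 0]
            sd[i, j] = sd[j, i] = sig.std()
    return betas, sd


def optimize_shear_pair(
    beta_range: tuple[float, float] = (0.01, 0.03),
    n_steps: int = 101,
    extent_mm: float = 7.066,
    n_pixels: int = 501,
    *,
    min_separation: float = 1e-3,
    include_dc: bool = True,
) -> tuple[float, float]:
    """Off-diagonal shear pair minimizing the sensitivity SD.

    Pairs closer than ``min_separation`` in ratio are excluded (they behave
    like a single shear).  Ties break toward the smaller first ratio, then the
    smaller second; the result is returned as ``(larger, smaller)``.
    """
    betas, sd = sd_map(beta_range, n_steps, extent_mm, n_pixels, include_dc=include_dc)
    bi, bj = np.meshgrid(betas, betas, indexing="ij")
    feasible = np.abs(bi - bj) >= min_separation
    if not feasible.any():
        raise ValueError("no shear pair satisfies the separation constraint")
    masked = np.where(feasible, sd, np.inf)
    # lexicographic tie-break toward smaller ratios
    best = np.argwhere(masked == masked.min())
    i, j = min((int(a), int(b)) for a, b in best)
    pair = (float(betas[i]), float(betas[j]))
    return (max(pair), min(pair))


def estimate_offset(
    phase_a: PhaseMap,
    phase_b: PhaseMap,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """Inter-arm translation from centroids of binarized phase images.

    Both maps are binarized at ``threshold`` times their own absolute maximum;
    the return value is ``centroid(B) - centroid(A)`` in pixels ``(dy, dx)``.
    Raises if either foreground is empty (no compact object present).
    """
    if phase_a.values.shape != phase_b.values.shape:
        raise ValueError("phase maps must share shape")

    def centroid(pm: PhaseMap) -> np.ndarray:
        mag = np.abs(pm.values)
        fg = mag >= threshold * mag.max()
        if mag.max() == 0 or fg.sum() < 4:
            raise ValueError("no foreground object after binarization")
        labels, n_lab = ndimage.label(fg)
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n_lab + 1))
        if sizes.max() < 0.5 * fg.sum():
            raise ValueError("foreground is scattered; no compact object found")
        return np.asarray(ndimage.center_of_mass(fg))

    ca = centroid(phase_a)
    cb = centroid(phase_b)
    return (float(cb[0] - ca[0]), float(cb[1] - ca[1]))
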