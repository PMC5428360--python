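"""Wavefront recovery from unwrapped shearing wavefronts.

Shearing a wavefront ``W`` by ``s`` along x multiplies its spectrum by
``-2i*sin(pi*s*u)`` (and by ``-2i*sin(pi*s*v)`` along y).  Single-shear
recovery inverts the two observations per frequency bin in the least-squares
sense; bins where both transfer factors vanish (the lattice ``u = m/s,
v = n/s``) are unobservable and must be regularized away — the spectral
leaking problem.  A second shear ``s'`` adds two more observations whose
transfer zeros do not coincide with the first pair's (for a well-chosen
ratio), so the four-observation least-squares fusion has no blind bins except
DC:

    F = i * sum_k sin_k * F_k / (2 * sum_k sin_k^2)

with ``sin_k`` running over {sin(pi*s*u), sin(pi*s*v), sin(pi*s'*u),
sin(pi*s'*v)}.  Piston (DC) is unobservable and fixed to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .demodulate import ShearingWavefrontPair
from .phantoms import PhaseMap

__all__ = [
    "ReconstructionResult",
    "shear_transfer",
    "reconstruct_single",
    "reconstruct_dual",
    "opd_to_depth",
    "subtract_background",
]

TWO_PI = 2.0 * np.pi


@dataclass
class ReconstructionResult:
    """Recovered wavefront plus spectral bookkeeping."""

    wavefront: PhaseMap
    suppressed_bins: int  # non-DC bins zeroed by the denominator guard


def shear_transfer(u: np.ndarray, v: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Transfer factors ``-2i*sin(pi*s*u)`` and ``-2i*sin(pi*s*v)``."""
    return (
        -2j * np.sin(np.pi * s * np.asarray(u)),
        -2j * np.sin(np.pi * s * np.asarray(v)),
    )


def _freq_grids(n: int, extent_mm: float) -> tuple[np.ndarray, np.ndarray]:
    f = np.fft.fftfreq(n, d=extent_mm / n)
    return f[None, :], f[:, None]  # u along x (axis 1), v along y (axis 0)


def _to_wavefront_spectra(
    pair: ShearingWavefrontPair, wavelength_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    if pair.wrapped:
        raise ValueError("shearing phases must be unwrapped before reconstruction")
    # phase (rad) -> shearing wavefront in OPD nm
    scale = wavelength_nm / TWO_PI
    return np.fft.fft2(pair.phi_x * scale), np.fft.fft2(pair.phi_y * scale)


def _fuse(
    sines: list[np.ndarray],
    spectra: list[np.ndarray],
    weights: list[float],
    extent_mm: float,
    eps_rel: float | None,
) -> tuple[PhaseMap, int]:
    num = sum(w * s * F for w, s, F in zip(weights, sines, spectra))
    denom = 2.0 * sum(w * s**2 for w, s in zip(weights, sines))
    suppressed = 0
    if eps_rel is not None:
        bad = denom < eps_rel * denom.max()
        bad[0, 0] = False
        suppressed = int(bad.sum())
        denom = np.where(bad, np.inf, denom)
    denom[0, 0] = np.inf  # piston unobservable
    F = 1j * num / denom
    w = np.fft.ifft2(F)
    return PhaseMap(w.real, extent_mm, "opd_nm"), suppressed


def reconstruct_single(
    pair: ShearingWavefrontPair,
    wavelength_nm: float,
    *,
    eps_rel: float = 1e-6,
) -> ReconstructionResult:
    """Invert one shear: ``F = i*(sin_u*Fx + sin_v*Fy) / (2*(sin_u^2+sin_v^2))``.

    Bins whose denominator falls below ``eps_rel`` times its maximum are
    zeroed and counted (``suppressed_bins``), because noise there would be
    amplified without bound — the spectral-leak lattice of Eq-type zeros.
    """
    Fx, Fy = _to_wavefront_spectra(pair, wavelength_nm)
    u, v = _freq_grids(pair.n_pixels, pair.extent_mm)
    su = np.sin(np.pi * pair.shear_mm * u) * np.ones_like(v)
    sv = np.sin(np.pi * pair.shear_mm * v) * np.ones_like(u)
    wavefront, suppressed = _fuse([su, sv], [Fx, Fy], [1.0, 1.0], pair.extent_mm, eps_rel)
    return ReconstructionResult(wavefront, suppressed)


def reconstruct_dual(
    pair_a: ShearingWavefrontPair,
    pair_b: ShearingWavefrontPair,
    wavelength_nm: float,
    *,
    weights: tuple[float, float] = (1.0, 1.0),
    eps_rel: float | None = None,
) -> ReconstructionResult:
    """Least-squares fusion of the four shearing-wavefront spectra.

    Equal weights assume equal noise in both arms; pass ``weights`` for
    unequal exposures.  With distinct shears in an irrational-like ratio the
    denominator vanishes only at DC, so no regularization is needed
    (``eps_rel=None``); it remains available for degenerate pairs.
    """
    if pair_a.n_pixels != pair_b.n_pixels or pair_a.extent_mm != pair_b.extent_mm:
        raise ValueError("shearing pairs must share grid and field size")
    if np.isclose(pair_a.shear_mm, pair_b.shear_mm):
        warnings.warn(
            "equal shears: dual reconstruction degenerates to single-shear "
            "behaviour (blind lattice bins reappear)",
            stacklevel=2,
        )
        if eps_rel is None:
            eps_rel = 1e-6
    Fax, Fay = _to_wavefront_spectra(pair_a, wavelength_nm)
    Fbx, Fby = _to_wavefront_spectra(pair_b, wavelength_nm)
    u, v = _freq_grids(pair_a.n_pixels, pair_a.extent_mm)
    ones = np.ones((pair_a.n_pixels, pair_a.n_pixels))
    sines = [
        np.sin(np.pi * pair_a.shear_mm * u) * ones,
        np.sin(np.pi * pair_a.shear_mm * v) * ones,
        np.sin(np.pi * pair_b.shear_mm * u) * ones,
        np.sin(np.pi * pair_b.shear_mm * v) * ones,
    ]
    wa, wb = weights
    wavefront, suppressed = _fuse(
        sines, [Fax, Fay, Fbx, Fby], [wa, wa, wb, wb], pair_a.extent_mm, eps_rel
    )
    return ReconstructionResult(wavefront, suppressed)


def opd_to_depth(opd: PhaseMap, refractive_index: float) -> PhaseMap:
    """Convert an OPD map to physical etch depth: ``z = OPD / (n - 1)``."""
    if refractive_index <= 1.0:
        raise ValueError("refractive index must exceed 1")
    if opd.unit != "opd_nm":
        raise ValueError("depth conversion requires an OPD map")
    return PhaseMap(opd.values / (refractive_index - 1.0), opd.extent_mm, "opd_nm")


def subtract_background(measured: PhaseMap, background: PhaseMap) -> PhaseMap:
    """Systematic-error subtraction: difference two maps, re-zero the piston."""
    if measured.values.shape != background.values.shape:
        raise ValueError("measured and background maps must share shape")
    if measured.unit != background.unit:
        raise ValueError("measured and background maps must share units")
    diff = measured.values - background.values
    return PhaseMap(diff - diff.mean(), measured.extent_mm, measured.unit)
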