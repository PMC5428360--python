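"""Differential leveling phase unwrapping (DLPU).

A path-independent unwrapper built entirely from element-wise operations and
FFTs, so every step is vectorizable:

1. *differentiate* — periodic forward differences of the wrapped phase;
2. *level* — re-wrap each differential into (-pi, pi], which restores the true
   differential wherever the true gradient magnitude is below pi/pixel;
3. *reference* — least-squares integration of the leveled differentials in the
   Fourier domain (one-pixel-shear phase retrieval), giving a continuous
   reference phase;
4. *correct* — per pixel, the rounded difference between reference and wrapped
   phase (in units of 2*pi) is the number of wraps to add back.

The output is congruent to the input (differs by an integer multiple of 2*pi
at every pixel) by construction.  Exact recovery, up to a global 2*pi
constant, holds whenever the true gradient magnitude stays below pi/pixel and
the field is compatible with the periodic boundary (compact features on a
flat background, or a plain tilt — see the slope handling below).  Inputs with
genuine residues (e.g. deep shot noise) are handled best-effort: the result is
still congruent, but no correctness is guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WrappedPhase",
    "wrap",
    "differentiate",
    "level",
    "reference_phase",
    "unwrap",
    "remove_plane",
    "fit_plane",
]

TWO_PI = 2.0 * np.pi


@dataclass
class WrappedPhase:
    """Phase grid wrapped into (-pi, pi], with an optional validity mask."""

    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("wrapped phase must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("wrapped phase must be finite")
        if self.values.min() <= -np.pi - 1e-12 or self.values.max() > np.pi + 1e-12:
            raise ValueError("wrapped phase must lie in (-pi, pi]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")


def wrap(values: np.ndarray) -> np.ndarray:
    """Wrap into (-pi, pi] (the principal value of the phasor argument)."""
    return np.angle(np.exp(1j * np.asarray(values, dtype=np.float64)))


def differentiate(wrapped: WrappedPhase | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Periodic forward differences along x (axis 1) and y (axis 0).

    The wrap-around entries in the last column/row keep the grids the same
    shape and make the Fourier integration self-consistent.
    """
    v = wrapped.values if isinstance(wrapped, WrappedPhase) else np.asarray(wrapped)
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("grid must be at least 2x2")
    dx = np.roll(v, -1, axis=1) - v
    dy = np.roll(v, -1, axis=0) - v
    return dx, dy


def level(diff_map: np.ndarray) -> np.ndarray:
    """Re-wrap raw differentials of a wrapped phase into (-pi, pi].

    Pixels straddling a 2*pi jump carry differentials offset by +/-2*pi; adding
    or subtracting one period restores the true differential wherever the true
    gradient is below pi/pixel.
    """
    return wrap(diff_map)


def _mean_slopes(dx: np.ndarray, dy: np.ndarray) -> tuple[float, float]:
    # wrap-around column/row excluded: for a non-periodic field they hold the
    # (leveled) jump across the boundary, not a real gradient sample
    return float(dx[:, :-1].mean()), float(dy[:-1, :].mean())


def _plane(shape: tuple[int, int], sx: float, sy: float) -> np.ndarray:
    ny, nx = shape
    x = np.arange(nx) - (nx - 1) / 2.0
    y = np.arange(ny) - (ny - 1) / 2.0
    return sy * y[:, None] + sx * x[None, :]


def reference_phase(leveled_dx: np.ndarray, leveled_dy: np.ndarray) -> np.ndarray:
    """Least-squares Fourier integration of two difference fields.

    Solves ``min || D_x p - dx ||^2 + || D_y p - dy ||^2`` over periodic
    fields ``p`` via the DFT: with ``H = exp(i*2*pi*k/N) - 1`` the per-bin
    solution is ``P = (conj(Hx)*Dx + conj(Hy)*Dy) / (|Hx|^2 + |Hy|^2)`` and
    the unobservable DC term is set to zero.

    A constant differential (a tilt) lives purely in the zeroed DC bin, so the
    mean slope is estimated separately from the differentials (excluding the
    wrap-around entries), removed before integration, and its plane added back
    afterwards.  The returned phase has zero mean plus that plane.
    """
    dx = np.asarray(leveled_dx, dtype=np.float64)
    dy = np.asarray(leveled_dy, dtype=np.float64)
    if dx.shape != dy.shape:
        raise ValueError("difference fields must share shape")
    ny, nx = dx.shape
    sx, sy = _mean_slopes(dx, dy)
    Dx = np.fft.fft2(dx - sx)
    Dy = np.fft.fft2(dy - sy)
    hx = np.exp(2j * np.pi * np.fft.fftfreq(nx)) - 1.0
    hy = np.exp(2j * np.pi * np.fft.fftfreq(ny)) - 1.0
    Hx = np.broadcast_to(hx[None, :], (ny, nx))
    Hy = np.broadcast_to(hy[:, None], (ny, nx))
    denom = np.abs(Hx) ** 2 + np.abs(Hy) ** 2
    denom[0, 0] = 1.0  # DC: numerator is zeroed below
    P = (np.conj(Hx) * Dx + np.conj(Hy) * Dy) / denom
    P[0, 0] = 0.0
    return np.fft.ifft2(P).real + _plane(dx.shape, sx, sy)


def fit_plane(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Ordinary least-squares plane (piston + tilt) of a continuous map."""
    v = np.asarray(values, dtype=np.float64)
    ny, nx = v.shape
    y, x = np.mgrid[0:ny, 0:nx].astype(np.float64)
    if mask is None:
        mask = np.ones_like(v, dtype=bool)
    A = np.column_stack([np.ones(mask.sum()), x[mask], y[mask]])
    coef, *_ = np.linalg.lstsq(A, v[mask], rcond=None)
    return coef[0] + coef[1] * x + coef[2] * y


def remove_plane(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    return values - fit_plane(values, mask)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def unwrap(wrapped: WrappedPhase | np.ndarray) -> np.ndarray:
    """Unwrap a 2D phase map; output minus input is 2*pi*integer everywhere.

    The reference is integrated from the leveled differentials, aligned to the
    wrapped input by a circular-mean piston, and the per-pixel wrap count is
    the half-away-from-zero rounding of their difference over 2*pi.  Tilt is
    carried by the reference's restored mean slope, so tilted inputs (e.g. a
    residual demodulation carrier) unwrap correctly as well.
    """
    if not isinstance(wrapped, WrappedPhase):
        wrapped = WrappedPhase(np.asarray(wrapped))
    w = wrapped.values
    dx, dy = differentiate(w)
    ref = reference_phase(level(dx), level(dy))
    # piston alignment on the circle; the mask (if any) restricts it to valid pixels
    sel = wrapped.mask if wrapped.mask is not None else slice(None)
    piston = np.angle(np.mean(np.exp(1j * (w[sel] - ref[sel]))))
    k = _round_half_away((ref + piston - w) / TWO_PI)
    return w + TWO_PI * k
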