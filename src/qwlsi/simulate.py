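"""Scalar forward model of a quadriwave lateral shearing interferogram.

The grating splits the probe into four replicas with carriers ``+/-f_c`` along
the two sensor axes (``f_c = sqrt(2)/d``).  After propagating the arm distance
``l`` each order is laterally displaced by ``l * lambda * f``, so the order
pair of one axis is separated by the shear ``s = 2*sqrt(2)*l*lambda/d``.  The
recorded intensity is

    I(r) = | sum_k exp(i*2*pi*f_k.r) * exp(i*phi(r - delta_k)) |^2

followed by optional sub-pixel translation (inter-camera offset), Poisson shot
noise scaled to a configurable mean maximum photon count, and quantization.

The model is monochromatic at the dominant wavelength; the first-order
achromaticity of the grating (carrier frequency set by the pitch alone, shear
compensated by the wavelength in the shearing phase) is a property of this
model and is exercised by the tests rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import AcquisitionConfig
from .phantoms import PhaseMap

__all__ = [
    "Interferogram",
    "render_intensity",
    "apply_camera",
    "render_interferogram",
    "fourier_shift",
]


@dataclass
class Interferogram:
    """A recorded (or rendered) interferogram plus its acquisition geometry."""

    intensity: np.ndarray
    config: AcquisitionConfig
    distance_mm: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2D")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def shear_mm(self) -> float:
        return self.config.shear_mm(self.distance_mm)

    @property
    def carrier_freq_cyc_mm(self) -> float:
        return self.config.carrier_freq_cyc_mm


def fourier_shift(field: np.ndarray, shift_px: tuple[float, float]) -> np.ndarray:
    """Sub-pixel translation by ``(dy, dx)`` pixels via the DFT shift theorem."""
    ny, nx = field.shape
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    phase = np.exp(-2j * np.pi * (ky * shift_px[0] + kx * shift_px[1]))
    out = np.fft.ifft2(np.fft.fft2(field) * phase)
    return out.real if np.isrealobj(field) else out


def _phase_on_sensor(phase: PhaseMap, config: AcquisitionConfig) -> np.ndarray:
    phi = phase.to_phase_rad(config.wavelength_nm).values
    n = config.sensor_pixels
    if phi.shape[0] != n:
        raise ValueError(
            f"phantom grid {phi.shape[0]} must match sensor_pixels {n}; "
            "generate the phantom at sensor resolution"
        )
    return phi


def render_intensity(
    phase: PhaseMap,
    config: AcquisitionConfig,
    distance_mm: float,
    *,
    offset_px: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Noiseless interferogram intensity (arbitrary units, max ~16).

    ``offset_px`` translates the whole frame (``dy``, ``dx``) to emulate an
    inter-camera registration offset or vibration; negative intensities from
    the band-limited interpolation are clipped at zero.
    """
    phi = _phase_on_sensor(phase, config)
    n = config.sensor_pixels
    s_px = config.shear_mm(distance_mm) / config.pixel_pitch_mm
    _warn_if_broadband(phi, config)

    # carrier of a single order, in cycles per pixel
    f_c = 0.5 * config.carrier_bins / n
    coord = np.arange(n, dtype=np.float64)
    cx = np.exp(2j * np.pi * f_c * coord)[None, :]
    cy = np.exp(2j * np.pi * f_c * coord)[:, None]

    spec = np.fft.fft2(np.exp(1j * phi))
    kx = np.fft.fftfreq(n)[None, :]
    ky = np.fft.fftfreq(n)[:, None]

    def shifted(dy: float, dx: float) -> np.ndarray:
        # exp(i*phi(r - delta)): translate the complex field by +delta
        return np.fft.ifft2(spec * np.exp(-2j * np.pi * (ky * dy + kx * dx)))

    half = s_px / 2.0
    field = (
        cx * shifted(0.0, half)
        + np.conj(cx) * shifted(0.0, -half)
        + cy * shifted(half, 0.0)
        + np.conj(cy) * shifted(-half, 0.0)
    )
    intensity = np.abs(field) ** 2
    if offset_px != (0.0, 0.0):
        intensity = np.clip(fourier_shift(intensity, offset_px), 0.0, None)
    return intensity


def _warn_if_broadband(phi: np.ndarray, config: AcquisitionConfig) -> None:
    # cheap bandwidth check: gradient beyond ~half the carrier would fold the
    # sidebands into each other
    gmax = max(
        np.abs(np.diff(phi, axis=0)).max(initial=0.0),
        np.abs(np.diff(phi, axis=1)).max(initial=0.0),
    )
    carrier_cyc_px = config.carrier_bins / config.sensor_pixels
    if gmax > np.pi * carrier_cyc_px:
        warnings.warn(
            "phantom phase gradient approaches the carrier separation; "
            "sidebands may overlap",
            stacklevel=3,
        )


def apply_camera(
    intensity: np.ndarray,
    config: AcquisitionConfig,
    *,
    noise: str = "shot",
    mean_max_count: float = 1400.0,
    target_gray: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Scale to photon counts, draw shot noise, quantize to gray levels.

    The noiseless maximum maps to ``mean_max_count`` photons, requantized so
    that it sits at ``target_gray`` (default: the saturation level).  Values
    are clipped to ``config.saturation_gray`` — a ``target_gray`` below
    saturation emulates a photon-starved acquisition whose noise peaks are
    still recorded faithfully.  ``noise='none'`` skips the Poisson draw but
    still quantizes.
    """
    if noise not in ("none", "shot"):
        raise ValueError("noise must be 'none' or 'shot'")
    peak = intensity.max()
    if peak <= 0:
        raise ValueError("intensity frame is empty")
    counts = intensity * (mean_max_count / peak)
    if noise == "shot":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(counts).astype(np.float64)
    if target_gray is None:
        target_gray = config.saturation_gray
    gray = np.rint(counts * (target_gray / mean_max_count))
    return np.clip(gray, 0, config.saturation_gray)


def render_interferogram(
    phase: PhaseMap,
    config: AcquisitionConfig,
    distance_mm: float,
    *,
    offset_px: tuple[float, float] = (0.0, 0.0),
    noise: str = "shot",
    mean_max_count: float = 1400.0,
    target_gray: int | None = None,
    seed: int | None = None,
) -> Interferogram:
    """Render one camera frame: forward model + camera model."""
    intensity = render_intensity(phase, config, distance_mm, offset_px=offset_px)
    gray = apply_camera(
        intensity,
        config,
        noise=noise,
        mean_max_count=mean_max_count,
        target_gray=target_gray,
        seed=seed,
    )
    return Interferogram(gray, config, distance_mm)
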