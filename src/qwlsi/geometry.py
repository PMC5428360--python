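"""Acquisition geometry of a quadriwave lateral shearing interferometer.

A quadriwave grating of pitch ``d`` splits the probe into four first orders
(+/-1 along two orthogonal axes).  After propagating a distance ``l`` from the
grating to the sensor, the two orders of one axis are laterally separated by

    s = 2 * sqrt(2) * l * lambda / d

which is the lateral shear.  The interference of the order pair produces a
fringe carrier at spatial frequency ``2*sqrt(2)/d`` (cycles per unit length),
independent of the wavelength — the achromatic property of grating shearing
interferometers.  The shear ratio ``beta = s / beam_size`` is the dimensionless
knob the sensitivity analysis works with.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

__all__ = ["AcquisitionConfig", "design_config"]

_SQRT2 = math.sqrt(2.0)


@dataclass
class AcquisitionConfig:
    """Physical and sampling parameters of one shearing interferometer arm.

    Parameters
    ----------
    wavelength_nm:
        Dominant illumination wavelength (nm).
    grating_pitch_um:
        Pitch ``d`` of the quadriwave grating (micrometres).
    beam_size_mm:
        Physical side length of the (square) field imaged on the sensor (mm).
    sensor_pixels:
        Sensor-side grid size used to render/record interferograms.
    n_pixels:
        Retrieval grid size; the sideband crop width, hence the resolution of
        the recovered phase maps.
    bit_depth:
        Quantization depth of the camera.
    max_gray:
        Saturation gray level of the camera.  ``None`` means full scale
        (``2**bit_depth - 1``).
    refractive_index:
        Substrate refractive index used for OPD -> etch-depth conversion.
    """

    wavelength_nm: float = 623.0
    grating_pitch_um: float = 30.0
    beam_size_mm: float = 7.066
    sensor_pixels: int = 2048
    n_pixels: int = 501
    bit_depth: int = 8
    max_gray: int | None = None
    refractive_index: float = 1.457

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0 or self.grating_pitch_um <= 0:
            raise ValueError("wavelength and grating pitch must be positive")
        if self.beam_size_mm <= 0:
            raise ValueError("beam_size_mm must be positive")
        if self.n_pixels < 8 or self.sensor_pixels < self.n_pixels:
            raise ValueError("need sensor_pixels >= n_pixels >= 8")

    # ---- derived geometry -------------------------------------------------

    @property
    def saturation_gray(self) -> int:
        return (2**self.bit_depth - 1) if self.max_gray is None else self.max_gray

    @property
    def pixel_pitch_mm(self) -> float:
        return self.beam_size_mm / self.sensor_pixels

    @property
    def carrier_freq_cyc_mm(self) -> float:
        """Fringe carrier of the +/-1 order pair, ``2*sqrt(2)/d`` (cycles/mm)."""
        return 2.0 * _SQRT2 / (self.grating_pitch_um * 1e-3)

    @property
    def carrier_bins(self) -> float:
        """Carrier position in DFT bins of the sensor grid (may be fractional)."""
        return self.carrier_freq_cyc_mm * self.beam_size_mm

    def shear_mm(self, distance_mm: float) -> float:
        """Lateral shear ``s = 2*sqrt(2)*l*lambda/d`` for arm distance ``l``."""
        if distance_mm <= 0:
            raise ValueError("grating-to-sensor distance must be positive")
        s = (
            2.0
            * _SQRT2
            * distance_mm
            * (self.wavelength_nm * 1e-6)
            / (self.grating_pitch_um * 1e-3)
        )
        if s >= self.beam_size_mm / 2:
            raise ValueError(
                f"shear {s:.4g} mm must stay below half the beam size "
                f"({self.beam_size_mm / 2:.4g} mm)"
            )
        return s

    def beta(self, distance_mm: float) -> float:
        """Shear ratio ``s / beam_size`` for arm distance ``l``; in (0, 0.5)."""
        return self.shear_mm(distance_mm) / self.beam_size_mm

    def distance_for_beta(self, beta: float) -> float:
        """Arm distance ``l`` (mm) realizing a given shear ratio."""
        if not 0.0 < beta < 0.5:
            raise ValueError("shear ratio must lie in (0, 0.5)")
        s = beta * self.beam_size_mm
        return s * (self.grating_pitch_um * 1e-3) / (2.0 * _SQRT2 * self.wavelength_nm * 1e-6)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        return cls(**d)


def design_config(
    *,
    beam_size_mm: float = 7.066,
    sensor_pixels: int = 512,
    carrier_bins: int = 160,
    n_pixels: int = 129,
    wavelength_nm: float = 623.0,
    bit_depth: int = 8,
    max_gray: int | None = None,
    refractive_index: float = 1.457,
) -> AcquisitionConfig:
    """Build a config whose fringe carrier lands on an integer DFT bin.

    Choosing the grating pitch as ``d = 2*sqrt(2)*L/carrier_bins`` puts the
    intensity carrier exactly on bin ``carrier_bins`` of the sensor spectrum,
    so the sideband crop removes the carrier with no residual tilt.  Handy for
    controlled simulations; hardware pitches generally leave a fractional
    residue that is calibrated away by background subtraction.
    """
    pitch_mm = 2.0 * _SQRT2 * beam_size_mm / carrier_bins
    return AcquisitionConfig(
        wavelength_nm=wavelength_nm,
        grating_pitch_um=pitch_mm * 1e3,
        beam_size_mm=beam_size_mm,
        sensor_pixels=sensor_pixels,
        n_pixels=n_pixels,
        bit_depth=bit_depth,
        max_gray=max_gray,
        refractive_index=refractive_index,
    )
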