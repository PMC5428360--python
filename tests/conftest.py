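"""Shared fixtures: small integer-carrier geometries and smooth phantoms.

The test geometry uses a 512-pixel sensor with the fringe carrier on bin 160
and a 129-bin sideband crop: the same spectral layout as the full-size
instrument (carrier bin 666 of 2048, 501-bin crop) scaled down so a render
plus retrieval costs milliseconds.  16-bit quantization is used wherever a
tolerance below the 8-bit quantization-ringing floor is asserted.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import qwlsi as q

SENSOR = 512
CARRIER = 160
N_OUT = 129


@pytest.fixture(scope="session")
def small_config() -> q.AcquisitionConfig:
    return q.design_config(
        sensor_pixels=SENSOR, carrier_bins=CARRIER, n_pixels=N_OUT, bit_depth=16
    )


@pytest.fixture(scope="session")
def small_config_8bit() -> q.AcquisitionConfig:
    return q.design_config(
        sensor_pixels=SENSOR, carrier_bins=CARRIER, n_pixels=N_OUT, bit_depth=8, max_gray=132
    )


@pytest.fixture(scope="session")
def cell_phantom(small_config) -> q.PhaseMap:
    return q.make_cell_phantom(
        4, (0.0, 300.0), seed=7, n_pixels=SENSOR, extent_mm=small_config.beam_size_mm
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def smooth_field(shape: tuple[int, int], amplitude: float, seed: int, sigma: float = 10.0):
    """Smooth compact random field: band-limited noise tapered to zero edges."""
    g = gaussian_filter(np.random.default_rng(seed).normal(size=shape), sigma)
    g *= amplitude / np.abs(g).max()
    win = np.outer(np.hanning(shape[0]), np.hanning(shape[1]))
    return g * win


def unwrap_pair(pair: q.ShearingWavefrontPair) -> q.ShearingWavefrontPair:
    return q.ShearingWavefrontPair(
        q.unwrap(pair.phi_x),
        q.unwrap(pair.phi_y),
        pair.shear_mm,
        pair.extent_mm,
        wrapped=False,
    )


def fourier_downsample(values: np.ndarray, n_out: int) -> np.ndarray:
    """Band-limited resample to the retrieval grid (matches the sideband crop)."""
    n = values.shape[0]
    spec = np.fft.fftshift(np.fft.fft2(values))
    c, h = n // 2, n_out // 2
    crop = spec[c - h : c + h + 1, c - h : c + h + 1]
    return np.fft.ifft2(np.fft.ifftshift(crop)).real * (n_out**2 / n**2)


def rel_rms(err: np.ndarray, ref_ptp: float) -> float:
    return float(np.sqrt(np.mean(err**2)) / ref_ptp)
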