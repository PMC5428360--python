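"""Spectral reconstruction: transfer factors, single/dual inversion, units."""

import numpy as np
import pytest

import qwlsi as q
from qwlsi.dlpu import remove_plane
from qwlsi.simulate import fourier_shift

from .conftest import fourier_downsample, rel_rms, smooth_field, unwrap_pair

TWO_PI = 2 * np.pi


def synth_pair(wavefront_nm, extent_mm, shear_mm, wavelength_nm):
    """Exact shearing-wavefront phases via band-limited (Fourier) shifts."""
    n = wavefront_nm.shape[0]
    s_px = shear_mm / (extent_mm / n)
    phi = TWO_PI * wavefront_nm / wavelength_nm
    phi_x = fourier_shift(phi, (0, s_px / 2)) - fourier_shift(phi, (0, -s_px / 2))
    phi_y = fourier_shift(phi, (s_px / 2, 0)) - fourier_shift(phi, (-s_px / 2, 0))
    return q.ShearingWavefrontPair(phi_x, phi_y, shear_mm, extent_mm, wrapped=False)


@pytest.fixture(scope="module")
def wavefront():
    return 150.0 * smooth_field((129, 129), 1.0, seed=21, sigma=9)  # nm (odd grid: no Nyquist-bin ambiguity)


class TestShearTransfer:
    def test_zero_frequency_gives_zero_factor(self):
        tx, _ = q.shear_transfer(np.array(0.0), np.array(0.0), 0.1)
        assert tx == 0

    def test_quarter_period_gives_minus_two_i(self):
        s = 0.1328
        tx, _ = q.shear_transfer(np.array(1 / (2 * s)), np.array(0.0), s)
        assert tx == pytest.approx(-2j, abs=1e-12)

    def test_factor_reproduces_spatial_shift_difference(self, wavefront):
        extent, s = 7.066, 0.1328
        n = wavefront.shape[0]
        f = np.fft.fftfreq(n, d=extent / n)
        tx, _ = q.shear_transfer(f[None, :], f[:, None], s)
        via_spectrum = np.fft.ifft2(np.fft.fft2(wavefront) * (tx * np.ones((n, n)))).real
        s_px = s / (extent / n)
        direct = fourier_shift(wavefront, (0, s_px / 2)) - fourier_shift(
            wavefront, (0, -s_px / 2)
        )
        np.testing.assert_allclose(via_spectrum, direct, atol=1e-9 * np.abs(direct).max())


class TestSingleShear:
    def test_noiseless_recovery(self, wavefront):
        extent, wl = 7.066, 623.0
        pair = synth_pair(wavefront, extent, 0.0188 * extent, wl)
        res = q.reconstruct_single(pair, wl)
        err = remove_plane(res.wavefront.values - wavefront)
        assert rel_rms(err, np.ptp(wavefront)) < 1e-9

    def test_zero_inputs_give_zero_wavefront(self):
        zero = q.ShearingWavefrontPair(
            np.zeros((64, 64)), np.zeros((64, 64)), 0.13, 7.066, wrapped=False
        )
        res = q.reconstruct_single(zero, 623.0)
        assert np.all(res.wavefront.values == 0)

    def test_wrapped_input_rejected(self):
        pair = q.ShearingWavefrontPair(
            np.zeros((64, 64)), np.zeros((64, 64)), 0.13, 7.066, wrapped=True
        )
        with pytest.raises(ValueError):
            q.reconstruct_single(pair, 623.0)

    def test_lattice_noise_amplified_single_but_not_dual(self, wavefront):
        # inject noise at the blind-lattice frequency u = 1/s of shear A: the
        # single-shear inversion amplifies it, the dual fusion does not
        extent, wl = 7.066, 623.0
        s_a, s_b = 0.0188 * extent, 0.0157 * extent
        n = wavefront.shape[0]
        k_lattice = round(n / (s_a / (extent / n)))  # nearest bin to u = 1/s_a
        noise_spec = np.zeros((n, n), complex)
        noise_spec[0, k_lattice] = 40.0 * n
        noise_spec[0, -k_lattice] = 40.0 * n
        noise = np.fft.ifft2(noise_spec).real * TWO_PI / wl

        pair_a = synth_pair(wavefront, extent, s_a, wl)
        pair_b = synth_pair(wavefront, extent, s_b, wl)
        noisy_a = q.ShearingWavefrontPair(
            pair_a.phi_x + noise, pair_a.phi_y, s_a, extent, wrapped=False
        )
        err_single = remove_plane(
            q.reconstruct_single(noisy_a, wl).wavefront.values - wavefront
        )
        err_dual = remove_plane(
            q.reconstruct_dual(noisy_a, pair_b, wl).wavefront.values - wavefront
        )
        assert np.abs(err_single).max() > 5 * np.abs(err_dual).max()


class TestDualShear:
    def test_noiseless_recovery_and_shear_consistency(self, wavefront):
        extent, wl = 7.066, 623.0
        pair_a = synth_pair(wavefront, extent, 0.0188 * extent, wl)
        pair_b = synth_pair(wavefront, extent, 0.0157 * extent, wl)
        res = q.reconstruct_dual(pair_a, pair_b, wl)
        err = remove_plane(res.wavefront.values - wavefront)
        assert rel_rms(err, np.ptp(wavefront)) < 1e-9
        # residual: re-shear the output and compare with the input observation
        check = synth_pair(res.wavefront.values, extent, 0.0188 * extent, wl)
        resid = check.phi_x - pair_a.phi_x
        assert np.sqrt(np.mean(resid**2)) < 1e-3

    def test_equal_shears_collapse_to_single(self, wavefront):
        extent, wl = 7.066, 623.0
        pair = synth_pair(wavefront, extent, 0.0188 * extent, wl)
        single = q.reconstruct_single(pair, wl)
        with pytest.warns(UserWarning, match="equal shears"):
            dual = q.reconstruct_dual(pair, pair, wl)
        np.testing.assert_allclose(
            dual.wavefront.values, single.wavefront.values, atol=1e-9
        )

    def test_linearity(self, wavefront):
        extent, wl = 7.066, 623.0
        pair = synth_pair(wavefront, extent, 0.0188 * extent, wl)
        pair2 = q.ShearingWavefrontPair(
            3.0 * pair.phi_x, 3.0 * pair.phi_y, pair.shear_mm, extent, wrapped=False
        )
        a = q.reconstruct_single(pair, wl).wavefront.values
        b = q.reconstruct_single(pair2, wl).wavefront.values
        np.testing.assert_allclose(b, 3.0 * a, atol=1e-9 * np.abs(a).max())

    def test_output_is_real_hermitian(self, wavefront):
        # the fused spectrum must be Hermitian: imaginary part at rounding level
        extent, wl = 7.066, 623.0
        pair_a = synth_pair(wavefront, extent, 0.0188 * extent, wl)
        pair_b = synth_pair(wavefront, extent, 0.0157 * extent, wl)
        Fa = [np.fft.fft2(pair_a.phi_x * wl / TWO_PI), np.fft.fft2(pair_a.phi_y * wl / TWO_PI)]
        Fb = [np.fft.fft2(pair_b.phi_x * wl / TWO_PI), np.fft.fft2(pair_b.phi_y * wl / TWO_PI)]
        n = wavefront.shape[0]
        f = np.fft.fftfreq(n, d=extent / n)
        ones = np.ones((n, n))
        sines = [
            np.sin(np.pi * pair_a.shear_mm * f)[None, :] * ones,
            np.sin(np.pi * pair_a.shear_mm * f)[:, None] * ones,
            np.sin(np.pi * pair_b.shear_mm * f)[None, :] * ones,
            np.sin(np.pi * pair_b.shear_mm * f)[:, None] * ones,
        ]
        denom = 2 * sum(s**2 for s in sines)
        denom[0, 0] = np.inf
        F = 1j * sum(s * o for s, o in zip(sines, Fa + Fb)) / denom
        w = np.fft.ifft2(F)
        assert np.abs(w.imag).max() < 1e-9 * max(np.abs(w.real).max(), 1e-30)

    def test_mismatched_grids_rejected(self):
        a = q.ShearingWavefrontPair(np.zeros((64, 64)), np.zeros((64, 64)), 0.1, 7.0, wrapped=False)
        b = q.ShearingWavefrontPair(np.zeros((32, 32)), np.zeros((32, 32)), 0.2, 7.0, wrapped=False)
        with pytest.raises(ValueError):
            q.reconstruct_dual(a, b, 623.0)


class TestUnits:
    def test_opd_to_depth_value(self):
        # 62.2 nm of OPD through n = 1.457 glass is 136.1 nm of etch depth
        pm = q.PhaseMap(np.full((16, 16), 62.2), 1.0, "opd_nm")
        depth = q.opd_to_depth(pm, 1.457)
        assert depth.values[0, 0] == pytest.approx(62.2 / 0.457, rel=1e-9)
        assert depth.values[0, 0] == pytest.approx(136.1, abs=0.1)

    def test_zero_opd_zero_depth(self):
        pm = q.PhaseMap(np.zeros((16, 16)), 1.0, "opd_nm")
        assert np.all(q.opd_to_depth(pm, 1.5).values == 0)

    def test_invalid_index_rejected(self):
        pm = q.PhaseMap(np.zeros((16, 16)), 1.0, "opd_nm")
        with pytest.raises(ValueError):
            q.opd_to_depth(pm, 1.0)

    def test_disc_depth_round_trip(self, small_config):
        # render -> demodulate -> unwrap -> fuse -> depth recovers the etch depth
        from .conftest import SENSOR

        depth_nm, n_glass = 136.0, small_config.refractive_index
        extent_um = small_config.beam_size_mm * 1e3
        pm = q.make_disc_phantom(
            extent_um / 4, depth_nm, n_glass, SENSOR, extent_um, edge_px=12.0
        )
        pairs = []
        for beta in (0.0188, 0.0157):
            fr = q.render_interferogram(
                pm, small_config, small_config.distance_for_beta(beta), noise="none"
            )
            pairs.append(unwrap_pair(q.extract_shearing_phases(fr)))
        rec = q.reconstruct_dual(pairs[0], pairs[1], small_config.wavelength_nm)
        depth = q.opd_to_depth(rec.wavefront, n_glass)
        vals = remove_plane(depth.values)
        # robust step height: median background minus median disc interior
        n_out = vals.shape[0]
        c = (n_out - 1) / 2
        yy, xx = np.mgrid[0:n_out, 0:n_out]
        r = np.hypot(xx - c, yy - c) * (small_config.beam_size_mm / n_out)
        radius = small_config.beam_size_mm / 8  # disc diameter is extent/4
        inside = np.median(vals[r < 0.7 * radius])
        outside = np.median(vals[r > 1.4 * radius])
        assert outside - inside == pytest.approx(depth_nm, rel=0.02)


class TestBackground:
    def test_identical_maps_cancel(self):
        pm = q.PhaseMap(np.random.default_rng(0).normal(size=(32, 32)), 1.0)
        out = q.subtract_background(pm, pm)
        np.testing.assert_allclose(out.values, 0, atol=1e-12)

    def test_aberration_removed(self, wavefront):
        aberration = 30.0 * smooth_field((129, 129), 1.0, seed=99, sigma=20)
        measured = q.PhaseMap(wavefront + aberration, 7.066)
        background = q.PhaseMap(aberration, 7.066)
        out = q.subtract_background(measured, background)
        err = out.values - (wavefront - wavefront.mean())
        assert np.abs(err).max() < 1e-9

    def test_zero_background_is_identity_up_to_piston(self, wavefront):
        pm = q.PhaseMap(wavefront, 7.066)
        out = q.subtract_background(pm, q.PhaseMap(np.zeros_like(wavefront), 7.066))
        np.testing.assert_allclose(out.values, wavefront - wavefront.mean(), atol=1e-12)

    def test_shape_mismatch_rejected(self):
        a = q.PhaseMap(np.zeros((16, 16)), 1.0)
        b = q.PhaseMap(np.zeros((32, 32)), 1.0)
        with pytest.raises(ValueError):
            q.subtract_background(a, b)
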