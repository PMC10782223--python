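"""Power spectra, radial profiles, whitening and ring-peak detection."""

import numpy as np
import pytest

from goldcal import (
    Micrograph,
    PowerSpectrum2D,
    accumulate,
    find_ring_peak,
    load_micrograph,
    power_spectrum,
    radial_profile,
    whiten,
)
from goldcal.errors import FitError, NoPeakError
from goldcal.mrcio import write_mrc
from goldcal.spectra import expected_radius


def _ps_from_values(values, **kw):
    return PowerSpectrum2D(np.asarray(values, float), L=values.shape[0], **kw)


class TestMicrographIO:
    def test_mrc_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        img = rng.random((128, 128)).astype(np.float32)
        path = tmp_path / "m.mrc"
        write_mrc(path, img, 0.6484)
        m = load_micrograph(path)
        assert np.allclose(m.pixels, img, atol=1e-6)
        assert m.nominal_pixel_size == pytest.approx(0.6484, abs=1e-6)

    def test_pixel_size_override(self, tmp_path):
        path = tmp_path / "m.mrc"
        write_mrc(path, np.zeros((64, 64), np.float32), 0.646)
        m = load_micrograph(path, override_pixel_size=0.669)
        assert m.nominal_pixel_size == 0.669

    def test_non_square_centre_cropped_with_warning(self, tmp_path):
        path = tmp_path / "m.mrc"
        write_mrc(path, np.zeros((128, 120), np.float32), 1.0)
        with pytest.warns(UserWarning, match="centre-cropping"):
            m = load_micrograph(path)
        assert m.pixels.shape == (120, 120)

    def test_stack_mean_and_frames(self, tmp_path):
        rng = np.random.default_rng(1)
        stack = rng.random((3, 64, 64)).astype(np.float32)
        path = tmp_path / "s.mrc"
        write_mrc(path, stack, 1.0)
        mean = load_micrograph(path, stack="mean")
        assert np.allclose(mean.pixels, stack.mean(axis=0), atol=1e-6)
        frames = load_micrograph(path, stack="frames")
        assert len(frames) == 3
        assert np.allclose(frames[2].pixels, stack[2], atol=1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            Micrograph(np.zeros((32, 32)), 1.0)


class TestPowerSpectrum:
    def test_constant_image_power_in_dc_only(self):
        m = Micrograph(np.full((64, 64), 7.0), 1.0)
        ps = power_spectrum(m)
        # mean subtraction removes DC entirely; everything else is zero
        assert ps.values.max() == pytest.approx(0.0, abs=1e-18)

    def test_cosine_grating_fourier_pair(self):
        L, p = 128, 8  # period 8 px -> radius L/p = 16
        x = np.arange(L)
        img = np.cos(2 * np.pi * x / p)[None, :] * np.ones((L, 1))
        ps = power_spectrum(Micrograph(img, 1.0))
        c = L // 2
        iy, ix = np.unravel_index(np.argmax(ps.values), ps.values.shape)
        assert iy == c and abs(ix - c) == L // p
        # symmetric Friedel mate has the same power
        assert ps.values[c, c + L // p] == pytest.approx(ps.values[c, c - L // p])

    def test_parseval(self):
        rng = np.random.default_rng(2)
        img = rng.random((96, 96))
        ps = power_spectrum(Micrograph(img, 1.0))
        var = np.var(img)
        assert ps.values.sum() == pytest.approx(96**2 * 96**2 * var, rel=1e-10)


class TestAccumulate:
    def test_mean_and_count(self):
        rng = np.random.default_rng(3)
        a = _ps_from_values(rng.random((64, 64)))
        b = _ps_from_values(rng.random((64, 64)))
        acc = accumulate([a, b])
        assert acc.n_accumulated == 2
        assert np.allclose(acc.values, (a.values + b.values) / 2, rtol=1e-12)
        same = accumulate([a, a])
        assert np.allclose(same.values, a.values, rtol=1e-12)

    def test_shape_mismatch(self):
        a = _ps_from_values(np.ones((64, 64)))
        b = _ps_from_values(np.ones((128, 128)))
        with pytest.raises(ValueError):
            accumulate([a, b])

    def test_noise_reduction_scales_as_sqrt_k(self):
        """Averaging k independent white-noise spectra shrinks the annulus
        scatter like 1/sqrt(k)."""
        rng = np.random.default_rng(4)
        L = 128

        def noise_ps():
            return power_spectrum(Micrograph(rng.standard_normal((L, L)), 1.0))

        def annulus_rel_sd(ps):
            y = np.arange(L) - L // 2
            r = np.hypot(y[:, None], y[None, :])
            sel = (r > 20) & (r < 28)
            v = ps.values[sel]
            return v.std() / v.mean()

        sds = {}
        for k in (1, 4, 16):
            acc = accumulate([noise_ps() for _ in range(k)])
            sds[k] = annulus_rel_sd(acc)
        assert sds[4] == pytest.approx(sds[1] / 2, rel=0.25)
        assert sds[16] == pytest.approx(sds[1] / 4, rel=0.25)


class TestRadialProfile:
    def test_gaussian_annulus_argmax(self, ring_image):
        values, L, R = ring_image
        prof = radial_profile(_ps_from_values(values))
        assert abs(prof.radii[np.argmax(prof.intensity)] - R) <= 1.0

    def test_profile_linear_in_accumulation(self, ring_image):
        values, L, R = ring_image
        ps = _ps_from_values(values)
        p1 = radial_profile(ps)
        p2 = radial_profile(accumulate([ps, ps]))
        assert np.allclose(p1.intensity, p2.intensity, rtol=1e-12)

    def test_center_outside_image_rejected(self, ring_image):
        values, L, R = ring_image
        with pytest.raises(ValueError):
            radial_profile(_ps_from_values(values), center=(-5.0, 10.0))


class TestWhiten:
    def _decaying_ps(self, L=512, r0=80.0):
        y = np.arange(L) - L // 2
        r = np.hypot(y[:, None], y[None, :])
        return r, _ps_from_values(np.exp(-r / r0))

    def test_pure_background_flattens_to_unity(self):
        L = 512
        r, ps = self._decaying_ps(L)
        w = whiten(ps, [])
        prof = radial_profile(w)
        sel = (prof.radii > 0.1 * L / 2) & (prof.radii < 0.9 * L / 2)
        assert np.all(np.abs(prof.intensity[sel] - 1.0) < 0.05)

    def test_weak_peak_shifts_inward_without_whitening(self):
        """On a decaying background the raw profile maximum of a weak ring
        sits inside the true radius; whitening moves it back out."""
        L, R = 512, 150.0
        r, _ = self._decaying_ps(L)
        values = np.exp(-r / 40.0) + 0.08 * np.exp(-0.5 * ((r - R) / 6.0) ** 2)
        ps = _ps_from_values(values)
        raw = radial_profile(ps)
        sel = (raw.radii > 100) & (raw.radii < 200)
        raw_argmax = raw.radii[sel][np.argmax(raw.intensity[sel])]
        wprof = radial_profile(whiten(ps, [(R - 25, R + 25)]))
        wsel = (wprof.radii > 100) & (wprof.radii < 200)
        white_argmax = wprof.radii[wsel][np.argmax(wprof.intensity[wsel])]
        assert raw_argmax < white_argmax
        assert abs(white_argmax - R) <= 2.0

    def test_strong_peak_position_stable_under_whitening(self, ring_image):
        values, L, R = ring_image
        y = np.arange(L) - L // 2
        r = np.hypot(y[:, None], y[None, :])
        ps = _ps_from_values(values * np.exp(-r / 120.0))
        raw_peak = find_ring_peak(
            radial_profile(ps), expected_d=1.0, nominal_pixel_size=R / L, L=L
        )
        white_peak = find_ring_peak(
            radial_profile(whiten(ps, [(R - 20, R + 20)])),
            expected_d=1.0,
            nominal_pixel_size=R / L,
            L=L,
        )
        assert abs(white_peak.radius - raw_peak.radius) < 0.5

    def test_flat_spectrum_whitening_is_identity_up_to_constant(self):
        rng = np.random.default_rng(5)
        base = np.full((256, 256), 3.0)
        ps = _ps_from_values(base)
        w = whiten(ps, [])
        ratio = w.values[50:200, 50:200] / base[50:200, 50:200]
        assert np.allclose(ratio, ratio.mean(), rtol=1e-6)
        assert ratio.mean() == pytest.approx(1 / 3, rel=0.02)

    def test_scale_invariance(self, ring_image):
        values, L, R = ring_image
        w1 = whiten(_ps_from_values(values), [(R - 20, R + 20)])
        w2 = whiten(_ps_from_values(values * 37.5), [(R - 20, R + 20)])
        assert np.allclose(w1.values, w2.values, rtol=1e-8)

    def test_excessive_exclusion_rejected(self):
        _, ps = self._decaying_ps()
        with pytest.raises(FitError):
            whiten(ps, [(0.0, 260.0)])


class TestFindRingPeak:
    def _profile(self, peaks, L=1024, noise=0.0, seed=0):
        """Whitened-like profile: unit baseline plus Gaussian peaks."""
        from goldcal.spectra import RadialProfile

        radii = np.arange(1, L // 2, dtype=float)
        rng = np.random.default_rng(seed)
        intensity = np.ones_like(radii) + noise * rng.standard_normal(radii.size)
        for r0, height, sigma in peaks:
            intensity += height * np.exp(-0.5 * ((radii - r0) / sigma) ** 2)
        return RadialProfile(radii, intensity, np.ones_like(radii))

    def test_subpixel_radius_recovery(self):
        prof = self._profile([(237.4, 30.0, 4.0)], noise=0.01)
        pnom, d, L = 0.6484, 2.35, 1024
        r_exp = expected_radius(d, pnom, L)  # 282.5 -> use d matching 237.4
        d_match = L * pnom / 237.4
        peak = find_ring_peak(prof, d_match, pnom, L)
        assert peak.radius == pytest.approx(237.4, abs=0.2)

    def test_outer_peak_selected_when_two_rings_in_window(self):
        """Target 2.35 Å with a 3% window: the 2.48 Å ring lies outside, so
        the fcc ring is selected even when the inner ring is stronger."""
        pnom, L = 0.6484, 1024
        r_fcc = expected_radius(2.35, pnom, L)
        r_hcp = expected_radius(2.48, pnom, L)
        prof = self._profile([(r_hcp, 50.0, 4.0), (r_fcc, 20.0, 4.0)])
        peak = find_ring_peak(prof, 2.35, pnom, L, tolerance_fraction=0.03)
        assert peak.radius == pytest.approx(r_fcc, abs=0.3)

    def test_flat_profile_raises(self):
        prof = self._profile([], noise=0.02)
        with pytest.raises(NoPeakError):
            find_ring_peak(prof, 2.35, 0.6484, 1024)

    def test_out_of_range_expected_radius_raises(self):
        prof = self._profile([(100.0, 10.0, 3.0)])
        with pytest.raises(NoPeakError):
            find_ring_peak(prof, 0.1, 0.6484, 1024)  # radius beyond Nyquist
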