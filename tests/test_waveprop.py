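"""Contrast formation: TIE vs Fresnel propagation, source blur, noise,
flat/dark correction."""

import numpy as np
import pytest

from propct import (
    ConeBeamGeometry,
    ExitWave,
    ProjectionStack,
    add_counting_noise,
    fresnel_forward,
    source_blur,
    tie_forward,
    flat_dark_correct,
    wavelength,
)

LAM = wavelength(25.0)
PX = 5.0


def gaussian_phase_wave(n=128, amp=-0.1, sigma=6.0, px=PX):
    yy, xx = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2, indexing="ij")
    phase = amp * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    return ExitWave(phase, np.ones((n, n)), 0.0, px)


def z_for_fresnel_number(f, px=PX, lam=LAM):
    """Distance (mm) at which a pixel-sized feature has Fresnel number f."""
    return px * px / (lam * f) / 1e3


class TestTIEForward:
    def test_constant_phase_is_identity(self):
        n = 64
        w = ExitWave(np.full((n, n), 0.7), np.full((n, n), 0.9), 0.0, PX)
        out = tie_forward(w, 500.0, LAM)
        np.testing.assert_allclose(out, 0.9, atol=1e-12)

    def test_sinusoidal_phase_analytic(self):
        """phi = a sin(2 pi nu x) gives contrast 2 pi lambda z nu^2 a sin."""
        n, cyc, a = 256, 12, 0.01
        x = np.arange(n)
        phase = a * np.sin(2 * np.pi * cyc * x / n)[None, :] * np.ones((n, 1))
        w = ExitWave(phase, np.ones((n, n)), 0.0, PX)
        z_mm = 500.0
        nu = cyc / (n * PX)
        out = tie_forward(w, z_mm, LAM)
        expected = 1.0 + 2 * np.pi * LAM * (z_mm * 1e3) * nu**2 * phase
        inner = (slice(None), slice(24, -24))  # away from mirror-pad kinks
        np.testing.assert_allclose(out[inner], expected[inner], atol=1e-5)

    def test_matches_finite_difference_laplacian(self):
        """Spectral Laplacian agrees with a 5-point stencil on a smooth field."""
        w = gaussian_phase_wave(n=128, sigma=8.0)
        z_mm = 300.0
        out = tie_forward(w, z_mm, LAM)
        lap = np.zeros_like(w.phase)
        lap[1:-1, 1:-1] = (
            w.phase[2:, 1:-1] + w.phase[:-2, 1:-1]
            + w.phase[1:-1, 2:] + w.phase[1:-1, :-2]
            - 4 * w.phase[1:-1, 1:-1]
        ) / PX**2
        expected = 1.0 - (z_mm * 1e3 * LAM / (2 * np.pi)) * lap
        inner = (slice(8, -8), slice(8, -8))
        rms = np.sqrt(np.mean((out[inner] - expected[inner]) ** 2))
        scale = np.sqrt(np.mean((expected[inner] - 1.0) ** 2))
        assert rms / scale < 0.01

    def test_negative_intensity_clipped_with_warning(self):
        w = gaussian_phase_wave(n=64, amp=-3.0, sigma=1.5)
        with pytest.warns(UserWarning, match="clipped"):
            out = tie_forward(w, 3000.0, LAM)
        assert np.all(out >= 0)


class TestFresnelForward:
    def test_zero_distance_identity(self):
        w = gaussian_phase_wave()
        np.testing.assert_array_equal(fresnel_forward(w, 0.0, LAM), w.exit_intensity)

    def test_plane_wave_invariant(self):
        n = 64
        w = ExitWave(np.full((n, n), 0.3), np.ones((n, n)), 0.0, PX)
        out = fresnel_forward(w, 800.0, LAM)
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_weak_grating_contrast_transfer(self):
        """Modulation of a weak phase grating follows sin(pi lambda z nu^2),
        agreeing with the TIE small-argument limit within 2%."""
        n, a = 256, 0.005
        for cyc, z_mm in [(16, 300.0), (24, 500.0), (32, 200.0)]:
            x = np.arange(n)
            phase = a * np.sin(2 * np.pi * cyc * x / n)[None, :] * np.ones((n, 1))
            w = ExitWave(phase, np.ones((n, n)), 0.0, PX)
            nu = cyc / (n * PX)
            arg = np.pi * LAM * z_mm * 1e3 * nu**2
            assert arg < 0.1  # TIE validity regime
            out = fresnel_forward(w, z_mm, LAM)
            central = out[:, 40:-40]  # away from mirror-pad kinks
            amp = (central.max() - central.min()) / 2
            assert amp == pytest.approx(2 * a * np.sin(arg), rel=0.02)

    def test_tie_agreement_improves_with_fresnel_number(self):
        """TIE and Fresnel agree < 1% (contrast-relative RMS) for F >= 10;
        the discrepancy grows monotonically as F decreases."""
        w = gaussian_phase_wave(n=128, amp=-0.05, sigma=1.5)
        discrepancies = []
        for f in (20.0, 5.0, 0.6):
            z = z_for_fresnel_number(f)
            a = tie_forward(w, z, LAM)
            b = fresnel_forward(w, z, LAM)
            rel = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean((b - 1) ** 2))
            discrepancies.append(rel)
        assert discrepancies[0] < 0.01
        assert discrepancies == sorted(discrepancies)

    def test_flux_conserved_for_pure_phase(self):
        w = gaussian_phase_wave(n=128, amp=-0.5, sigma=5.0)
        out = fresnel_forward(w, z_for_fresnel_number(0.6), LAM)
        assert out.mean() == pytest.approx(1.0, abs=1e-3)

    def test_undersampled_kernel_warns(self):
        w = gaussian_phase_wave(n=32)
        with pytest.warns(UserWarning, match="under-sampled"):
            fresnel_forward(w, 5e5, LAM)


class TestSourceBlur:
    def test_identity_cases(self, mucls_geom):
        frame = np.random.default_rng(0).random((32, 32))
        contact = ConeBeamGeometry(100.0, 100.0, 6.5, 25.0, source_fwhm_um=98.0)
        np.testing.assert_array_equal(source_blur(frame, 0.0, mucls_geom), frame)
        np.testing.assert_array_equal(source_blur(frame, 98.0, contact), frame)

    def test_impulse_response_fwhm(self, mucls_geom):
        """Measured FWHM of the blurred impulse matches s(M-1)/M/p_eff."""
        n = 129
        frame = np.zeros((n, n))
        frame[n // 2, n // 2] = 1.0
        out = source_blur(frame, 98.0, mucls_geom)
        profile = out[n // 2]
        half = profile.max() / 2
        above = np.nonzero(profile >= half)[0]
        # sub-pixel FWHM by linear interpolation at both half crossings
        lo, hi = above[0], above[-1]
        f_lo = lo - (profile[lo] - half) / (profile[lo] - profile[lo - 1])
        f_hi = hi + (profile[hi] - half) / (profile[hi] - profile[hi + 1])
        measured = f_hi - f_lo
        m = mucls_geom.magnification
        expected = 98.0 * (m - 1) / m / mucls_geom.effective_pixel_um
        assert measured == pytest.approx(expected, rel=0.02)


class TestCountingNoise:
    def test_deterministic_per_seed(self):
        frame = np.full((64, 64), 0.5)
        a = add_counting_noise(frame, 1e4, (3, 17))
        b = add_counting_noise(frame, 1e4, (3, 17))
        c = add_counting_noise(frame, 1e4, (3, 18))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_poisson_moments(self):
        """Counts-domain variance/mean within 5% of 1 at 1e4 counts."""
        frame = np.full((256, 256), 1.0)
        noisy = add_counting_noise(frame, 1e4, 42)
        counts = noisy * 1e4
        assert counts.var() / counts.mean() == pytest.approx(1.0, rel=0.05)

    def test_relative_error_shrinks_with_counts(self):
        frame = np.full((128, 128), 1.0)
        lo = add_counting_noise(frame, 1e2, 0).std()
        hi = add_counting_noise(frame, 1e6, 0).std()
        assert hi < lo / 10

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            add_counting_noise(np.array([[-0.1]]), 100.0, 0)


class TestFlatDarkCorrect:
    def _stack(self, frames, flats, darks=None):
        return ProjectionStack(
            frames=frames,
            angles_deg=np.arange(len(frames), dtype=float),
            pixel_um=PX,
            flats=flats,
            darks=darks,
        )

    def test_raw_equals_flat_gives_ones(self):
        flat = np.random.default_rng(1).uniform(0.5, 1.5, (16, 16))
        out = flat_dark_correct(self._stack(flat[None].repeat(3, 0), flat[None]))
        np.testing.assert_allclose(out.frames, 1.0, atol=1e-12)

    def test_raw_equals_dark_gives_zeros(self):
        flat = np.full((16, 16), 2.0)
        dark = np.full((16, 16), 0.25)
        out = flat_dark_correct(
            self._stack(dark[None].repeat(2, 0), flat[None], dark[None])
        )
        np.testing.assert_allclose(out.frames, 0.0, atol=1e-12)

    def test_recovers_known_transmission(self, rng):
        flat = rng.uniform(0.8, 1.2, (32, 32))
        trans = rng.uniform(0.1, 1.0, (32, 32))
        out = flat_dark_correct(self._stack((flat * trans)[None], flat[None]))
        np.testing.assert_allclose(out.frames[0], trans, atol=1e-6)

    def test_nonpositive_flat_rejected(self):
        flat = np.ones((8, 8))
        dark = np.ones((8, 8))  # flat - dark == 0 everywhere
        with pytest.raises(ValueError, match="pixels"):
            flat_dark_correct(self._stack(np.ones((1, 8, 8)), flat[None], dark[None]))

    def test_missing_flats_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            flat_dark_correct(self._stack(np.ones((1, 8, 8)), None))
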