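"""Baseline estimation, peak extraction, d-spacings and lamellar grouping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bicellix import (
    Peak,
    PeakSet,
    SASCurve,
    ValidationError,
    d_spacing,
    difference_intensity,
    estimate_baseline,
    extract_peaks,
    find_lamellar_series,
    gaussian_peak_profile,
    low_q_slope,
    powerlaw_intensity,
    subtract_baseline,
    uniform_cylinder_intensity,
)

TWO_PI = 2 * np.pi


def _powerlaw_curve(n=300, lo=0.02, hi=0.3, amp=1e-3, exponent=-2.0, background=0.0):
    q = np.geomspace(lo, hi, n)
    return q, powerlaw_intensity(q, amp, exponent, background=background)


class TestBaseline:
    def test_smooth_powerlaw_reproduced(self):
        q, i = _powerlaw_curve(background=0.01)
        c = SASCurve(q, i)
        base = estimate_baseline(c)
        assert np.max(np.abs(base.intensity - i) / i) < 0.01

    def test_flat_curve_flat_baseline(self):
        q = np.geomspace(0.01, 0.3, 200)
        c = SASCurve(q, np.full(200, 3.0))
        base = estimate_baseline(c)
        assert base.intensity == pytest.approx(np.full(200, 3.0), rel=1e-9)

    def test_baseline_under_peak_tracks_background(self):
        """A peak narrower than the clipping window is removed entirely:
        the baseline under it stays on the smooth background."""
        q, bg = _powerlaw_curve()
        peak = gaussian_peak_profile(q, TWO_PI / 73, 0.0015, 5.0 * np.interp(TWO_PI / 73, q, bg))
        c = SASCurve(q, bg + peak)
        base = estimate_baseline(c, half_width=24, n_iter=2)
        under = np.abs(q - TWO_PI / 73) < 0.01
        assert np.max(np.abs(base.intensity[under] - bg[under]) / bg[under]) < 0.02

    def test_baseline_below_curve_almost_everywhere(self):
        q, bg = _powerlaw_curve(background=0.01)
        c = SASCurve(q, bg + gaussian_peak_profile(q, 0.1, 0.004, 1.0))
        base = estimate_baseline(c)
        frac_below = np.mean(base.intensity <= c.intensity * (1 + 1e-9))
        assert frac_below >= 0.95

    def test_too_short_curve_rejected(self):
        c = SASCurve([0.01, 0.02, 0.03], [1, 1, 1])
        with pytest.raises(ValidationError):
            estimate_baseline(c, half_width=12)


class TestSubtract:
    def test_self_subtraction_is_zero(self, simple_curve):
        r = subtract_baseline(simple_curve, simple_curve)
        assert np.all(r.intensity == 0.0)

    def test_subtraction_inverts(self, simple_curve):
        base = estimate_baseline(
            SASCurve(simple_curve.q, simple_curve.intensity), half_width=5
        )
        r = subtract_baseline(simple_curve, base)
        assert r.intensity + base.intensity == pytest.approx(
            simple_curve.intensity, abs=1e-12
        )

    def test_residual_integrates_to_peak_area(self):
        q, bg = _powerlaw_curve()
        sigma_q, amp = 0.003, 2.0
        c = SASCurve(q, bg + gaussian_peak_profile(q, 0.1, sigma_q, amp))
        base = estimate_baseline(c)
        resid = subtract_baseline(c, base)
        area = np.trapezoid(resid.intensity, q)
        assert area == pytest.approx(amp * sigma_q * np.sqrt(2 * np.pi), rel=0.05)

    def test_grid_mismatch_rejected(self, simple_curve):
        other = SASCurve(simple_curve.q * 1.001, simple_curve.intensity)
        with pytest.raises(ValidationError):
            subtract_baseline(simple_curve, other)


class TestExtractPeaks:
    def test_flat_residual_gives_empty_set(self):
        q = np.geomspace(0.01, 0.3, 100)
        ps = extract_peaks(SASCurve(q, np.zeros(100) + 1e-30))
        assert len(ps) == 0

    def test_single_gaussian_center_recovered(self):
        q0 = 0.0861
        q = np.geomspace(0.02, 0.3, 400)
        resid = gaussian_peak_profile(q, q0, 0.002, 1.0)
        ps = extract_peaks(SASCurve(q, resid + 1e-12))
        assert len(ps) == 1
        assert ps.peaks[0].q_max == pytest.approx(q0, abs=1e-4)
        assert ps.peaks[0].amplitude == pytest.approx(1.0, rel=0.02)

    def test_order_pair_ratio_is_two(self):
        """Two injected orders at q and 2q come back with a 1:2 position
        ratio to a quarter percent."""
        d = 73.0
        q = np.geomspace(0.02, 0.3, 400)
        resid = gaussian_peak_profile(q, TWO_PI / d, 0.002, 2.0)
        resid += gaussian_peak_profile(q, 2 * TWO_PI / d, 0.003, 0.7)
        ps = extract_peaks(SASCurve(q, resid + 1e-12))
        assert len(ps) == 2
        ratio = ps.peaks[1].q_max / ps.peaks[0].q_max
        assert ratio == pytest.approx(2.0, rel=0.005)

    def test_amplitudes_recovered_on_noisy_background(self):
        rng = np.random.default_rng(0)
        q = np.geomspace(0.02, 0.3, 400)
        amp = 2.0
        clean = gaussian_peak_profile(q, 0.1, 0.004, amp)
        noise_sigma = amp / 20  # SNR 20
        resid = clean + rng.normal(0, noise_sigma, len(q))
        ps = extract_peaks(
            SASCurve(q, np.maximum(resid, 0) + 1e-12), min_prominence=0.3
        )
        assert len(ps) >= 1
        main = max(ps.peaks, key=lambda p: p.amplitude)
        assert main.amplitude == pytest.approx(amp, rel=0.05)


class TestDSpacing:
    def test_known_value(self):
        assert d_spacing(0.0628319) == pytest.approx(100.0, abs=1e-3)

    def test_inverse_identity(self):
        assert d_spacing(TWO_PI / 73.0) == pytest.approx(73.0, rel=1e-12)

    @given(st.floats(1e-4, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_involution(self, q):
        assert d_spacing(d_spacing(q)) == pytest.approx(q, rel=1e-12)

    def test_peak_carries_consistent_spacing(self):
        p = Peak(q_max=TWO_PI / 73, amplitude=1.0, fwhm=0.003)
        assert p.d_spacing * p.q_max == pytest.approx(TWO_PI, abs=1e-9)


class TestLamellarSeries:
    def _peaks(self, qs, fwhm=0.003):
        return PeakSet(tuple(Peak(q, 1.0, fwhm) for q in sorted(qs)))

    def test_two_orders_grouped(self):
        ps = self._peaks([TWO_PI / 73, 2 * TWO_PI / 73])
        series = find_lamellar_series(ps)
        assert len(series) == 1
        assert series[0].d == pytest.approx(73.0, rel=1e-6)
        assert series[0].max_order == 2

    def test_transient_pair_not_merged(self):
        """Positions with ratio 1.886 (spacings 660 and 350 A) are not a
        1:2 series at 3% tolerance: two singletons."""
        ps = self._peaks([TWO_PI / 660, TWO_PI / 350], fwhm=0.0008)
        series = find_lamellar_series(ps, rel_tol=0.03)
        assert len(series) == 2
        assert all(s.max_order == 1 for s in series)

    def test_empty_input(self):
        assert find_lamellar_series(PeakSet(())) == []

    def test_each_peak_in_one_series_and_d_recovered(self):
        d = 80.0
        qs = [TWO_PI / d, 2 * TWO_PI / d * 1.01, 3 * TWO_PI / d * 0.995]
        series = find_lamellar_series(self._peaks(qs))
        members = [q for s in series for _, q in s.orders]
        assert sorted(members) == sorted(qs)
        assert series[0].d == pytest.approx(d, rel=0.03)


class TestLowQSlope:
    def test_pure_powerlaw_exact(self):
        q = np.geomspace(0.006, 0.04, 50)
        c = SASCurve(q, powerlaw_intensity(q, 1.0, -2.0))
        slope, _ = low_q_slope(c, (0.006, 0.04))
        assert slope == pytest.approx(-2.0, abs=1e-12)

    def test_crystallization_system_slope(self):
        q = np.geomspace(0.006, 0.04, 50)
        c = SASCurve(q, powerlaw_intensity(q, 1.0, -1.8))
        slope, _ = low_q_slope(c, (0.006, 0.04))
        assert slope == pytest.approx(-1.8, abs=1e-12)

    def test_large_thin_disc_asymptote(self):
        """A sheet-like disc scatters as q^-2 where 1/q sits between the
        thickness and the radius; with the window capped at q << 1/L the
        numerical slope reaches the asymptote."""
        q = np.geomspace(0.006, 0.015, 60)
        i = uniform_cylinder_intensity(q, 3000.0, 49.0, 1e-6)
        slope, _ = low_q_slope(SASCurve(q, i), (0.006, 0.015))
        assert slope == pytest.approx(-2.0, abs=0.08)

    def test_too_few_points_rejected(self):
        q = np.geomspace(0.01, 0.02, 4)
        c = SASCurve(q, np.ones(4))
        with pytest.raises(ValidationError):
            low_q_slope(c, (0.01, 0.02))


class TestDifferenceIntensity:
    def test_zero_coefficient_keeps_system(self, simple_curve):
        d = difference_intensity(simple_curve, simple_curve, coefficient=0.0)
        assert np.array_equal(d.intensity, simple_curve.intensity)

    def test_self_difference_zero_with_sqrt2_sigma(self, simple_curve):
        d = difference_intensity(simple_curve, simple_curve, coefficient=1.0)
        assert np.all(d.intensity == 0.0)
        assert d.sigma == pytest.approx(np.sqrt(2) * simple_curve.sigma)

    def test_recovers_component_of_composite(self, bicelle_5045):
        from bicellix import bicelle_intensity

        q = np.geomspace(0.006, 0.5, 150)
        pm = powerlaw_intensity(q, 1e-2, -2.0)
        bic = bicelle_intensity(q, bicelle_5045)
        sys_c = SASCurve(q, pm + bic)
        ref_c = SASCurve(q, pm)
        diff = difference_intensity(sys_c, ref_c)
        assert np.max(np.abs(diff.intensity - bic)) < 1e-10

    def test_grid_mismatch_requires_rebin(self, simple_curve):
        shifted = SASCurve(simple_curve.q * 1.01, simple_curve.intensity)
        with pytest.raises(ValidationError):
            difference_intensity(simple_curve, shifted)
        d = difference_intensity(simple_curve, shifted, rebin=True)
        assert len(d) > 0
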