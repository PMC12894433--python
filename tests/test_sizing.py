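"""Histograms, FWHM-seeded Gaussian fits, calibration regression."""

import math

import numpy as np
import pytest

import puncta_sizer as ps
from puncta_sizer.sizing import FWHM_TO_SIGMA, UnresolvedPeakError


def _mixture_intensities(n=6000, seed=0, cv=0.06, sizes=(2686, 5562, 12920)):
    pops = [ps.PopulationSpec(size_bp=s, fraction=1 / len(sizes), intensity_cv=cv) for s in sizes]
    return ps.gen_intensity_table(pops, n, seed)["intensity"].to_numpy()


class TestBuildHistogram:
    def test_identical_values_single_bin(self):
        hist = ps.build_histogram([5.0] * 100, n_bins=10, hist_range=(0, 10))
        assert hist.counts.max() == 100
        assert (hist.counts > 0).sum() == 1

    def test_count_conservation(self):
        x = _mixture_intensities(2000, seed=1)
        hist = ps.build_histogram(x, n_bins=80)
        assert hist.counts.sum() == len(x) == hist.n_total

    def test_auto_binning_resolves_three_populations(self):
        x = _mixture_intensities(6000, seed=2)
        hist = ps.build_histogram(x, n_bins="auto")
        counts = hist.counts
        interior = (counts[1:-1] > counts[:-2]) & (counts[1:-1] >= counts[2:])
        # at least 3 local maxima, one per plasmid population
        assert interior.sum() >= 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ps.build_histogram([])


class TestFindPeaks:
    def test_monotone_histogram_no_interior_peak(self):
        hist = ps.build_histogram(np.repeat(np.arange(10), np.arange(1, 11)), n_bins=10, hist_range=(0, 10))
        # increasing counts: only the right edge is maximal, no interior peak
        assert ps.find_peaks(hist, smooth=1) == []

    def test_three_population_peak_positions(self):
        x = _mixture_intensities(6000, seed=3)
        hist = ps.build_histogram(x, n_bins=100)
        peaks = ps.find_peaks(hist)
        assert len(peaks) == 3
        for peak, size in zip(peaks, (2686, 5562, 12920)):
            assert peak == pytest.approx(size * 10.0, rel=0.05)

    def test_unresolvably_close_populations_merge(self):
        # two populations ~1 FWHM apart collapse into one peak, and the
        # missing population surfaces as an unresolved-size error downstream
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(100, 10, 4000), rng.normal(118, 10, 4000)])
        hist = ps.build_histogram(x, n_bins=60, hist_range=(40, 180))
        assert len(ps.find_peaks(hist)) < 2


class TestInitGaussian:
    def test_fwhm_sigma_conversion_closed_form(self):
        assert 23.548 * FWHM_TO_SIGMA == pytest.approx(10.0, abs=1e-3)
        assert FWHM_TO_SIGMA == pytest.approx(1 / (2 * math.sqrt(2 * math.log(2))), rel=1e-12)

    def test_sigma_seed_from_discretized_gaussian(self):
        rng = np.random.default_rng(5)
        x = rng.normal(100, 10, 50_000)
        hist = ps.build_histogram(x, n_bins=80, hist_range=(50, 150))
        mu0, sd0, amp0 = ps.init_gaussian(hist, 100.0)
        assert sd0 == pytest.approx(10.0, rel=0.10)
        assert mu0 == pytest.approx(100.0, abs=2.0)
        assert amp0 > 0

    def test_edge_truncated_peak_signals_unresolved(self):
        rng = np.random.default_rng(6)
        x = np.abs(rng.normal(0, 10, 5000))  # half-Gaussian peaked at the edge
        hist = ps.build_histogram(x, n_bins=40, hist_range=(0, 40))
        with pytest.raises(UnresolvedPeakError):
            ps.init_gaussian(hist, hist.centers[0])


class TestFitPopulation:
    def test_parameter_recovery_single_population(self):
        rng = np.random.default_rng(7)
        mu, sd, n = 500.0, 40.0, 5000
        x = rng.normal(mu, sd, n)
        fit = ps.fit_population(x, (mu * 1.02, sd * 1.2, 100.0))
        assert fit.mean == pytest.approx(mu, abs=2 * sd / math.sqrt(n) * 3)
        assert fit.sd == pytest.approx(sd, rel=0.10)
        assert fit.n_molecules <= n

    def test_window_shields_mean_from_second_population(self):
        rng = np.random.default_rng(8)
        main = rng.normal(100, 5, 4000)
        init = (100.0, 5.0, 300.0)
        isolated = ps.fit_population(main, init)
        contaminated = ps.fit_population(
            np.concatenate([main, rng.normal(200, 5, 4000)]), init
        )
        assert contaminated.mean == pytest.approx(isolated.mean, rel=0.01)

    def test_symmetric_sample_mean_recovered(self):
        x = np.concatenate([np.linspace(80, 120, 2001)])  # exactly symmetric
        fit = ps.fit_population(x, (100.0, 10.0, 50.0))
        assert fit.mean == pytest.approx(x.mean(), rel=0.01)

    def test_too_few_molecules_rejected(self):
        with pytest.raises(ValueError, match="molecules"):
            ps.fit_population(np.full(5, 100.0), (100.0, 5.0, 5.0))


class TestFitCalibration:
    def test_exact_line(self):
        points = [(10.0, 1000.0), (20.0, 2000.0), (40.0, 4000.0)]
        curve = ps.fit_calibration(points)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(100.0, rel=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.uniform(10, 1000, 6)
            y = rng.uniform(100, 20000, 6)
            curve = ps.fit_calibration(list(zip(x, y)))
            # brute-force normal equations
            A = np.column_stack([x, np.ones_like(x)])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert curve.slope == pytest.approx(beta[0], rel=1e-10)
            assert curve.intercept == pytest.approx(beta[1], rel=1e-10)

    def test_through_origin_never_beats_free_fit(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            x = rng.uniform(10, 1000, 5)
            y = 3.0 * x + rng.normal(50, 30, 5)
            free = ps.fit_calibration(list(zip(x, y)))
            forced = ps.fit_calibration(list(zip(x, y)), through_origin=True)
            assert forced.intercept == 0.0
            assert forced.r_squared <= free.r_squared + 1e-12

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            ps.fit_calibration([(5.0, 100.0), (5.0, 200.0)])
        with pytest.raises(ValueError):
            ps.fit_calibration([(5.0, 100.0)])


class TestIntensityToSize:
    @pytest.fixture()
    def noisy_curve(self):
        rng = np.random.default_rng(11)
        x = np.array([26860.0, 55620.0, 129200.0, 80000.0, 40000.0])
        y = 0.1 * x + rng.normal(0, 150, x.size)
        return ps.fit_calibration(list(zip(x, y)), ci_level=0.99)

    def test_in_sample_prediction(self, noisy_curve):
        est = ps.intensity_to_size(noisy_curve, 55620.0)
        assert est.size_bp == pytest.approx(5562.0, abs=3 * noisy_curve.residual_sd)
        assert not est.extrapolated
        assert est.valid

    def test_error_grows_away_from_centroid(self, noisy_curve):
        center = noisy_curve.x_mean
        widths = [
            ps.intensity_to_size(noisy_curve, center + d).error_bp
            for d in (0.0, 2e4, 4e4, 8e4)
        ]
        assert all(a < b for a, b in zip(widths, widths[1:]))

    def test_extrapolation_flagged(self, noisy_curve):
        assert ps.intensity_to_size(noisy_curve, 1e6).extrapolated

    def test_negative_prediction_invalid(self):
        curve = ps.fit_calibration([(10.0, 100.0), (20.0, 1100.0), (30.0, 2100.0)])
        est = ps.intensity_to_size(curve, 0.0)
        assert est.size_bp < 0 and not est.valid

    def test_curve_roundtrip_via_json(self, tmp_path, noisy_curve):
        path = tmp_path / "curve.json"
        noisy_curve.to_json(path)
        loaded = ps.CalibrationCurve.from_json(path)
        assert loaded == noisy_curve


class TestErrorScaling:
    def test_absolute_error_grows_relative_error_constant(self):
        """Fitted population SD (a.u.) grows with DNA size at fixed CV while
        SD/mean stays flat: larger molecules are absolutely less precise but
        relatively more precise or equal."""
        sds, rels = [], []
        for size in (2686, 5562, 12920):
            pops = [ps.PopulationSpec(size_bp=size, fraction=1.0, intensity_cv=0.06)]
            x = ps.gen_intensity_table(pops, 5000, seed=size)["intensity"].to_numpy()
            mu0 = size * 10.0
            fit = ps.fit_population(x, (mu0, 0.06 * mu0, 100.0))
            sds.append(fit.sd)
            rels.append(fit.sd / fit.mean)
        assert sds[0] < sds[1] < sds[2]
        assert max(rels) - min(rels) < 0.01
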