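"""Background-histogram subtraction and exact 1-D k-means population calls."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import puncta_sizer as ps


def _hist_pair(target, background, n_bins=50):
    hi = max(target.max(), background.max()) * 1.02
    ht = ps.build_histogram(target, n_bins, (0.0, hi), source="target")
    hb = ps.build_histogram(background, n_bins, (0.0, hi), source="background")
    return ht, hb


class TestSubtractBackground:
    def test_identical_sample_cancels_exactly(self):
        pop = [ps.PopulationSpec(size_bp=2686, fraction=1.0, intensity_cv=0.05)]
        x = ps.gen_intensity_table(pop, 5000, seed=0)["intensity"].to_numpy()
        h = ps.build_histogram(x, 50, (0.0, x.max() * 1.02))
        diff = ps.subtract_background(h, h)
        assert diff.surviving_fraction == 0.0
        assert not diff.residual.any()

    def test_independent_replicates_nearly_cancel(self):
        """Two independent 1e4-molecule draws from the same population leave
        <2% surviving mass: the pipeline's false-discovery control."""
        pop = [ps.PopulationSpec(size_bp=2686, fraction=1.0, intensity_cv=0.05)]
        a = ps.gen_intensity_table(pop, 10_000, seed=1)["intensity"].to_numpy()
        b = ps.gen_intensity_table(pop, 10_000, seed=2)["intensity"].to_numpy()
        diff = ps.subtract_background(*_hist_pair(a, b))
        assert diff.surviving_fraction < 0.02

    def test_seven_percent_spike_in_survives(self):
        """Background plus a 7% spike of monomer/dimer molecules leaves a
        surviving fraction of 7 +/- 2 percentage points."""
        bg_pop = [ps.PopulationSpec(size_bp=5000, fraction=1.0, intensity_cv=0.35)]
        target_pops = [
            ps.PopulationSpec(size_bp=5000, fraction=0.93, intensity_cv=0.35),
            ps.PopulationSpec(size_bp=2684, fraction=0.0686, intensity_cv=0.07),
            ps.PopulationSpec(size_bp=5368, fraction=0.0014, intensity_cv=0.07),
        ]
        t = ps.gen_intensity_table(target_pops, 30_000, seed=3)["intensity"].to_numpy()
        b = ps.gen_intensity_table(bg_pop, 30_000, seed=4)["intensity"].to_numpy()
        diff = ps.subtract_background(*_hist_pair(t, b))
        assert diff.surviving_fraction == pytest.approx(0.07, abs=0.02)

    def test_disjoint_distributions_fully_survive(self):
        t = np.full(1000, 100.0)
        b = np.full(1000, 900.0)
        diff = ps.subtract_background(*_hist_pair(t, b, n_bins=20))
        assert diff.surviving_fraction == 1.0

    def test_field_normalization_rescales_background(self):
        pop = [ps.PopulationSpec(size_bp=2686, fraction=1.0, intensity_cv=0.05)]
        x = ps.gen_intensity_table(pop, 4000, seed=5)["intensity"].to_numpy()
        h = ps.build_histogram(x, 50, (0.0, x.max() * 1.02))
        diff = ps.subtract_background(h, h, target_fields=10, bg_fields=20)
        assert diff.bg_scale == 0.5
        assert diff.surviving_fraction == pytest.approx(0.5, abs=1e-9)

    def test_binning_mismatch_rejected(self):
        a = ps.build_histogram([1.0, 2.0], 10, (0, 5))
        b = ps.build_histogram([1.0, 2.0], 10, (0, 6))
        with pytest.raises(ValueError, match="bin edges"):
            ps.subtract_background(a, b)

    def test_clipped_mass_recorded(self):
        a = ps.build_histogram([1.0] * 5 + [3.0] * 10, 4, (0, 4))
        b = ps.build_histogram([1.0] * 10 + [3.0] * 5, 4, (0, 4))
        diff = ps.subtract_background(a, b)
        assert diff.clipped_mass == 5.0
        assert (diff.residual >= 0).all()


class TestResidualSample:
    def test_single_bin_residual(self):
        a = ps.build_histogram([5.0] * 15, 10, (0, 10))
        b = ps.build_histogram([5.0] * 5, 10, (0, 10))
        values = ps.residual_sample(ps.subtract_background(a, b))
        assert len(values) == 10
        assert np.allclose(values, values[0])

    def test_total_conservation(self):
        rng = np.random.default_rng(6)
        a = ps.build_histogram(rng.uniform(0, 10, 500), 20, (0, 10))
        b = ps.build_histogram(rng.uniform(0, 10, 200), 20, (0, 10))
        diff = ps.subtract_background(a, b)
        values = ps.residual_sample(diff)
        assert len(values) == int(np.rint(diff.residual).sum())

    def test_empty_residual_rejected(self):
        a = ps.build_histogram([1.0] * 10, 5, (0, 5))
        diff = ps.subtract_background(a, a)
        with pytest.raises(ValueError):
            ps.residual_sample(diff)


def _brute_force_sse(x, k):
    """Exhaustive search over contiguous partitions of the sorted values."""
    xs = np.sort(x)
    n = len(xs)
    best = np.inf
    for splits in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *splits, n]
        sse = sum(
            ((xs[lo:hi] - xs[lo:hi].mean()) ** 2).sum()
            for lo, hi in zip(bounds[:-1], bounds[1:])
        )
        best = min(best, sse)
    return best


def _calls_sse(x, calls):
    xs = np.sort(x)
    sse, lo = 0.0, 0
    for c in calls:
        seg = xs[lo : lo + c.n_members]
        sse += ((seg - seg.mean()) ** 2).sum()
        lo += c.n_members
    return sse


class TestKMeans1D:
    def test_two_obvious_clusters(self):
        calls = ps.kmeans_1d([1.0, 1.0, 1.0, 10.0, 10.0, 10.0], k=2)
        assert [c.n_members for c in calls] == [3, 3]
        assert calls[0].mean_intensity == 1.0
        assert calls[1].mean_intensity == 10.0

    def test_k_equal_one_returns_sample_mean(self):
        x = [3.0, 5.0, 9.0]
        calls = ps.kmeans_1d(x, k=1)
        assert len(calls) == 1
        assert calls[0].mean_intensity == pytest.approx(np.mean(x))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        x=st.lists(st.floats(-100, 100, allow_nan=False), min_size=4, max_size=14),
        k=st.integers(2, 4),
    )
    def test_matches_brute_force_on_small_instances(self, x, k):
        if len(set(x)) < k:
            x = list(np.asarray(x) + np.linspace(0, 1e-3, len(x)))
        calls = ps.kmeans_1d(x, k)
        assert _calls_sse(x, calls) == pytest.approx(_brute_force_sse(x, k), abs=1e-6)

    def test_brute_force_on_random_instances_n20(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.uniform(0, 100, 20)
            for k in (2, 3):
                calls = ps.kmeans_1d(x, k)
                assert _calls_sse(x, calls) == pytest.approx(
                    _brute_force_sse(x, k), rel=1e-9
                )

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            ps.kmeans_1d([1.0, 2.0], k=3)

    def test_abundances_sum_to_one(self):
        rng = np.random.default_rng(8)
        calls = ps.kmeans_1d(rng.normal(size=100), k=3)
        assert sum(c.relative_abundance for c in calls) == pytest.approx(1.0, abs=1e-9)


class TestCallPopulations:
    @pytest.fixture()
    def curve(self):
        x = np.array([26860.0, 55620.0, 129200.0])
        y = np.array([2686.0, 5562.0, 12920.0])
        return ps.fit_calibration(list(zip(x, y)), condition="buffer_A")

    def test_calibration_point_cluster_sized_exactly(self, curve):
        calls = ps.call_populations([26860.0] * 50, k=1, curve=curve)
        assert calls[0].size_bp == pytest.approx(2686.0, abs=max(curve.residual_sd, 1.0))

    def test_monomer_dimer_mixture_sizes_within_error(self, curve):
        pops = [
            ps.PopulationSpec(size_bp=2684, fraction=0.88, intensity_cv=0.07),
            ps.PopulationSpec(size_bp=5368, fraction=0.12, intensity_cv=0.07),
        ]
        x = ps.gen_intensity_table(pops, 3000, seed=9)["intensity"].to_numpy()
        calls = ps.call_populations(x, k=2, curve=curve, condition="buffer_A")
        assert len(calls) == 2
        assert calls[0].size_bp == pytest.approx(2684, rel=0.10)
        assert calls[1].size_bp == pytest.approx(5368, rel=0.10)
        assert calls[0].relative_abundance == pytest.approx(0.88, abs=0.05)

    def test_condition_mismatch_warns(self, curve):
        with pytest.warns(UserWarning, match="condition"):
            ps.call_populations([1.0, 2.0, 3.0], k=1, curve=curve, condition="buffer_B")

    def test_matching_condition_silent(self, curve):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            ps.call_populations([1.0, 2.0, 3.0], k=1, curve=curve, condition="buffer_A")
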