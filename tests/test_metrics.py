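"""Surface-delivery metrics: thresholds, binning, dose-response slope."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfquant.metrics import (
    Thresholds,
    assign_bins,
    bin_sample,
    compute_sample_metrics,
    compute_threshold,
    define_bins,
    fit_esurface,
    flag_transfected,
    fraction_stained,
    mean_surface_signal,
    normalize_ab,
    sample_metrics,
    thresholds_from_controls,
)


def make_table(fp, ab, sample_id="s", replicate_id="r1", saturated=None):
    fp = np.asarray(fp, dtype=float)
    n = fp.size
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "replicate_id": replicate_id,
            "field_id": "f",
            "cell_id": np.arange(1, n + 1),
            "fp_cell": fp,
            "ab_cell": np.asarray(ab, dtype=float),
            "saturated": np.zeros(n, dtype=bool) if saturated is None else saturated,
        }
    )


class TestComputeThreshold:
    def test_constant_list(self):
        with pytest.warns(UserWarning):
            assert compute_threshold([5, 5, 5, 5], 0.995) == 5.0

    def test_order_statistic_oracle(self):
        """1..1000 at q=0.995: linear interpolation between sorted order
        statistics, computed brute-force."""
        values = np.arange(1, 1001, dtype=float)
        rng = np.random.default_rng(0)
        rng.shuffle(values)
        # brute-force oracle: sort, interpolate at h = (n-1) q
        s = np.sort(values)
        h = (len(s) - 1) * 0.995
        lo = int(np.floor(h))
        expected = s[lo] + (h - lo) * (s[lo + 1] - s[lo])
        assert expected == pytest.approx(995.005)
        assert compute_threshold(values, 0.995) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_exceedance_bound(self, seed):
        """Fraction of control values strictly above the threshold <= 1 - q
        (the probability a designated-transfected cell is untransfected)."""
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 5, size=2000)
        t = compute_threshold(values, 0.995)
        assert (values > t).mean() <= 0.005

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_threshold([], 0.995)

    def test_bad_quantile_errors(self):
        with pytest.raises(ValueError, match="quantile"):
            compute_threshold([1.0] * 200, 1.5)

    def test_pooled_controls(self):
        rng = np.random.default_rng(1)
        th = thresholds_from_controls(
            rng.normal(0, 5, 1000), rng.normal(0, 3, 800), quantile=0.99
        )
        assert th.n_mock_cells == 1000 and th.n_untagged_cells == 800
        assert th.quantile == 0.99


class TestFlagging:
    def test_all_below(self):
        t = flag_transfected(make_table([1, 2, 3], [0, 0, 0]), t_fp=10.0)
        assert t["transfected"].sum() == 0

    def test_strict_inequality(self):
        t = flag_transfected(make_table([1, 2, 3], [0, 0, 0]), t_fp=2.0)
        assert list(t["transfected"]) == [False, False, True]

    def test_saturated_never_transfected(self):
        t = make_table([100, 100], [0, 0], saturated=np.array([True, False]))
        t = flag_transfected(t, t_fp=1.0)
        assert list(t["transfected"]) == [False, True]

    def test_recovers_planted_fraction(self):
        from surfquant.synthetic import SyntheticConfig, simulate_cell_table

        cfg = SyntheticConfig(seed=42, n_cells=10_000, transfected_fraction=0.5)
        table = simulate_cell_table(cfg)
        t = flag_transfected(table, t_fp=compute_threshold(
            np.random.default_rng(0).normal(0, cfg.fp_background_sigma, 10_000), 0.995
        ))
        frac = t["transfected"].mean()
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(frac - 0.5) <= 3 * se


class TestFractionStained:
    def test_half_above(self):
        t = flag_transfected(make_table([10, 10, 10, 10], [1, 2, 3, 4]), 0.0)
        assert fraction_stained(t, t_ab=2.5) == 0.5

    def test_all_below_is_zero(self):
        t = flag_transfected(make_table([10, 10], [1, 2]), 0.0)
        assert fraction_stained(t, t_ab=2.0) == 0.0  # strict: equal not counted

    def test_no_transfected_is_nan(self):
        t = flag_transfected(make_table([1, 1], [5, 5]), t_fp=10.0)
        assert np.isnan(fraction_stained(t, t_ab=0.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        ab=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=50),
        t1=st.floats(-50, 50),
        t2=st.floats(-50, 50),
    )
    def test_monotone_in_threshold(self, ab, t1, t2):
        """f+ is monotone non-increasing in the stain threshold and in [0, 1]."""
        t = flag_transfected(make_table(np.full(len(ab), 10.0), ab), 0.0)
        lo, hi = min(t1, t2), max(t1, t2)
        f_lo, f_hi = fraction_stained(t, lo), fraction_stained(t, hi)
        assert 0.0 <= f_hi <= f_lo <= 1.0


class TestMeanAndNormalize:
    def test_symmetric_mean_zero(self):
        t = flag_transfected(make_table([10, 10], [-1, 1]), 0.0)
        assert mean_surface_signal(t) == 0.0

    def test_normalize_identity_and_half(self):
        assert normalize_ab(3.7, 3.7) == 1.0
        assert normalize_ab(2.0, 4.0) == 0.5

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_ab(1.0, 0.0)


class TestBins:
    def test_geometric_midpoint(self):
        np.testing.assert_allclose(
            define_bins([1.0, 100.0], n_bins=2), [1.0, 10.0, 100.0]
        )

    def test_equal_count_exact_split(self):
        rng = np.random.default_rng(0)
        fp = rng.lognormal(0, 1, 1000)
        edges = define_bins(fp, n_bins=10, mode="equal_count")
        idx = assign_bins(fp, edges)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        assert counts.sum() == 1000
        assert counts.max() - counts.min() <= 1

    @pytest.mark.parametrize("mode", ["log_spaced", "equal_count"])
    def test_assignment_matches_linear_scan_oracle(self, mode):
        """Every pooled cell lands in exactly one bin; assignment agrees with
        a brute-force linear scan over edges."""
        rng = np.random.default_rng(3)
        fp = rng.uniform(0.5, 200.0, 500)
        edges = define_bins(fp, n_bins=8, mode=mode)
        idx = assign_bins(fp, edges)

        def scan(v):
            if v == edges[-1]:
                return len(edges) - 2
            for i in range(len(edges) - 1):
                if edges[i] <= v < edges[i + 1]:
                    return i
            return -1

        expected = np.array([scan(v) for v in fp])
        np.testing.assert_array_equal(idx, expected)
        assert np.all(idx >= 0)
        # fp_bin means lie within their bin's edges
        table = flag_transfected(make_table(fp, fp), -np.inf)
        fp_bin, _, n_per_bin = bin_sample(table, edges)
        assert n_per_bin.sum() == 500
        for i, m in enumerate(fp_bin):
            if n_per_bin[i]:
                assert edges[i] <= m <= edges[i + 1]

    def test_too_few_bins_errors(self):
        with pytest.raises(ValueError):
            define_bins([1.0, 2.0, 3.0], n_bins=1)

    def test_nonpositive_values_dropped(self):
        edges = define_bins([-5.0, 0.0, 1.0, 2.0, 4.0, 8.0], n_bins=3)
        assert edges[0] == pytest.approx(1.0)


class TestFitEsurface:
    def test_identity_slope_one(self):
        fp = np.geomspace(1, 100, 10)
        slope, intercept, stderr, n = fit_esurface(fp, fp)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert n == 10

    def test_constant_slope_zero(self):
        fp = np.geomspace(1, 100, 10)
        slope, *_ = fit_esurface(fp, np.full(10, 5.0))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_power_law(self):
        fp = np.geomspace(1, 1000, 12)
        ab = 2.0 * fp**0.7
        slope, intercept, stderr, n = fit_esurface(fp, ab)
        assert slope == pytest.approx(0.7, abs=1e-12)
        assert intercept == pytest.approx(np.log(2.0), abs=1e-12)
        assert stderr == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_bins_excluded(self):
        fp = np.geomspace(1, 100, 6)
        ab = 3.0 * fp.copy()
        ab[0] = -1.0
        ab[1] = 0.0  # excluded too: log undefined at 0
        slope, _, _, n = fit_esurface(fp, ab)
        assert n == 4
        assert slope == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_bins_gives_nan(self):
        slope, intercept, stderr, n = fit_esurface([1.0, 2.0], [-1.0, 3.0])
        assert n == 1
        assert np.isnan(slope) and np.isnan(intercept)

    def test_base_and_scale_invariance(self):
        """Esurface is invariant under ab -> c*ab and fp -> d*fp, c, d > 0."""
        rng = np.random.default_rng(8)
        fp = np.geomspace(2, 500, 15)
        ab = 0.5 * fp**1.3 * rng.lognormal(0, 0.1, 15)
        s0, *_ = fit_esurface(fp, ab)
        s1, *_ = fit_esurface(7.3 * fp, 0.02 * ab)
        assert s1 == pytest.approx(s0, abs=1e-12)


class TestSampleMetrics:
    def _thresholds(self):
        return Thresholds(t_fp=10.0, t_ab=5.0)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        fp = rng.lognormal(4, 1, 500)
        ab = fp**0.9
        t = make_table(fp, ab)
        edges = define_bins(fp, n_bins=10)
        m1 = sample_metrics(t, self._thresholds(), edges)
        m2 = sample_metrics(t.copy(), self._thresholds(), edges)
        np.testing.assert_equal(vars(m1), vars(m2))  # NaN-tolerant equality

    def test_mixed_table_rejected(self):
        t = pd.concat([make_table([1], [1], "a"), make_table([1], [1], "b")])
        with pytest.raises(ValueError, match="single"):
            sample_metrics(t, self._thresholds(), np.array([1.0, 2.0, 4.0]))

    def test_reference_normalization(self):
        rng = np.random.default_rng(4)
        fp = rng.lognormal(4, 1, 2000)
        pos = make_table(fp, 2.0 * fp, sample_id="pos")
        dim = make_table(fp, 0.5 * fp, sample_id="dim")
        cells = pd.concat([pos, dim], ignore_index=True)
        out, _ = compute_sample_metrics(
            cells, self._thresholds(), n_bins=8, reference_sample="pos"
        )
        out = out.set_index("sample_id")
        assert out.loc["pos", "ab_mean_norm"] == pytest.approx(1.0)
        assert out.loc["dim", "ab_mean_norm"] == pytest.approx(0.25)

    def test_binning_partition_sums_to_transfected(self):
        rng = np.random.default_rng(9)
        fp = rng.lognormal(4, 1, 3000)
        cells = make_table(fp, fp)
        th = Thresholds(t_fp=0.0, t_ab=0.0)
        out, binned = compute_sample_metrics(cells, th, n_bins=12)
        key = ("s", "r1")
        # all fp are positive here, so the partition covers every transfected cell
        assert binned.n_per_bin[key].sum() == out["n_transfected"].iloc[0]

    def test_missing_reference_errors(self):
        cells = make_table(np.linspace(20.0, 100.0, 10), [1.0] * 10)
        with pytest.raises(ValueError, match="reference"):
            compute_sample_metrics(cells, self._thresholds(), n_bins=2,
                                   reference_sample="nope")
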