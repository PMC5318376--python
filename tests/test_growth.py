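"""BAI transform, windowed growth metrics and cross-dating QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendromort.growth import (
    BAISeries,
    GrowthMetricsError,
    estimate_pith_offset,
    growth_metrics,
    mean_ring_width,
    series_intercorrelation_qc,
    to_bai,
)
from dendromort.io_formats import RingWidthSeries


def series(widths_mm, start=2000, offset=0.0, tid="t"):
    return RingWidthSeries(
        tid, np.arange(start, start + len(widths_mm)), np.asarray(widths_mm),
        pith_offset_mm=offset,
    )


def bai_from_values(values, start=2000, tid="t"):
    values = np.asarray(values, dtype=float)
    radius = np.sqrt(np.cumsum(values) / np.pi)
    return BAISeries(tid, np.arange(start, start + values.size), values, radius)


class TestPithOffset:
    def test_exact_division(self):
        s = series([1.0] * 6)
        assert estimate_pith_offset(s, 5, distance_to_pith_mm=5.0) == (5.0, 5)

    def test_no_distance_means_zero(self):
        assert estimate_pith_offset(series([1.0] * 6)) == (0.0, 0)

    @pytest.mark.parametrize(
        "distance,expected", [(5.4, 5), (5.5, 6), (4.5, 4), (5.6, 6)]
    )
    def test_round_half_even(self, distance, expected):
        s = series([1.0] * 6)
        assert estimate_pith_offset(s, 5, distance_to_pith_mm=distance)[1] == expected

    def test_k_validation(self):
        with pytest.raises(ValueError):
            estimate_pith_offset(series([1.0] * 6), 0, distance_to_pith_mm=1.0)


class TestToBai:
    def test_hand_computed_annulus(self):
        # 10 mm then another 10 mm of radius: second ring pi*(2^2 - 1^2)
        b = to_bai(series([10.0, 10.0]))
        np.testing.assert_allclose(b.bai_cm2, [np.pi, 3 * np.pi])

    def test_zero_widths_give_zero_bai(self):
        b = to_bai(series([0.0] * 5))
        assert np.all(b.bai_cm2 == 0)

    def test_pith_offset_enters_radius(self):
        b = to_bai(series([10.0], offset=10.0))  # R goes 1 cm -> 2 cm
        np.testing.assert_allclose(b.bai_cm2, [3 * np.pi])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 8.0, allow_nan=False), min_size=1, max_size=150)
    )
    def test_conservation_telescoping(self, widths):
        b = to_bai(series(widths, start=1900))
        total = float(np.sum(b.bai_cm2))
        expected = np.pi * b.radius_cm[-1] ** 2
        assert total == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_split_and_reconcatenate_invariance(self, rng):
        widths = rng.uniform(0.1, 4.0, 60)
        full = to_bai(series(widths, start=1950))
        first = series(widths[:30], start=1950)
        second = series(
            widths[30:], start=1980, offset=float(np.sum(widths[:30]))
        )
        joined = np.concatenate([to_bai(first).bai_cm2, to_bai(second).bai_cm2])
        np.testing.assert_allclose(joined, full.bai_cm2, rtol=1e-9)


class TestGrowthMetrics:
    def test_exact_linear_case(self):
        years = np.arange(2000, 2015)
        values = 1.0 + 0.04 * (years - 2000)
        m = growth_metrics(bai_from_values(values), (2000, 2014))
        assert m.trend_cm2_per_yr == pytest.approx(0.04, abs=1e-12)
        assert m.a1 == pytest.approx(1.0, abs=1e-9)
        assert m.median_cm2 == pytest.approx(values[7])
        sd = np.std(values, ddof=1)
        assert m.cv_pct == pytest.approx(100 * sd / values.mean(), rel=1e-12)
        assert not m.partial

    def test_constant_series_degenerate_a1(self):
        m = growth_metrics(bai_from_values([2.0] * 10), (2000, 2009))
        assert m.cv_pct == 0.0
        assert m.trend_cm2_per_yr == pytest.approx(0.0, abs=1e-12)
        assert m.a1 == 0.0 and m.a1_degenerate

    def test_partial_window_flagged(self):
        # series ends 2013, window runs to 2014 (tree without the final ring)
        m = growth_metrics(bai_from_values(np.arange(1, 15.0)), (2000, 2014))
        assert m.partial
        assert m.n_years == 14

    def test_too_few_years_error(self):
        with pytest.raises(GrowthMetricsError):
            growth_metrics(bai_from_values([1.0, 2.0]), (2000, 2001))

    def test_zero_mean_cv_undefined(self):
        with pytest.raises(GrowthMetricsError, match="zero-mean"):
            growth_metrics(bai_from_values([0.0] * 5), (2000, 2004))

    def test_matches_first_principles_oracle(self, rng):
        """Windowed metrics equal a brute-force recomputation."""
        for _ in range(25):
            n = int(rng.integers(8, 40))
            values = rng.lognormal(1.0, 0.5, n)
            start = 2014 - n + 1
            b = bai_from_values(values, start=start)
            w0 = int(rng.integers(start, 2010))
            w1 = int(rng.integers(w0 + 4, 2015))
            sub = values[(np.arange(start, 2015) >= w0) & (np.arange(start, 2015) <= w1)]
            if sub.size < 3:
                continue
            m = growth_metrics(b, (w0, w1))
            yrs = np.arange(max(start, w0), min(2014, w1) + 1, dtype=float)
            # OLS slope from the normal equations
            slope = (
                np.sum((yrs - yrs.mean()) * (sub - sub.mean()))
                / np.sum((yrs - yrs.mean()) ** 2)
            )
            a1 = np.corrcoef(sub[1:], sub[:-1])[0, 1]
            assert m.median_cm2 == pytest.approx(float(np.median(sub)))
            assert m.cv_pct == pytest.approx(
                100 * np.std(sub, ddof=1) / sub.mean(), rel=1e-10
            )
            assert m.trend_cm2_per_yr == pytest.approx(slope, rel=1e-8)
            assert m.a1 == pytest.approx(a1, rel=1e-8)

    def test_ar1_recovery(self, rng):
        """Mean estimated lag-1 autocorrelation recovers phi = 0.5."""
        phi, n, reps = 0.5, 200, 400
        est = []
        for _ in range(reps):
            e = rng.normal(size=n)
            x = np.empty(n)
            x[0] = e[0] / np.sqrt(1 - phi**2)
            for i in range(1, n):
                x[i] = phi * x[i - 1] + e[i]
            b = bai_from_values(np.exp(0.1 * x) + 1.0, start=2015 - n)
            est.append(growth_metrics(b, (2015 - n, 2014)).a1)
        assert np.mean(est) == pytest.approx(phi, abs=0.05)


class TestMeanRingWidth:
    def test_arithmetic_means(self):
        assert mean_ring_width([series([0.5, 1.0])]) == pytest.approx(0.75)
        two = [series([1.0], tid="a"), series([2.0], tid="b")]
        assert mean_ring_width(two) == pytest.approx(1.5)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            mean_ring_width([])


class TestIntercorrelationQC:
    def test_identical_series_have_r_one(self, rng):
        w = rng.uniform(0.5, 2.0, 40)
        group = [series(w, start=1970, tid=f"t{i}") for i in range(4)]
        qc = series_intercorrelation_qc(group)
        assert np.allclose(qc["r"], 1.0)
        assert not qc["flagged"].any()

    def test_misdated_series_ranks_lowest(self, rng):
        signal = rng.uniform(0.5, 2.0, 60)
        group = [
            series(signal + rng.normal(0, 0.05, 60), start=1950, tid=f"g{i}")
            for i in range(5)
        ]
        # same widths shifted by one year: classic misdating
        group.append(series(signal, start=1951, tid="shifted"))
        qc = series_intercorrelation_qc(group).set_index("tree_id")
        assert qc["r"].idxmin() == "shifted"

    def test_white_noise_mean_r_near_zero(self, rng):
        group = [
            series(rng.uniform(0.2, 3.0, 80), start=1930, tid=f"w{i}")
            for i in range(20)
        ]
        qc = series_intercorrelation_qc(group, threshold=-1.0)
        assert abs(qc["r"].mean()) < 0.1

    def test_short_overlap_unassessable(self, rng):
        group = [series(rng.uniform(1, 2, 40), start=1970, tid=f"t{i}") for i in range(3)]
        group.append(series([1.0] * 5, start=2010, tid="short"))
        qc = series_intercorrelation_qc(group).set_index("tree_id")
        assert not qc.loc["short", "assessable"]
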