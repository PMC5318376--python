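"""Drift-diffusion-jump estimation, standardization, bands and transitions."""

import numpy as np
import pandas as pd
import pytest

from dendromort.ddj_ews import (
    METRICS,
    DDJError,
    DDJResult,
    cohort_ddj,
    ddj_metrics,
    detect_transition,
    ensemble_bands,
    log1p_bai,
    standardize_01,
)
from dendromort.synthetic_data import simulate_ddj_process


class TestSimulateProcess:
    def test_deterministic_under_seed(self):
        a = simulate_ddj_process(n_steps=100, seed=3)
        b = simulate_ddj_process(n_steps=100, seed=3)
        np.testing.assert_array_equal(a, b)
        c = simulate_ddj_process(n_steps=100, seed=4)
        assert not np.array_equal(a, c)

    def test_jump_free_increment_variance(self):
        x = simulate_ddj_process(diffusion_sigma=2.0, n_steps=50_000, seed=1)
        assert np.var(np.diff(x)) == pytest.approx(4.0, rel=0.05)

    def test_jumps_fatten_tails(self):
        from scipy import stats

        x = simulate_ddj_process(
            diffusion_sigma=1.0, jump_rate=0.1, jump_sd=5.0,
            n_steps=100_000, seed=2,
        )
        assert stats.kurtosis(np.diff(x), fisher=False) > 3.5

    def test_drift_function_applied(self):
        x = simulate_ddj_process(
            drift_fn=lambda v: -0.5 * v, diffusion_sigma=0.0,
            n_steps=30, x0=8.0, seed=0,
        )
        np.testing.assert_allclose(x[:4], [8.0, 4.0, 2.0, 1.0])

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_ddj_process(jump_rate=1.5, n_steps=50)
        with pytest.raises(ValueError):
            simulate_ddj_process(n_steps=10)


class TestDDJMetrics:
    def test_constant_series_undefined(self):
        with pytest.raises(DDJError, match="zero-variance"):
            ddj_metrics(np.ones(40))

    def test_short_series_rejected(self):
        with pytest.raises(DDJError):
            ddj_metrics(np.random.default_rng(0).normal(size=10))

    def test_time_axis_drops_final_year(self):
        x = simulate_ddj_process(n_steps=40, seed=5)
        years = np.arange(1970, 1970 + x.size)
        res = ddj_metrics(x, years)
        np.testing.assert_array_equal(res.years, years[:-1])

    def test_conditional_variance_identity_on_grid(self):
        x = simulate_ddj_process(n_steps=500, seed=6)
        res = ddj_metrics(x)
        gm = res.grid_metrics
        np.testing.assert_allclose(
            gm["conditional_variance_raw"],
            gm["total_variance"] - gm["drift"] ** 2,
            rtol=1e-12,
        )

    def test_translation_invariance(self):
        x = simulate_ddj_process(n_steps=300, seed=7)
        a = ddj_metrics(x)
        b = ddj_metrics(x + 100.0)
        for m in METRICS:
            np.testing.assert_allclose(
                a.series_metrics[m], b.series_metrics[m], atol=1e-9
            )

    def test_jump_free_random_walk_recovery(self):
        sigma = 1.3
        x = simulate_ddj_process(diffusion_sigma=sigma, n_steps=2000, seed=8)
        res = ddj_metrics(x)
        assert not res.jumps_detected
        est = np.mean(res.series_metrics["diffusion2"])
        assert est == pytest.approx(sigma**2, rel=0.15)
        assert np.all(res.series_metrics["jump_intensity"] == 0)
        # without jumps, total variance ~ diffusion^2
        gap = np.mean(res.series_metrics["total_variance"]) - est
        assert abs(gap) / sigma**2 < 0.1

    def test_jump_recovery_and_variance_inflation(self):
        xf = simulate_ddj_process(diffusion_sigma=1.0, n_steps=5000, seed=9)
        xj = simulate_ddj_process(
            diffusion_sigma=1.0, jump_rate=0.1, jump_sd=5.0,
            n_steps=5000, seed=9,
        )
        free = ddj_metrics(xf)
        jump = ddj_metrics(xj)
        assert jump.jumps_detected
        lam = np.mean(jump.series_metrics["jump_intensity"])
        assert 0.05 <= lam <= 0.15
        assert np.mean(jump.series_metrics["conditional_variance"]) > np.mean(
            free.series_metrics["conditional_variance"]
        )


class TestStandardize:
    def test_linear_map(self):
        np.testing.assert_allclose(standardize_01([2, 4, 6]), [0, 0.5, 1])

    def test_already_unit_range_unchanged(self):
        x = np.array([0.0, 0.25, 1.0])
        np.testing.assert_array_equal(standardize_01(x), x)

    def test_postcondition_min_zero_max_one(self, rng):
        s = standardize_01(rng.normal(size=50))
        assert s.min() == 0.0 and s.max() == 1.0

    def test_constant_series_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = standardize_01([3.0, 3.0, 3.0])
        assert np.all(out == 0)


def _fake_result(years, **metrics) -> DDJResult:
    n = len(years)
    base = {m: np.linspace(1, 2, n) for m in METRICS}
    base.update({k: np.asarray(v, dtype=float) for k, v in metrics.items()})
    return DDJResult(
        years=np.asarray(years), states=np.linspace(0, 1, n),
        grid=np.linspace(0, 1, 10), bandwidth=0.1, jumps_detected=False,
        grid_metrics={}, series_metrics=base,
    )


class TestEnsembleBands:
    def test_identical_series_collapse_to_median(self):
        years = np.arange(1970, 2014)
        results = [_fake_result(years) for _ in range(5)]
        bands = ensemble_bands(results)
        sub = bands[bands["metric"] == "diffusion2"]
        np.testing.assert_allclose(sub["q10"], sub["median"])
        np.testing.assert_allclose(sub["q90"], sub["median"])

    def test_symmetric_shifts_leave_median_at_base(self, rng):
        years = np.arange(1970, 2014)
        base = np.cumsum(rng.uniform(0.1, 1, years.size))
        results = [
            _fake_result(years, diffusion2=base + c) for c in (-2, -1, 0, 1, 2)
        ]
        bands = ensemble_bands(results)
        sub = bands[bands["metric"] == "diffusion2"].sort_values("year")
        np.testing.assert_allclose(
            sub["median"].to_numpy(), standardize_01(base), atol=1e-12
        )

    def test_misaligned_axes_rejected(self):
        a = _fake_result(np.arange(1970, 2000))
        b = _fake_result(np.arange(2001, 2031))
        with pytest.raises(DDJError, match="misaligned"):
            ensemble_bands([a, b, a])

    def test_needs_three_trees(self):
        a = _fake_result(np.arange(1970, 2000))
        with pytest.raises(DDJError):
            ensemble_bands([a, a])


class TestDetectTransition:
    def test_monotone_increasing_is_no_transition(self):
        years = np.arange(1970, 2014)
        res = _fake_result(years, diffusion2=np.linspace(0.1, 1.0, years.size))
        assert detect_transition(res).no_transition

    def test_step_down_located_exactly(self):
        years = np.arange(1970, 2014)
        diffusion = np.where(years < 1998, 1.0, 0.2)
        res = _fake_result(
            years, diffusion2=diffusion,
            conditional_variance=np.where(years == 1995, 2.0, 1.0),
        )
        res.states = diffusion.astype(float)  # state follows the same step
        report = detect_transition(res)
        assert report.diffusion_drop_year == 1998
        assert report.cond_var_peak_year == 1995
        # the least-squares knot of a ramp fit leads a hard step slightly
        assert 1988 <= report.suggested_window_start <= 1998

    def test_reference_removes_shared_signal(self, rng):
        """A shared wiggle is not an onset once the reference absorbs it."""
        years = np.arange(1970, 2014)
        common = np.cumsum(rng.normal(0, 0.05, years.size))
        decline = -0.04 * np.clip(years - 2000, 0, None)
        target = _fake_result(years, diffusion2=np.ones(years.size))
        target.states = 1.0 + common + decline
        ref = _fake_result(years, diffusion2=np.ones(years.size))
        ref.states = 2.0 + common
        # make the diffusion trajectory show some decline so detection runs
        target.series_metrics["diffusion2"] = 1.0 + 0.3 * (target.states - 1.0)
        report = detect_transition(target, reference=ref)
        assert not report.no_transition
        assert abs(report.suggested_window_start - 2000) <= 2


class TestCohort:
    def test_single_tree_cohort_matches_direct(self):
        x = log1p_bai(np.exp(simulate_ddj_process(n_steps=60, seed=11) * 0.1) * 3)
        years = np.arange(1950, 1950 + x.size)
        single = ddj_metrics(x, years)
        pooled = cohort_ddj([(years, x)])
        for m in METRICS:
            np.testing.assert_allclose(
                pooled.series_metrics[m], single.series_metrics[m], rtol=1e-9
            )

    def test_disjoint_cohort_rejected(self):
        a = (np.arange(1950, 1990), np.random.default_rng(0).normal(size=40))
        b = (np.arange(2000, 2040), np.random.default_rng(1).normal(size=40))
        with pytest.raises(DDJError):
            cohort_ddj([a, b])

    def test_log1p_rejects_negative(self):
        with pytest.raises(DDJError):
            log1p_bai([-1.0, 2.0])
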