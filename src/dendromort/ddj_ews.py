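"""Non-parametric drift-diffusion-jump (DDJ) early-warning metrics.

A growth series (log(BAI+1), annual step) is treated as a realisation of
an unknown stochastic process

    dx = f(x) dt + g(x) dW + J dN

with deterministic drift f, Gaussian diffusion g, and intermittent jumps J
arriving at intensity lambda. All components are estimated without a
parametric model: the conditional moments of the increments
M_k(x) = E[(dx)^k | x] are obtained by Gaussian-kernel regression of
increment powers on the state, evaluated on a grid spanning the observed
states.

From the moments: drift = M1; total variance = M2; conditional variance =
M2 - M1^2 (rises approaching a critical transition). Jumps and diffusion
are separated by matching the 2nd, 4th and 6th *central* conditional
moments of the increments to a two-component Gaussian mixture (diffusion
noise of variance s2, plus a jump of variance s2 + sJ2 occurring with
probability lambda per step). This is an exact moment match at the annual
sampling step of tree-ring data — the small-timestep limits that divide
higher moments by the 4th/6th-moment jump ratios misattribute all variance
to jumps when increments are close to Gaussian, so jump terms are only
activated when a one-sided kurtosis test on the increments finds heavier
than Gaussian tails (default alpha 0.01). Negative variance estimates are
clipped to zero and counted.

Per-time-point trajectories are the grid estimates evaluated at each
observed state, so the output time axis is the input years minus the final
year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: metric columns reported per time point / grid point
METRICS = (
    "drift",
    "total_variance",
    "conditional_variance",
    "diffusion2",
    "jump_intensity",
    "jump_magnitude_variance",
)

MIN_POINTS = 25


class DDJError(ValueError):
    pass


@dataclass
class DDJResult:
    """DDJ estimates on the state grid and along the observed trajectory."""

    years: np.ndarray          # input years minus the final year
    states: np.ndarray         # x_t at those years
    grid: np.ndarray
    bandwidth: float
    jumps_detected: bool
    grid_metrics: dict[str, np.ndarray] = field(default_factory=dict)
    series_metrics: dict[str, np.ndarray] = field(default_factory=dict)
    n_clipped: int = 0

    def standardized(self, metric: str) -> np.ndarray:
        v = self.series_metrics[metric]
        if np.nanmax(v) == np.nanmin(v):  # e.g. jump intensity without jumps
            return np.zeros_like(v)
        return standardize_01(v)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.years, "state": self.states})
        for m in METRICS:
            df[m] = self.series_metrics[m]
        return df


@dataclass
class TransitionReport:
    no_transition: bool
    cond_var_peak_year: int | None = None
    diffusion_drop_year: int | None = None
    suggested_window_start: int | None = None


def log1p_bai(bai_cm2) -> np.ndarray:
    """The log(BAI + 1) transform applied before DDJ estimation."""
    x = np.asarray(bai_cm2, dtype=float)
    if np.any(x < 0):
        raise DDJError("negative BAI")
    return np.log1p(x)


def standardize_01(series) -> np.ndarray:
    """Map a series linearly onto [0, 1]; constant input becomes all zeros."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise DDJError("need >= 2 values to standardize")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        warnings.warn("constant series standardized to all zeros", stacklevel=2)
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Estimation internals
# ---------------------------------------------------------------------------

def _kernel_moments(x0, dx, grid, bw):
    k = np.exp(-0.5 * ((grid[:, None] - x0[None, :]) / bw) ** 2)
    w = k / k.sum(axis=1, keepdims=True)
    m1 = w @ dx
    m2 = w @ dx**2
    resid = dx - np.interp(x0, grid, m1)
    m2c = w @ resid**2
    m4c = w @ resid**4
    m6c = w @ resid**6
    return m1, m2, m2c, m4c, m6c


def _jump_decomposition(m2c, m4c, m6c, jumps_detected):
    """Two-point moment match of the conditional increment-variance mixture.

    The increment variance V is treated as two-valued: s2 (no jump, prob
    1-lambda) and s2 + sJ2 (jump, prob lambda). Matching E[V] = M2c,
    E[V^2] = M4c/3, E[V^6]... E[V^3] = M6c/15 identifies (s2, sJ2, lambda)
    exactly; with the jump gate closed everything is diffusion.
    """
    if not jumps_detected:
        return m2c.copy(), np.zeros_like(m2c), np.zeros_like(m2c)
    mu = m2c
    ev2 = m4c / 3.0
    ev3 = m6c / 15.0
    s2_spread = np.clip(ev2 - mu**2, 0.0, None)          # Var(V)
    g3 = ev3 - 3.0 * mu * ev2 + 2.0 * mu**3              # 3rd central moment
    lam = np.zeros_like(mu)
    sj2 = np.zeros_like(mu)
    diff2 = mu.copy()
    active = s2_spread > 1e-12 * np.maximum(mu**2, 1e-300)
    if np.any(active):
        g = g3[active] / s2_spread[active] ** 1.5
        lam_a = 0.5 * (1.0 - g / np.sqrt(4.0 + g**2))
        lam_a = np.clip(lam_a, 1e-6, 1.0 - 1e-6)
        spread = np.sqrt(s2_spread[active] / (lam_a * (1.0 - lam_a)))
        low = mu[active] - lam_a * spread                # diffusion variance
        lam[active] = lam_a
        sj2[active] = spread
        diff2[active] = np.clip(low, 0.0, None)
    return diff2, sj2, lam


def _estimate(
    x0: np.ndarray,
    dx: np.ndarray,
    bandwidth: float | None,
    bandwidth_frac: float,
    grid_size: int,
    jump_alpha: float,
):
    sd = float(np.std(x0, ddof=1))
    if sd == 0:
        raise DDJError("zero-variance series; DDJ metrics undefined")
    bw = bandwidth if bandwidth is not None else bandwidth_frac * sd
    grid = np.linspace(float(np.min(x0)), float(np.max(x0)), grid_size)
    m1, m2, m2c, m4c, m6c = _kernel_moments(x0, dx, grid, bw)

    kt_stat, kt_p = stats.kurtosistest(dx, alternative="greater")
    jumps_detected = bool(kt_p < jump_alpha)
    diff2, sj2, lam = _jump_decomposition(m2c, m4c, m6c, jumps_detected)

    cond_var = m2 - m1**2
    n_clipped = int(np.sum(cond_var < 0))
    cond_var_clipped = np.clip(cond_var, 0.0, None)
    grid_metrics = {
        "drift": m1,
        "total_variance": m2,
        "conditional_variance": cond_var_clipped,
        "conditional_variance_raw": cond_var,
        "diffusion2": diff2,
        "jump_intensity": lam,
        "jump_magnitude_variance": sj2,
    }
    return grid, bw, jumps_detected, grid_metrics, n_clipped


def _evaluate_at(grid, grid_metrics, states):
    return {
        m: np.interp(states, grid, grid_metrics[m])
        for m in METRICS
    }


def ddj_metrics(
    x,
    years=None,
    bandwidth: float | None = None,
    bandwidth_frac: float = 0.3,
    grid_size: int = 100,
    jump_alpha: float = 0.01,
) -> DDJResult:
    """DDJ metrics of one (already log+1 transformed) series.

    ``bandwidth`` defaults to ``bandwidth_frac`` times the SD of the states.
    """
    x = np.asarray(x, dtype=float)
    if x.size < MIN_POINTS:
        raise DDJError(f"need >= {MIN_POINTS} points, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DDJError("non-finite values")
    years = (
        np.arange(x.size) if years is None else np.asarray(years, dtype=int)
    )
    if years.size != x.size:
        raise DDJError("years/series length mismatch")
    x0, dx = x[:-1], np.diff(x)
    grid, bw, jumps, gm, n_clip = _estimate(
        x0, dx, bandwidth, bandwidth_frac, grid_size, jump_alpha
    )
    return DDJResult(
        years=years[:-1],
        states=x0,
        grid=grid,
        bandwidth=bw,
        jumps_detected=jumps,
        grid_metrics=gm,
        series_metrics=_evaluate_at(grid, gm, x0),
        n_clipped=n_clip,
    )


def cohort_ddj(
    series: list[tuple[np.ndarray, np.ndarray]],
    bandwidth: float | None = None,
    bandwidth_frac: float = 0.3,
    grid_size: int = 100,
    jump_alpha: float = 0.01,
) -> DDJResult:
    """Pooled DDJ estimate for a cohort of trees sharing one dynamic.

    All (state, increment) pairs of the cohort enter one kernel regression,
    trading per-tree resolution for much lower estimator variance. The
    per-time-point trajectory evaluates the pooled grid estimates at the
    cohort's median state in each year.

    ``series`` is a list of ``(years, x)`` pairs (x already log+1
    transformed); series may end in different years (trees dying earlier)
    but must overlap in a common calendar span.
    """
    if not series:
        raise DDJError("empty cohort")
    frames = []
    for years, x in series:
        years = np.asarray(years, dtype=int)
        x = np.asarray(x, dtype=float)
        if years.size != x.size:
            raise DDJError("years/series length mismatch")
        frames.append(pd.Series(x, index=years))
    mat = pd.DataFrame({i: s for i, s in enumerate(frames)})
    if mat.dropna(how="any").empty:
        raise DDJError("cohort series have no common years")
    x0_all, dx_all = [], []
    for s in frames:
        v = s.to_numpy()
        x0_all.append(v[:-1])
        dx_all.append(np.diff(v))
    x0 = np.concatenate(x0_all)
    dx = np.concatenate(dx_all)
    if x0.size < MIN_POINTS:
        raise DDJError("cohort too small for DDJ estimation")
    grid, bw, jumps, gm, n_clip = _estimate(
        x0, dx, bandwidth, bandwidth_frac, grid_size, jump_alpha
    )
    median_state = mat.median(axis=1)
    years_out = median_state.index.to_numpy()[:-1]
    states_out = median_state.to_numpy()[:-1]
    return DDJResult(
        years=years_out,
        states=states_out,
        grid=grid,
        bandwidth=bw,
        jumps_detected=jumps,
        grid_metrics=gm,
        series_metrics=_evaluate_at(grid, gm, states_out),
        n_clipped=n_clip,
    )


# ---------------------------------------------------------------------------
# Multi-tree summaries and transition detection
# ---------------------------------------------------------------------------

def ensemble_bands(
    results: list[DDJResult],
    metrics: tuple[str, ...] = METRICS,
    min_trees: int = 3,
) -> pd.DataFrame:
    """Median and 10-90% / 40-60% quantile bands across trees, per metric.

    Each tree's metric trajectory is standardized to [0, 1] before
    aggregation so that trees of different growth level are comparable,
    matching how the trajectories are displayed. Years covered by fewer
    than 3 trees are dropped; cohorts whose time axes never overlap are an
    error.
    """
    if len(results) < min_trees:
        raise DDJError(f"need >= {min_trees} trees for ensemble bands")
    all_years = [set(r.years.tolist()) for r in results]
    if not set.intersection(*all_years):
        raise DDJError("misaligned time axes: no common years across trees")
    rows = []
    for metric in metrics:
        frame = pd.DataFrame(
            {
                i: pd.Series(r.standardized(metric), index=r.years)
                for i, r in enumerate(results)
            }
        )
        counts = frame.notna().sum(axis=1)
        frame = frame.loc[counts >= 3]
        q = frame.quantile([0.1, 0.4, 0.5, 0.6, 0.9], axis=1).T
        for year, row in q.iterrows():
            rows.append(
                {
                    "year": int(year),
                    "metric": metric,
                    "median": row[0.5],
                    "q10": row[0.1],
                    "q90": row[0.9],
                    "q40": row[0.4],
                    "q60": row[0.6],
                    "n_trees": int(counts.loc[year]),
                }
            )
    return pd.DataFrame(rows).sort_values(["metric", "year"]).reset_index(drop=True)


def _broken_stick_start(
    years: np.ndarray, y: np.ndarray, reference: np.ndarray | None = None
) -> tuple[int | None, float]:
    """Flat-then-linear changepoint: year where a sustained decline begins.

    With a ``reference`` trajectory (a control cohort sharing the common
    climate signal), the level term is replaced by a regression on the
    reference, so shared year-to-year variability does not masquerade as
    a decline onset.
    """
    n = y.size
    best = (None, np.inf, 0.0)
    for ci in range(2, n - 3):
        z = np.clip(np.arange(n) - ci, 0, None).astype(float)
        cols = [np.ones(n)]
        if reference is not None:
            cols.append(reference)
        cols.append(z)
        design = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sse = float(resid @ resid)
        if sse < best[1] - 1e-15:
            best = (ci, sse, float(coef[-1]))
    ci, _, slope = best
    if ci is None or slope >= 0:
        return None, slope if ci is not None else 0.0
    return int(years[ci]), slope


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(ypad, kernel, mode="valid")[: y.size]


def detect_transition(
    result: DDJResult | pd.DataFrame,
    smooth_window: int = 1,
    reference: DDJResult | None = None,
) -> TransitionReport:
    """Locate the growth transition in the DDJ trajectories.

    Reports the year of maximum conditional variance, the year of steepest
    decline of the (optionally smoothed) diffusion series, and a suggested
    start year for the growth-trend window of the mortality models: the
    changepoint of a flat-then-declining fit to the cohort's state
    trajectory — the growth level whose collapse drives the diffusion
    drop. When a ``reference`` cohort is supplied (the living trees of the
    paired design), its state trajectory is regressed out first so the
    climate signal shared by both cohorts cannot masquerade as an onset.
    Flat or monotonically rising diffusion yields a no-transition report.
    """
    ref_states = None
    if isinstance(result, pd.DataFrame):
        diff = result[result["metric"] == "diffusion2"].sort_values("year")
        cond = result[result["metric"] == "conditional_variance"].sort_values("year")
        years = diff["year"].to_numpy(dtype=int)
        diffusion = diff["median"].to_numpy(dtype=float)
        cond_years = cond["year"].to_numpy(dtype=int)
        cond_var = cond["median"].to_numpy(dtype=float)
        states = None
    else:
        years = result.years
        diffusion = result.series_metrics["diffusion2"]
        cond_years = result.years
        cond_var = result.series_metrics["conditional_variance"]
        states = result.states
        if reference is not None:
            aligned = pd.Series(reference.states, index=reference.years).reindex(
                years
            )
            if aligned.notna().all():
                ref_states = aligned.to_numpy()
    if years.size < 5:
        raise DDJError("too few time points for transition detection")

    smooth = _moving_average(diffusion, smooth_window)
    drops = np.diff(smooth)
    if np.ptp(smooth) < 1e-12 or np.min(drops) >= 0:
        return TransitionReport(no_transition=True)

    drop_year = int(years[int(np.argmin(drops)) + 1])
    peak_year = int(cond_years[int(np.argmax(cond_var))])
    if states is not None:
        start, _slope = _broken_stick_start(years, states, ref_states)
    else:
        start, _slope = _broken_stick_start(years, smooth)
    if start is None:
        start = drop_year
    return TransitionReport(
        no_transition=False,
        cond_var_peak_year=peak_year,
        diffusion_drop_year=drop_year,
        suggested_window_start=start,
    )
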