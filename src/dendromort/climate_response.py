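"""Drought-growth correlation analysis over pre-dieback and dieback periods.

Raw BAI of each tree is correlated (Pearson) with an annual drought-index
value — by convention a single month/time-scale column such as the May
value of a 10-month SPEI — over two equally long windows: one before the
dieback onset (default 1950-1981) and one spanning it (default 1982-2013).
Group contrasts of the per-tree correlations use the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growth import BAISeries
from .io_formats import DroughtIndexSeries, ValidationError
from .stats_tests import TestResult, mann_whitney_u, pearson_correlation


@dataclass
class ResponseWindowSpec:
    pre_period: tuple[int, int] = (1950, 1981)
    dieback_period: tuple[int, int] = (1982, 2013)
    index_label: str = "May SPEI (10-month)"

    def __post_init__(self) -> None:
        p, d = self.pre_period, self.dieback_period
        if (p[1] - p[0]) != (d[1] - d[0]):
            raise ValidationError("response periods must have equal length")
        if not (p[1] < d[0] or d[1] < p[0]):
            raise ValidationError("response periods must not overlap")

    @property
    def periods(self) -> dict[str, tuple[int, int]]:
        return {"pre": tuple(self.pre_period), "dieback": tuple(self.dieback_period)}


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical Pearson r at sample size n (t transform, n-2 df)."""
    if n < 3:
        raise ValueError("n must be >= 3")
    t = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return float(t / np.sqrt(t**2 + n - 2))


def drought_growth_correlations(
    bai_list: list[BAISeries],
    index: DroughtIndexSeries,
    spec: ResponseWindowSpec | None = None,
    min_coverage: float = 0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-tree, per-period Pearson correlations of raw BAI with the index.

    Trees covering less than ``min_coverage`` of a period are flagged and
    excluded from group summaries. The output's ``attrs`` carry the
    computed two-sided critical r for the full period length.
    """
    spec = spec or ResponseWindowSpec()
    rows = []
    for name, (start, end) in spec.periods.items():
        period_years = np.arange(start, end + 1)
        idx_vals = index.value_for_years(period_years)  # raises on gaps
        idx_series = pd.Series(idx_vals, index=period_years)
        for bai in bai_list:
            sub = bai.window(start, end)
            coverage = sub.years.size / period_years.size
            row = {
                "tree_id": bai.tree_id,
                "period": name,
                "start": start,
                "end": end,
                "n": int(sub.years.size),
                "coverage": coverage,
            }
            if coverage < min_coverage or sub.years.size < 3:
                row.update({"r": np.nan, "p_value": np.nan, "flagged": True})
            else:
                try:
                    res = pearson_correlation(
                        sub.bai_cm2, idx_series.loc[sub.years].to_numpy()
                    )
                    row.update(
                        {"r": res.statistic, "p_value": res.p_value, "flagged": False}
                    )
                except ValueError:
                    row.update({"r": np.nan, "p_value": np.nan, "flagged": True})
            rows.append(row)
    df = pd.DataFrame(rows)
    n_full = spec.pre_period[1] - spec.pre_period[0] + 1
    df.attrs["critical_r"] = critical_r(n_full, alpha=alpha)
    df.attrs["critical_r_n"] = n_full
    df.attrs["index_label"] = spec.index_label
    return df


def compare_group_responses(r_living, r_dead) -> TestResult:
    """Mann-Whitney contrast of living vs dead per-tree correlations."""
    r_living = np.asarray(r_living, dtype=float)
    r_dead = np.asarray(r_dead, dtype=float)
    r_living = r_living[np.isfinite(r_living)]
    r_dead = r_dead[np.isfinite(r_dead)]
    if r_living.size < 3 or r_dead.size < 3:
        raise ValueError("need >= 3 finite correlations per group")
    res = mann_whitney_u(r_living, r_dead)
    res.extra["direction"] = (
        "living_higher"
        if np.median(r_living) > np.median(r_dead)
        else "dead_higher_or_equal"
    )
    return res
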