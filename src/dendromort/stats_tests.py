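"""Non-parametric tests and correlation machinery.

Thin, contract-enforcing wrappers around the scipy.stats implementations:
two-sided throughout, exact null distributions on small tie-free samples
(Mann-Whitney when n1+n2 <= 20, Wilcoxon signed-rank when n <= 25), and
normal approximations with midrank tie corrections otherwise. No
multiple-testing correction is applied anywhere; output metadata says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .growth import BAISeries

#: metadata attached to serialized outputs
MULTIPLE_TESTING_NOTE = "no multiple-testing correction applied"


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    alternative: str = "two-sided"
    exact: bool = False
    extra: dict = field(default_factory=dict)


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test; statistic is U of the first sample.

    Exact null when n1 + n2 <= 20 and the pooled sample is tie-free,
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    exact = (x.size + y.size) <= 20 and not _has_ties(np.concatenate([x, y]))
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="mann_whitney_u",
        n=(int(x.size), int(y.size)),
        exact=exact,
    )


def wilcoxon_signed_rank(paired_diff) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (their count is reported); the statistic
    is W+, the sum of the midranks of the positive differences. Exact null
    for n <= 25 without tied magnitudes, else normal approximation with
    continuity correction.
    """
    d = np.asarray(paired_diff, dtype=float)
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    exact = d.size <= 25 and not _has_ties(np.abs(d))
    res = stats.wilcoxon(
        d,
        alternative="two-sided",
        correction=not exact,
        method="exact" if exact else "approx",
    )
    return TestResult(
        statistic=w_plus,
        p_value=float(res.pvalue),
        method="wilcoxon_signed_rank",
        n=(int(d.size),),
        exact=exact,
        extra={"n_zero_dropped": n_zero},
    )


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with the two-sided t-transform p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples differ in length")
    if x.size < 3:
        raise ValueError("Pearson correlation requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    res = stats.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="pearson",
        n=(int(x.size),),
    )


def per_year_paired_comparison(
    living: list[BAISeries],
    dead: list[BAISeries],
    couples: list[tuple[str, str]],
    alpha: float = 0.05,
    min_couples: int = 6,
) -> pd.DataFrame:
    """Per-year paired Wilcoxon tests of living vs dead BAI across couples.

    For every calendar year with at least ``min_couples`` couples holding
    data on both sides, the signed-rank test is applied to the living-dead
    differences. A year is flagged when p < alpha *and* the median paired
    difference favours the living trees, mirroring the study's shaded
    "living significantly higher" periods. Years with too few couples are
    marked unassessable.
    """
    if not couples:
        raise ValueError("no couples supplied")
    liv = {b.tree_id: pd.Series(b.bai_cm2, index=b.years) for b in living}
    ded = {b.tree_id: pd.Series(b.bai_cm2, index=b.years) for b in dead}
    years = sorted(
        set().union(*(set(s.index) for s in liv.values()), *(set(s.index) for s in ded.values()))
    )
    rows = []
    for year in years:
        diffs = []
        for lid, did in couples:
            lv = liv.get(lid)
            dv = ded.get(did)
            if lv is None or dv is None:
                continue
            if year in lv.index and year in dv.index:
                diffs.append(float(lv[year] - dv[year]))
        n = len(diffs)
        if n < min_couples or all(d == 0 for d in diffs):
            rows.append(
                {"year": year, "n_couples": n, "statistic": np.nan,
                 "p_value": np.nan, "living_higher": np.nan,
                 "significant": False, "assessable": False}
            )
            continue
        res = wilcoxon_signed_rank(diffs)
        living_higher = bool(np.median(diffs) > 0)
        rows.append(
            {"year": year, "n_couples": n, "statistic": res.statistic,
             "p_value": res.p_value, "living_higher": living_higher,
             "significant": bool(res.p_value < alpha and living_higher),
             "assessable": True}
        )
    df = pd.DataFrame(rows)
    df.attrs["note"] = MULTIPLE_TESTING_NOTE
    return df


def significant_periods(per_year: pd.DataFrame) -> list[tuple[int, int]]:
    """Contiguous runs of significant years, as inclusive (start, end) pairs."""
    years = per_year.loc[per_year["significant"], "year"].astype(int).tolist()
    periods: list[tuple[int, int]] = []
    for y in years:
        if periods and y == periods[-1][1] + 1:
            periods[-1] = (periods[-1][0], y)
        else:
            periods.append((y, y))
    return periods
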