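"""Basal area increment and windowed growth metrics.

The central transform is ring width -> basal area increment (BAI),

    BAI_t = pi * (R_t^2 - R_{t-1}^2)   [cm^2 yr^-1]

with the radius reconstructed by accumulating ring widths on top of the
pith offset. BAI is a size-standardised proxy of biomass growth; no
detrending or chronology standardisation is applied, all metrics operate
on raw BAI.

Windowed metrics per tree: the median, the coefficient of variation
(sample SD, in percent of the mean), the OLS slope of BAI on calendar year,
and the lag-1 autocorrelation computed as the Pearson correlation of the
(BAI_t, BAI_{t-1}) pairs inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import RingWidthSeries, ValidationError


class GrowthMetricsError(ValueError):
    """Metrics are undefined for this series/window combination."""


@dataclass
class BAISeries:
    """Per-year basal area increment (cm^2) with the cumulative radius (cm)."""

    tree_id: str
    years: np.ndarray
    bai_cm2: np.ndarray
    radius_cm: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.bai_cm2 = np.asarray(self.bai_cm2, dtype=float)
        self.radius_cm = np.asarray(self.radius_cm, dtype=float)

    def window(self, start: int, end: int) -> "BAISeries":
        mask = (self.years >= start) & (self.years <= end)
        return BAISeries(
            self.tree_id, self.years[mask], self.bai_cm2[mask], self.radius_cm[mask]
        )


@dataclass
class GrowthMetrics:
    """Windowed BAI summary for one tree."""

    tree_id: str
    window: tuple[int, int]
    median_cm2: float
    cv_pct: float
    trend_cm2_per_yr: float
    a1: float
    n_years: int
    partial: bool = False
    a1_degenerate: bool = False


def estimate_pith_offset(
    series: RingWidthSeries,
    k_innermost: int = 5,
    distance_to_pith_mm: float | None = None,
) -> tuple[float, int]:
    """Missing length and ring count between the innermost ring and the pith.

    The geometric distance-to-pith estimate (from the curvature of the
    innermost rings) is an *input*; the number of missing rings is that
    distance divided by the mean width of the ``k_innermost`` measured
    rings, rounded half-to-even. Without a distance estimate the offset
    is zero.
    """
    if k_innermost < 1:
        raise ValueError("k_innermost must be >= 1")
    if distance_to_pith_mm is None:
        return 0.0, 0
    if distance_to_pith_mm < 0:
        raise ValueError("distance_to_pith_mm must be >= 0")
    if len(series) < k_innermost:
        raise GrowthMetricsError(
            f"{series.tree_id}: fewer than {k_innermost} rings"
        )
    mean_width = float(np.mean(series.widths_mm[:k_innermost]))
    if mean_width <= 0:
        raise GrowthMetricsError(f"{series.tree_id}: innermost rings have zero width")
    n_missing = int(round(distance_to_pith_mm / mean_width))
    return float(distance_to_pith_mm), n_missing


def to_bai(series: RingWidthSeries) -> BAISeries:
    """Transform ring widths (mm) into basal area increments (cm^2).

    R_0 is the pith offset; each subsequent radius adds one ring width.
    The telescoping identity Sum(BAI) = pi * (R_last^2 - R_0^2) holds to
    rounding error by construction.
    """
    if np.any(series.widths_mm < 0):
        raise ValidationError(f"{series.tree_id}: negative widths")
    widths_cm = series.widths_mm / 10.0
    r0 = series.pith_offset_mm / 10.0
    radius = r0 + np.cumsum(widths_cm)
    prev = np.concatenate(([r0], radius[:-1]))
    bai = np.pi * (radius**2 - prev**2)
    return BAISeries(series.tree_id, series.years.copy(), bai, radius)


def growth_metrics(
    bai: BAISeries, window: tuple[int, int], min_years: int = 3
) -> GrowthMetrics:
    """Median, CV, OLS trend and lag-1 autocorrelation of BAI in a window.

    Dead trees whose series end inside the window use the available years
    and are flagged ``partial``. Fewer than ``min_years`` usable years, or a
    zero-mean window, is an error (callers exclude such trees from group
    summaries).
    """
    start, end = int(window[0]), int(window[1])
    if start > end:
        raise ValueError(f"window start > end: {window}")
    sub = bai.window(start, end)
    n = sub.years.size
    if n < min_years:
        raise GrowthMetricsError(
            f"{bai.tree_id}: only {n} usable years in window {window}"
        )
    x = sub.bai_cm2
    mean = float(np.mean(x))
    if mean == 0:
        raise GrowthMetricsError(f"{bai.tree_id}: zero-mean BAI in window {window}")
    cv = 100.0 * float(np.std(x, ddof=1)) / mean
    trend = float(np.polyfit(sub.years.astype(float), x, 1)[0])
    lead, lag = x[1:], x[:-1]
    degenerate = bool(np.std(lead) == 0 or np.std(lag) == 0)
    a1 = 0.0 if degenerate else float(np.corrcoef(lead, lag)[0, 1])
    partial = not (sub.years[0] == start and sub.years[-1] == end)
    return GrowthMetrics(
        tree_id=bai.tree_id,
        window=(start, end),
        median_cm2=float(np.median(x)),
        cv_pct=cv,
        trend_cm2_per_yr=trend,
        a1=a1,
        n_years=int(n),
        partial=partial,
        a1_degenerate=degenerate,
    )


def metrics_table(
    bai_list: list[BAISeries],
    windows: dict[str, tuple[int, int]],
    min_years: int = 3,
) -> pd.DataFrame:
    """Tidy per-tree-per-window metrics; trees with too few years are skipped."""
    rows = []
    for bai in bai_list:
        for name, window in windows.items():
            try:
                m = growth_metrics(bai, tuple(window), min_years=min_years)
            except GrowthMetricsError:
                continue
            rows.append(
                {
                    "tree_id": m.tree_id,
                    "window": name,
                    "start": m.window[0],
                    "end": m.window[1],
                    "median_cm2": m.median_cm2,
                    "cv_pct": m.cv_pct,
                    "trend_cm2_per_yr": m.trend_cm2_per_yr,
                    "a1": m.a1,
                    "n_years": m.n_years,
                    "partial": m.partial,
                }
            )
    return pd.DataFrame(rows)


def mean_ring_width(series: list[RingWidthSeries]) -> float:
    """Grand mean ring width (mm) over all rings of all trees."""
    if not series:
        raise ValueError("no series supplied")
    widths = np.concatenate([s.widths_mm for s in series])
    return float(np.mean(widths))


def bai_frame(bai_list: list[BAISeries]) -> pd.DataFrame:
    """Year x tree matrix of BAI values (NaN outside each series)."""
    cols = {b.tree_id: pd.Series(b.bai_cm2, index=b.years) for b in bai_list}
    df = pd.DataFrame(cols)
    df.index.name = "year"
    return df.sort_index()


def series_intercorrelation_qc(
    series: list[RingWidthSeries],
    threshold: float = 0.32,
    min_overlap: int = 15,
) -> pd.DataFrame:
    """Cross-dating quality control by series inter-correlation.

    Each ring-width series is correlated against the mean of all other
    series over their common years; low correlation flags a possible
    dating or measurement problem. This is a light surrogate for a full
    cross-dating validation program, not a replacement for it.
    """
    if len(series) < 3:
        raise ValueError("need >= 3 series for intercorrelation QC")
    frame = pd.DataFrame(
        {s.tree_id: pd.Series(s.widths_mm, index=s.years) for s in series}
    )
    rows = []
    for sid in frame.columns:
        others = frame.drop(columns=[sid]).mean(axis=1)
        paired = pd.concat([frame[sid], others], axis=1, keys=["s", "m"]).dropna()
        n = len(paired)
        if n < min_overlap or paired["s"].std() == 0 or paired["m"].std() == 0:
            rows.append(
                {"tree_id": sid, "n_overlap": n, "r": np.nan,
                 "flagged": True, "assessable": False}
            )
            continue
        r = float(paired["s"].corr(paired["m"]))
        rows.append(
            {"tree_id": sid, "n_overlap": n, "r": r,
             "flagged": bool(r < threshold), "assessable": True}
        )
    return pd.DataFrame(rows)
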