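"""Synthetic study datasets with the living/dead tree-couple design.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline can be exercised and validated
without field data:

* couples of coexisting living and dead trees less than 20 m apart, with
  dead trees shorter and slightly thinner than living ones;
* annual basal area increment built multiplicatively on the log scale:
  a negative-exponential age ramp towards a per-tree asymptote, a shared
  standardized drought-index signal, and AR(1) residual noise — so BAI
  stays positive and correlates positively with the drought index;
* a post-divergence multiplicative BAI decline in dying trees (and a mild
  release in survivors), producing the late growth divergence between the
  groups;
* ring widths back-computed from BAI and the target diameter, so that the
  growth module's BAI transform inverts the generator exactly;
* death years concentrated in the final year (by default 70% of dead
  trees carry their last ring in 2014), with earlier deaths truncating
  the series;
* per-vessel anatomy tables with configurable earlywood/latewood lumen
  distributions and a latewood shift for dead trees;
* neighbour tables drawn identically for both statuses (no competition
  effect by construction).

One integer seed drives named substreams for drought, tree attributes,
growth noise, death years, neighbours and vessels, so a run is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io_formats import (
    DroughtIndexSeries,
    RingWidthSeries,
    TreeRecord,
    ValidationError,
    VesselTable,
)


def _default_death_probs() -> dict[int, float]:
    return {2014: 0.70, 2013: 0.09, 2012: 0.06, 2011: 0.05,
            2010: 0.04, 2009: 0.03, 2008: 0.02, 2007: 0.01}


@dataclass
class SimulationConfig:
    """All knobs of the site generator, with study-like defaults.

    Group means/SDs follow the descriptive statistics of the emulated
    study design (SP-like site): living heights 14.1 +/- 4.4 m vs dead
    9.5 +/- 2.4 m, dbh 32.6 vs 28.2 cm, ages around 145 years. The BAI
    level, noise and drought-response defaults are chosen so that group
    medians sit near 2-3 cm^2, the coefficient of variation near 35-45%,
    lag-1 autocorrelation near 0.3, and BAI-index correlations near
    0.4-0.5 in living trees; the decline rate of 0.98/yr after the 2000
    divergence gives dying trees a 2000-2014 BAI trend close to
    -0.04 cm^2 yr^-1 while survivors' release of 1.3%/yr gives +0.04.
    """

    site: str = "SP"
    n_couples: int = 24
    year_range: tuple[int, int] = (1860, 2014)

    # tree attributes
    age_mean: float = 145.0
    age_sd: float = 8.0
    dbh_mean_living: float = 32.6
    dbh_sd_living: float = 4.4
    dbh_mean_dead: float = 28.2
    dbh_sd_dead: float = 4.9
    height_mean_living: float = 14.1
    height_sd_living: float = 4.4
    height_mean_dead: float = 9.5
    height_sd_dead: float = 2.4
    height_dbh_corr_living: float = 0.65
    height_dbh_corr_dead: float = 0.35
    bark_fraction: float = 0.12

    # growth process (log-BAI scale)
    bai_asymptote_cm2: float = 2.6
    bai_age_rate: float = 0.04
    level_sd: float = 0.4
    ar1_phi: float = 0.35
    noise_sd: float = 0.25
    drought_beta: float = 0.20
    drought_beta_dead: float = 0.12
    drought_phi: float = 0.3

    # dieback dynamics
    divergence_year: int = 2000
    decline_rate: float = 0.98
    release_rate: float = 1.013
    death_year_probs: dict[int, float] = field(default_factory=_default_death_probs)

    # spatial layout / competition
    couple_distance_range: tuple[float, float] = (3.0, 18.0)
    n_neighbors: int = 3
    neighbor_dbh_mean: float = 35.0
    neighbor_dbh_sd: float = 8.0
    neighbor_distance_range: tuple[float, float] = (2.0, 10.0)

    # wood anatomy
    n_anatomy_couples: int = 5
    ew_diam_mean: float = 265.0
    ew_diam_sd: float = 40.0
    lw_diam_mean: float = 30.0
    lw_diam_sd: float = 8.0
    lw_diam_shift_dead: float = 1.4
    ew_density_mm2: float = 8.0
    lw_density_mm2: float = 170.0
    ew_width_frac: float = 0.6

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_phi < 1:
            raise ValidationError("ar1_phi must be in [0, 1)")
        if not 0 < self.decline_rate <= 1:
            raise ValidationError("decline_rate must be in (0, 1]")
        if self.release_rate <= 0:
            raise ValidationError("release_rate must be > 0")
        for name in ("noise_sd", "level_sd", "age_sd", "ew_diam_sd", "lw_diam_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        total = sum(self.death_year_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("death_year_probs must sum to 1")
        y0, y1 = self.year_range
        if y0 >= y1:
            raise ValidationError("year_range start must precede end")

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimulationConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {unknown}")
        kwargs = dict(mapping)
        if "death_year_probs" in kwargs:
            kwargs["death_year_probs"] = {
                int(k): float(v) for k, v in kwargs["death_year_probs"].items()
            }
        for key in ("year_range", "couple_distance_range", "neighbor_distance_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class SimulatedSite:
    """Everything one simulated site produces, plus generator ground truth."""

    config: SimulationConfig
    series: list[RingWidthSeries]
    trees: list[TreeRecord]
    vessels: VesselTable
    ring_dimensions: pd.DataFrame
    drought_index: DroughtIndexSeries
    true_bai: dict[str, pd.Series]


def _ar1(rng, n, t, phi, sd):
    """n stationary AR(1) paths of length t."""
    e = rng.normal(0.0, sd, size=(n, t))
    if phi > 0:
        e[:, 0] /= np.sqrt(1.0 - phi**2)
        return lfilter([1.0], [1.0, -phi], e, axis=1)
    return e


def simulate_drought_index(
    years: np.ndarray, rng: np.random.Generator, phi: float = 0.3
) -> DroughtIndexSeries:
    """Standardized AR(1) surrogate for a multiscalar drought index."""
    values = _ar1(rng, 1, years.size, phi, np.sqrt(1.0 - phi**2))[0]
    return DroughtIndexSeries(years=years, values=values, label="synthetic index")


def simulate_site(
    config: SimulationConfig,
    drought_index: DroughtIndexSeries | None = None,
) -> SimulatedSite:
    """Generate one site of living/dead couples. See the module docstring."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    r_drought, r_attrs, r_growth, r_death, r_neigh, r_vessel = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )
    y0, y1 = int(cfg.year_range[0]), int(cfg.year_range[1])
    years = np.arange(y0, y1 + 1)
    t = years.size
    if drought_index is None:
        drought_index = simulate_drought_index(years, r_drought, cfg.drought_phi)
    index_vals = drought_index.value_for_years(years)

    n = 2 * cfg.n_couples
    living = np.tile([True, False], cfg.n_couples)

    # --- static attributes -------------------------------------------------
    dbh_mean = np.where(living, cfg.dbh_mean_living, cfg.dbh_mean_dead)
    dbh_sd = np.where(living, cfg.dbh_sd_living, cfg.dbh_sd_dead)
    h_mean = np.where(living, cfg.height_mean_living, cfg.height_mean_dead)
    h_sd = np.where(living, cfg.height_sd_living, cfg.height_sd_dead)
    rho = np.where(living, cfg.height_dbh_corr_living, cfg.height_dbh_corr_dead)

    dbh = np.clip(r_attrs.normal(dbh_mean, dbh_sd), 8.0, None)
    zd = (dbh - dbh_mean) / dbh_sd
    height = h_mean + rho * h_sd * zd + np.sqrt(1 - rho**2) * h_sd * r_attrs.normal(size=n)
    height = np.clip(height, 2.0, None)
    ages = np.clip(r_attrs.normal(cfg.age_mean, cfg.age_sd, size=n), 60, t).astype(int)
    first_year = np.maximum(y0, y1 - ages + 1)

    death_years = np.full(n, y1, dtype=int)
    dy_choices = np.array(sorted(cfg.death_year_probs))
    dy_probs = np.array([cfg.death_year_probs[int(y)] for y in dy_choices])
    death_years[~living] = r_death.choice(
        dy_choices, size=int(np.sum(~living)), p=dy_probs
    )

    # --- growth ------------------------------------------------------------
    log_level = (
        np.log(cfg.bai_asymptote_cm2 * dbh / cfg.dbh_mean_living)
        + r_growth.normal(0.0, cfg.level_sd, size=n)
    )
    beta = np.where(living, cfg.drought_beta, cfg.drought_beta_dead)
    noise = _ar1(r_growth, n, t, cfg.ar1_phi, cfg.noise_sd)
    age_at = years[None, :] - first_year[:, None] + 1  # cambial age, >= 1 when alive
    ramp = np.log1p(-np.exp(-cfg.bai_age_rate * np.maximum(age_at, 1)))
    post = np.clip(years[None, :] - cfg.divergence_year, 0, None).astype(float)
    trend = np.where(
        living[:, None], np.log(cfg.release_rate) * post, np.log(cfg.decline_rate) * post
    )
    log_bai = log_level[:, None] + ramp + beta[:, None] * index_vals[None, :] + noise + trend

    alive_mask = (age_at >= 1) & (years[None, :] <= death_years[:, None])
    bai = np.where(alive_mask, np.exp(log_bai), np.nan)

    # --- back-compute widths so the BAI transform inverts the generator ----
    series: list[RingWidthSeries] = []
    trees: list[TreeRecord] = []
    true_bai: dict[str, pd.Series] = {}
    r_target = dbh / 2.0 * (1.0 - cfg.bark_fraction)
    for i in range(n):
        mask = alive_mask[i]
        row = bai[i, mask]
        yrs = years[mask]
        total = float(np.sum(row))
        r0_sq = r_target[i] ** 2 - total / np.pi
        attempt = 0
        while r0_sq <= 0.01 and attempt < 8:  # BAI would imply negative radius
            offset = r_growth.normal(0.0, cfg.level_sd) - log_level[i] + np.log(
                cfg.bai_asymptote_cm2 * dbh[i] / cfg.dbh_mean_living
            )
            row = row * np.exp(offset)
            total = float(np.sum(row))
            r0_sq = r_target[i] ** 2 - total / np.pi
            attempt += 1
        if r0_sq <= 0.01:  # fall back: keep growth, let the stem be thicker
            r0_sq = 0.01
            dbh[i] = 2.0 * np.sqrt(r0_sq + total / np.pi) / (1.0 - cfg.bark_fraction)
        r0 = np.sqrt(r0_sq)
        radius = np.sqrt(r0**2 + np.cumsum(row) / np.pi)
        widths_mm = np.diff(np.concatenate(([r0], radius))) * 10.0

        status = "living" if living[i] else "dead"
        couple = i // 2
        tid = f"{cfg.site}{'L' if living[i] else 'D'}{couple:03d}"
        series.append(
            RingWidthSeries(
                tree_id=tid,
                years=yrs,
                widths_mm=widths_mm,
                site=cfg.site,
                pith_offset_mm=r0 * 10.0,
            )
        )
        true_bai[tid] = pd.Series(row, index=yrs)
        neighbors = [
            (
                float(np.pi * (max(d, 10.0) / 2.0) ** 2),
                float(r_neigh.uniform(*cfg.neighbor_distance_range)),
            )
            for d in r_neigh.normal(
                cfg.neighbor_dbh_mean, cfg.neighbor_dbh_sd, size=cfg.n_neighbors
            )
        ]
        trees.append(
            TreeRecord(
                tree_id=tid,
                site=cfg.site,
                status=status,
                dbh_cm=float(dbh[i]),
                height_m=float(height[i]),
                age_years=float(y1 - first_year[i] + 1),
                death_year=None if living[i] else int(death_years[i]),
                couple_id=f"{cfg.site}C{couple:03d}",
                couple_distance_m=float(r_neigh.uniform(*cfg.couple_distance_range)),
                pith_offset_mm=float(r0 * 10.0),
                neighbors=neighbors,
            )
        )

    vessels, ring_dims = _simulate_vessels(cfg, series, trees, r_vessel)
    return SimulatedSite(
        config=cfg,
        series=series,
        trees=trees,
        vessels=vessels,
        ring_dimensions=ring_dims,
        drought_index=drought_index,
        true_bai=true_bai,
    )


def _cap_lumen_area(diams: np.ndarray, zone_area_um2: float) -> np.ndarray:
    """Drop vessels until total lumen stays below 90% of the zone area."""
    areas = np.pi * (diams / 2.0) ** 2
    keep = np.cumsum(areas) <= 0.9 * zone_area_um2
    return diams[keep]


def _simulate_vessels(cfg, series, trees, rng):
    """Per-vessel tables for the first ``n_anatomy_couples`` couples."""
    rows = []
    dim_rows = []
    chosen = {
        t.tree_id for t in trees if int(t.couple_id[-3:]) < cfg.n_anatomy_couples
    }
    by_id = {s.tree_id: s for s in series}
    for tid in sorted(chosen):
        s = by_id[tid]
        dead = tid[len(cfg.site)] == "D"
        lw_mean = cfg.lw_diam_mean + (cfg.lw_diam_shift_dead if dead else 0.0)
        for year, width in zip(s.years, s.widths_mm):
            if not 1980 <= year <= 2013:
                continue
            if width < 0.2:  # too narrow for reliable vessel measurement
                continue
            ew_w = cfg.ew_width_frac * width
            lw_w = width - ew_w
            dim_rows.append(
                {"tree_id": tid, "ring_year": int(year),
                 "ew_width_mm": ew_w, "lw_width_mm": lw_w}
            )
            n_ew = rng.poisson(cfg.ew_density_mm2 * 2.0 * ew_w)
            n_lw = rng.poisson(cfg.lw_density_mm2 * 0.3 * lw_w)
            d_ew = np.clip(
                rng.normal(cfg.ew_diam_mean, cfg.ew_diam_sd, size=n_ew), 60.0, None
            )
            d_lw = np.clip(
                rng.normal(lw_mean, cfg.lw_diam_sd, size=n_lw), 5.0, 49.5
            )
            # lumina cannot physically exceed the sampled zone area
            d_ew = _cap_lumen_area(d_ew, 2.0 * ew_w * 1e6)
            d_lw = _cap_lumen_area(d_lw, 0.3 * lw_w * 1e6)
            for d in np.concatenate([d_ew, d_lw]):
                rows.append(
                    {"tree_id": tid, "ring_year": int(year),
                     "lumen_diameter_um": float(d),
                     "lumen_area_um2": float(np.pi * (d / 2.0) ** 2)}
                )
    vessels = VesselTable(
        pd.DataFrame(
            rows,
            columns=["tree_id", "ring_year", "lumen_diameter_um", "lumen_area_um2"],
        )
    )
    dims = pd.DataFrame(
        dim_rows, columns=["tree_id", "ring_year", "ew_width_mm", "lw_width_mm"]
    )
    return vessels, dims


def simulate_ddj_process(
    drift_fn=None,
    diffusion_sigma: float = 1.0,
    jump_rate: float = 0.0,
    jump_sd: float = 0.0,
    n_steps: int = 1000,
    x0: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate x_{t+1} = x_t + f(x_t) + N(0,s^2) + B(rate) * N(0,sJ^2).

    The validation oracle for the DDJ estimator: all parameters are known,
    so recovery can be checked directly. Deterministic under ``seed``.
    """
    if not 0.0 <= jump_rate <= 1.0:
        raise ValidationError("jump_rate must be in [0, 1]")
    if n_steps < 30:
        raise ValidationError("n_steps must be >= 30")
    if diffusion_sigma < 0 or jump_sd < 0:
        raise ValidationError("scales must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, diffusion_sigma, size=n_steps)
    jumps = rng.binomial(1, jump_rate, size=n_steps) * rng.normal(
        0.0, jump_sd, size=n_steps
    )
    if drift_fn is None:
        return np.concatenate(([x0], x0 + np.cumsum(noise + jumps)))
    x = np.empty(n_steps + 1)
    x[0] = x0
    for i in range(n_steps):
        x[i + 1] = x[i] + drift_fn(x[i]) + noise[i] + jumps[i]
    return x
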