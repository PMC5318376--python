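# dendromort

Growth–mortality analysis of drought-induced tree dieback, built around the
paired sampling design used in dieback studies of Mediterranean oaks: couples
of coexisting living and recently dead trees are compared in size, radial
growth, competition, wood anatomy and drought sensitivity, and the probability
of survival is modelled from size and recent growth.

The package takes dated ring-width series (Tucson `.rwl`), tree metadata,
neighbour and per-vessel tables, and an annual drought index (e.g. SPEI), and
computes:

* **Basal area increment** — BAI<sub>t</sub> = π(R<sub>t</sub>² − R<sub>t−1</sub>²),
  with pith-offset handling, and windowed growth metrics per tree: median,
  CV = 100·SD/mean, the OLS trend of BAI on year, and the lag-1
  autocorrelation (A1), over long/mid/short windows (1980–2014, 2000–2014,
  2005–2014 by default).
* **Competition intensity** — CI<sub>i</sub> = Σ<sub>j</sub> BA<sub>j</sub>/d<sub>ij</sub>
  over the three nearest neighbours.
* **Wood anatomy** — earlywood/latewood vessel classification (lumen diameter
  > 50 µm ⇒ earlywood), vessel density and percent lumen area per zone, and
  the hydraulically weighted diameter D<sub>h</sub> = Σd⁵/Σd⁴ per ring.
* **Non-parametric comparisons** — Mann–Whitney U for group contrasts,
  per-year paired Wilcoxon signed-rank tests across couples, and Pearson
  BAI–drought-index correlations over pre-dieback (1950–1981) and dieback
  (1982–2013) periods.
* **Logistic mortality models** — survival (alive = 1) regressed on height,
  dbh, age, CI and windowed BAI metrics; every predictor subset is fitted and
  ranked by AIC, ΔAIC and Akaike weights W<sub>i</sub> = e^(−Δ<sub>i</sub>/2)/Σe^(−Δ<sub>j</sub>/2),
  with rank-based AUC and McFadden pseudo-R² for discrimination.
* **Drift–diffusion–jump (DDJ) early-warning metrics** — kernel-regression
  estimates of the drift, total and conditional variance, diffusion and jump
  intensity of log(BAI+1) series (1970–2014), per tree and pooled per cohort,
  with ensemble quantile bands and a transition report that suggests the
  start year of the growth-trend window for the mortality models.

A first-class synthetic-data generator reproduces the statistical structure of
the study design (paired couples, shorter dead trees, shared drought signal,
AR(1) growth noise, post-2000 growth divergence, mortality concentrated in the
final year), so the entire pipeline is testable without field data.

## Worked example

Simulate one site of 24 living/dead couples, compute the 2000–2014 growth
trend per tree, and fit the height + trend survival model:

```python
import pandas as pd
from dendromort import (SimulationConfig, simulate_site, to_bai,
                        growth_metrics, fit_logistic)

site = simulate_site(SimulationConfig(seed=42))
rows = []
for t in site.trees:
    b = to_bai(next(s for s in site.series if s.tree_id == t.tree_id))
    m = growth_metrics(b, (2000, 2014))
    rows.append({"alive": int(t.alive), "height_m": t.height_m,
                 "trend": m.trend_cm2_per_yr, "median_bai": m.median_cm2})
df = pd.DataFrame(rows)
print(df.groupby("alive")[["height_m", "trend", "median_bai"]].mean().round(2))
fit = fit_logistic(df["alive"], df[["height_m", "trend"]])
print(f"AUC = {fit.auc:.3f}  McFadden R2 = {fit.mcfadden_r2:.2f}")
```

prints

```
       height_m  trend  median_bai
alive
0          9.20  -0.07        1.78
1         15.03   0.03        3.15
AUC = 0.913  McFadden R2 = 0.45
```

Dead trees are shorter (9.2 vs 15.0 m), grow less (median BAI 1.8 vs
3.2 cm²) and decline after 2000 (trend −0.07 vs +0.03 cm² yr⁻¹); height and
recent trend together discriminate survivors from dead trees with an
in-sample AUC of 0.91 — at the threshold conventionally read as excellent
discrimination.

The same analysis, end to end with reports and plots:

```bash
dendromort run-all --simulate --seed 1 --out runs/demo
dendromort report runs/demo
```

Every stage writes tidy CSV plus a JSON manifest (config hash, seed, file
digests), so reruns are reproducible and cached stage-by-stage. Individual
stages are exposed as `simulate | bai | metrics | traits | climate |
mortality | ddj` subcommands.

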