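"""End-to-end orchestration: simulate -> growth -> traits -> climate ->
mortality -> ddj -> report.

Every stage reads and writes tidy CSV in one output directory and records
itself in a JSON run manifest (config hash, seed, input/output digests,
versions). A rerun with an unchanged manifest entry and existing outputs
skips the stage, so partial reruns reuse cached upstream results.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, climate_response, ddj_ews, growth, io_formats
from . import mortality_models as mm
from . import stats_tests, synthetic_data, traits
from .io_formats import config_hash, file_digest


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class Manifest:
    """JSON run manifest with digest-based stage caching."""

    def __init__(self, path: Path):
        self.path = Path(path)
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"stages": {}}

    def stage_fresh(self, name: str, inputs: dict[str, str]) -> bool:
        entry = self.data["stages"].get(name)
        if entry is None or entry.get("inputs") != inputs:
            return False
        return all(Path(p).exists() for p in entry.get("outputs", []))

    def record(self, name: str, inputs: dict[str, str], outputs: list[Path]) -> None:
        self.data["stages"][name] = {
            "inputs": inputs,
            "outputs": [str(p) for p in outputs],
            "output_digests": {str(p): file_digest(p) for p in outputs},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def save(self, header: dict) -> None:
        self.data.update(header)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


def _digests(paths: dict[str, Path]) -> dict[str, str]:
    return {k: file_digest(p) for k, p in paths.items() if Path(p).exists()}


def run_all(
    cfg: dict,
    outdir: str | Path,
    seed: int | None = None,
    simulate: bool = True,
    indir: str | Path | None = None,
) -> Path:
    """Run every enabled stage; returns the output directory.

    With ``simulate`` the input tables are generated first; otherwise they
    are read from ``indir`` (``.rwl``, ``trees.csv``, ``neighbors.csv``,
    ``index.csv``, optionally ``vessels.csv`` + ``ring_dims.csv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    manifest = Manifest(outdir / "manifest.json")
    cfg_hash = config_hash(cfg)
    stages_cfg = cfg["stages"]

    # ------------------------------------------------------------------ data
    if simulate:
        sim_inputs = {"config": cfg_hash, "seed": str(seed)}
        data_dir = outdir
        paths = {
            "rwl": data_dir / "rings.rwl",
            "trees": data_dir / "trees.csv",
            "neighbors": data_dir / "neighbors.csv",
            "index": data_dir / "index.csv",
            "vessels": data_dir / "vessels.csv",
            "ring_dims": data_dir / "ring_dims.csv",
        }
        if not manifest.stage_fresh("simulate", sim_inputs):
            sim_cfg = synthetic_data.SimulationConfig.from_dict(
                {**cfg["simulation"], "seed": seed}
            )
            site = synthetic_data.simulate_site(sim_cfg)
            io_formats.write_rwl(paths["rwl"], site.series)
            io_formats.write_tree_table(paths["trees"], site.trees, paths["neighbors"])
            io_formats.write_drought_index(paths["index"], site.drought_index)
            io_formats.write_vessel_table(paths["vessels"], site.vessels)
            site.ring_dimensions.to_csv(paths["ring_dims"], index=False)
            manifest.record("simulate", sim_inputs, list(paths.values()))
    else:
        if indir is None:
            raise PipelineError("input", "either --simulate or an input directory")
        indir = Path(indir)
        rwls = sorted(indir.glob("*.rwl"))
        if not rwls:
            raise PipelineError("input", f"no .rwl file in {indir}")
        paths = {
            "rwl": rwls[0],
            "trees": indir / "trees.csv",
            "neighbors": indir / "neighbors.csv",
            "index": indir / "index.csv",
            "vessels": indir / "vessels.csv",
            "ring_dims": indir / "ring_dims.csv",
        }

    trees = io_formats.read_tree_table(
        paths["trees"], paths["neighbors"] if Path(paths["neighbors"]).exists() else None
    )
    if not simulate:  # the report stage reads tree metadata from the run dir
        io_formats.write_tree_table(outdir / "trees.csv", trees)
    series = io_formats.read_rwl(paths["rwl"])
    offsets = {t.tree_id: t.pith_offset_mm for t in trees}
    for s in series:
        s.pith_offset_mm = offsets.get(s.tree_id, 0.0)
    index = (
        io_formats.read_drought_index(paths["index"], cfg["climate"]["index_label"])
        if Path(paths["index"]).exists()
        else None
    )
    by_status = {
        "living": [t.tree_id for t in trees if t.alive],
        "dead": [t.tree_id for t in trees if not t.alive],
    }
    couples: dict[str, dict[str, str]] = {}
    for t in trees:
        if t.couple_id:
            couples.setdefault(t.couple_id, {})[t.status] = t.tree_id
    couple_pairs = [
        (c["living"], c["dead"]) for c in couples.values() if len(c) == 2
    ]
    data_digests = _digests(paths)
    io_formats.write_run_log(outdir / "run.log", cfg, seed, {})

    # ------------------------------------------------------------------- qc
    def stage(name: str, outputs: list[Path], fn, extra_inputs: dict | None = None):
        inputs = {"config": cfg_hash, **data_digests, **(extra_inputs or {})}
        if manifest.stage_fresh(name, inputs):
            return
        try:
            fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        manifest.record(name, inputs, outputs)

    qc_path = outdir / "qc.csv"

    def _qc():
        qc = growth.series_intercorrelation_qc(
            series,
            threshold=cfg["qc"]["threshold"],
            min_overlap=cfg["qc"]["min_overlap"],
        )
        qc.to_csv(qc_path, index=False)

    stage("qc", [qc_path], _qc)

    # ----------------------------------------------------------------- growth
    bai_list = [growth.to_bai(s) for s in series]
    bai_by_id = {b.tree_id: b for b in bai_list}
    bai_path = outdir / "bai.csv"
    metrics_path = outdir / "metrics.csv"

    def _growth():
        growth.bai_frame(bai_list).to_csv(bai_path)
        windows = {k: tuple(v) for k, v in cfg["windows"].items()}
        growth.metrics_table(bai_list, windows).to_csv(metrics_path, index=False)

    stage("growth", [bai_path, metrics_path], _growth)

    # ----------------------------------------------------------------- traits
    competition_path = outdir / "competition.csv"
    anatomy_ring_path = outdir / "anatomy_rings.csv"
    anatomy_tree_path = outdir / "anatomy_trees.csv"

    def _traits():
        traits.competition_table(trees).to_csv(competition_path, index=False)
        outputs = [competition_path]
        if stages_cfg["anatomy"] and Path(paths["vessels"]).exists():
            vessels = io_formats.read_vessel_table(paths["vessels"])
            dims = io_formats.read_ring_dimensions(paths["ring_dims"])
            classified = traits.classify_vessels(vessels, cfg["ew_threshold_um"])
            rings = traits.ring_anatomy(
                classified, dims, tuple(cfg["anatomy_window"])
            )
            rings.to_csv(anatomy_ring_path, index=False)
            traits.tree_anatomy_summary(rings).to_csv(anatomy_tree_path, index=False)
            outputs += [anatomy_ring_path, anatomy_tree_path]
        return outputs

    stage(
        "traits",
        [competition_path]
        + (
            [anatomy_ring_path, anatomy_tree_path]
            if stages_cfg["anatomy"] and Path(paths["vessels"]).exists()
            else []
        ),
        _traits,
    )

    # ---------------------------------------------------------------- climate
    climate_path = outdir / "climate_correlations.csv"
    climate_group_path = outdir / "climate_group_test.csv"
    if stages_cfg["climate"] and index is not None:

        def _climate():
            spec = climate_response.ResponseWindowSpec(
                tuple(cfg["climate"]["pre_period"]),
                tuple(cfg["climate"]["dieback_period"]),
                cfg["climate"]["index_label"],
            )
            corr = climate_response.drought_growth_correlations(
                bai_list, index, spec, alpha=cfg["alpha"]
            )
            corr["status"] = corr["tree_id"].map(
                {t.tree_id: t.status for t in trees}
            )
            corr.to_csv(climate_path, index=False)
            rows = []
            for period in ("pre", "dieback"):
                sub = corr[(corr["period"] == period) & ~corr["flagged"]]
                res = climate_response.compare_group_responses(
                    sub.loc[sub["status"] == "living", "r"],
                    sub.loc[sub["status"] == "dead", "r"],
                )
                rows.append(
                    {"period": period, "statistic": res.statistic,
                     "p_value": res.p_value, "direction": res.extra["direction"],
                     "critical_r": corr.attrs["critical_r"]}
                )
            pd.DataFrame(rows).to_csv(climate_group_path, index=False)

        stage("climate", [climate_path, climate_group_path], _climate)

    # ------------------------------------------------- per-year paired tests
    per_year_path = outdir / "per_year_tests.csv"

    def _per_year():
        per_year = stats_tests.per_year_paired_comparison(
            [bai_by_id[l] for l, _ in couple_pairs if l in bai_by_id],
            [bai_by_id[d] for _, d in couple_pairs if d in bai_by_id],
            couple_pairs,
            alpha=cfg["alpha"],
        )
        per_year.to_csv(per_year_path, index=False)

    if couple_pairs:
        stage("per_year", [per_year_path], _per_year)

    # -------------------------------------------------------------- mortality
    mortality_path = outdir / "mortality_ranking.csv"
    mortality_top_path = outdir / "mortality_top3.csv"
    if stages_cfg["mortality"]:

        def _mortality():
            data = _model_frame(trees, bai_by_id, cfg)
            pool = cfg["mortality"]["predictors"]
            predictors = [
                p for p in pool if p in data.columns and data[p].notna().all()
            ]
            results = mm.enumerate_and_rank(
                data,
                "survival",
                predictors,
                max_terms=cfg["mortality"]["max_terms"],
                collinearity_bar=cfg["mortality"]["collinearity_bar"],
            )
            mm.ranking_table(results).to_csv(mortality_path, index=False)
            mm.top_table(results).to_csv(mortality_top_path, index=False)

        stage("mortality", [mortality_path, mortality_top_path], _mortality)

    # -------------------------------------------------------------------- ddj
    ddj_band_paths = {
        st: outdir / f"ddj_bands_{st}.csv" for st in ("living", "dead")
    }
    ddj_transition_path = outdir / "ddj_transition.json"
    if stages_cfg["ddj"]:

        def _ddj():
            dcfg = cfg["ddj"]
            window = tuple(dcfg["window"])
            report = {}
            pooled_by_status = {}
            for st, ids in by_status.items():
                results = []
                cohort = []
                for tid in ids:
                    b = bai_by_id[tid].window(*window)
                    if b.years.size < ddj_ews.MIN_POINTS:
                        continue
                    x = ddj_ews.log1p_bai(b.bai_cm2)
                    cohort.append((b.years, x))
                    results.append(
                        ddj_ews.ddj_metrics(
                            x,
                            b.years,
                            bandwidth_frac=dcfg["bandwidth_frac"],
                            grid_size=dcfg["grid_size"],
                            jump_alpha=dcfg["jump_alpha"],
                        )
                    )
                if len(results) < 3:
                    continue
                bands = ddj_ews.ensemble_bands(results)
                bands.to_csv(ddj_band_paths[st], index=False)
                pooled_by_status[st] = ddj_ews.cohort_ddj(
                    cohort,
                    bandwidth_frac=dcfg["bandwidth_frac"],
                    grid_size=dcfg["grid_size"],
                    jump_alpha=dcfg["jump_alpha"],
                )
            for st, pooled in pooled_by_status.items():
                # the living cohort is the climate reference for the dead one
                reference = pooled_by_status.get("living") if st == "dead" else None
                tr = ddj_ews.detect_transition(
                    pooled, smooth_window=dcfg["smooth_window"], reference=reference
                )
                report[st] = {
                    "no_transition": tr.no_transition,
                    "cond_var_peak_year": tr.cond_var_peak_year,
                    "diffusion_drop_year": tr.diffusion_drop_year,
                    "suggested_window_start": tr.suggested_window_start,
                }
            Path(ddj_transition_path).write_text(json.dumps(report, indent=2))

        stage(
            "ddj",
            [p for p in ddj_band_paths.values()] + [ddj_transition_path],
            _ddj,
        )

    manifest.save(
        {
            "config_sha256": cfg_hash,
            "seed": seed,
            "dendromort_version": __version__,
            "input_digests": data_digests,
        }
    )
    return outdir


def _model_frame(trees, bai_by_id, cfg) -> pd.DataFrame:
    """Per-tree modelling table: survival, size, CI and windowed BAI metrics."""
    windows = {k: tuple(v) for k, v in cfg["windows"].items()}
    rows = []
    for t in trees:
        row = {
            "tree_id": t.tree_id,
            "survival": 1 if t.alive else 0,
            "height": t.height_m,
            "dbh": t.dbh_cm,
            "age": t.age_years,
        }
        if t.neighbors:
            row["ci"] = traits.competition_index(t).ci
        b = bai_by_id.get(t.tree_id)
        if b is not None:
            for name, window in windows.items():
                try:
                    m = growth.growth_metrics(b, window)
                except growth.GrowthMetricsError:
                    continue
                row[f"bai_median_{name}"] = m.median_cm2
                row[f"bai_cv_{name}"] = m.cv_pct
                row[f"bai_trend_{name}"] = m.trend_cm2_per_yr
                row[f"bai_a1_{name}"] = m.a1
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def report(outdir: str | Path, make_plots: bool = True) -> Path:
    """Render a markdown summary of a completed run (idempotent)."""
    outdir = Path(outdir)
    missing = [
        name
        for name, p in {
            "growth metrics": outdir / "metrics.csv",
            "tree table": outdir / "trees.csv",
        }.items()
        if not p.exists()
    ]
    if missing:
        raise PipelineError("report", f"missing upstream outputs: {missing}")

    trees = pd.read_csv(outdir / "trees.csv")
    metrics = pd.read_csv(outdir / "metrics.csv")
    status = trees.set_index("tree_id")["status"]
    metrics["status"] = metrics["tree_id"].map(status)

    lines = ["# Run report", ""]

    comp_path = outdir / "competition.csv"
    lines += ["## Tree characteristics (mean +/- SE by status)", ""]
    char = trees[["tree_id", "status", "dbh_cm", "height_m", "age_years"]].copy()
    if comp_path.exists():
        comp = pd.read_csv(comp_path)
        char = char.merge(comp[["tree_id", "ci"]], on="tree_id", how="left")
    lines += _group_table(char.drop(columns=["tree_id"]), "status")

    lines += ["", "## Windowed BAI metrics (mean +/- SE by status)", ""]
    for window in metrics["window"].unique():
        sub = metrics[metrics["window"] == window]
        lines.append(f"### {window} ({sub['start'].iat[0]}-{sub['end'].iat[0]})")
        lines += _group_table(
            sub[["status", "median_cm2", "cv_pct", "trend_cm2_per_yr", "a1"]],
            "status",
        )
        lines.append("")

    anat_path = outdir / "anatomy_trees.csv"
    if anat_path.exists():
        anat = pd.read_csv(anat_path)
        anat["status"] = anat["tree_id"].map(status)
        cols = [
            c
            for c in (
                "dh_um", "ew_vessel_diam_um", "lw_vessel_diam_um",
                "ew_vessel_density_mm2", "lw_vessel_density_mm2",
                "ew_vessel_area_pct", "lw_vessel_area_pct",
            )
            if c in anat.columns
        ]
        lines += ["## Wood anatomy (per-tree means)", ""]
        lines += _group_table(anat[["status"] + cols], "status")
        lines.append("")

    top_path = outdir / "mortality_top3.csv"
    if top_path.exists():
        lines += ["## Top mortality models", ""]
        lines += _md_table(pd.read_csv(top_path))
        lines.append("")

    tr_path = outdir / "ddj_transition.json"
    if tr_path.exists():
        lines += ["## DDJ transition report", "", "```json",
                  tr_path.read_text().strip(), "```", ""]

    if make_plots:
        plot_path = _plot_ddj_bands(outdir)
        if plot_path is not None:
            lines += [f"![DDJ bands]({plot_path.name})", ""]

    path = outdir / "report.md"
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def _group_table(df: pd.DataFrame, by: str) -> list[str]:
    g = df.groupby(by)
    mean = g.mean(numeric_only=True)
    se = g.sem(numeric_only=True)
    out = mean.round(2).astype(str) + " +/- " + se.round(2).astype(str)
    out.insert(0, "n", g.size())
    return _md_table(out.reset_index())


def _md_table(df: pd.DataFrame) -> list[str]:
    df = df.round(3)
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "|".join("---" for _ in df.columns) + "|"
    rows = [
        "| " + " | ".join(str(v) for v in row) + " |"
        for row in df.itertuples(index=False)
    ]
    return [header, sep] + rows


def _plot_ddj_bands(outdir: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    band_files = {
        st: outdir / f"ddj_bands_{st}.csv" for st in ("dead", "living")
    }
    band_files = {st: p for st, p in band_files.items() if p.exists()}
    if not band_files:
        return None
    metrics = ["total_variance", "conditional_variance", "diffusion2", "jump_intensity"]
    fig, axes = plt.subplots(
        len(metrics), len(band_files), figsize=(5 * len(band_files), 2.2 * len(metrics)),
        sharex=True, squeeze=False,
    )
    for j, (st, path) in enumerate(band_files.items()):
        bands = pd.read_csv(path)
        for i, metric in enumerate(metrics):
            ax = axes[i][j]
            sub = bands[bands["metric"] == metric]
            ax.fill_between(sub["year"], sub["q10"], sub["q90"], alpha=0.25)
            ax.fill_between(sub["year"], sub["q40"], sub["q60"], alpha=0.45)
            ax.plot(sub["year"], sub["median"], color="crimson", lw=1.2)
            if j == 0:
                ax.set_ylabel(metric, fontsize=8)
            if i == 0:
                ax.set_title(f"{st} trees")
    fig.tight_layout()
    path = outdir / "ddj_bands.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
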