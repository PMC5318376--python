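"""Competition index and wood-anatomy statistics.

Competition follows the distance-weighted basal-area formulation over the
nearest neighbours of a focal tree:

    CI_i = sum_j BA_j / d_ij      [cm^2 m^-1]

Vessel statistics distinguish earlywood (EW) from latewood (LW) by a lumen
diameter threshold (default 50 um, strictly "larger than"), and summarise
each ring by vessel density, percent lumen area and the hydraulically
weighted diameter Dh = sum(d^5) / sum(d^4), which weights each conduit by
its theoretical Hagen-Poiseuille conductivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import TreeRecord, ValidationError, VesselTable, ZONE_WINDOW_MM


@dataclass
class CompetitionResult:
    tree_id: str
    ci: float
    neighbors_used: int
    flagged: bool = False  # True when fewer neighbours than requested exist


def competition_index(focal: TreeRecord, n_neighbors: int = 3) -> CompetitionResult:
    """Sum of neighbour basal area over distance for the nearest neighbours."""
    if not focal.neighbors:
        raise ValueError(f"{focal.tree_id}: no neighbors, CI undefined")
    for ba, dist in focal.neighbors:
        if dist <= 0:
            raise ValidationError(f"{focal.tree_id}: neighbor distance <= 0")
        if ba <= 0:
            raise ValidationError(f"{focal.tree_id}: neighbor basal area <= 0")
    nearest = sorted(focal.neighbors, key=lambda p: p[1])[:n_neighbors]
    ci = float(sum(ba / dist for ba, dist in nearest))
    return CompetitionResult(
        tree_id=focal.tree_id,
        ci=ci,
        neighbors_used=len(nearest),
        flagged=len(nearest) < n_neighbors,
    )


def competition_table(
    records: list[TreeRecord], n_neighbors: int = 3
) -> pd.DataFrame:
    rows = []
    for r in records:
        if not r.neighbors:
            rows.append(
                {"tree_id": r.tree_id, "ci": np.nan, "neighbors_used": 0,
                 "flagged": True}
            )
            continue
        res = competition_index(r, n_neighbors=n_neighbors)
        rows.append(
            {"tree_id": res.tree_id, "ci": res.ci,
             "neighbors_used": res.neighbors_used, "flagged": res.flagged}
        )
    return pd.DataFrame(rows)


def classify_vessels(
    table: VesselTable, ew_threshold_um: float = 50.0
) -> VesselTable:
    """Assign every vessel to EW (diameter strictly above threshold) or LW.

    A lumen exactly at the threshold goes to LW. The zone's tangential
    window width is filled in where absent (2 mm for EW, 0.3 mm for LW).
    """
    df = table.data.copy()
    if len(df):
        ew = df["lumen_diameter_um"] > ew_threshold_um
        df["zone"] = np.where(ew, "EW", "LW")
        widths = df["zone"].map(ZONE_WINDOW_MM)
        df["window_width_mm"] = df["window_width_mm"].where(
            df["window_width_mm"].notna(), widths
        )
    return VesselTable(df)


def hydraulic_diameter(diameters_um) -> float:
    """Hydraulically weighted mean diameter, Dh = sum(d^5)/sum(d^4)."""
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        raise ValueError("hydraulic diameter undefined for empty vessel set")
    if np.any(d <= 0):
        raise ValidationError("vessel diameters must be > 0")
    return float(np.sum(d**5) / np.sum(d**4))


def ring_anatomy(
    table: VesselTable,
    ring_dimensions: pd.DataFrame,
    window: tuple[int, int] = (1980, 2013),
) -> pd.DataFrame:
    """Per-ring anatomical statistics from a classified vessel table.

    ``ring_dimensions`` supplies the radial extents of the EW and LW zones
    (``tree_id, ring_year, ew_width_mm, lw_width_mm``); sampled zone area is
    the tangential window width times that extent. Densities are vessels per
    mm^2, lumen-area percentages are bounded at 100 (with a warning), and Dh
    is computed per ring over all vessels of that ring.
    """
    df = table.data
    if len(df) and df["zone"].isna().any():
        raise ValidationError("ring_anatomy requires a classified vessel table")
    start, end = int(window[0]), int(window[1])
    dims = ring_dimensions.set_index(["tree_id", "ring_year"])
    rows = []
    for (tid, year), ring in df.groupby(["tree_id", "ring_year"], sort=True):
        if not (start <= year <= end):
            continue
        try:
            ew_ext, lw_ext = dims.loc[(tid, year), ["ew_width_mm", "lw_width_mm"]]
        except KeyError:
            continue
        row: dict = {"tree_id": tid, "ring_year": int(year)}
        row["dh_um"] = hydraulic_diameter(ring["lumen_diameter_um"])
        for zone, ext in (("EW", ew_ext), ("LW", lw_ext)):
            z = ring[ring["zone"] == zone]
            prefix = zone.lower()
            area_mm2 = ZONE_WINDOW_MM[zone] * float(ext)
            row[f"{prefix}_area_mm2"] = area_mm2
            d = z["lumen_diameter_um"].to_numpy()
            row[f"{prefix}_vessel_diam_um"] = float(d.mean()) if d.size else np.nan
            row[f"{prefix}_vessel_diam_min_um"] = float(d.min()) if d.size else np.nan
            row[f"{prefix}_vessel_diam_max_um"] = float(d.max()) if d.size else np.nan
            if area_mm2 <= 0:
                row[f"{prefix}_vessel_density_mm2"] = np.nan
                row[f"{prefix}_vessel_area_pct"] = np.nan
                continue
            row[f"{prefix}_vessel_density_mm2"] = len(z) / area_mm2
            lumen_mm2 = float(z["lumen_area_um2"].sum()) * 1e-6
            pct = 100.0 * lumen_mm2 / area_mm2
            if pct > 100.0:
                warnings.warn(
                    f"{tid} {year} {zone}: lumen area exceeds sampled zone "
                    "area; percentage bounded at 100",
                    stacklevel=2,
                )
                pct = 100.0
            row[f"{prefix}_vessel_area_pct"] = pct
        row["ring_area_mm2"] = row["ew_area_mm2"] + row["lw_area_mm2"]
        rows.append(row)
    return pd.DataFrame(rows)


def tree_anatomy_summary(ring_table: pd.DataFrame) -> pd.DataFrame:
    """Per-tree anatomy: unweighted means of the per-ring statistics."""
    if ring_table.empty:
        return pd.DataFrame()
    value_cols = [
        c for c in ring_table.columns if c not in ("tree_id", "ring_year")
    ]
    out = ring_table.groupby("tree_id")[value_cols].mean().reset_index()
    counts = ring_table.groupby("tree_id").size().rename("n_rings").reset_index()
    return out.merge(counts, on="tree_id")
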