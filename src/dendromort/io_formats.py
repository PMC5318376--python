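"""Readers, writers, configuration and run logging.

External formats handled here:

* Tucson/decadal ``.rwl`` ring-width files (units of 0.01 mm; both the ``999``
  and ``-9999`` stop-marker dialects are accepted on read, ``999`` is written).
* Comma-delimited UTF-8 CSV tables for tree metadata, neighbours, vessels,
  ring dimensions and the drought index (decimal point, header row).
* YAML run configuration with documented defaults and unknown-key rejection.
* A plain-text run log capturing config hash, seed and input digests.

Calendar years are integers and every analysis window is inclusive on both
ends, so ``[1980, 2014]`` covers 35 values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file could not be parsed as the expected external format."""


class SchemaError(FormatError):
    """A table is missing required columns."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


class ConfigError(ValueError):
    """The run configuration is malformed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RingWidthSeries:
    """Dated ring widths of one tree.

    Years are strictly increasing and contiguous; widths are in mm (>= 0).
    ``pith_offset_mm`` is the estimated distance from the innermost measured
    ring to the pith, used when reconstructing absolute radius.
    """

    tree_id: str
    years: np.ndarray
    widths_mm: np.ndarray
    site: str = ""
    pith_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.widths_mm = np.asarray(self.widths_mm, dtype=float)
        if self.years.size != self.widths_mm.size:
            raise ValidationError(
                f"{self.tree_id}: {self.years.size} years vs "
                f"{self.widths_mm.size} widths"
            )
        if self.years.size == 0:
            raise ValidationError(f"{self.tree_id}: empty series")
        if np.any(np.diff(self.years) != 1):
            raise ValidationError(f"{self.tree_id}: years not contiguous")
        if not np.all(np.isfinite(self.widths_mm)):
            raise ValidationError(f"{self.tree_id}: non-finite widths")
        if np.any(self.widths_mm < 0):
            raise ValidationError(f"{self.tree_id}: negative widths")
        if self.pith_offset_mm < 0:
            raise ValidationError(f"{self.tree_id}: negative pith offset")

    def __len__(self) -> int:
        return int(self.years.size)

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])


@dataclass
class TreeRecord:
    """Static attributes of one sampled tree.

    ``status`` is ``"living"`` or ``"dead"``; dead trees carry a
    ``death_year`` (calendar year of the last formed ring). ``neighbors``
    holds ``(basal_area_cm2, distance_m)`` pairs for the competition index.
    """

    tree_id: str
    site: str
    status: str
    dbh_cm: float
    height_m: float
    age_years: float
    death_year: int | None = None
    couple_id: str | None = None
    couple_distance_m: float | None = None
    pith_offset_mm: float = 0.0
    neighbors: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in ("living", "dead"):
            raise ValidationError(
                f"{self.tree_id}: status must be living/dead, got {self.status!r}"
            )
        if self.status == "dead" and self.death_year is None:
            raise ValidationError(f"{self.tree_id}: dead tree lacks death_year")
        for name in ("dbh_cm", "height_m", "age_years"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{self.tree_id}: {name} must be > 0, got {v}")
        for ba, dist in self.neighbors:
            if ba <= 0:
                raise ValidationError(f"{self.tree_id}: neighbor basal area <= 0")
            if dist <= 0:
                raise ValidationError(f"{self.tree_id}: neighbor distance <= 0")

    @property
    def alive(self) -> bool:
        return self.status == "living"


@dataclass
class DroughtIndexSeries:
    """Annual values of a standardized drought index (negative = dry)."""

    years: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size != self.values.size:
            raise ValidationError("drought index: years/values length mismatch")
        if np.unique(self.years).size != self.years.size:
            raise ValidationError("drought index: duplicated years")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("drought index: non-finite values")
        order = np.argsort(self.years)
        self.years = self.years[order]
        self.values = self.values[order]

    def value_for_years(self, years: Sequence[int]) -> np.ndarray:
        """Index values aligned to ``years``; raises listing any gaps."""
        years = np.asarray(years, dtype=int)
        missing = sorted(set(years.tolist()) - set(self.years.tolist()))
        if missing:
            raise ValidationError(f"drought index missing years: {missing}")
        pos = {int(y): i for i, y in enumerate(self.years)}
        return self.values[[pos[int(y)] for y in years]]


VESSEL_COLUMNS = ("tree_id", "ring_year", "lumen_diameter_um", "lumen_area_um2")

#: tangential window widths (mm) used when measuring each zone
ZONE_WINDOW_MM = {"EW": 2.0, "LW": 0.3}


@dataclass
class VesselTable:
    """Per-vessel measurements (one row per vessel lumen).

    Columns: ``tree_id, ring_year, lumen_diameter_um, lumen_area_um2`` plus
    optional ``zone`` ("EW"/"LW", NaN when unassigned) and
    ``window_width_mm``. Zone classification itself lives in
    :mod:`dendromort.traits`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in VESSEL_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"vessel table missing column {col!r}")
        if "zone" not in df.columns:
            df["zone"] = pd.Series([pd.NA] * len(df), dtype="object")
        if "window_width_mm" not in df.columns:
            df["window_width_mm"] = np.nan
        if len(df):
            if (df["lumen_diameter_um"] <= 0).any():
                raise ValidationError("vessel table: non-positive lumen diameter")
            if (df["lumen_area_um2"] <= 0).any():
                raise ValidationError("vessel table: non-positive lumen area")
            bad_zone = ~df["zone"].isin(["EW", "LW"]) & df["zone"].notna()
            if bad_zone.any():
                raise ValidationError("vessel table: zone must be EW/LW or unset")
            assigned = df["zone"].notna() & df["window_width_mm"].notna()
            for zone, expected in ZONE_WINDOW_MM.items():
                sel = assigned & (df["zone"] == zone)
                if sel.any() and not np.allclose(
                    df.loc[sel, "window_width_mm"], expected
                ):
                    raise ValidationError(
                        f"vessel table: {zone} window width must be {expected} mm"
                    )
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Tucson .rwl
# ---------------------------------------------------------------------------

_STOP_MARKERS = (999, -9999)


def read_rwl(path: str | Path, site: str = "") -> list[RingWidthSeries]:
    """Read a Tucson/decadal ``.rwl`` file.

    Widths are stored as integers in 0.01 mm and converted to mm. Both the
    ``999`` and ``-9999`` stop-marker dialects terminate a series.
    """
    path = Path(path)
    collected: dict[str, list[tuple[int, float]]] = {}
    finished: list[RingWidthSeries] = []
    order: list[str] = []

    def _finish(sid: str) -> None:
        rings = collected.pop(sid)
        years = [y for y, _ in rings]
        widths = [w for _, w in rings]
        finished.append(
            RingWidthSeries(tree_id=sid, years=years, widths_mm=widths, site=site)
        )

    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise FormatError(f"{path}:{lineno}: malformed decade line: {line!r}")
            sid = tokens[0]
            try:
                decade_year = int(tokens[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: bad decade year {tokens[1]!r}"
                ) from exc
            try:
                values = [int(t) for t in tokens[2:]]
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer ring value in {line!r}"
                ) from exc
            if not values:
                raise FormatError(f"{path}:{lineno}: decade line has no values")
            rings = collected.setdefault(sid, [])
            if sid not in order:
                order.append(sid)
            if rings and decade_year != rings[-1][0] + 1:
                raise ValidationError(
                    f"{path}:{lineno}: series {sid} jumps from year "
                    f"{rings[-1][0]} to {decade_year}"
                )
            year = decade_year
            stopped = False
            for i, v in enumerate(values):
                if v in _STOP_MARKERS:
                    if i != len(values) - 1:
                        raise FormatError(
                            f"{path}:{lineno}: stop marker not last on line"
                        )
                    stopped = True
                    break
                rings.append((year, v / 100.0))
                year += 1
            if stopped:
                if not rings:
                    raise FormatError(f"{path}:{lineno}: series {sid} is empty")
                _finish(sid)
    if collected:
        missing = ", ".join(sorted(collected))
        raise FormatError(f"{path}: series without stop marker: {missing}")
    finished.sort(key=lambda s: order.index(s.tree_id))
    return finished


def write_rwl(path: str | Path, series: Sequence[RingWidthSeries]) -> None:
    """Write Tucson/decadal ``.rwl`` (0.01 mm units, ``999`` stop marker)."""
    path = Path(path)
    lines: list[str] = []
    for s in series:
        sid = s.tree_id[:8]
        values = [int(round(w * 100)) for w in s.widths_mm]
        year = s.first_year
        i = 0
        while i < len(values):
            row_start = year + i
            # first row runs to the end of its decade, later rows are full
            n_row = 10 - (row_start % 10) if i == 0 else 10
            chunk = values[i : i + n_row]
            cells = "".join(f"{v:6d}" for v in chunk)
            i += len(chunk)
            if i == len(values) and len(chunk) < n_row:
                cells += f"{999:6d}"
                lines.append(f"{sid:<8s}{row_start:4d}{cells}")
            else:
                lines.append(f"{sid:<8s}{row_start:4d}{cells}")
                if i == len(values):  # stop marker needs its own row
                    lines.append(f"{sid:<8s}{year + i:4d}{999:6d}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_STATUS_ALIASES = {
    "l": "living", "living": "living", "alive": "living", "1": "living",
    "d": "dead", "dead": "dead", "0": "dead",
}

_TREE_REQUIRED = ("tree_id", "site", "status", "dbh_cm", "height_m", "age_years")


def read_tree_table(
    path: str | Path, neighbors_path: str | Path | None = None
) -> list[TreeRecord]:
    """Read the tree metadata CSV, optionally joining a neighbour table.

    The neighbour CSV has columns ``tree_id, neighbor_ba_cm2, distance_m``
    (one row per focal-tree/neighbour pair).
    """
    df = pd.read_csv(path)
    missing = [c for c in _TREE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    ids = df["tree_id"].astype(str)
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise ValidationError(f"{path}: duplicated tree_id values: {dupes}")

    neighbors: dict[str, list[tuple[float, float]]] = {}
    if neighbors_path is not None:
        ndf = pd.read_csv(neighbors_path)
        for col in ("tree_id", "neighbor_ba_cm2", "distance_m"):
            if col not in ndf.columns:
                raise SchemaError(f"{neighbors_path}: missing column {col!r}")
        for _, row in ndf.iterrows():
            neighbors.setdefault(str(row["tree_id"]), []).append(
                (float(row["neighbor_ba_cm2"]), float(row["distance_m"]))
            )

    records = []
    for _, row in df.iterrows():
        status_raw = str(row["status"]).strip().lower()
        if status_raw not in _STATUS_ALIASES:
            raise ValidationError(f"unknown status {row['status']!r}")
        death_year = row.get("death_year")
        death_year = None if pd.isna(death_year) else int(death_year)
        couple_id = row.get("couple_id")
        couple_id = None if pd.isna(couple_id) else str(couple_id)
        cdist = row.get("couple_distance_m")
        cdist = None if pd.isna(cdist) else float(cdist)
        offset = row.get("pith_offset_mm", 0.0)
        offset = 0.0 if pd.isna(offset) else float(offset)
        tid = str(row["tree_id"])
        records.append(
            TreeRecord(
                tree_id=tid,
                site=str(row["site"]),
                status=_STATUS_ALIASES[status_raw],
                dbh_cm=float(row["dbh_cm"]),
                height_m=float(row["height_m"]),
                age_years=float(row["age_years"]),
                death_year=death_year,
                couple_id=couple_id,
                couple_distance_m=cdist,
                pith_offset_mm=offset,
                neighbors=neighbors.get(tid, []),
            )
        )
    return records


def write_tree_table(
    path: str | Path,
    records: Sequence[TreeRecord],
    neighbors_path: str | Path | None = None,
) -> None:
    rows = []
    nrows = []
    for r in records:
        rows.append(
            {
                "tree_id": r.tree_id,
                "site": r.site,
                "status": r.status,
                "dbh_cm": r.dbh_cm,
                "height_m": r.height_m,
                "age_years": r.age_years,
                "death_year": r.death_year,
                "couple_id": r.couple_id,
                "couple_distance_m": r.couple_distance_m,
                "pith_offset_mm": r.pith_offset_mm,
            }
        )
        for ba, dist in r.neighbors:
            nrows.append(
                {"tree_id": r.tree_id, "neighbor_ba_cm2": ba, "distance_m": dist}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    if neighbors_path is not None:
        pd.DataFrame(
            nrows, columns=["tree_id", "neighbor_ba_cm2", "distance_m"]
        ).to_csv(neighbors_path, index=False)


def read_vessel_table(path: str | Path) -> VesselTable:
    df = pd.read_csv(path)
    if "zone" in df.columns:
        df["zone"] = df["zone"].where(df["zone"].isin(["EW", "LW"]), pd.NA)
    return VesselTable(df)


def write_vessel_table(path: str | Path, table: VesselTable) -> None:
    table.data.to_csv(path, index=False)


def read_ring_dimensions(path: str | Path) -> pd.DataFrame:
    """Read per-ring radial extents: tree_id, ring_year, ew_width_mm, lw_width_mm."""
    df = pd.read_csv(path)
    for col in ("tree_id", "ring_year", "ew_width_mm", "lw_width_mm"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if ((df["ew_width_mm"] < 0) | (df["lw_width_mm"] < 0)).any():
        raise ValidationError(f"{path}: negative zone widths")
    return df


def read_drought_index(path: str | Path, label: str = "") -> DroughtIndexSeries:
    df = pd.read_csv(path)
    for col in ("year", "value"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return DroughtIndexSeries(
        years=df["year"].to_numpy(), values=df["value"].to_numpy(), label=label
    )


def write_drought_index(path: str | Path, index: DroughtIndexSeries) -> None:
    pd.DataFrame({"year": index.years, "value": index.values}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Leaf keys whose dict values are free-form (not checked against defaults).
_OPAQUE_KEYS = {"death_year_probs"}


def default_config() -> dict:
    """The full default run configuration (deep copy)."""
    from . import synthetic_data  # local import avoids a cycle

    return {
        "windows": {
            "long": [1980, 2014],
            "mid": [2000, 2014],
            "short": [2005, 2014],
        },
        "anatomy_window": [1980, 2013],
        "ew_threshold_um": 50.0,
        "alpha": 0.05,
        "qc": {"threshold": 0.32, "min_overlap": 15},
        "climate": {
            "pre_period": [1950, 1981],
            "dieback_period": [1982, 2013],
            "index_label": "May SPEI (10-month)",
        },
        "ddj": {
            "window": [1970, 2014],
            "bandwidth_frac": 0.3,
            "grid_size": 100,
            "jump_alpha": 0.01,
            "smooth_window": 5,
        },
        "mortality": {
            "max_terms": 4,
            "collinearity_bar": None,
            # study-like candidate pool: size, age, competition and one BAI
            # metric of each kind (median/CV short window, trend mid window,
            # A1 short window)
            "predictors": [
                "height", "dbh", "age", "ci",
                "bai_median_short", "bai_cv_short",
                "bai_trend_mid", "bai_a1_short",
            ],
        },
        "stages": {"anatomy": True, "climate": True, "mortality": True, "ddj": True},
        "seed": 0,
        "simulation": dataclasses.asdict(synthetic_data.SimulationConfig()),
    }


def _merge(defaults: dict, override: dict, prefix: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in override:
            oval = override[key]
            if (
                isinstance(dval, dict)
                and key not in _OPAQUE_KEYS
                and isinstance(oval, dict)
            ):
                out[key] = _merge(dval, oval, prefix=f"{prefix}{key}.")
            else:
                out[key] = oval
        else:
            out[key] = dval
    unknown = sorted(set(override) - set(defaults))
    if unknown:
        raise ConfigError(f"unknown config keys: {[prefix + k for k in unknown]}")
    return out


def _check_window(name: str, window) -> None:
    if len(window) != 2 or int(window[0]) > int(window[1]):
        raise ValidationError(f"config window {name!r} has start > end: {window}")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load YAML config, merge over defaults, reject unknown keys, validate."""
    cfg = default_config()
    loaded: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    for name, window in cfg["windows"].items():
        _check_window(f"windows.{name}", window)
    _check_window("anatomy_window", cfg["anatomy_window"])
    _check_window("ddj.window", cfg["ddj"]["window"])
    _check_window("climate.pre_period", cfg["climate"]["pre_period"])
    _check_window("climate.dieback_period", cfg["climate"]["dieback_period"])
    # simulation block is validated by the generator's own config type
    from . import synthetic_data

    synthetic_data.SimulationConfig(**cfg["simulation"])
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable sha256 of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(
    path: str | Path,
    cfg: dict,
    seed: int,
    inputs: dict[str, str | Path] | None = None,
) -> None:
    """Append a plain-text log entry: config hash, seed, input digests, versions."""
    import scipy

    from . import __version__

    lines = [
        f"timestamp: {time.strftime('%Y-%m-%dT%H:%M:%S')}",
        f"dendromort: {__version__}",
        f"numpy: {np.__version__}  scipy: {scipy.__version__}  pandas: {pd.__version__}",
        f"seed: {seed}",
        f"config_sha256: {config_hash(cfg)}",
    ]
    for name, p in (inputs or {}).items():
        lines.append(f"input {name}: {Path(p).name} sha256={file_digest(p)}")
    lines.append("")
    with open(path, "a", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
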