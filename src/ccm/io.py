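"""Readers, writers, run configuration, and the full-pipeline driver.

Tabular products are TSV with a leading ``# manifest:`` comment naming
the run they came from; spatial products are GeoJSON (cell polygons)
and an ESRI-style ASCII grid for the utilization distribution.  Dates
are ISO-8601 calendar days throughout; "day index" is days since the
first record, 1-based.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from . import __version__
from .agreement import correlation_sweep, moving_window, temporal_stability
from .dispersion import aggregate_ccm_counts, aggregate_plot_counts, dispersion_agreement, species_morisita
from .distribution import distribution_agreement, presence_agreement
from .grid import DEFAULT_SIZE_MINIMA, FeedingRecord, GridSpec, OccupancyGrid, rasterize_records, surveyed_area
from .homerange import Tracklog, UtilizationDistribution, assign_cells, assign_plots, cells_within_isopleth, estimate_utilization
from .indices import PlotInventory, species_index_table

logger = logging.getLogger(__name__)

FEEDING_COLUMNS = ["date", "group", "species", "x", "y", "dbh_cm", "lifeform"]
PLOT_COLUMNS = ["plot_id", "plot_x", "plot_y", "species", "dbh_cm", "lifeform"]


class RowErrors(ValueError):
    """Raised when too many rows of an input table fail validation."""

    def __init__(self, message: str, rows: list[tuple[int, str]]):
        super().__init__(message)
        self.rows = rows


def read_feeding_csv(path, max_invalid_frac: float = 0.01) -> list[FeedingRecord]:
    """Read feeding records; aborts if more than ``max_invalid_frac`` rows fail.

    Unknown extra columns are ignored with a warning; missing required
    columns are a named rejection.
    """
    df = pd.read_csv(path)
    missing = [c for c in FEEDING_COLUMNS if c not in df.columns and c != "dbh_cm"]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extras = [c for c in df.columns if c not in FEEDING_COLUMNS]
    if extras:
        logger.warning("%s: ignoring extra column(s) %s", path, extras)
    records: list[FeedingRecord] = []
    bad: list[tuple[int, str]] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            dbh = getattr(row, "dbh_cm", None)
            if dbh is not None and (isinstance(dbh, float) and math.isnan(dbh)):
                dbh = None
            records.append(
                FeedingRecord(
                    date=_dt.date.fromisoformat(str(row.date)),
                    group_id=str(row.group),
                    species="" if pd.isna(row.species) else str(row.species),
                    x=float(row.x),
                    y=float(row.y),
                    dbh=None if dbh is None else float(dbh),
                    lifeform=str(row.lifeform),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((line_no, str(exc)))
    if len(df) and len(bad) / len(df) > max_invalid_frac:
        raise RowErrors(
            f"{path}: {len(bad)}/{len(df)} rows invalid (first: line {bad[0][0]}: {bad[0][1]})",
            bad,
        )
    for line_no, msg in bad:
        logger.warning("%s line %d: dropped row (%s)", path, line_no, msg)
    return records


def write_feeding_csv(records, path) -> None:
    pd.DataFrame(
        [
            dict(date=r.date.isoformat(), group=r.group_id, species=r.species,
                 x=r.x, y=r.y, dbh_cm=r.dbh, lifeform=r.lifeform)
            for r in records
        ],
        columns=FEEDING_COLUMNS,
    ).to_csv(path, index=False)


def read_plot_csv(path, footprint: float = 50.0) -> PlotInventory:
    """Read a plot inventory from one CSV.

    Columns: plot_id, plot_x, plot_y (centroid, repeated per stem row),
    species, dbh_cm, lifeform.  Rows with an empty species mark a plot
    with no stems.  An optional ``footprint_m`` column is validated
    against ``footprint`` (pass the override explicitly if plots are
    not 50 m).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("plot_id", "plot_x", "plot_y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "footprint_m" in df.columns:
        sizes = set(df.footprint_m.dropna().unique())
        if sizes - {footprint}:
            raise ValueError(
                f"{path}: footprint(s) {sorted(sizes)} differ from expected {footprint} m; "
                "pass footprint= explicitly to accept them"
            )
    plots = (
        df[["plot_id", "plot_x", "plot_y"]]
        .drop_duplicates("plot_id")
        .rename(columns={"plot_x": "x", "plot_y": "y"})
    )
    has_stem = df.get("species")
    if has_stem is not None:
        stems = df[df.species.notna() & (df.species.astype(str) != "")][
            ["plot_id", "species", "dbh_cm", "lifeform"]
        ]
    else:
        stems = pd.DataFrame(columns=["plot_id", "species", "dbh_cm", "lifeform"])
    return PlotInventory(plots=plots, stems=stems, footprint=footprint)


def write_plot_csv(inv: PlotInventory, path) -> None:
    cent = inv.plots.rename(columns={"x": "plot_x", "y": "plot_y"})
    if len(inv.stems):
        df = inv.stems.merge(cent, on="plot_id")
        empty = cent[~cent.plot_id.isin(inv.stems.plot_id)]
    else:
        df = pd.DataFrame(columns=PLOT_COLUMNS)
        empty = cent
    if len(empty):
        df = pd.concat([df, empty.assign(species="", dbh_cm=np.nan, lifeform="")],
                       ignore_index=True)
    df["footprint_m"] = inv.footprint
    df[PLOT_COLUMNS + ["footprint_m"]].to_csv(path, index=False)


def read_tracklog(path) -> Tracklog:
    """Read a tracklog from CSV (timestamp, x, y) or GPX (trkpt lat/lon as x/y).

    GPX coordinates are taken as already-projected meters in ``lon``/
    ``lat`` order; real geographic GPX must be projected upstream (CRS
    handling is out of scope).
    """
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
        root = ET.parse(path).getroot()
        pts = root.findall(".//gpx:trkpt", ns) or root.findall(".//trkpt")
        xy = np.array([[float(p.get("lon")), float(p.get("lat"))] for p in pts])
        times = [p.findtext("gpx:time", namespaces=ns) or p.findtext("time") for p in pts]
        ts = (
            np.array([np.datetime64(t.rstrip("Z")) for t in times])
            if all(t is not None for t in times) and len(times)
            else None
        )
        return Tracklog(xy=xy, timestamps=ts)
    df = pd.read_csv(path)
    ts = np.array(df.timestamp.astype("datetime64[s]")) if "timestamp" in df.columns else None
    return Tracklog(xy=df[["x", "y"]].values.astype(float), timestamps=ts)


def write_tracklog_csv(track: Tracklog, path) -> None:
    df = pd.DataFrame(track.xy, columns=["x", "y"])
    if track.timestamps is not None:
        df.insert(0, "timestamp", track.timestamps)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spatial exports

def occupancy_to_frame(occ: OccupancyGrid) -> pd.DataFrame:
    rows = [
        dict(species=sp, i=i, j=j, first_date=v.first_date.isoformat(), n_records=v.n_records)
        for sp, cells in sorted(occ.species.items())
        for (i, j), v in sorted(cells.items())
    ]
    return pd.DataFrame(rows, columns=["species", "i", "j", "first_date", "n_records"])


def export_occupancy_geojson(occ: OccupancyGrid, path) -> None:
    """Visited cells as polygons, each carrying its species list."""
    by_cell: dict[tuple[int, int], list[str]] = {c: [] for c in occ.visited_cells}
    for sp, cells in occ.species.items():
        for c in cells:
            by_cell[c].append(sp)
    features = []
    for (i, j) in sorted(by_cell):
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(box(*occ.grid.cell_bounds(i, j))),
                "properties": {"i": i, "j": j, "species": sorted(by_cell[(i, j)])},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection",
                    "crs_label": occ.grid.crs_label, "features": features})
    )


def export_isopleth_geojson(cell_ka, grid: GridSpec, percents, path) -> None:
    """Isopleth cell sets dissolved into polygons, one feature per percent."""
    features = []
    for p in percents:
        cells = cells_within_isopleth(cell_ka, p)
        if not cells:
            continue
        geom = unary_union([box(*grid.cell_bounds(i, j)) for (i, j) in cells])
        features.append(
            {"type": "Feature", "geometry": mapping(geom),
             "properties": {"percent_kernel": p, "n_cells": len(cells)}}
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def export_ud_ascii(ud: UtilizationDistribution, path) -> None:
    """Single-band ESRI-style ASCII grid of the utilization density."""
    ny, nx = ud.density.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {ud.xmin}\nyllcorner {ud.ymin}\n"
        f"cellsize {ud.resolution}\nNODATA_value -9999\n"
    )
    body = "\n".join(
        " ".join(f"{v:.8g}" for v in row) for row in ud.density[::-1]
    )
    Path(path).write_text(header + body + "\n")


def write_tsv(df: pd.DataFrame, path, manifest_tag: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest_tag}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclass
class RunConfig:
    """Paths, grids, thresholds, and seeds for one full pipeline run."""

    out_dir: str = "ccm-out"
    feeding_csv: str | None = None
    tracklog_path: str | None = None
    plot_csv: str | None = None
    simulate: bool = False  # generate inputs with the default scenario
    seed: int = 0
    cell_size: float = 50.0
    agg_sizes: tuple[float, ...] = (500.0, 1000.0, 1500.0)
    kernel_isopleth: float = 95.0
    kernel_range: tuple[int, int] = (20, 95)
    min_species: int = 10
    min_plots: int = 10
    min_window_plots: int = 20
    min_window_cells: int = 200
    size_minima: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_MINIMA))
    bandwidth: float | None = None
    eval_resolution: float = 25.0
    n_days: int = 600

    def __post_init__(self) -> None:
        for name in ("min_species", "min_plots", "min_window_plots"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.kernel_range
        if not (0 < lo <= hi <= 100):
            raise ValueError(f"kernel_range {self.kernel_range} outside (0, 100]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        for key in ("agg_sizes", "kernel_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute grid -> home range -> indices -> agreement -> dispersion ->
    distribution, writing every product plus a machine-readable manifest.

    Returns the manifest dict.  Input data come either from the three
    configured paths or, with ``simulate=True``, from the default
    synthetic scenario under ``seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "artifacts": [],
        "counts": {},
    }
    tag = f"ccm-{__version__} seed={config.seed}"

    stage = "inputs"
    try:
        if config.simulate:
            from .simulate import (
                ScenarioConfig, generate_forest, simulate_forager, simulate_plot_survey,
            )
            scfg = ScenarioConfig(n_days=config.n_days)
            ss = np.random.SeedSequence(config.seed)
            s1, s2, s3 = ss.spawn(3)
            forest = generate_forest(scfg.species, scfg.window, s1)
            records, track, _ = simulate_forager(forest, scfg.species, scfg.forager,
                                                 scfg.n_days, s2)
            inv = simulate_plot_survey(forest, scfg.window, scfg.plots_per_cell, s3)
            write_feeding_csv(records, out / "feeding.csv")
            write_tracklog_csv(track, out / "tracklog.csv")
            write_plot_csv(inv, out / "plots.csv")
            manifest["inputs"] = {"simulated": True, "n_days": scfg.n_days}
        else:
            if not (config.feeding_csv and config.tracklog_path and config.plot_csv):
                raise ValueError("feeding_csv, tracklog_path and plot_csv are all required "
                                 "unless simulate=True")
            records = read_feeding_csv(config.feeding_csv)
            track = read_tracklog(config.tracklog_path)
            inv = read_plot_csv(config.plot_csv)
            manifest["inputs"] = {
                p: _sha256(p)
                for p in (config.feeding_csv, config.tracklog_path, config.plot_csv)
            }

        stage = "grid"
        grid = GridSpec(cell_size=config.cell_size)
        occ = rasterize_records(records, grid)
        manifest["counts"]["records"] = len(records)
        manifest["counts"]["records_unidentified"] = occ.n_skipped_unidentified
        manifest["counts"]["visited_cells"] = len(occ.visited_cells)
        manifest["counts"]["surveyed_area_km2"] = surveyed_area(occ)
        export_occupancy_geojson(occ, out / "occupancy.geojson")
        write_tsv(occupancy_to_frame(occ), out / "occupancy.tsv", tag)

        stage = "home_range"
        ud = estimate_utilization(track, bandwidth=config.bandwidth,
                                  eval_resolution=config.eval_resolution)
        cell_ka = assign_cells(ud, occ.visited_cells, grid)
        plot_ka = assign_plots(ud, inv.plot_centroids())
        hr_cells = cells_within_isopleth(cell_ka, config.kernel_isopleth)
        inv_hr = inv.subset(cells_within_isopleth(plot_ka, config.kernel_isopleth))
        manifest["counts"]["hr_cells"] = len(hr_cells)
        manifest["counts"]["plots_total"] = inv.n_plots
        manifest["counts"]["plots_in_hr"] = inv_hr.n_plots
        export_ud_ascii(ud, out / "utilization.asc")
        export_isopleth_geojson(cell_ka, grid, [50, config.kernel_isopleth],
                                out / "isopleths.geojson")

        stage = "indices"
        table = species_index_table(occ, inv_hr, hr_cells, config.size_minima)
        write_tsv(table.reset_index(), out / "species_indices.tsv", tag)

        stage = "agreement"
        sweep = correlation_sweep(
            occ, inv, cell_ka, plot_ka, kernel_range=config.kernel_range,
            min_species=config.min_species, min_plots=config.min_plots,
            minima=config.size_minima,
        )
        write_tsv(sweep, out / "sweep.tsv", tag)
        window = moving_window(
            occ, inv, cell_ka, plot_ka, min_plots=config.min_window_plots,
            min_cells=config.min_window_cells, minima=config.size_minima,
        )
        write_tsv(window, out / "moving_window.tsv", tag)
        if hr_cells and inv_hr.n_plots:
            series, stab = temporal_stability(occ, inv_hr, hr_cells,
                                              minima=config.size_minima)
            write_tsv(series, out / "temporal_stability.tsv", tag)
            manifest["counts"]["stability_day"] = stab

        stage = "dispersion"
        disp_rows = []
        for size in config.agg_sizes:
            agg = GridSpec(cell_size=size)
            cg_ccm = aggregate_ccm_counts(occ, agg)
            cg_plot = aggregate_plot_counts(inv, agg, config.size_minima)
            for src, cg in (("ccm", cg_ccm), ("plot", cg_plot)):
                m = species_morisita(cg)
                m = m.assign(cell_size=size, source=src)
                disp_rows.append(m.reset_index())
            try:
                agree = dispersion_agreement(cg_ccm, cg_plot,
                                             min_species=config.min_species)
                manifest.setdefault("dispersion_agreement", {})[str(int(size))] = {
                    k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in agree.items() if not isinstance(v, tuple)
                }
            except ValueError as exc:
                manifest.setdefault("dispersion_agreement", {})[str(int(size))] = str(exc)
        write_tsv(pd.concat(disp_rows, ignore_index=True), out / "dispersion.tsv", tag)

        stage = "distribution"
        dist_tables = []
        summaries = []
        for size in config.agg_sizes:
            agg = GridSpec(cell_size=size)
            cg_ccm = aggregate_ccm_counts(occ, agg)
            cg_plot = aggregate_plot_counts(inv, agg, config.size_minima)
            if not cg_plot.cells:
                continue
            tbl, summary = distribution_agreement(cg_ccm, cg_plot, inv, plot_ka)
            dist_tables.append(tbl.reset_index())
            summaries.append(asdict(summary))
            _, pooled = presence_agreement(cg_ccm, cg_plot, inv, plot_ka)
            manifest.setdefault("presence_agreement", {})[str(int(size))] = {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in pooled.items() if not isinstance(v, tuple)
            }
        if dist_tables:
            write_tsv(pd.concat(dist_tables, ignore_index=True),
                      out / "distribution_fits.tsv", tag)
            write_tsv(pd.DataFrame(summaries), out / "distribution_summary.tsv", tag)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["artifacts"] = sorted(
        p.name for p in out.iterdir() if p.name != "manifest.json"
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
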