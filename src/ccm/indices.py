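"""The three density indices and the response metrics built on them.

Three per-species estimates of how common a food species is:

* **CCM Index** — fraction of home-range cells in which the consumer
  fed on the species (presence cells within the kernel home range over
  all home-range cells); unitless in [0, 1].
* **Plot Density** — stems per unit area from fixed 50 x 50 m
  vegetation plots (individuals/km² and /ha).
* **Plot Presence** — fraction of plots containing at least one
  qualifying stem of the species; unitless in [0, 1].

Also here: species accumulation curves over observation days and the
day they effectively saturate, the per-species rate at which the
consumer "misses" plot-detected occurrences at coarse aggregation
scales, the standardized density-difference response, and the DBH
selectivity contrast between consumed and plot-measured stems.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .grid import DEFAULT_SIZE_MINIMA, GridSpec, OccupancyGrid

__all__ = [
    "PlotInventory",
    "ccm_index",
    "plot_density",
    "plot_presence",
    "consumption_rank",
    "species_index_table",
    "accumulation_curve",
    "accumulation_speed",
    "miss_rate",
    "density_difference",
    "dbh_selectivity",
]

PLOT_AREA_KM2 = 0.0025  # one 50 x 50 m plot
PLOT_AREA_HA = 0.25


@dataclass
class PlotInventory:
    """Fixed-area vegetation plots and the stems measured inside them.

    ``plots``: DataFrame with columns plot_id, x, y (centroid, m).
    ``stems``: DataFrame with columns plot_id, species, dbh_cm, lifeform.
    All plots share one square footprint of side ``footprint`` meters.
    """

    plots: pd.DataFrame
    stems: pd.DataFrame
    footprint: float = 50.0

    def __post_init__(self) -> None:
        self.plots = pd.DataFrame(self.plots).reset_index(drop=True)
        self.stems = pd.DataFrame(self.stems).reset_index(drop=True)
        for col in ("plot_id", "x", "y"):
            if col not in self.plots.columns:
                raise ValueError(f"plots table missing column {col!r}")
        if self.plots.plot_id.duplicated().any():
            raise ValueError("duplicate plot ids")
        if len(self.stems):
            for col in ("plot_id", "species", "dbh_cm", "lifeform"):
                if col not in self.stems.columns:
                    raise ValueError(f"stems table missing column {col!r}")
            unknown = set(self.stems.plot_id) - set(self.plots.plot_id)
            if unknown:
                raise ValueError(f"stems reference unknown plot id(s): {sorted(unknown)[:5]}")

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    def plot_centroids(self) -> dict:
        return {r.plot_id: (r.x, r.y) for r in self.plots.itertuples()}

    def qualifying_stems(self, minima: Mapping[str, float] | None = None) -> pd.DataFrame:
        """Stems meeting the per-lifeform DBH minima (all stems if minima is None)."""
        if not len(self.stems):
            return self.stems
        if minima is None:
            return self.stems
        keep = pd.Series(False, index=self.stems.index)
        for lifeform, lo in minima.items():
            keep |= (self.stems.lifeform == lifeform) & (self.stems.dbh_cm >= lo)
        return self.stems[keep]

    def subset(self, plot_ids) -> "PlotInventory":
        ids = set(plot_ids)
        return PlotInventory(
            plots=self.plots[self.plots.plot_id.isin(ids)],
            stems=self.stems[self.stems.plot_id.isin(ids)] if len(self.stems) else self.stems,
            footprint=self.footprint,
        )


def ccm_index(occupancy: OccupancyGrid, hr_cells: set) -> pd.Series:
    """Per-species fraction of home-range cells with a feeding presence."""
    if not hr_cells:
        raise ValueError("home-range cell set is empty")
    n = len(hr_cells)
    vals = {
        sp: len(set(cells) & hr_cells) / n for sp, cells in occupancy.species.items()
    }
    return pd.Series(vals, dtype=float).sort_index().rename("ccm_index")


def plot_density(
    inv: PlotInventory, minima: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Per-species stem density over the sampled plot area.

    Columns ``per_km2`` and ``per_ha``; denominator is the total plot
    area (n_plots x 0.25 ha), as for a pooled transect.
    """
    if inv.n_plots == 0:
        raise ValueError("plot density requires at least one plot")
    stems = inv.qualifying_stems(minima)
    counts = stems.groupby("species").size() if len(stems) else pd.Series(dtype=int)
    per_km2 = counts / (inv.n_plots * PLOT_AREA_KM2)
    per_ha = counts / (inv.n_plots * PLOT_AREA_HA)
    out = pd.DataFrame({"per_km2": per_km2, "per_ha": per_ha}).astype(float)
    out.index.name = "species"
    return out.sort_index()


def pooled_plot_density(inv: PlotInventory, minima: Mapping[str, float] | None = None) -> float:
    """All-species pooled density, individuals/ha."""
    if inv.n_plots == 0:
        raise ValueError("plot density requires at least one plot")
    n = len(inv.qualifying_stems(minima))
    return n / (inv.n_plots * PLOT_AREA_HA)


def plot_presence(
    inv: PlotInventory, minima: Mapping[str, float] | None = None
) -> pd.Series:
    """Per-species fraction of plots containing >= 1 qualifying stem."""
    if inv.n_plots == 0:
        raise ValueError("plot presence requires at least one plot")
    stems = inv.qualifying_stems(minima)
    if not len(stems):
        return pd.Series(dtype=float, name="plot_presence")
    n_present = stems.groupby("species").plot_id.nunique()
    return (n_present / inv.n_plots).astype(float).sort_index().rename("plot_presence")


def consumption_rank(occupancy: OccupancyGrid) -> pd.Series:
    """Rank species by number of distinct presence cells (1 = most consumed).

    Ties are broken lexicographically by species label so the ranking is
    deterministic.
    """
    items = sorted(
        ((sp, len(cells)) for sp, cells in occupancy.species.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return pd.Series(
        {sp: rank for rank, (sp, _) in enumerate(items, start=1)}, dtype=int
    ).rename("consumption_rank")


def species_index_table(
    occupancy: OccupancyGrid,
    inv: PlotInventory,
    hr_cells: set,
    minima: Mapping[str, float] | None = DEFAULT_SIZE_MINIMA,
) -> pd.DataFrame:
    """One row per species: all three indices plus ranks and raw counts."""
    ccm = ccm_index(occupancy, hr_cells)
    dens = plot_density(inv, minima)
    pres = plot_presence(inv, minima)
    ranks = consumption_rank(occupancy)
    species = sorted(set(ccm.index) | set(dens.index) | set(pres.index))
    tbl = pd.DataFrame(index=pd.Index(species, name="species"))
    tbl["ccm_index"] = ccm.reindex(species).fillna(0.0)
    tbl["plot_density_km2"] = dens.per_km2.reindex(species).fillna(0.0)
    tbl["plot_density_ha"] = dens.per_ha.reindex(species).fillna(0.0)
    tbl["plot_presence"] = pres.reindex(species).fillna(0.0)
    tbl["consumption_rank"] = ranks.reindex(species)
    tbl["n_presence_cells"] = [occupancy.n_presence_cells(sp) for sp in species]
    stems = inv.qualifying_stems(minima)
    n_ind = stems.groupby("species").size() if len(stems) else pd.Series(dtype=int)
    tbl["n_plot_individuals"] = n_ind.reindex(species).fillna(0).astype(int)
    return tbl


def accumulation_curve(
    occupancy: OccupancyGrid, species: str | None = None
) -> pd.Series:
    """Cumulative unique presence cells against 1-based day index.

    Day index counts days since the first record.  ``species=None``
    accumulates all (species, cell) presences together.  The result is a
    non-decreasing step function sampled at days on which anything was
    added, ending at the total.
    """
    if species is None:
        dates = [
            v.first_date for cells in occupancy.species.values() for v in cells.values()
        ]
    else:
        dates = [v.first_date for v in occupancy.species.get(species, {}).values()]
    if not dates:
        return pd.Series(dtype=float, name="cumulative_presences")
    day0 = min(
        v.first_date for cells in occupancy.species.values() for v in cells.values()
    )
    idx = sorted((d - day0).days + 1 for d in dates)
    ser = pd.Series(idx).value_counts().sort_index().cumsum()
    ser.index.name = "day_index"
    return ser.astype(float).rename("cumulative_presences")


def fraction_by_day(curve: pd.Series, day: int) -> float:
    """Fraction of the curve's final value accumulated by the given day."""
    if curve.empty:
        raise ValueError("empty accumulation curve")
    upto = curve[curve.index <= day]
    return float(upto.iloc[-1] / curve.iloc[-1]) if len(upto) else 0.0


def accumulation_speed(curve: pd.Series, threshold: float = 0.9) -> int:
    """First day index at which the curve reaches ``threshold`` of its final value."""
    if curve.empty:
        raise ValueError("empty accumulation curve")
    target = threshold * curve.iloc[-1]
    hit = curve[curve >= target]
    return int(hit.index[0])


def miss_rate(
    occupancy: OccupancyGrid,
    inv: PlotInventory,
    agg_grid: GridSpec,
    visited_only: bool = True,
) -> pd.Series:
    """Per-species fraction of plot-detected aggregation cells the CCM missed.

    Plot detections and CCM presences are both mapped onto the coarse
    ``agg_grid``.  For each species the rate is the share of cells where
    plots found the species but the consumer dataset shows no presence.
    With ``visited_only`` (default) the universe is restricted to
    aggregation cells the consumer visited at all — an unvisited cell
    cannot logically contain a CCM presence.  Species never detected in
    plots get NaN (undefined), not 0.
    """
    plot_cell = dict(
        zip(inv.plots.plot_id, zip(*agg_grid.index(inv.plots.x.values, inv.plots.y.values)))
    ) if inv.n_plots else {}
    visited_agg = {
        (int(i), int(j))
        for i, j in zip(*agg_grid.index(
            np.array([occupancy.grid.cell_center(ci, cj)[0] for ci, cj in occupancy.visited_cells]),
            np.array([occupancy.grid.cell_center(ci, cj)[1] for ci, cj in occupancy.visited_cells]),
        ))
    } if occupancy.visited_cells else set()

    stems = inv.qualifying_stems(None)
    out: dict[str, float] = {}
    all_species = sorted(set(occupancy.species) | (set(stems.species) if len(stems) else set()))
    for sp in all_species:
        sp_plots = stems[stems.species == sp].plot_id.unique() if len(stems) else []
        detected = {plot_cell[p] for p in sp_plots if p in plot_cell}
        if visited_only:
            detected &= visited_agg
        if not detected:
            out[sp] = np.nan
            continue
        ccm_cells = {
            tuple(int(v) for v in agg_grid.index(*occupancy.grid.cell_center(ci, cj)))
            for (ci, cj) in occupancy.presence_cells(sp)
        }
        missed = len(detected - ccm_cells)
        out[sp] = missed / len(detected)
    return pd.Series(out, dtype=float).rename("miss_rate")


def density_difference(table: pd.DataFrame) -> pd.Series:
    """Standardized CCM-vs-plot density difference per species.

    Both indices are log-transformed (zero entries excluded) and
    z-scored across species; the difference z(log CCM) - z(log Plot
    Density) is positive where the CCM overestimates relative to plots.
    """
    ok = (table.ccm_index > 0) & (table.plot_density_km2 > 0)
    if ok.sum() < 3:
        raise ValueError("density_difference needs >= 3 species with both indices > 0")
    lc = np.log(table.ccm_index[ok])
    lp = np.log(table.plot_density_km2[ok])
    z = lambda v: (v - v.mean()) / v.std(ddof=1)
    return (z(lc) - z(lp)).rename("density_difference")


def dbh_selectivity(fed_dbh, plot_dbh) -> tuple[float, float, float]:
    """Welch two-sample t contrast of consumed vs plot-measured DBH.

    Returns ``(mean_difference_cm, t, p)`` with the difference signed
    fed minus plot (positive = consumer selects larger stems).
    """
    fed = np.asarray(fed_dbh, dtype=float)
    plot = np.asarray(plot_dbh, dtype=float)
    if len(fed) < 2 or len(plot) < 2:
        raise ValueError("both DBH samples need n >= 2")
    if np.any(fed <= 0) or np.any(plot <= 0):
        raise ValueError("DBH values must be positive")
    if fed.std(ddof=1) == 0 and plot.std(ddof=1) == 0:
        if fed.mean() == plot.mean():
            return 0.0, 0.0, 1.0
        raise ValueError("both samples are constant; Welch t undefined")
    t, p = stats.ttest_ind(fed, plot, equal_var=False)
    return float(fed.mean() - plot.mean()), float(t), float(p)
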