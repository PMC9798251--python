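"""Cross-method agreement: correlation sweeps, moving windows, stability.

Agreement between the consumer-centric indices and the plot-based
indices is measured with Pearson's r on log-transformed index values,
swept over two inclusion axes: how much of the kernel home range is
considered (isopleth percent, 20-95 in 1% steps) and how much of the
diet (the top-k most consumed species, k from 10 up to the full diet).
A comparison is only emitted when it rests on at least 10 species and
10 vegetation plots.  p-values are carried along for completeness but
never used to filter (thousands of non-independent correlations are
evaluated; inference rests on r).

The moving window slides a percent-kernel band across the home range,
growing its half-width until enough plots and observational cells fall
inside, so core and periphery are compared on similarly sized datasets.
Temporal stability recomputes the CCM index on growing day-prefixes of
the feeding dataset against the fixed plot estimates, to find the day
from which agreement stays put.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import DEFAULT_SIZE_MINIMA, OccupancyGrid
from .homerange import KernelAssignment
from .indices import PLOT_AREA_KM2, PlotInventory, consumption_rank

__all__ = [
    "pearson",
    "correlation_sweep",
    "moving_window",
    "temporal_stability",
    "COMPARISONS",
]

COMPARISONS = (
    "ccm~plot_density",
    "ccm~plot_presence",
    "plot_presence~plot_density",
)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p from the t transform.

    A constant vector leaves r undefined: returns (nan, nan) with a
    warning rather than raising, so sweep callers can flag and move on.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _log_pairs(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete log values: species with either index at 0 drop out."""
    ok = (a > 0) & (b > 0)
    return np.log(a[ok].values), np.log(b[ok].values)


def _corr_rows(ccm: pd.Series, dens: pd.Series, pres: pd.Series) -> dict:
    out = {}
    for name, (a, b) in {
        "ccm~plot_density": (ccm, dens),
        "ccm~plot_presence": (ccm, pres),
        "plot_presence~plot_density": (pres, dens),
    }.items():
        la, lb = _log_pairs(a, b)
        if len(la) >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p = pearson(la, lb)
        else:
            r, p = float("nan"), float("nan")
        out[name] = (r, p, len(la))
    return out


class _SweepData:
    """Percent-kernel-indexed views of the datasets, shared by the sweeps."""

    def __init__(
        self,
        occupancy: OccupancyGrid,
        inv: PlotInventory,
        cell_ka: KernelAssignment,
        plot_ka: KernelAssignment,
        minima: Mapping[str, float] | None,
    ):
        self.inv = inv
        self.ranks = consumption_rank(occupancy)
        self.all_cell_pcts = np.sort(np.fromiter(cell_ka.percents.values(), dtype=float))
        self.species_pcts = {
            sp: np.sort(
                np.array([cell_ka.percents[c] for c in cells if c in cell_ka.percents])
            )
            for sp, cells in occupancy.species.items()
        }
        ids = list(plot_ka.percents)
        self.plot_ids = np.array(ids, dtype=object)
        self.plot_pcts = np.array([plot_ka.percents[p] for p in ids])
        stems = inv.qualifying_stems(minima)
        if len(stems):
            counts = stems.groupby(["species", "plot_id"]).size().unstack(fill_value=0)
            self.counts = counts.reindex(columns=ids, fill_value=0)
        else:
            self.counts = pd.DataFrame(index=pd.Index([], name="species"), columns=ids).fillna(0)

    def n_cells_upto(self, p: float) -> int:
        return int(np.searchsorted(self.all_cell_pcts, p, side="right"))

    def n_cells_band(self, lo: float, hi: float) -> int:
        a = np.searchsorted(self.all_cell_pcts, lo, side="left")
        b = np.searchsorted(self.all_cell_pcts, hi, side="right")
        return int(b - a)

    def indices_in_band(
        self, lo: float, hi: float, species: Sequence[str]
    ) -> tuple[pd.Series, pd.Series, pd.Series, int, int] | None:
        """CCM index, plot density, plot presence over a percent band.

        Returns None when no observational cell falls in the band.
        """
        n_cells = self.n_cells_band(lo, hi)
        if n_cells == 0:
            return None
        in_band = (self.plot_pcts >= lo) & (self.plot_pcts <= hi)
        plot_ids = self.plot_ids[in_band]
        n_plots = len(plot_ids)
        ccm = pd.Series(
            {
                sp: (
                    np.searchsorted(self.species_pcts.get(sp, np.empty(0)), hi, side="right")
                    - np.searchsorted(self.species_pcts.get(sp, np.empty(0)), lo, side="left")
                )
                / n_cells
                for sp in species
            },
            dtype=float,
        )
        if n_plots:
            sub = self.counts.loc[:, self.counts.columns.isin(plot_ids)]
            totals = sub.sum(axis=1).reindex(species).fillna(0.0)
            dens = totals / (n_plots * PLOT_AREA_KM2)
            pres = (sub > 0).sum(axis=1).reindex(species).fillna(0) / n_plots
        else:
            dens = pd.Series(0.0, index=species)
            pres = pd.Series(0.0, index=species)
        return ccm, dens.astype(float), pres.astype(float), n_cells, n_plots


def correlation_sweep(
    occupancy: OccupancyGrid,
    inv: PlotInventory,
    cell_ka: KernelAssignment,
    plot_ka: KernelAssignment,
    kernel_range: tuple[int, int] = (20, 95),
    kernel_step: int = 1,
    top_k_values: Iterable[int] | None = None,
    min_species: int = 10,
    min_plots: int = 10,
    minima: Mapping[str, float] | None = DEFAULT_SIZE_MINIMA,
    group: str = "",
) -> pd.DataFrame:
    """All pairwise index correlations over the kernel% x diet-size sweep.

    At each (kernel p, top_k): the CCM index is recomputed with the p%
    isopleth cells as denominator, plots are restricted to centroids
    inside the isopleth, and species to the top_k consumption ranks that
    have at least one qualifying stem in an in-scope plot.  Grid points
    failing the >= ``min_species`` / >= ``min_plots`` thresholds are
    omitted, not zero-filled.  Deterministic: no randomness anywhere.
    """
    data = _SweepData(occupancy, inv, cell_ka, plot_ka, minima)
    diet = data.ranks.sort_values().index.tolist()
    if top_k_values is None:
        top_k_values = range(min(10, len(diet)), len(diet) + 1)
    rows = []
    lo_p, hi_p = kernel_range
    for p in range(lo_p, hi_p + 1, kernel_step):
        band = data.indices_in_band(0.0, float(p), diet)
        if band is None:
            continue
        ccm_all, dens_all, pres_all, n_cells, n_plots = band
        if n_plots < min_plots:
            continue
        present_in_plots = dens_all > 0
        for k in top_k_values:
            topk = diet[:k]
            eligible = [sp for sp in topk if present_in_plots.get(sp, False)]
            if len(eligible) < min_species:
                continue
            res = _corr_rows(ccm_all[eligible], dens_all[eligible], pres_all[eligible])
            for comp, (r, pv, n) in res.items():
                rows.append(
                    dict(group=group, kernel_percent=p, top_k=k, comparison=comp,
                         r=r, p=pv, n_species=n, n_plots=n_plots, n_cells=n_cells)
                )
    return pd.DataFrame(
        rows,
        columns=["group", "kernel_percent", "top_k", "comparison", "r", "p",
                 "n_species", "n_plots", "n_cells"],
    )


def moving_window(
    occupancy: OccupancyGrid,
    inv: PlotInventory,
    cell_ka: KernelAssignment,
    plot_ka: KernelAssignment,
    centers: Iterable[int] = range(20, 96),
    min_plots: int = 20,
    min_cells: int = 200,
    top_k: int | None = None,
    min_species: int = 10,
    minima: Mapping[str, float] | None = DEFAULT_SIZE_MINIMA,
    group: str = "",
) -> pd.DataFrame:
    """Index agreement within a sliding percent-kernel band.

    For each center percent the band half-width grows in 1% steps until
    at least ``min_plots`` plots and ``min_cells`` observational cells
    fall inside (``min_cells`` defaults to 200, which matches 20 plots
    in covered area: 20 x 2500 m² = 200 x 250... exposed in config).
    Centers whose band cannot satisfy the minima even at full range are
    flagged unsatisfiable rather than dropped.
    """
    data = _SweepData(occupancy, inv, cell_ka, plot_ka, minima)
    diet = data.ranks.sort_values().index.tolist()
    species = diet[:top_k] if top_k else diet
    rows = []
    for c in centers:
        w = 0.0
        while True:
            lo, hi = max(0.0, c - w), min(100.0, c + w)
            n_plots = int(np.sum((data.plot_pcts >= lo) & (data.plot_pcts <= hi)))
            n_cells = data.n_cells_band(lo, hi)
            if (n_plots >= min_plots and n_cells >= min_cells) or (lo == 0.0 and hi == 100.0):
                break
            w += 1.0
        satisfiable = n_plots >= min_plots and n_cells >= min_cells
        row = dict(group=group, center=c, half_width=w, n_plots=n_plots,
                   n_cells=n_cells, satisfiable=satisfiable)
        band = data.indices_in_band(lo, hi, species) if n_cells else None
        if band is not None and n_plots > 0:
            ccm, dens, pres, _, _ = band
            eligible = dens[dens > 0].index.tolist()
            if len(eligible) >= min_species:
                for comp, (r, pv, n) in _corr_rows(
                    ccm[eligible], dens[eligible], pres[eligible]
                ).items():
                    row[f"r_{comp}"] = r
                    row[f"p_{comp}"] = pv
                row["n_species"] = len(eligible)
        rows.append(row)
    return pd.DataFrame(rows)


def temporal_stability(
    occupancy: OccupancyGrid,
    inv: PlotInventory,
    hr_cells: set,
    eval_stride: int = 30,
    epsilon: float = 0.05,
    min_species: int = 10,
    minima: Mapping[str, float] | None = DEFAULT_SIZE_MINIMA,
) -> tuple[pd.DataFrame, int | None]:
    """Agreement of day-prefix CCM indices with the fixed plot estimates.

    Evaluates Pearson r (log scale) of the CCM index computed from all
    records up to day d against the full plot index, at days
    ``eval_stride, 2*eval_stride, ..., final``.  Returns the series and
    the stability day: the first evaluation day after which r stays
    within ``epsilon`` of its final value.
    """
    if not hr_cells:
        raise ValueError("home-range cell set is empty")
    first_days: dict[str, np.ndarray] = {}
    all_dates = [
        v.first_date for cells in occupancy.species.values() for v in cells.values()
    ]
    if not all_dates:
        raise ValueError("occupancy has no dated presences")
    day0 = min(all_dates)
    for sp, cells in occupancy.species.items():
        days = np.sort(
            np.array(
                [(v.first_date - day0).days + 1 for cell, v in cells.items() if cell in hr_cells]
            )
        )
        first_days[sp] = days
    total_days = max((int(d[-1]) for d in first_days.values() if len(d)), default=1)

    from .indices import plot_density  # local import to avoid cycle at module load

    dens = plot_density(inv, minima).per_km2
    pres_sp = dens[dens > 0]
    n_hr = len(hr_cells)

    eval_days = sorted(set(range(eval_stride, total_days + 1, eval_stride)) | {total_days})
    rows = []
    for d in eval_days:
        ccm = pd.Series(
            {sp: np.searchsorted(first_days.get(sp, np.empty(0)), d, side="right") / n_hr
             for sp in pres_sp.index},
            dtype=float,
        )
        la, lb = _log_pairs(ccm, pres_sp)
        if len(la) >= max(3, min_species):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, pv = pearson(la, lb)
        else:
            r, pv = float("nan"), float("nan")
        rows.append(dict(day=d, r=r, p=pv, n_species=len(la)))
    series = pd.DataFrame(rows)

    r_final = series.r.iloc[-1]
    stability_day: int | None = None
    for i in range(len(series)):
        tail = series.r.iloc[i:]
        if tail.notna().all() and (tail - r_final).abs().max() <= epsilon:
            stability_day = int(series.day.iloc[i])
            break
    return series, stability_day
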