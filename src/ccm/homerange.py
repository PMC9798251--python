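"""Kernel utilization distributions and percent-kernel (isopleth) lookup.

The home range is summarized as a kernel density estimate (KDE) of the
consumer's recorded positions, evaluated on a regular raster.  The
"percent kernel" of a location is the level of the smallest isopleth
(highest-density region) that contains it: a location at the density
mode has a percent near 0 (deep core) and a far-field location has 100
(extreme periphery).  Observational cells and vegetation plots are
assigned the percent kernel of their center/centroid, which is how both
are later restricted to, e.g., the 95% kernel home range.

The KDE is a product-Gaussian estimate computed by binning points onto
the evaluation raster and convolving with a Gaussian (an accurate and
fast equivalent of the direct sum when the bandwidth spans several
pixels).  The default per-axis bandwidth is the 2-D reference
(Silverman-type) rule ``sigma_axis * n^(-1/6)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "Tracklog",
    "UtilizationDistribution",
    "KernelAssignment",
    "reference_bandwidth",
    "estimate_utilization",
    "percent_kernel",
    "assign_cells",
    "assign_plots",
    "cells_within_isopleth",
]


@dataclass
class Tracklog:
    """Ordered, optionally timestamped positions of one consumer group."""

    xy: np.ndarray  # (n, 2) metric coordinates
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("tracklog xy must be (n, 2)")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("tracklog contains non-finite coordinates")
        if self.timestamps is not None:
            ts = np.asarray(self.timestamps)
            if len(ts) != len(self.xy):
                raise ValueError("timestamps and xy lengths differ")
            if np.any(ts[1:] < ts[:-1]):
                raise ValueError("timestamps must be non-decreasing")
            self.timestamps = ts

    def __len__(self) -> int:
        return len(self.xy)


def reference_bandwidth(xy: np.ndarray) -> float:
    """Per-axis reference-rule bandwidth (m): mean axis SD times n^(-1/6)."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    sd = xy.std(axis=0, ddof=1)
    h = float(sd.mean()) * n ** (-1.0 / 6.0)
    if not h > 0:
        raise ValueError("degenerate (all-identical) points give zero bandwidth; pass one explicitly")
    return h


@dataclass
class UtilizationDistribution:
    """A space-use density surface on a regular raster, unit total mass.

    ``density[j, i]`` is the density at pixel column i (x) and row j (y);
    pixel (0, 0) spans ``[xmin, xmin+resolution) x [ymin, ymin+resolution)``.
    """

    density: np.ndarray
    xmin: float
    ymin: float
    resolution: float
    bandwidth: float
    _order: np.ndarray = field(init=False, repr=False)
    _cummass: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        mass = self.density.sum() * self.resolution**2
        if mass <= 0:
            raise ValueError("utilization distribution has zero mass")
        self.density = self.density / mass
        # Sorted descending densities and their cumulative mass: the
        # percent kernel of a density level d is the mass of all pixels
        # with density >= d.
        flat = np.sort(self.density.ravel())[::-1]
        self._order = flat
        self._cummass = np.cumsum(flat) * self.resolution**2

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.resolution**2)

    def contains(self, x: float, y: float) -> bool:
        ny, nx = self.density.shape
        return (
            self.xmin <= x < self.xmin + nx * self.resolution
            and self.ymin <= y < self.ymin + ny * self.resolution
        )

    def density_at(self, x, y):
        """Bilinearly interpolated density at (x, y); NaN outside the raster."""
        scalar = np.isscalar(x) and np.isscalar(y)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        ny, nx = self.density.shape
        res = self.resolution
        # fractional pixel-center coordinates
        fx = (x - self.xmin) / res - 0.5
        fy = (y - self.ymin) / res - 0.5
        inside = (fx >= -0.5) & (fx < nx - 0.5) & (fy >= -0.5) & (fy < ny - 0.5)
        out = np.full(x.shape, np.nan)
        if inside.any():
            fxi = np.clip(fx[inside], 0, nx - 1)
            fyi = np.clip(fy[inside], 0, ny - 1)
            i0 = np.clip(np.floor(fxi).astype(int), 0, nx - 2) if nx > 1 else np.zeros(fxi.shape, int)
            j0 = np.clip(np.floor(fyi).astype(int), 0, ny - 2) if ny > 1 else np.zeros(fyi.shape, int)
            tx = fxi - i0 if nx > 1 else np.zeros_like(fxi)
            ty = fyi - j0 if ny > 1 else np.zeros_like(fyi)
            i1 = np.minimum(i0 + 1, nx - 1)
            j1 = np.minimum(j0 + 1, ny - 1)
            d = self.density
            out[inside] = (
                d[j0, i0] * (1 - tx) * (1 - ty)
                + d[j0, i1] * tx * (1 - ty)
                + d[j1, i0] * (1 - tx) * ty
                + d[j1, i1] * tx * ty
            )
        return float(out[0]) if scalar else out

    def percent_at(self, x, y):
        """Percent kernel in (0, 100] of each location.

        100 * mass of all pixels at least as dense as the location's
        pixel, i.e. the level of the smallest isopleth containing it.
        Locations outside the raster get 100 with a warning.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        d = np.atleast_1d(self.density_at(x, y))
        outside = np.isnan(d)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} location(s) outside the UD raster assigned percent 100",
                stacklevel=2,
            )
        pct = np.full(d.shape, 100.0)
        inside = ~outside
        if inside.any():
            # index of the last sorted density >= d  (descending order)
            idx = np.searchsorted(-self._order, -d[inside], side="right") - 1
            pct[inside] = np.minimum(100.0, 100.0 * self._cummass[idx])
        return pct if pct.size > 1 else float(pct[0])


def estimate_utilization(
    track: Tracklog | np.ndarray,
    bandwidth: float | None = None,
    eval_resolution: float = 25.0,
    pad_bandwidths: float = 5.0,
) -> UtilizationDistribution:
    """Gaussian-kernel utilization distribution from recorded positions.

    The raster extends ``pad_bandwidths`` bandwidths beyond the data
    bounding box so that essentially no kernel mass is truncated.
    Needs at least 10 points (an estimate from fewer is not a home range).
    """
    xy = track.xy if isinstance(track, Tracklog) else np.asarray(track, dtype=float)
    if len(xy) < 10:
        raise ValueError(f"need >= 10 track points for a utilization distribution, got {len(xy)}")
    if bandwidth is None:
        bandwidth = reference_bandwidth(xy)
    if not bandwidth > 0:
        raise ValueError("bandwidth must be > 0")

    pad = pad_bandwidths * bandwidth
    res = float(eval_resolution)
    xmin = np.floor((xy[:, 0].min() - pad) / res) * res
    ymin = np.floor((xy[:, 1].min() - pad) / res) * res
    nx = int(np.ceil((xy[:, 0].max() + pad - xmin) / res))
    ny = int(np.ceil((xy[:, 1].max() + pad - ymin) / res))

    hist = np.zeros((ny, nx))
    i = np.clip(((xy[:, 0] - xmin) / res).astype(int), 0, nx - 1)
    j = np.clip(((xy[:, 1] - ymin) / res).astype(int), 0, ny - 1)
    np.add.at(hist, (j, i), 1.0)
    density = ndimage.gaussian_filter(hist, sigma=bandwidth / res, mode="constant")
    return UtilizationDistribution(
        density=density, xmin=float(xmin), ymin=float(ymin), resolution=res, bandwidth=float(bandwidth)
    )


def percent_kernel(ud: UtilizationDistribution, location: tuple[float, float]) -> float:
    """Percent kernel of a single location (see ``UtilizationDistribution.percent_at``)."""
    return float(ud.percent_at(location[0], location[1]))


@dataclass
class KernelAssignment:
    """Percent-kernel values assigned to cells (by center) or plots (by centroid)."""

    percents: dict  # key (cell index or plot id) -> percent in (0, 100]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.percents.items() if not (0 < v <= 100)}
        if bad:
            raise ValueError(f"percent-kernel values outside (0, 100]: {bad}")

    def cells_within(self, p: float) -> set:
        if not (0 < p <= 100):
            raise ValueError(f"isopleth percent must be in (0, 100], got {p}")
        return {k for k, v in self.percents.items() if v <= p}

    def __len__(self) -> int:
        return len(self.percents)


def assign_cells(
    ud: UtilizationDistribution,
    cells: Iterable[tuple[int, int]],
    grid,
) -> KernelAssignment:
    """Percent kernel of each grid cell, looked up at the cell center."""
    cells = list(cells)
    if not cells:
        return KernelAssignment(percents={})
    centers = np.array([grid.cell_center(i, j) for (i, j) in cells])
    pct = np.atleast_1d(ud.percent_at(centers[:, 0], centers[:, 1]))
    return KernelAssignment(percents=dict(zip(cells, pct.tolist())))


def assign_plots(ud: UtilizationDistribution, plot_xy: Mapping[object, tuple[float, float]]) -> KernelAssignment:
    """Percent kernel of each plot, looked up at its centroid."""
    if not plot_xy:
        return KernelAssignment(percents={})
    ids = list(plot_xy)
    coords = np.array([plot_xy[k] for k in ids], dtype=float)
    pct = np.atleast_1d(ud.percent_at(coords[:, 0], coords[:, 1]))
    return KernelAssignment(percents=dict(zip(ids, pct.tolist())))


def cells_within_isopleth(ka: KernelAssignment, p: float) -> set:
    """Cells (or plots) whose percent kernel is <= p — the p% home range."""
    return ka.cells_within(p)
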