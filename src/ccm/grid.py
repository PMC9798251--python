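"""Square-grid rasterization of feeding locations into species occupancy.

The consumer-centric method (CCM) reduces GPS feeding locations to
presence/absence of each food species in square "observational cells"
(50 x 50 m in the field protocol, chosen to absorb typical handheld-GPS
error of 15-20 m).  This module owns the deterministic point -> cell
mapping, the per-species occupancy bookkeeping, and the two simple
filters applied before any index is computed: minimum stem size (DBH)
per lifeform, and the surveyed-area arithmetic.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "FeedingRecord",
    "OccupancyGrid",
    "DEFAULT_SIZE_MINIMA",
    "snap_to_cell",
    "rasterize_records",
    "surveyed_area",
    "apply_size_minima",
]

logger = logging.getLogger(__name__)

#: Minimum diameter at breast height (cm) for a stem to count as an
#: available feeding patch, per lifeform.  Boundary is inclusive (>=).
DEFAULT_SIZE_MINIMA: dict[str, float] = {"tree": 20.0, "liana": 5.0}


@dataclass(frozen=True)
class GridSpec:
    """A regular square grid anchored at ``(origin_x, origin_y)``.

    Cells are half-open squares ``[edge, edge + cell_size)`` on both
    axes, indexed by ``(i, j) = (floor((x-x0)/s), floor((y-y0)/s))``.
    Coordinates are metric (a projected CRS); ``crs_label`` is carried
    as free text and never interpreted.
    """

    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        if not (self.cell_size > 0):
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    def index(self, x, y):
        """Vectorized point -> (i, j) cell index (floor semantics)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite coordinates cannot be assigned to a cell")
        i = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        j = np.floor((y - self.origin_y) / self.cell_size).astype(int)
        return i, j

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        s = self.cell_size
        return (self.origin_x + (i + 0.5) * s, self.origin_y + (j + 0.5) * s)

    def cell_bounds(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the half-open cell."""
        s = self.cell_size
        x0 = self.origin_x + i * s
        y0 = self.origin_y + j * s
        return (x0, y0, x0 + s, y0 + s)


@dataclass(frozen=True)
class FeedingRecord:
    """One visit to a consumed stem: when, where, what species, how large.

    ``dbh`` is in cm and may be ``None`` when the stem was not measured;
    ``lifeform`` is ``"tree"`` or ``"liana"``.
    """

    date: _dt.date
    group_id: str
    species: str
    x: float
    y: float
    dbh: float | None = None
    lifeform: str = "tree"

    def __post_init__(self) -> None:
        if self.dbh is not None and not self.dbh > 0:
            raise ValueError(f"dbh must be > 0 when present, got {self.dbh}")


@dataclass(frozen=True)
class CellVisit:
    first_date: _dt.date
    n_records: int


@dataclass
class OccupancyGrid:
    """Per-species presence over grid cells, plus the visited-cell universe.

    ``species`` maps species label -> {cell_index: CellVisit}; repeated
    visits to one (species, cell) collapse to a single presence with the
    earliest date kept.  ``visited_cells`` is every cell the consumer fed
    in, including cells whose records lacked a species identification —
    visitation is evidence of space use even when the item is unresolved.
    """

    grid: GridSpec
    species: dict[str, dict[tuple[int, int], CellVisit]] = field(default_factory=dict)
    visited_cells: set[tuple[int, int]] = field(default_factory=set)
    n_skipped_unidentified: int = 0

    def presence_cells(self, species: str) -> set[tuple[int, int]]:
        return set(self.species.get(species, {}))

    @property
    def species_list(self) -> list[str]:
        return sorted(self.species)

    def n_presence_cells(self, species: str) -> int:
        return len(self.species.get(species, {}))

    def total_presences(self) -> int:
        """Total unique (species, cell) feeding locations."""
        return sum(len(cells) for cells in self.species.values())

    def validate(self) -> None:
        for sp, cells in self.species.items():
            for cell, visit in cells.items():
                if cell not in self.visited_cells:
                    raise AssertionError(f"{sp} presence cell {cell} not in visited set")
                if visit.n_records < 1:
                    raise AssertionError(f"{sp} cell {cell} has n_records < 1")


def snap_to_cell(point: tuple[float, float], grid: GridSpec) -> tuple[int, int]:
    """Assign a point to its (half-open) grid cell."""
    x, y = point
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite coordinates {point!r} cannot be snapped to a cell")
    i, j = grid.index(x, y)
    return int(i), int(j)


def rasterize_records(records: Iterable[FeedingRecord], grid: GridSpec) -> OccupancyGrid:
    """Collapse dated feeding records into per-species cell presences.

    Records with an empty species label are skipped from the species maps
    (counted in ``n_skipped_unidentified``) but their cells still enter
    ``visited_cells``.
    """
    occ = OccupancyGrid(grid=grid)
    for rec in records:
        cell = snap_to_cell((rec.x, rec.y), grid)
        occ.visited_cells.add(cell)
        if not rec.species:
            occ.n_skipped_unidentified += 1
            continue
        cells = occ.species.setdefault(rec.species, {})
        prior = cells.get(cell)
        if prior is None:
            cells[cell] = CellVisit(first_date=rec.date, n_records=1)
        else:
            cells[cell] = CellVisit(
                first_date=min(prior.first_date, rec.date),
                n_records=prior.n_records + 1,
            )
    if occ.n_skipped_unidentified:
        logger.info(
            "rasterize_records: %d records had no species label (visited cells kept)",
            occ.n_skipped_unidentified,
        )
    return occ


def surveyed_area(occupancy: OccupancyGrid, ndigits: int | None = 1) -> float:
    """Area 'surveyed' by the consumer, in km²: |visited cells| x cell area.

    Reported to one decimal by default (pass ``ndigits=None`` for the
    exact value).
    """
    area_km2 = len(occupancy.visited_cells) * occupancy.grid.cell_size**2 / 1e6
    return area_km2 if ndigits is None else round(area_km2, ndigits)


def apply_size_minima(
    stems: Sequence[tuple[str, float | None, str]],
    minima: Mapping[str, float] = DEFAULT_SIZE_MINIMA,
) -> tuple[list[tuple[str, float, str]], int]:
    """Keep stems at or above their lifeform's DBH minimum (inclusive).

    ``stems`` rows are (species, dbh_cm, lifeform).  Stems with missing
    DBH are dropped and counted; an unknown lifeform is an error listing
    the offending rows.

    Returns ``(kept, n_dropped_missing_dbh)``.
    """
    if any(v < 0 for v in minima.values()):
        raise ValueError("size minima must be non-negative")
    unknown = [row for row in stems if row[2] not in minima]
    if unknown:
        raise ValueError(
            f"unknown lifeform(s) in {len(unknown)} stem row(s): {unknown[:5]!r}"
        )
    kept: list[tuple[str, float, str]] = []
    n_missing = 0
    for species, dbh, lifeform in stems:
        if dbh is None or (isinstance(dbh, float) and math.isnan(dbh)):
            n_missing += 1
            continue
        if dbh >= minima[lifeform]:
            kept.append((species, float(dbh), lifeform))
    return kept, n_missing
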