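"""Square analysis grids over a country polygon.

Cells are half-open squares ``[x0+c·s, x0+(c+1)·s) × [y0+r·s, y0+(r+1)·s)``
laid over the country's bounding box, indexed ``(col, row)`` from the grid
origin (default: lower-left bounding-box corner). A cell is kept only if
its intersection with the country has positive area; the clipped area (in
km²) is what area-based summaries use, while point-in-cell assignment uses
the full square extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .occurrences import OccurrenceSet

__all__ = [
    "AnalysisGrid",
    "CellAssignment",
    "SubGrid",
    "build_grid",
    "assign",
    "subgrid_incidence",
    "unsampled_area",
]

Cell = tuple[int, int]

# Clipped areas below this fraction of a full cell are treated as numerical
# slivers from polygon intersection and dropped.
_AREA_EPS_FRAC = 1e-12


@dataclass
class AnalysisGrid:
    """A rectangular lattice of half-open square cells clipped to a country."""

    origin: tuple[float, float]
    cell_size: float
    n_cols: int
    n_rows: int
    country: BaseGeometry
    #: (col, row) → clipped area in km²; cells fully outside are absent.
    cell_area_km2: dict[Cell, float]
    crs_tag: str = "planar"
    _cell_set: frozenset = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._cell_set = frozenset(self.cell_area_km2)

    def __contains__(self, cell: Cell) -> bool:
        return cell in self._cell_set

    @property
    def cells(self) -> list[Cell]:
        return sorted(self.cell_area_km2)

    @property
    def country_area_km2(self) -> float:
        return self.country.area / 1e6

    def cell_polygon(self, cell: Cell):
        c, r = cell
        x0, y0 = self.origin
        s = self.cell_size
        return box(x0 + c * s, y0 + r * s, x0 + (c + 1) * s, y0 + (r + 1) * s)

    def cell_centroid(self, cell: Cell) -> tuple[float, float]:
        """Centroid of the full square (not the clipped polygon)."""
        c, r = cell
        x0, y0 = self.origin
        s = self.cell_size
        return (x0 + (c + 0.5) * s, y0 + (r + 0.5) * s)

    def centroids(self, cells: list[Cell] | None = None) -> np.ndarray:
        cells = self.cells if cells is None else cells
        return np.array([self.cell_centroid(c) for c in cells], dtype=float)


@dataclass
class CellAssignment:
    """Per-record cell indices; records outside the grid are flagged.

    ``cells`` is a DataFrame aligned with the occurrence frame, columns
    ``col``/``row`` (nullable Int64, NA = outside the gridded country).
    """

    cells: pd.DataFrame
    n_outside: int

    def labels(self) -> pd.Series:
        """Series of (col, row) tuples, None where outside."""
        inside = self.cells["col"].notna().to_numpy()
        out = np.empty(len(self.cells), dtype=object)
        out[:] = None
        pairs = list(
            zip(
                self.cells.loc[inside, "col"].astype(int),
                self.cells.loc[inside, "row"].astype(int),
            )
        )
        if pairs:
            arr = np.empty(len(pairs), dtype=object)
            arr[:] = pairs
            out[inside] = arr
        return pd.Series(out, dtype=object)


@dataclass
class SubGrid:
    """1-km (by default) sub-cell species presence sets inside one cell."""

    parent: Cell
    sub_size: float
    #: (sub_col, sub_row) → set of species present
    presence: dict[Cell, set[str]]

    def incidence_counts(self) -> dict[str, int]:
        """Y_j: number of sub-cells where species j occurs at least once."""
        counts: dict[str, int] = {}
        for species_set in self.presence.values():
            for sp in species_set:
                counts[sp] = counts.get(sp, 0) + 1
        return counts

    @property
    def n_units(self) -> int:
        """T: number of sub-cells holding at least one record."""
        return len(self.presence)


def build_grid(
    country: BaseGeometry,
    cell_size: float,
    origin: tuple[float, float] | None = None,
    crs_tag: str = "planar",
) -> AnalysisGrid:
    """Lay a square grid over ``country`` and clip cells to it.

    Parameters
    ----------
    country
        Valid (multi)polygon in planar metres.
    cell_size
        Cell edge in metres (12500, 25000 and 50000 are the standard
        analysis resolutions).
    origin
        Grid origin; defaults to the lower-left corner of the country's
        bounding box.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if country is None or country.is_empty or country.area == 0:
        raise ValueError("country polygon is empty")
    if not country.is_valid:
        country = country.buffer(0)

    minx, miny, maxx, maxy = country.bounds
    if origin is None:
        origin = (minx, miny)
    x0, y0 = origin
    n_cols = max(1, math.ceil((maxx - x0) / cell_size - 1e-12))
    n_rows = max(1, math.ceil((maxy - y0) / cell_size - 1e-12))

    prepared = prep(country)
    eps = _AREA_EPS_FRAC * cell_size**2
    areas: dict[Cell, float] = {}
    for c in range(n_cols):
        for r in range(n_rows):
            sq = box(
                x0 + c * cell_size,
                y0 + r * cell_size,
                x0 + (c + 1) * cell_size,
                y0 + (r + 1) * cell_size,
            )
            if not prepared.intersects(sq):
                continue
            if prepared.contains_properly(sq):
                a = cell_size**2
            else:
                a = country.intersection(sq).area
                if a <= eps:
                    continue
            areas[(c, r)] = a / 1e6
    return AnalysisGrid(
        origin=(x0, y0),
        cell_size=float(cell_size),
        n_cols=n_cols,
        n_rows=n_rows,
        country=country,
        cell_area_km2=areas,
        crs_tag=crs_tag,
    )


def assign(occ: OccurrenceSet, grid: AnalysisGrid) -> CellAssignment:
    """Map each record to its half-open cell, or flag it "outside".

    Records falling outside the gridded bounding box, or in cells whose
    clipped area is zero (fully outside the country), are excluded from
    all downstream per-cell tallies and counted in ``n_outside``.
    """
    if occ.crs_tag != grid.crs_tag:
        raise ValueError(
            f"CRS mismatch: records {occ.crs_tag!r} vs grid {grid.crs_tag!r}"
        )
    x = occ.frame["x"].to_numpy(float)
    y = occ.frame["y"].to_numpy(float)
    x0, y0 = grid.origin
    col = np.floor((x - x0) / grid.cell_size).astype(int)
    row = np.floor((y - y0) / grid.cell_size).astype(int)
    in_bbox = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    valid = np.zeros((grid.n_cols, grid.n_rows), dtype=bool)
    for c, r in grid.cell_area_km2:
        valid[c, r] = True
    in_grid = in_bbox & valid[np.clip(col, 0, grid.n_cols - 1),
                              np.clip(row, 0, grid.n_rows - 1)]
    cells = pd.DataFrame(
        {
            "col": pd.array(np.where(in_grid, col, -1), dtype="Int64"),
            "row": pd.array(np.where(in_grid, row, -1), dtype="Int64"),
        }
    )
    cells.loc[~in_grid, ["col", "row"]] = pd.NA
    return CellAssignment(cells=cells, n_outside=int((~in_grid).sum()))


def subgrid_incidence(
    occ: OccurrenceSet,
    grid: AnalysisGrid,
    cell: Cell,
    sub_size: float | None = None,
) -> SubGrid:
    """Divide one cell into square sub-cells and record species presences.

    A species' incidence count Y_j is the number of sub-cells in which it
    appears at least once; multiple records in the same sub-cell collapse
    to one incidence.

    ``sub_size`` defaults to 1000 m and must divide the cell size exactly
    (12.5-km cells therefore need an explicit divisor such as 500 m).
    """
    if cell not in grid:
        raise KeyError(f"cell {cell} not in grid")
    if sub_size is None:
        sub_size = 1000.0
    ratio = grid.cell_size / sub_size
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"sub_size {sub_size} does not divide cell_size {grid.cell_size}; "
            "pass an explicit divisor"
        )
    asn = assign(occ, grid)
    labels = asn.labels()
    mask = labels == cell
    sub = occ.frame[mask.to_numpy(bool)]
    x0, y0 = grid.origin
    c, r = cell
    cx0 = x0 + c * grid.cell_size
    cy0 = y0 + r * grid.cell_size
    presence: dict[Cell, set[str]] = {}
    sc = np.floor((sub["x"].to_numpy(float) - cx0) / sub_size).astype(int)
    sr = np.floor((sub["y"].to_numpy(float) - cy0) / sub_size).astype(int)
    for (i, j), sp in zip(zip(sc, sr), sub["species"]):
        presence.setdefault((int(i), int(j)), set()).add(sp)
    return SubGrid(parent=cell, sub_size=float(sub_size), presence=presence)


def subgrid_incidence_all(
    occ: OccurrenceSet,
    grid: AnalysisGrid,
    sub_size: float | None = None,
    assignment: CellAssignment | None = None,
) -> dict[Cell, SubGrid]:
    """Build sub-cell species presence sets for every occupied cell at once.

    Equivalent to calling :func:`subgrid_incidence` per occupied cell but
    with a single record→cell assignment pass.
    """
    if sub_size is None:
        sub_size = 1000.0
    ratio = grid.cell_size / sub_size
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"sub_size {sub_size} does not divide cell_size {grid.cell_size}"
        )
    if assignment is None:
        assignment = assign(occ, grid)
    labels = assignment.labels()
    mask = labels.notna().to_numpy()
    frame = occ.frame[mask]
    labs = labels[mask]
    x0, y0 = grid.origin
    x = frame["x"].to_numpy(float)
    y = frame["y"].to_numpy(float)
    sc = np.floor((x - x0) / sub_size).astype(int)
    sr = np.floor((y - y0) / sub_size).astype(int)
    per = int(round(ratio))
    out: dict[Cell, SubGrid] = {}
    for (cell, si, sj, sp) in zip(labs, sc, sr, frame["species"]):
        sub = out.get(cell)
        if sub is None:
            sub = out[cell] = SubGrid(parent=cell, sub_size=float(sub_size), presence={})
        # sub-cell index local to the parent cell
        key = (int(si - cell[0] * per), int(sj - cell[1] * per))
        sub.presence.setdefault(key, set()).add(sp)
    return out


def unsampled_area(
    grid: AnalysisGrid, assignment: CellAssignment
) -> tuple[float, float]:
    """Total clipped area of record-free cells, in km² and % of the country."""
    occupied = set(assignment.labels().dropna())
    km2 = sum(a for cell, a in grid.cell_area_km2.items() if cell not in occupied)
    return km2, 100.0 * km2 / grid.country_area_km2
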