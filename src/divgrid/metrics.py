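"""Per-cell diversity and vulnerability metrics.

For each grid cell the pipeline tallies

* **effort** — number of (deduplicated) records,
* **SR** — species richness, the number of distinct species,
* **E** — weighted endemism (range-size-weighted richness): each species
  present contributes ``q_ij = 1 / (number of cells it occupies)``, so a
  species confined to one cell contributes 1 there while a widespread one
  spreads a single unit of "endemism mass" over its range.  Summed over
  all cells, E therefore equals the number of recorded species exactly,
* **TSN / TSP** — number and proportion of threatened species (IUCN
  categories CR, EN or VU), at the global or national assessment level;
  ``TSP = TSN / SR`` with the cell's species count as denominator.

All tallies operate on the record→cell assignment; records flagged
"outside" never enter any tally.
"""

from __future__ import annotations

import pandas as pd

from .gridding import AnalysisGrid, CellAssignment, assign as _assign
from .occurrences import THREATENED, OccurrenceSet

__all__ = [
    "NoAssessmentError",
    "effort",
    "species_richness",
    "endemism",
    "threatened_metrics",
    "cell_metric_table",
]


class NoAssessmentError(ValueError):
    """Raised when national-level metrics are requested for a group with no
    national Red List (mammals; tetrapods combined)."""


def _assigned_frame(occ: OccurrenceSet, assignment: CellAssignment) -> pd.DataFrame:
    frame = occ.frame.copy()
    frame["cell"] = assignment.labels()
    return frame[frame["cell"].notna()]


def effort(assignment: CellAssignment) -> pd.Series:
    """Record count per cell (only cells with ≥1 record appear)."""
    labels = assignment.labels().dropna()
    counts = labels.value_counts().sort_index()
    counts.name = "effort"
    return counts


def species_richness(assignment: CellAssignment, occ: OccurrenceSet) -> pd.Series:
    """Distinct-species count per occupied cell."""
    df = _assigned_frame(occ, assignment)
    sr = df.groupby("cell")["species"].nunique().sort_index()
    sr.name = "SR"
    return sr


def endemism(assignment: CellAssignment, occ: OccurrenceSet) -> pd.Series:
    """Weighted endemism E_i = Σ_j q_ij with q_ij = 1/occupancy_j."""
    df = _assigned_frame(occ, assignment)
    if df.empty:
        return pd.Series(dtype=float, name="E")
    occupancy = df.groupby("species")["cell"].nunique()
    pairs = df.drop_duplicates(["species", "cell"])
    weights = pairs["species"].map(1.0 / occupancy)
    e = weights.groupby(pairs["cell"]).sum().sort_index()
    e.name = "E"
    return e


def threatened_metrics(
    assignment: CellAssignment,
    occ: OccurrenceSet,
    level: str = "global",
) -> pd.DataFrame:
    """Threatened-species number and proportion per occupied cell.

    ``level`` is ``"global"`` or ``"national"``. A species counts as
    threatened if its category at that level is CR, EN or VU. Cells with
    records but no threatened species get TSN = TSP = 0 (they are
    sampled, just unthreatened); record-free cells do not appear.

    Raises
    ------
    NoAssessmentError
        For national-level requests on a set whose statuses are all NE
        (mammals, or tetrapods combined) — there is nothing to assess.
    """
    if level not in ("global", "national"):
        raise ValueError(f"unknown level {level!r}")
    col = "status_global" if level == "global" else "status_national"
    if level == "national" and len(occ):
        # Mammals have no national Red List, so both the all-mammal set and
        # the tetrapods-combined set (whose denominator would silently
        # include unassessed mammals) are refused.
        if (occ.frame[col] == "NE").all() or (occ.frame["class_group"] == "Mammalia").any():
            raise NoAssessmentError(
                "no national assessment exists for (part of) this group; "
                "national-level metrics are undefined"
            )
    df = _assigned_frame(occ, assignment)
    sr = df.groupby("cell")["species"].nunique()
    threatened = df[df[col].isin(THREATENED)]
    tsn = threatened.groupby("cell")["species"].nunique()
    tsn = tsn.reindex(sr.index, fill_value=0).astype(int)
    out = pd.DataFrame({"TSN": tsn, "TSP": tsn / sr}).sort_index()
    return out


def cell_metric_table(
    occ: OccurrenceSet,
    grid: AnalysisGrid,
    assignment: CellAssignment | None = None,
    national: bool | None = None,
) -> pd.DataFrame:
    """Full per-cell metric table over every grid cell.

    One row per cell (including record-free ones), columns: ``col, row,
    area_km2, effort, SR, E, TSN_g, TSP_g`` and, when a national
    assessment exists, ``TSN_n, TSP_n``. Metric columns are NA for cells
    without records; TSP columns are NA where SR = 0.

    ``national`` defaults to automatic: national columns are included iff
    some record carries a non-NE national status.
    """
    if assignment is None:
        assignment = _assign(occ, grid)
    cells = grid.cells
    idx = pd.Index(cells, name="cell", tupleize_cols=False)
    table = pd.DataFrame(index=idx)
    table["area_km2"] = [grid.cell_area_km2[c] for c in cells]
    table["effort"] = effort(assignment).reindex(idx).fillna(0).astype(int)
    table["SR"] = species_richness(assignment, occ).reindex(idx).fillna(0).astype(int)
    table["E"] = endemism(assignment, occ).reindex(idx).fillna(0.0)
    tg = threatened_metrics(assignment, occ, "global").reindex(idx)
    table["TSN_g"] = tg["TSN"].fillna(0).astype(int)
    table["TSP_g"] = tg["TSP"]
    if national is None:
        national = (
            bool(len(occ))
            and not (occ.frame["status_national"] == "NE").all()
            and not (occ.frame["class_group"] == "Mammalia").any()
        )
    if national:
        tn = threatened_metrics(assignment, occ, "national").reindex(idx)
        table["TSN_n"] = tn["TSN"].fillna(0).astype(int)
        table["TSP_n"] = tn["TSP"]
    # empty cells: zero-fill above marked SR/effort 0; TSP stays NA there
    table.loc[table["effort"] == 0, "TSP_g"] = pd.NA
    if national:
        table.loc[table["effort"] == 0, "TSP_n"] = pd.NA
    return table


def write_metric_csv(table: pd.DataFrame, path) -> None:
    """Write a metric table keyed by (col, row) with NA sentinels."""
    out = table.copy()
    out.insert(0, "col", [c for c, _ in out.index])
    out.insert(1, "row", [r for _, r in out.index])
    out.to_csv(path, index=False, na_rep="NA")
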