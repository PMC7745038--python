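"""Hotspot selection, congruence sweeps and protected-area overlap.

A hotspot is operationalised as the top *d* % of non-empty grid cells on
a metric's gradient (richness, endemism, threatened-species number or
proportion), rather than any fixed threshold. Congruence between two or
more hotspot maps at the same *d* is the Jaccard-style percentage

    100 · |∩ selections| / |∪ selections|

— the number of cells that are hotspots under *every* metric, over the
cells that are a hotspot under at least one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .gridding import AnalysisGrid, Cell

__all__ = [
    "HotspotSelection",
    "select_hotspots",
    "congruence",
    "congruence_curve",
    "pa_overlap",
]


@dataclass(frozen=True)
class HotspotSelection:
    """Top-d% cells of one metric, drawn from the non-empty-cell universe."""

    metric: str
    definition: float  # d, percent of non-empty cells
    selected: frozenset
    n_nonempty: int


def select_hotspots(values: pd.Series, d: float, metric: str = "") -> HotspotSelection:
    """Select the top ``ceil(d/100 · n)`` cells of a per-cell metric.

    ``values`` must already be restricted to the non-empty-cell universe
    (cells with ≥1 record); its index holds ``(col, row)`` tuples. Ties at
    the cut are broken deterministically by ascending (col, row), which
    makes selections nested across increasing *d*.
    """
    if not 0 < d <= 100:
        raise ValueError("definition d must be in (0, 100]")
    n = len(values)
    if n == 0:
        raise ValueError("no non-empty cells to select from")
    k = min(n, math.ceil(d / 100.0 * n))
    order = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen = frozenset(cell for cell, _ in order[:k])
    return HotspotSelection(
        metric=metric or getattr(values, "name", "") or "",
        definition=float(d),
        selected=chosen,
        n_nonempty=n,
    )


def congruence(selections: Sequence[HotspotSelection]) -> float:
    """Percent congruence of ≥2 selections at a common definition d."""
    if len(selections) < 2:
        raise ValueError("need at least two selections")
    d0, n0 = selections[0].definition, selections[0].n_nonempty
    for s in selections[1:]:
        if s.definition != d0 or s.n_nonempty != n0:
            raise ValueError("selections must share grid universe and definition")
    sets = [set(s.selected) for s in selections]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    if not union:
        return 0.0
    return 100.0 * len(inter) / len(union)


def congruence_curve(
    metrics: Mapping[str, pd.Series],
    definitions: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Sweep the hotspot definition and evaluate congruence at each step.

    ``metrics`` maps metric name → per-cell values on a shared non-empty
    universe. The default sweep runs d = 0.5, 1.0, …, 100 in half-percent
    steps. Returns a DataFrame with columns ``d`` and ``congruence``.
    """
    if len(metrics) < 2:
        raise ValueError("need at least two metrics")
    universes = {frozenset(v.index) for v in metrics.values()}
    if len(universes) != 1:
        raise ValueError("metrics must share one non-empty-cell universe")
    if definitions is None:
        definitions = np.arange(0.5, 100.0 + 0.25, 0.5)
    rows = []
    for d in definitions:
        sels = [select_hotspots(v, d, name) for name, v in metrics.items()]
        rows.append((float(d), congruence(sels)))
    return pd.DataFrame(rows, columns=["d", "congruence"])


def pa_overlap(
    selection: HotspotSelection,
    protected_areas: Sequence[BaseGeometry],
    grid: AnalysisGrid,
) -> float:
    """Percent of hotspot cells at least partially covered by a protected area.

    A cell counts as covered when its full square geometry intersects any
    protected-area polygon — touching at a boundary qualifies ("at least
    partially covered").
    """
    if not selection.selected:
        raise ValueError("empty hotspot selection")
    pas = [g for g in protected_areas if g is not None and not g.is_empty]
    if not pas:
        return 0.0
    tree = STRtree(pas)
    covered = 0
    for cell in selection.selected:
        poly = grid.cell_polygon(cell)
        hits = tree.query(poly, predicate="intersects")
        if len(hits):
            covered += 1
    return 100.0 * covered / len(selection.selected)
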