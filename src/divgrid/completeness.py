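"""Survey completeness: exact species-accumulation curves and priority maps.

The inventory of a grid cell is scored by the *terminal slope* of its
smoothed species-accumulation curve (SAC): a cell whose SAC is still
rising steeply after all its records are accumulated is under-sampled,
one whose curve has flattened is close to complete. The exact ("sample-
based, analytic") SAC gives, for every number of samples n, the mean
richness over all equally-likely accumulation orders; its slope over the
final 10% of the curve classifies the cell on a five-level sampling-
priority scale:

    Null      slope ≤ 0.05          (well sampled)
    Low       0.05 < slope ≤ 0.25
    Medium    0.25 < slope ≤ 1
    High      records present but too few to fit a SAC
    Very High no records at all
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .gridding import AnalysisGrid, CellAssignment
from .occurrences import OccurrenceSet

__all__ = [
    "PRIORITY_LEVELS",
    "SacResult",
    "exact_sac",
    "terminal_slope",
    "classify_priority",
    "cell_completeness_table",
    "wellsampled_summary",
]

PRIORITY_LEVELS = ("Null", "Low", "Medium", "High", "VeryHigh")

#: Minimum samples needed before a SAC slope is attempted.
MIN_RECORDS_SAC = 2


@dataclass(frozen=True)
class SacResult:
    """Per-cell accumulation curve, terminal slope and priority class."""

    n_samples: int
    curve: np.ndarray  # S_exp(n), n = 1..N; empty for record-free cells
    slope: float | None
    priority: str


def exact_sac(samples: Sequence[str]) -> np.ndarray:
    """Exact (analytic) species-accumulation curve from per-sample labels.

    ``samples`` lists the species observed in each sampling unit — here
    one occurrence record per unit, each contributing a single species.
    With N_j = number of samples containing species j,

        S_exp(n) = Σ_j [1 − binom(N−N_j, n) / binom(N, n)],

    the average richness over all n-sample subsets, i.e. the mean of
    every possible accumulation order (the classic smoothed SAC).
    """
    if len(samples) == 0:
        raise ValueError("empty cell: no accumulation curve")
    counts = pd.Series(list(samples)).value_counts().to_numpy(float)
    N = len(samples)
    n = np.arange(1, N + 1, dtype=float)
    # log binomial ratios, zeroed where N−N_j < n
    lognum = gammaln(N - counts + 1)[:, None] - gammaln(n + 1)[None, :] \
        - gammaln(np.maximum(N - counts[:, None] - n[None, :], 0) + 1)
    logden = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
    ratio = np.exp(lognum - logden[None, :])
    ratio[(N - counts[:, None]) < n[None, :]] = 0.0
    return (1.0 - ratio).sum(axis=0)


def terminal_slope(curve: np.ndarray, min_records: int = MIN_RECORDS_SAC) -> float | None:
    """Mean slope of the final 10% of a SAC, or None when unfittable.

    The window start is n0 = floor(0.9·N), clamped to [1, N−1]; the mean
    slope over [n0, N] telescopes to the endpoint slope
    (S(N) − S(n0)) / (N − n0). Values lie in [0, 1] for the exact curve.
    """
    N = len(curve)
    if N < max(2, min_records):
        return None
    n0 = min(max(int(np.floor(0.9 * N)), 1), N - 1)
    return float((curve[-1] - curve[n0 - 1]) / (N - n0))


def classify_priority(n_records: int, slope: float | None) -> str:
    """Five-level sampling priority from record count and SAC slope.

    Record-free cells are 'VeryHigh' priority; cells with records but no
    computable slope are 'High'; otherwise the slope thresholds 0.05,
    0.25 and 1 (all right-closed) give 'Null', 'Low' and 'Medium'.
    """
    if n_records == 0:
        return "VeryHigh"
    if slope is None:
        return "High"
    if slope <= 0.05:
        return "Null"
    if slope <= 0.25:
        return "Low"
    return "Medium"


def sac_result(samples: Sequence[str], min_records: int = MIN_RECORDS_SAC) -> SacResult:
    """Convenience: curve + slope + priority for one cell's samples."""
    if len(samples) == 0:
        return SacResult(0, np.array([]), None, "VeryHigh")
    curve = exact_sac(samples)
    slope = terminal_slope(curve, min_records=min_records)
    return SacResult(len(samples), curve, slope, classify_priority(len(samples), slope))


def cell_completeness_table(
    occ: OccurrenceSet,
    grid: AnalysisGrid,
    assignment: CellAssignment,
    min_records: int = MIN_RECORDS_SAC,
) -> pd.DataFrame:
    """Per-cell completeness: N, S_obs, terminal slope and priority class.

    Covers every grid cell, including record-free ones (priority
    'VeryHigh'). Sampling units are individual records.
    """
    frame = occ.frame.copy()
    frame["cell"] = assignment.labels()
    frame = frame[frame["cell"].notna()]
    rows = []
    grouped = dict(tuple(frame.groupby("cell")["species"]))
    for cell in grid.cells:
        if cell in grouped:
            species = grouped[cell].tolist()
            res = sac_result(species, min_records=min_records)
            s_obs = len(set(species))
        else:
            res = SacResult(0, np.array([]), None, "VeryHigh")
            s_obs = 0
        rows.append(
            {
                "cell": cell,
                "N": res.n_samples,
                "S_obs": s_obs,
                "slope": res.slope if res.slope is not None else np.nan,
                "priority": res.priority,
                "area_km2": grid.cell_area_km2[cell],
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def wellsampled_summary(table: pd.DataFrame, country_area_km2: float) -> tuple[int, float]:
    """(number of well-sampled cells, % of country area under-sampled).

    Well-sampled means a computed SAC slope ≤ 0.05. Everything else —
    steeper slopes, cells too sparse for a SAC, and record-free cells —
    counts its clipped area towards the under-sampled percentage.
    """
    well = table["slope"].notna() & (table["slope"] <= 0.05)
    under_km2 = float(table.loc[~well, "area_km2"].sum())
    return int(well.sum()), 100.0 * under_km2 / country_area_km2
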