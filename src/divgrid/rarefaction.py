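"""Incidence-based coverage rarefaction and extrapolation (Hill q = 0).

Each grid cell yields an *incidence* sample: T sampling units (1-km
sub-cells holding ≥1 record of the focal group) and per-species incidence
counts Y_j (number of units where species j was detected). From the
incidence frequency counts — U = ΣY_j total incidences, Q1 singletons
(species seen in exactly one unit), Q2 doubletons — the Chao-style
framework gives:

* expected richness when rarefying to t ≤ T units (exact hypergeometric
  form) and when extrapolating beyond T (via the Chao2 estimate Q̂0 of
  the number of undetected species);
* estimated sample coverage Ĉ(t): the fraction of the assemblage's total
  incidence probability represented by the species detected in t units.

Comparisons across cells with unequal effort are made at a *common
coverage*: every included cell is extrapolated to double its reference
size, C_max is the minimum and C_5% the 5th percentile of those doubled
coverages, and each cell's richness is read off its curve at that target
coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .gridding import SubGrid

__all__ = [
    "IncidenceFrequencies",
    "StandardisationLevel",
    "include_cell",
    "reference_coverage",
    "rarefy_richness",
    "extrapolate_richness",
    "interpolated_coverage",
    "extrapolated_coverage",
    "coverage_at",
    "richness_at",
    "richness_at_coverage",
    "standardise",
]


@dataclass(frozen=True)
class IncidenceFrequencies:
    """Incidence sample of one grid cell: T units and counts Y_j."""

    T: int
    Y: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be ≥ 1")
        if any(y < 1 or y > self.T for y in self.Y):
            raise ValueError("incidence counts must satisfy 1 ≤ Y_j ≤ T")

    @classmethod
    def from_subgrid(cls, sub: SubGrid) -> "IncidenceFrequencies":
        counts = sub.incidence_counts()
        if not counts:
            return cls(T=1, Y=())
        return cls(T=sub.n_units, Y=tuple(sorted(counts.values(), reverse=True)))

    # -- frequency summaries -----------------------------------------
    @property
    def S_obs(self) -> int:
        return len(self.Y)

    @property
    def U(self) -> int:
        return int(sum(self.Y))

    @property
    def Q1(self) -> int:
        return sum(1 for y in self.Y if y == 1)

    @property
    def Q2(self) -> int:
        return sum(1 for y in self.Y if y == 2)


def include_cell(inc: IncidenceFrequencies) -> bool:
    """Reliability filter: keep a cell only if its sample can support
    rarefaction/extrapolation.

    A cell is *excluded* when any of the following holds: fewer than six
    observed species (S_obs < 6), fewer than six occupied sampling units
    (T < 6), or every species a singleton (U == S_obs), which leaves the
    estimators degenerate.
    """
    return not (inc.S_obs < 6 or inc.T < 6 or inc.U == inc.S_obs)


def _log_binom(a: np.ndarray, b: float) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _binom_ratio(T: int, Y: np.ndarray, t: float) -> np.ndarray:
    """binom(T−Y, t) / binom(T, t), elementwise; 0 where T−Y < t."""
    Y = np.asarray(Y, dtype=float)
    out = np.zeros_like(Y)
    ok = (T - Y) >= t
    if np.any(ok):
        out[ok] = np.exp(_log_binom(T - Y[ok], t) - _log_binom(np.float64(T), t))
    return out


def rarefy_richness(inc: IncidenceFrequencies, t: float) -> float:
    """Expected richness in t ≤ T sampling units (interpolation).

    S(t) = Σ_j [1 − binom(T−Y_j, t)/binom(T, t)] — the exact expectation
    of the number of species detected in a uniform random subset of t of
    the T units. Non-integer t interpolates linearly between the adjacent
    integer efforts.
    """
    if not 1 <= t <= inc.T:
        raise ValueError(f"t={t} outside [1, T={inc.T}]")
    if t != int(t):
        lo, hi = math.floor(t), math.ceil(t)
        s_lo = rarefy_richness(inc, lo)
        s_hi = rarefy_richness(inc, hi)
        return s_lo + (s_hi - s_lo) * (t - lo)
    Y = np.asarray(inc.Y, dtype=float)
    if Y.size == 0:
        return 0.0
    return float(np.sum(1.0 - _binom_ratio(inc.T, Y, float(t))))


def extrapolate_richness(inc: IncidenceFrequencies, t_star: float) -> float:
    """Expected richness t_star units *beyond* T (extrapolation).

    Uses the Chao2 estimate of undetected species,
    Q̂0 = ((T−1)/T)·Q1²/(2Q2) (or ((T−1)/T)·Q1(Q1−1)/2 when Q2 = 0), in
    S(T+t*) = S_obs + Q̂0·[1 − (1 − Q1/(T·Q̂0 + Q1))^t*].
    """
    if t_star < 0:
        raise ValueError("t_star must be ≥ 0")
    S, T, Q1, Q2 = inc.S_obs, inc.T, inc.Q1, inc.Q2
    if t_star == 0 or Q1 == 0:
        return float(S)
    if Q2 > 0:
        q0 = (T - 1) / T * Q1 * Q1 / (2.0 * Q2)
    else:
        q0 = (T - 1) / T * Q1 * (Q1 - 1) / 2.0
    if q0 == 0:
        return float(S)
    return float(S + q0 * (1.0 - (1.0 - Q1 / (T * q0 + Q1)) ** t_star))


def reference_coverage(inc: IncidenceFrequencies) -> float:
    """Estimated sample coverage at the reference size T.

    Ĉ(T) = 1 − (Q1/U)·[(T−1)Q1 / ((T−1)Q1 + 2Q2)].
    """
    U = inc.U
    if U == 0:
        raise ValueError("no incidences: coverage undefined")
    T, Q1, Q2 = inc.T, inc.Q1, inc.Q2
    if Q1 == 0:
        return 1.0
    denom = (T - 1) * Q1 + 2 * Q2
    a = (T - 1) * Q1 / denom if denom > 0 else 1.0
    return 1.0 - (Q1 / U) * a


def interpolated_coverage(inc: IncidenceFrequencies, t: float) -> float:
    """Estimated coverage of a rarefied sample of t < T units.

    Ĉ(t) = 1 − Σ_j (Y_j/U)·binom(T−Y_j, t)/binom(T−1, t), the standard
    incidence-data form; it meets :func:`reference_coverage` at t = T.
    Non-integer t interpolates linearly between adjacent integers.
    """
    if not 1 <= t <= inc.T:
        raise ValueError(f"t={t} outside [1, T={inc.T}]")
    if t == inc.T:
        return reference_coverage(inc)
    if t != int(t):
        lo, hi = math.floor(t), math.ceil(t)
        c_lo = interpolated_coverage(inc, lo)
        c_hi = interpolated_coverage(inc, hi)
        return c_lo + (c_hi - c_lo) * (t - lo)
    U = inc.U
    if U == 0:
        raise ValueError("no incidences: coverage undefined")
    Y = np.asarray(inc.Y, dtype=float)
    T = inc.T
    out = np.zeros_like(Y)
    ok = (T - Y) >= t
    if np.any(ok):
        out[ok] = np.exp(_log_binom(T - Y[ok], t) - _log_binom(np.float64(T - 1), t))
    return float(1.0 - np.sum((Y / U) * out))


def extrapolated_coverage(inc: IncidenceFrequencies, t_star: float) -> float:
    """Estimated coverage t_star units beyond T.

    Ĉ(T+t*) = 1 − (Q1/U)·[(T−1)Q1/((T−1)Q1 + 2Q2)]^(t*+1); reduces to the
    reference coverage at t* = 0 and approaches 1 as t* grows.
    """
    if t_star < 0:
        raise ValueError("t_star must be ≥ 0")
    U = inc.U
    if U == 0:
        raise ValueError("no incidences: coverage undefined")
    T, Q1, Q2 = inc.T, inc.Q1, inc.Q2
    if Q1 == 0:
        return 1.0
    denom = (T - 1) * Q1 + 2 * Q2
    a = (T - 1) * Q1 / denom if denom > 0 else 1.0
    return float(1.0 - (Q1 / U) * a ** (t_star + 1.0))


def coverage_at(inc: IncidenceFrequencies, t: float) -> float:
    """Coverage at any effort t ≥ 1 (interpolated or extrapolated branch)."""
    return interpolated_coverage(inc, t) if t <= inc.T else extrapolated_coverage(inc, t - inc.T)


def richness_at(inc: IncidenceFrequencies, t: float) -> float:
    """Expected richness at any effort t ≥ 1 (both branches, continuous at T)."""
    return rarefy_richness(inc, t) if t <= inc.T else extrapolate_richness(inc, t - inc.T)


def richness_at_coverage(
    inc: IncidenceFrequencies,
    target: float,
    t_cap: float | None = None,
) -> tuple[float, float, bool]:
    """Invert the coverage curve: richness at a target coverage level.

    Finds the effort t with Ĉ(t) = target on the monotone coverage curve
    (integer scan with linear interpolation on the rarefied branch; the
    extrapolated branch solved in closed form) and returns
    ``(S(t), t, capped)``. Efforts are capped at ``t_cap`` (default 2T,
    the doubled reference size); a target above the capped coverage
    returns the capped values with ``capped=True``.
    """
    if not 0 <= target <= 1:
        raise ValueError("target coverage must be in [0, 1]")
    T = inc.T
    cap = 2.0 * T if t_cap is None else float(t_cap)
    c_ref = reference_coverage(inc)
    if target <= c_ref:
        # rarefied branch: find bracketing integer efforts
        if T == 1 or target <= interpolated_coverage(inc, 1):
            return rarefy_richness(inc, 1), 1.0, False
        lo, hi = 1, T
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if interpolated_coverage(inc, mid) < target:
                lo = mid
            else:
                hi = mid
        c_lo = interpolated_coverage(inc, lo)
        c_hi = interpolated_coverage(inc, hi)
        frac = 0.0 if c_hi == c_lo else (target - c_lo) / (c_hi - c_lo)
        t = lo + max(0.0, min(1.0, frac))
        return rarefy_richness(inc, t), t, False
    # extrapolated branch, closed form
    Q1, Q2, U = inc.Q1, inc.Q2, inc.U
    if Q1 == 0:  # coverage is already 1; nothing beyond S_obs to see
        return float(inc.S_obs), float(T), False
    denom = (T - 1) * Q1 + 2 * Q2
    a = (T - 1) * Q1 / denom if denom > 0 else 1.0
    if a <= 0 or a >= 1:
        return richness_at(inc, cap), cap, True
    # 1 − (Q1/U) a^(t*+1) = target  →  t* = log(U(1−target)/Q1)/log(a) − 1
    t_star = math.log((1.0 - target) * U / Q1) / math.log(a) - 1.0
    t = T + max(0.0, t_star)
    if t > cap:
        return richness_at(inc, cap), cap, True
    return richness_at(inc, t), t, False


@dataclass
class StandardisationLevel:
    """Common coverage levels and per-cell richness standardised to them."""

    c_max: float
    c_5pct: float
    table: pd.DataFrame = field(repr=False)


def standardise(cells: dict, doubling: float = 2.0) -> StandardisationLevel:
    """Standardise richness across cells at shared coverage levels.

    ``cells`` maps cell id → included :class:`IncidenceFrequencies`.
    Every cell is extrapolated to ``doubling × T`` units; C_max is the
    minimum and C_5% the (linearly interpolated) 5th percentile of those
    coverages. Each cell's richness is then read off its own curve at
    both targets. Cells whose curve cannot reach a target inside the
    doubled effort are capped there and flagged.
    """
    if not cells:
        raise ValueError("no included cells")
    ids = list(cells)
    c2t = {i: coverage_at(cells[i], doubling * cells[i].T) for i in ids}
    vals = np.array([c2t[i] for i in ids])
    c_max = float(vals.min())
    c_5 = float(np.percentile(vals, 5.0))  # linear interpolation
    rows = []
    for i in ids:
        inc = cells[i]
        s_max, t_max, cap_max = richness_at_coverage(inc, c_max, t_cap=doubling * inc.T)
        s_5, t_5, cap_5 = richness_at_coverage(inc, c_5, t_cap=doubling * inc.T)
        rows.append(
            {
                "cell": i,
                "T": inc.T,
                "S_obs": inc.S_obs,
                "U": inc.U,
                "Q1": inc.Q1,
                "Q2": inc.Q2,
                "C_ref": reference_coverage(inc),
                "C_2T": c2t[i],
                "S_at_Cmax": s_max,
                "t_at_Cmax": t_max,
                "S_at_C5": s_5,
                "t_at_C5": t_5,
                "capped": bool(cap_max or cap_5),
            }
        )
    return StandardisationLevel(c_max=c_max, c_5pct=c_5, table=pd.DataFrame(rows).set_index("cell"))
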