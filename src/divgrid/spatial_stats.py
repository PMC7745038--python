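"""Pearson correlation with inference corrected for spatial autocorrelation.

Grid-cell summaries of neighbouring cells are not independent, so the
nominal sample size n overstates the information available and the usual
t-test on a Pearson correlation is anti-conservative. The modified t-test
(Clifford–Richardson–Hémon / Dutilleul family) keeps the correlation
estimate r untouched and replaces n with an *effective sample size* M̂
derived from estimated spatial correlation matrices of the two variables:

1. centre each variable; estimate a Moran-type correlogram ρ̂(h) over k
   equal-width distance classes of the pairwise centroid distances;
2. build R̂_A, R̂_B with unit diagonal and ρ̂(class(i,j)) off-diagonal;
3. v̂ = trace(R̂_A R̂_B)/n², M̂ = 1 + 1/v̂ (capped at n+1; independence
   gives v̂ = 1/n and M̂ = n+1 exactly);
4. t = r·sqrt((M̂−2)/(1−r²)) referred to a t distribution with M̂−2
   (possibly non-integer) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = ["ModifiedCorrelationResult", "modified_correlation", "correlation_matrix"]

#: Default number of equal-width distance classes for the correlogram.
DEFAULT_N_CLASSES = 13


@dataclass(frozen=True)
class ModifiedCorrelationResult:
    """Corrected correlation test between two per-cell variables."""

    r: float
    m_hat: float  # effective sample size
    t_stat: float
    p_value: float
    n: int
    k: int

    @property
    def df(self) -> float:
        return self.m_hat - 2.0


def _correlogram(z: np.ndarray, class_of_pair: np.ndarray, k: int) -> np.ndarray:
    """Moran-type ρ̂ per distance class for one centred variable.

    ρ̂(h) = mean over pairs (i,j) in class h of z_i z_j / s², with s² the
    biased variance. Empty classes contribute 0.
    """
    s2 = np.mean(z * z)
    n = len(z)
    iu, ju = np.triu_indices(n, k=1)
    prod = z[iu] * z[ju] / s2
    rho = np.zeros(k)
    for h in range(k):
        mask = class_of_pair == h
        if mask.any():
            rho[h] = prod[mask].mean()
    return rho


def modified_correlation(
    a: np.ndarray | pd.Series,
    b: np.ndarray | pd.Series,
    centroids: np.ndarray,
    k: int = DEFAULT_N_CLASSES,
) -> ModifiedCorrelationResult:
    """Correlate two per-cell variables with autocorrelation-corrected inference.

    Parameters
    ----------
    a, b
        Aligned per-cell values; cells without records must have been
        removed beforehand (double zeros inflate correlations).
    centroids
        (n, 2) planar cell-centroid coordinates. Duplicate locations are
        rejected — on a grid each cell has a distinct centroid.
    k
        Number of equal-width distance classes spanning (0, max distance].

    Raises
    ------
    ValueError
        For n < 5, zero variance in either variable, or coincident
        centroids. A perfectly collinear pair (|r| = 1) is returned with
        an infinite t statistic and p = 0 rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    n = len(a)
    if len(b) != n or centroids.shape != (n, 2):
        raise ValueError("a, b and centroids must be aligned")
    if n < 5:
        raise ValueError("need at least 5 cells")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance variable")

    dist = pdist(centroids)
    if np.any(dist == 0):
        raise ValueError("coincident cell centroids")
    dmax = dist.max()
    # equal-width classes over (0, dmax]; right-closed so dmax lands in k-1
    class_of_pair = np.minimum((np.ceil(dist / (dmax / k)) - 1).astype(int), k - 1)

    za = a - a.mean()
    zb = b - b.mean()
    r = float(np.dot(za, zb) / np.sqrt(np.dot(za, za) * np.dot(zb, zb)))

    rho_a = _correlogram(za, class_of_pair, k)
    rho_b = _correlogram(zb, class_of_pair, k)
    # trace(R_A R_B) = n + 2 Σ_{i<j} ρA(class_ij) ρB(class_ij)
    trace = n + 2.0 * np.sum(rho_a[class_of_pair] * rho_b[class_of_pair])
    v_hat = max(trace / n**2, 1.0 / n)  # floor keeps M̂ ≤ n+1
    m_hat = 1.0 + 1.0 / v_hat
    if m_hat <= 2.0:
        raise ValueError("effective sample size ≤ 2: test undefined")

    if abs(r) >= 1.0:
        t = float(np.inf) if r > 0 else float(-np.inf)
        p = 0.0
    else:
        t = r * np.sqrt((m_hat - 2.0) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=m_hat - 2.0)
    return ModifiedCorrelationResult(
        r=r, m_hat=float(m_hat), t_stat=float(t), p_value=float(p), n=n, k=k
    )


def correlation_matrix(
    tables: Mapping[str, pd.Series],
    centroids: np.ndarray,
    pairs: Sequence[tuple[str, str]],
    k: int = DEFAULT_N_CLASSES,
) -> pd.DataFrame:
    """Run the modified test over a list of named variable pairs.

    ``tables`` maps variable name → per-cell values sharing one index (a
    common non-empty-cell universe); ``centroids`` is aligned with that
    index. Returns one row per pair: var_a, var_b, r, M_hat, t, p, n.
    """
    rows = []
    for name_a, name_b in pairs:
        if name_a not in tables or name_b not in tables:
            raise KeyError(f"unknown metric in pair ({name_a}, {name_b})")
        res = modified_correlation(tables[name_a], tables[name_b], centroids, k=k)
        rows.append(
            {
                "var_a": name_a,
                "var_b": name_b,
                "r": res.r,
                "M_hat": res.m_hat,
                "t": res.t_stat,
                "p": res.p_value,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "M_hat", "t", "p", "n"])
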