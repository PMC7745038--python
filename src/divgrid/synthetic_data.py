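"""Synthetic occurrence datasets with known ground truth.

The generator emulates the statistical structure of a national presence-
only tetrapod database without any real geography:

* a species pool split over the four class groups, each species occupying
  a disc-shaped range whose size (expressed as an equivalent number of
  25-km grid cells) is log-normally distributed — a few widespread
  species, many restricted-range ones;
* sampling effort concentrated around "cities" (bias centres with a
  characteristic decay length over a uniform floor), so observed richness
  peaks where collectors live, not necessarily where species do;
* per-record collection years, and IUCN-style threat categories whose
  probability decreases with range size (small-ranged species are likelier
  to be threatened), at a global and — except for mammals — a national
  assessment level;
* a handful of rectangular protected areas covering a small fraction of
  the country.

Everything is drawn from one :class:`numpy.random.Generator` seeded from
the config, in a fixed order (range centres → range sizes → global threat
labels → national threat labels → record locations/species/years →
protected areas), so a seed reproduces a dataset bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .occurrences import CLASS_GROUPS, OccurrenceSet, write_occurrences

__all__ = [
    "EffortCentre",
    "SyntheticConfig",
    "GroundTruth",
    "SimulationResult",
    "generate",
    "bias_scenario",
]


@dataclass(frozen=True)
class EffortCentre:
    """One sampling-bias centre: position (km), mixture weight, decay (km)."""

    x_km: float
    y_km: float
    weight: float
    decay_km: float


# Default species pool mirrors a national tetrapod checklist's class balance.
_DEFAULT_POOL: dict[str, int] = {
    "Amphibia": 50,
    "Reptilia": 68,
    "Aves": 430,
    "Mammalia": 116,
}

# Three "coastal city" bias centres along the southern edge of the rectangle.
_CITY_CENTRES: tuple[EffortCentre, ...] = (
    EffortCentre(140.0, 30.0, 0.5, 30.0),
    EffortCentre(260.0, 25.0, 0.25, 30.0),
    EffortCentre(430.0, 45.0, 0.25, 30.0),
)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Range sizes are parameterised as occupied-cell counts of a 25-km grid
    (log-normal in log cell-count) and realised as discs of matching
    area. The threat model is a logistic decreasing in log range size,
    scaled by ``threat_max_p``.
    """

    seed: int = 0
    n_species: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_POOL))
    country_km: tuple[float, float] = (500.0, 350.0)
    range_mean_log: float = math.log(15.0)  # mean log cell count
    range_sd_log: float = 1.1
    effort_centres: tuple[EffortCentre, ...] = _CITY_CENTRES
    uniform_floor: float = 0.2  # fraction of records drawn uniformly
    n_records: int = 69_364
    threat_midpoint_log: float = math.log(4.0)
    threat_slope: float = 1.0
    threat_max_p: float = 0.5
    national_threat_boost: float = 2.0  # odds multiplier at national level
    year_range: tuple[int, int] = (1950, 2019)
    n_protected_areas: int = 8
    pa_area_fraction: float = 0.015  # total PA share of the country
    reference_cell_km: float = 25.0

    def validate(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be ≥ 0")
        if not 0.0 <= self.uniform_floor <= 1.0:
            raise ValueError("uniform_floor must be in [0, 1]")
        if any(c.decay_km <= 0 for c in self.effort_centres):
            raise ValueError("decay lengths must be positive")
        if not 0.0 <= self.threat_max_p <= 1.0:
            raise ValueError("threat_max_p must be a probability")
        w, h = self.country_km
        max_cells = (w * h) / self.reference_cell_km**2
        # ranges are clipped to the country, so only absurd sizes are refused
        if math.exp(self.range_mean_log) > 1e4 * max_cells:
            raise ValueError("range sizes infeasibly exceed the country")


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    species: pd.DataFrame  # species, class_group, cx, cy, radius_m, status cols

    def covers(self, x: float, y: float) -> np.ndarray:
        """Boolean mask of species whose range disc covers a point."""
        dx = self.species["cx"].to_numpy() - x
        dy = self.species["cy"].to_numpy() - y
        return dx * dx + dy * dy <= self.species["radius_m"].to_numpy() ** 2

    def true_richness(self, grid) -> pd.Series:
        """Per-cell count of species whose disc intersects the cell square."""
        cx = self.species["cx"].to_numpy()
        cy = self.species["cy"].to_numpy()
        rad = self.species["radius_m"].to_numpy()
        out = {}
        s = grid.cell_size
        x0, y0 = grid.origin
        for (c, r) in grid.cells:
            # distance from disc centre to the cell square
            qx = np.clip(cx, x0 + c * s, x0 + (c + 1) * s)
            qy = np.clip(cy, y0 + r * s, y0 + (r + 1) * s)
            d2 = (cx - qx) ** 2 + (cy - qy) ** 2
            out[(c, r)] = int(np.sum(d2 <= rad * rad))
        return pd.Series(out).sort_index()


@dataclass
class SimulationResult:
    occurrences: OccurrenceSet
    country: object  # shapely polygon
    protected_areas: list
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> None:
        from .geoio import write_polygons

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_occurrences(self.occurrences, outdir / "occurrences.csv")
        write_polygons([self.country], outdir / "country.geojson")
        write_polygons(self.protected_areas, outdir / "pas.geojson")
        truth = {
            "config": {
                **{k: v for k, v in asdict(self.config).items()
                   if k not in ("effort_centres", "n_species")},
                "n_species": dict(self.config.n_species),
                "effort_centres": [asdict(c) for c in self.config.effort_centres],
            },
            "species": self.truth.species.to_dict(orient="records"),
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh)


def _sample_threat(rng: np.random.Generator, p_threat: np.ndarray) -> np.ndarray:
    """Draw categories: threatened → CR/EN/VU, else NT/LC/DD."""
    n = len(p_threat)
    threatened = rng.random(n) < p_threat
    cats = np.empty(n, dtype=object)
    cats[threatened] = rng.choice(
        ["CR", "EN", "VU"], size=int(threatened.sum()), p=[0.2, 0.35, 0.45]
    )
    cats[~threatened] = rng.choice(
        ["NT", "LC", "DD"], size=int((~threatened).sum()), p=[0.1, 0.8, 0.1]
    )
    return cats


def generate(config: SyntheticConfig) -> SimulationResult:
    """Generate one dataset: occurrences, country, protected areas, truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    w_m = config.country_km[0] * 1000.0
    h_m = config.country_km[1] * 1000.0
    country = box(0.0, 0.0, w_m, h_m)
    cell_area_m2 = (config.reference_cell_km * 1000.0) ** 2

    # 1-2. species ranges: centres uniform, disc area = cell_count × cell area
    names, groups = [], []
    for grp in CLASS_GROUPS:
        k = int(config.n_species.get(grp, 0))
        names += [f"{grp}_sp{i:04d}" for i in range(k)]
        groups += [grp] * k
    n_sp = len(names)
    centres = rng.uniform([0, 0], [w_m, h_m], size=(n_sp, 2))
    log_cells = rng.normal(config.range_mean_log, config.range_sd_log, size=n_sp)
    cell_count = np.exp(log_cells)
    radius = np.sqrt(cell_count * cell_area_m2 / math.pi)
    max_radius = math.hypot(w_m, h_m)
    radius = np.minimum(radius, max_radius)

    # 3-4. threat labels from the range-size logistic
    z = -(log_cells - config.threat_midpoint_log) / config.threat_slope
    p_threat = config.threat_max_p / (1.0 + np.exp(-z))
    status_global = _sample_threat(rng, p_threat)
    odds = p_threat / np.maximum(1.0 - p_threat, 1e-12) * config.national_threat_boost
    p_threat_nat = odds / (1.0 + odds)
    status_national = _sample_threat(rng, p_threat_nat)
    status_national[np.array(groups) == "Mammalia"] = "NE"  # no national list

    truth = GroundTruth(
        species=pd.DataFrame(
            {
                "species": names,
                "class_group": groups,
                "cx": centres[:, 0],
                "cy": centres[:, 1],
                "radius_m": radius,
                "range_cells": cell_count,
                "status_global": status_global,
                "status_national": status_national,
            }
        )
    )

    # 5-7. records: location from the effort mixture, species uniform among
    # covering ranges, year uniform. Locations outside the country or covered
    # by no species are rejected and redrawn.
    weights = np.array([c.weight for c in config.effort_centres], dtype=float)
    if weights.size and weights.sum() > 0:
        weights = weights / weights.sum() * (1.0 - config.uniform_floor)
        probs = np.concatenate([[config.uniform_floor], weights])
    else:
        probs = np.array([1.0])
    cxs = np.array([c.x_km * 1000.0 for c in config.effort_centres])
    cys = np.array([c.y_km * 1000.0 for c in config.effort_centres])
    decays = np.array([c.decay_km * 1000.0 for c in config.effort_centres])

    need = config.n_records
    xs = np.empty(need)
    ys = np.empty(need)
    sp_idx = np.empty(need, dtype=int)
    got = 0
    guard = 0
    while got < need:
        guard += 1
        if guard > 10_000:
            raise RuntimeError("record sampling failed to converge; "
                               "check ranges cover the effort surface")
        m = min(max(4096, need - got), 8192)
        comp = rng.choice(len(probs), size=m, p=probs)
        x = rng.uniform(0, w_m, size=m)
        y = rng.uniform(0, h_m, size=m)
        biased = comp > 0
        if biased.any():
            j = comp[biased] - 1
            # half-normal radial kernel: ~95% of draws within 2 decay lengths
            r = np.abs(rng.normal(0.0, decays[j]))
            theta = rng.uniform(0, 2 * math.pi, size=int(biased.sum()))
            x[biased] = cxs[j] + r * np.cos(theta)
            y[biased] = cys[j] + r * np.sin(theta)
        inside = (x >= 0) & (x < w_m) & (y >= 0) & (y < h_m)
        pick = rng.random(m)  # drawn unconditionally to keep the stream aligned
        xi, yi, pi = x[inside], y[inside], pick[inside]
        dx = xi[:, None] - centres[None, :, 0]
        dy = yi[:, None] - centres[None, :, 1]
        mask = dx * dx + dy * dy <= (radius * radius)[None, :]
        k = mask.sum(axis=1)
        ok = k > 0
        if not ok.any():
            continue
        choice = np.minimum((pi[ok] * k[ok]).astype(int), k[ok] - 1)
        cs = np.cumsum(mask[ok], axis=1)
        sel = np.argmax(cs > choice[:, None], axis=1)
        take = min(int(ok.sum()), need - got)
        sp_idx[got:got + take] = sel[:take]
        xs[got:got + take] = xi[ok][:take]
        ys[got:got + take] = yi[ok][:take]
        got += take
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=need)

    frame = pd.DataFrame(
        {
            "species": [names[i] for i in sp_idx],
            "class_group": [groups[i] for i in sp_idx],
            "x": xs,
            "y": ys,
            "year": years,
            "status_global": status_global[sp_idx],
            "status_national": status_national[sp_idx],
        }
    )
    occ = OccurrenceSet(frame, crs_tag="synthetic-planar")

    # 8. protected areas: random rectangles totalling pa_area_fraction
    pas = []
    if config.n_protected_areas > 0:
        each = config.pa_area_fraction * w_m * h_m / config.n_protected_areas
        side = math.sqrt(each)
        for _ in range(config.n_protected_areas):
            aspect = rng.uniform(0.5, 2.0)
            pw, ph = side * aspect, side / aspect
            px = rng.uniform(0, max(w_m - pw, 1.0))
            py = rng.uniform(0, max(h_m - ph, 1.0))
            pas.append(box(px, py, px + pw, py + ph))

    return SimulationResult(
        occurrences=occ, country=country, protected_areas=pas, truth=truth,
        config=config,
    )


def bias_scenario(level: str, **overrides) -> SyntheticConfig:
    """Preset configs for the three sampling-bias scenarios.

    ``"none"`` — spatially uniform effort; ``"city"`` — three coastal
    bias centres over a uniform floor (the default, emulating collection
    concentrated around major cities); ``"extreme"`` — a single centre
    receiving 95% of the sampling, with ~90% of records landing within
    two decay lengths of it.
    """
    if level == "none":
        cfg = SyntheticConfig(effort_centres=(), uniform_floor=1.0)
    elif level == "city":
        cfg = SyntheticConfig(effort_centres=_CITY_CENTRES, uniform_floor=0.2)
    elif level == "extreme":
        cfg = SyntheticConfig(
            effort_centres=(EffortCentre(250.0, 175.0, 1.0, 25.0),),
            uniform_floor=0.05,
        )
    else:
        raise ValueError(f"unknown bias level {level!r}")
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    return cfg
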