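"""Occurrence records: data model, CSV I/O, validation and deduplication.

An occurrence record is a single georeferenced observation of a tetrapod
species: taxon name, class group (Amphibia, Reptilia, Aves or Mammalia),
planar coordinates in metres, an optional collection year, and IUCN Red
List categories at the global and national assessment level.

Records are held column-wise in a :class:`pandas.DataFrame` wrapped by
:class:`OccurrenceSet`; all downstream per-cell tallies are vectorised
pandas group-bys, so sets of 10^5 records are cheap.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_GROUPS",
    "ThreatCategory",
    "THREATENED",
    "OccurrenceRecord",
    "OccurrenceSet",
    "ValidationReport",
    "read_occurrences",
    "write_occurrences",
    "deduplicate",
    "split_by_class",
    "lonlat_to_planar",
]

#: Recognised tetrapod class groups, in canonical order.
CLASS_GROUPS: tuple[str, ...] = ("Amphibia", "Reptilia", "Aves", "Mammalia")


class ThreatCategory(str, enum.Enum):
    """IUCN Red List category of a single assessment.

    ``NE`` (not evaluated) doubles as the value used when no assessment
    exists at a level — e.g. mammals have no national Red List here.
    """

    CR = "CR"  # critically endangered
    EN = "EN"  # endangered
    VU = "VU"  # vulnerable
    NT = "NT"  # near threatened
    LC = "LC"  # least concern
    DD = "DD"  # data deficient
    NE = "NE"  # not evaluated

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Categories that count a species as "threatened" (the CR+EN+VU numerator).
THREATENED: frozenset[str] = frozenset({"CR", "EN", "VU"})

#: Sentinel used in place of a missing year inside deduplication keys.
_YEAR_UNKNOWN = "unknown"

_COLUMNS = ("species", "class_group", "x", "y", "year",
            "status_global", "status_national")

#: Default CSV header names, Darwin-Core flavoured.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "species": "scientificName",
    "class_group": "classGroup",
    "x": "x",
    "y": "y",
    "year": "year",
    "status_global": "iucnGlobal",
    "status_national": "iucnNational",
}


@dataclass(frozen=True, slots=True)
class OccurrenceRecord:
    """One species observation with planar coordinates in metres."""

    species: str
    class_group: str
    x: float
    y: float
    year: int | None = None
    status_global: ThreatCategory = ThreatCategory.NE
    status_national: ThreatCategory = ThreatCategory.NE

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")
        if self.class_group not in CLASS_GROUPS:
            raise ValueError(f"unknown class group {self.class_group!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("coordinates must be finite")


@dataclass
class ValidationReport:
    """Per-row outcomes of reading a CSV: rejected rows and soft warnings."""

    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )
    n_unknown_threat_codes: int = 0
    n_year_coerced: int = 0
    n_national_forced_ne: int = 0

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def to_csv(self, path: str | Path) -> None:
        self.rejected.to_csv(path, index=False)


class OccurrenceSet:
    """An ordered collection of occurrence records.

    Parameters
    ----------
    frame
        DataFrame with columns ``species, class_group, x, y, year,
        status_global, status_national``. ``year`` is nullable integer.
    crs_tag
        Free-form name of the planar reference system the coordinates are
        expressed in (e.g. ``"UTM21S"``). Grids refuse to mix tags.
    """

    def __init__(self, frame: pd.DataFrame, crs_tag: str = "planar") -> None:
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        frame = frame.loc[:, list(_COLUMNS)].reset_index(drop=True)
        frame["year"] = frame["year"].astype("Int64")
        self.frame = frame
        self.crs_tag = crs_tag

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[OccurrenceRecord]:
        for row in self.frame.itertuples(index=False):
            yield OccurrenceRecord(
                species=row.species,
                class_group=row.class_group,
                x=float(row.x),
                y=float(row.y),
                year=None if pd.isna(row.year) else int(row.year),
                status_global=ThreatCategory(row.status_global),
                status_national=ThreatCategory(row.status_national),
            )

    @classmethod
    def from_records(
        cls, records: Iterable[OccurrenceRecord], crs_tag: str = "planar"
    ) -> "OccurrenceSet":
        rows = [
            (r.species, r.class_group, r.x, r.y, r.year,
             r.status_global.value, r.status_national.value)
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(_COLUMNS))
        if frame.empty:
            frame = _empty_frame()
        return cls(frame, crs_tag=crs_tag)

    @property
    def species(self) -> pd.Series:
        return self.frame["species"]

    def n_species(self) -> int:
        return int(self.frame["species"].nunique())


def _empty_frame() -> pd.DataFrame:
    frame = pd.DataFrame({c: pd.Series(dtype=object) for c in _COLUMNS})
    frame["x"] = frame["x"].astype(float)
    frame["y"] = frame["y"].astype(float)
    frame["year"] = frame["year"].astype("Int64")
    return frame


def _coerce_threat(series: pd.Series) -> tuple[pd.Series, int]:
    """Normalise an IUCN-code column; unknown/blank codes become NE."""
    codes = series.astype("string").str.strip().str.upper()
    valid = codes.isin([c.value for c in ThreatCategory])
    n_unknown = int((~valid & codes.notna() & (codes != "")).sum())
    out = codes.where(valid, other="NE").fillna("NE").replace("", "NE")
    return out.astype(object), n_unknown


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    crs_tag: str = "planar",
) -> tuple[OccurrenceSet, ValidationReport]:
    """Read and validate an occurrence CSV.

    Rows whose coordinates do not parse as finite numbers, with an empty
    species name, or with an unrecognised class group are rejected and
    listed (with the offending row index and a reason) in the returned
    :class:`ValidationReport`. Unknown threat codes are mapped to ``NE``
    and counted; unparsable years become missing; national categories of
    mammals are forced to ``NE`` (no national assessment exists).

    Raises
    ------
    FileNotFoundError
        If the CSV does not exist.
    ValueError
        If a mapped mandatory column is absent or the table is empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.empty:
        raise ValueError(f"empty occurrence table: {path}")
    for key in ("species", "class_group", "x", "y"):
        if cmap[key] not in raw.columns:
            raise ValueError(f"missing mandatory column {cmap[key]!r}")

    report = ValidationReport()
    n = len(raw)
    species = raw[cmap["species"]].str.strip()
    class_group = raw[cmap["class_group"]].str.strip()
    x = pd.to_numeric(raw[cmap["x"]], errors="coerce")
    y = pd.to_numeric(raw[cmap["y"]], errors="coerce")

    reasons = pd.Series([""] * n)
    bad_coord = ~(np.isfinite(x.to_numpy(float, na_value=np.nan))
                  & np.isfinite(y.to_numpy(float, na_value=np.nan)))
    reasons[bad_coord] = "unparsable or non-finite coordinates"
    bad_species = species == ""
    reasons[bad_species & (reasons == "")] = "empty species name"
    bad_class = ~class_group.isin(CLASS_GROUPS)
    reasons[bad_class & (reasons == "")] = "unknown class group"
    bad = reasons != ""
    report.rejected = pd.DataFrame(
        {"row": np.flatnonzero(bad.to_numpy()), "reason": reasons[bad].to_numpy()}
    )

    if cmap["year"] in raw.columns:
        year_raw = raw[cmap["year"]].str.strip()
        year = pd.to_numeric(year_raw, errors="coerce")
        report.n_year_coerced = int(((year_raw != "") & year.isna()).sum())
        year = year.round().astype("Int64")
    else:
        year = pd.Series([pd.NA] * n, dtype="Int64")

    if cmap["status_global"] in raw.columns:
        sg, n_bad_g = _coerce_threat(raw[cmap["status_global"]])
    else:
        sg, n_bad_g = pd.Series(["NE"] * n, dtype=object), 0
    if cmap["status_national"] in raw.columns:
        sn, n_bad_n = _coerce_threat(raw[cmap["status_national"]])
    else:
        sn, n_bad_n = pd.Series(["NE"] * n, dtype=object), 0
    report.n_unknown_threat_codes = n_bad_g + n_bad_n

    # Mammals carry no national Red List: force NE rather than trusting input.
    mammal_natl = class_group.eq("Mammalia") & sn.ne("NE")
    report.n_national_forced_ne = int(mammal_natl.sum())
    sn = sn.mask(mammal_natl, "NE")

    keep = ~bad
    frame = pd.DataFrame(
        {
            "species": species[keep].to_numpy(object),
            "class_group": class_group[keep].to_numpy(object),
            "x": x[keep].to_numpy(float),
            "y": y[keep].to_numpy(float),
            "year": year[keep].to_numpy(object),
            "status_global": sg[keep].to_numpy(object),
            "status_national": sn[keep].to_numpy(object),
        }
    )
    return OccurrenceSet(frame, crs_tag=crs_tag), report


def write_occurrences(
    occ: OccurrenceSet,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write an OccurrenceSet back to CSV using the (default) header names."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = occ.frame.rename(columns={k: v for k, v in cmap.items()})
    out.to_csv(path, index=False)


def deduplicate(
    occ: OccurrenceSet, coordinate_decimals: int | None = None
) -> tuple[OccurrenceSet, int]:
    """Drop repeated (species, x, y, year) records, keeping first occurrences.

    This is the pseudo-replication filter applied before any per-cell
    tally: repeated reports of the same species at the same coordinates in
    the same year collapse to one record. Missing years compare equal to
    each other (conservative against over-counting).

    Parameters
    ----------
    coordinate_decimals
        Optional rounding (decimal places) applied to coordinates for key
        construction only; default ``None`` compares exact floats.

    Returns
    -------
    (deduplicated set, number of records removed)
    """
    frame = occ.frame
    kx = frame["x"] if coordinate_decimals is None else frame["x"].round(coordinate_decimals)
    ky = frame["y"] if coordinate_decimals is None else frame["y"].round(coordinate_decimals)
    kyear = frame["year"].astype(object).where(frame["year"].notna(), _YEAR_UNKNOWN)
    key = pd.MultiIndex.from_arrays([frame["species"], kx, ky, kyear])
    keep = ~key.duplicated(keep="first")
    out = OccurrenceSet(frame[keep].reset_index(drop=True), crs_tag=occ.crs_tag)
    return out, int((~keep).sum())


def split_by_class(occ: OccurrenceSet) -> dict[str, OccurrenceSet]:
    """Partition a set into the four class groups (some possibly empty)."""
    out: dict[str, OccurrenceSet] = {}
    for group in CLASS_GROUPS:
        sub = occ.frame[occ.frame["class_group"] == group].reset_index(drop=True)
        if sub.empty:
            sub = _empty_frame()
        out[group] = OccurrenceSet(sub, crs_tag=occ.crs_tag)
    return out


_EARTH_RADIUS_M = 6_371_008.8  # mean Earth radius


def lonlat_to_planar(
    lon: np.ndarray | float,
    lat: np.ndarray | float,
    ref_lon: float,
    ref_lat: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Project longitude/latitude (degrees) to local planar metres.

    Spherical equirectangular projection about a reference point:
    ``x = R (λ − λ0) cos φ0``, ``y = R (φ − φ0)``. Adequate for
    country-scale extents where kilometre-sized grid cells are the unit of
    analysis; for survey-grade work supply already-projected coordinates.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = np.radians(lon - ref_lon) * math.cos(math.radians(ref_lat)) * _EARTH_RADIUS_M
    y = np.radians(lat - ref_lat) * _EARTH_RADIUS_M
    return x, y
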