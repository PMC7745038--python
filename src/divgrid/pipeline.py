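"""End-to-end orchestration: dedup → grid → metrics → hotspots →
correlations → rarefaction → completeness → protected-area overlap.

`run_all` executes every stage for each requested grid resolution, for
the four class groups and all tetrapods combined, and writes per-stage
CSV/GeoJSON outputs plus a single JSON summary (record counts and
unsampled areas per group and resolution, hotspot congruence at the
requested definitions, correlation tables, coverage-standardisation
levels, sampling-priority tallies, and protected-area overlap).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import completeness as comp
from . import geoio
from . import hotspots as hs
from . import metrics as met
from . import rarefaction as rf
from . import spatial_stats as ss
from .gridding import assign, build_grid, subgrid_incidence_all, unsampled_area
from .occurrences import (
    CLASS_GROUPS,
    OccurrenceSet,
    deduplicate,
    read_occurrences,
    split_by_class,
)

__all__ = ["RunConfig", "run_all", "run_analysis"]

log = logging.getLogger("divgrid")

COMBINED = "Tetrapoda"


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    occurrences_csv: str | None = None
    country_geojson: str | None = None
    pas_geojson: str | None = None
    projection_ref: tuple[float, float] | None = None
    cell_sizes: Sequence[float] = (12500.0, 25000.0, 50000.0)
    sub_size: float = 1000.0
    rarefaction_cell_sizes: Sequence[float] = (25000.0, 50000.0)
    definitions: Sequence[float] = (2.5, 10.0)
    correlation_classes: int = 13
    min_records_sac: int = 2
    seed: int = 0
    outdir: str = "divgrid_out"

    def validate(self) -> None:
        if any(s <= 0 for s in self.cell_sizes):
            raise ValueError("cell sizes must be positive")
        if any(not 0 < d <= 100 for d in self.definitions):
            raise ValueError("hotspot definitions must be in (0, 100]")


def _group_sets(occ: OccurrenceSet) -> dict[str, OccurrenceSet]:
    groups = {COMBINED: occ}
    groups.update(split_by_class(occ))
    return groups


def _metric_universe(table: pd.DataFrame) -> pd.DataFrame:
    """Restrict a metric table to the non-empty-cell universe."""
    return table[table["effort"] > 0]


def run_analysis(
    occ: OccurrenceSet,
    country,
    protected_areas: Sequence,
    config: RunConfig,
) -> dict:
    """Run every stage in memory; returns the nested results/summary dict."""
    config.validate()
    occ, n_dup = deduplicate(occ)
    log.info("deduplicated: %d records kept, %d removed", len(occ), n_dup)
    groups = _group_sets(occ)

    results: dict = {
        "n_records": len(occ),
        "n_duplicates_removed": n_dup,
        "n_species": occ.n_species(),
        "per_scale": {},
    }
    table1_rows = []

    for cell_size in config.cell_sizes:
        grid = build_grid(country, cell_size, crs_tag=occ.crs_tag)
        scale_key = f"{cell_size / 1000:g}km"
        scale_out: dict = {"tables": {}, "congruence": {}, "correlations": {},
                           "rarefaction": {}, "completeness": {}, "pa_overlap": {}}
        log.info("grid %s: %d cells", scale_key, len(grid.cells))

        for gname, gocc in groups.items():
            if len(gocc) == 0:
                continue
            asn = assign(gocc, grid)
            table = met.cell_metric_table(gocc, grid, asn)
            scale_out["tables"][gname] = table
            km2, pct = unsampled_area(grid, asn)
            table1_rows.append(
                {
                    "group": gname,
                    "cell_km": cell_size / 1000,
                    "n_records": len(gocc),
                    "n_species": gocc.n_species(),
                    "unsampled_km2": km2,
                    "unsampled_pct": pct,
                }
            )

            # ---- hotspot congruence -------------------------------
            uni = _metric_universe(table)
            cong: dict = {}
            metric_sets = {"TSN_g": ["SR", "E", "TSN_g"], "TSP_g": ["SR", "E", "TSP_g"]}
            if "TSN_n" in table.columns:
                metric_sets["TSN_n"] = ["SR", "E", "TSN_n"]
                metric_sets["TSP_n"] = ["SR", "E", "TSP_n"]
            if len(uni) >= 1:
                for mname, cols in metric_sets.items():
                    metric_map = {c: uni[c].astype(float).fillna(0.0) for c in cols}
                    vals = {}
                    for d in config.definitions:
                        sels = [hs.select_hotspots(v, d, c) for c, v in metric_map.items()]
                        vals[d] = hs.congruence(sels)
                    cong[mname] = vals
            scale_out["congruence"][gname] = cong

            # ---- correlations -------------------------------------
            if len(uni) >= 5:
                centroids = grid.centroids(list(uni.index))
                tables = {
                    "effort": uni["effort"].astype(float),
                    "SR": uni["SR"].astype(float),
                    "E": uni["E"].astype(float),
                    "TSN_g": uni["TSN_g"].astype(float),
                }
                pairs = [("effort", "SR"), ("effort", "E"), ("effort", "TSN_g"),
                         ("SR", "E"), ("SR", "TSN_g"), ("E", "TSN_g")]
                try:
                    scale_out["correlations"][gname] = ss.correlation_matrix(
                        tables, centroids, pairs, k=config.correlation_classes
                    )
                except ValueError as exc:  # zero variance etc.
                    log.warning("correlations skipped for %s at %s: %s",
                                gname, scale_key, exc)

            # ---- coverage-standardised richness -------------------
            if cell_size in config.rarefaction_cell_sizes:
                subs = subgrid_incidence_all(gocc, grid, config.sub_size, asn)
                incs = {
                    cell: rf.IncidenceFrequencies.from_subgrid(sg)
                    for cell, sg in subs.items()
                }
                included = {c: i for c, i in incs.items() if rf.include_cell(i)}
                if included:
                    std = rf.standardise(included)
                    scale_out["rarefaction"][gname] = std
                    log.info("%s %s: %d/%d cells included, Cmax=%.3f C5=%.3f",
                             gname, scale_key, len(included), len(incs),
                             std.c_max, std.c_5pct)

            # ---- completeness -------------------------------------
            ctab = comp.cell_completeness_table(
                gocc, grid, asn, min_records=config.min_records_sac
            )
            n_well, pct_under = comp.wellsampled_summary(ctab, grid.country_area_km2)
            scale_out["completeness"][gname] = {
                "table": ctab,
                "n_wellsampled": n_well,
                "pct_under_sampled": pct_under,
            }

            # ---- protected-area overlap ---------------------------
            if protected_areas and len(uni) >= 1:
                d0 = min(config.definitions)
                over = {}
                for mcol in ("SR", "E", "TSN_g"):
                    sel = hs.select_hotspots(uni[mcol].astype(float), d0, mcol)
                    over[mcol] = hs.pa_overlap(sel, protected_areas, grid)
                scale_out["pa_overlap"][gname] = over

        results["per_scale"][scale_key] = scale_out

    results["table1"] = pd.DataFrame(table1_rows)
    return results


def _summarise(results: dict) -> dict:
    """JSON-safe summary extracted from the in-memory results."""
    out = {
        "n_records": results["n_records"],
        "n_duplicates_removed": results["n_duplicates_removed"],
        "n_species": results["n_species"],
        "table1": results["table1"].to_dict(orient="records"),
        "per_scale": {},
    }
    for scale, sc in results["per_scale"].items():
        entry: dict = {"congruence": sc["congruence"], "pa_overlap": sc["pa_overlap"],
                       "completeness": {}, "rarefaction": {}, "correlations": {}}
        for g, c in sc["completeness"].items():
            entry["completeness"][g] = {
                "n_wellsampled": c["n_wellsampled"],
                "pct_under_sampled": c["pct_under_sampled"],
            }
        for g, std in sc["rarefaction"].items():
            entry["rarefaction"][g] = {
                "c_max": std.c_max,
                "c_5pct": std.c_5pct,
                "n_cells": int(len(std.table)),
            }
        for g, tab in sc["correlations"].items():
            entry["correlations"][g] = tab.to_dict(orient="records")
        out["per_scale"][scale] = entry
    return out


def run_all(config: RunConfig) -> dict:
    """Load inputs per config, run the full analysis, write the report bundle.

    Returns the summary dict (also written as ``summary.json``).
    """
    config.validate()
    if not (config.occurrences_csv and config.country_geojson):
        raise ValueError("occurrences_csv and country_geojson are required")
    occ, report = read_occurrences(
        config.occurrences_csv, crs_tag="planar"
    )
    country = geoio.read_country(config.country_geojson, config.projection_ref)
    pas = (
        geoio.read_polygons(config.pas_geojson, config.projection_ref)
        if config.pas_geojson
        else []
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if report.n_rejected:
        report.to_csv(outdir / "validation_report.csv")

    results = run_analysis(occ, country, pas, config)

    for scale, sc in results["per_scale"].items():
        for gname, table in sc["tables"].items():
            met.write_metric_csv(table, outdir / f"metrics_{gname}_{scale}.csv")
        for gname, c in sc["completeness"].items():
            tab = c["table"].copy()
            tab.insert(0, "col", [x for x, _ in tab.index])
            tab.insert(1, "row", [y for _, y in tab.index])
            tab.to_csv(outdir / f"completeness_{gname}_{scale}.csv", index=False,
                       na_rep="NA")
        for gname, std in sc["rarefaction"].items():
            std.table.to_csv(outdir / f"rarefaction_{gname}_{scale}.csv", na_rep="NA")
    results["table1"].to_csv(outdir / "table1_records_unsampled.csv", index=False)

    summary = _summarise(results)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    log.info("report bundle written to %s", outdir)
    return summary
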