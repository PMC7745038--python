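"""Grid construction, half-open cell assignment and sub-grid incidence."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from divgrid.gridding import (
    assign,
    build_grid,
    subgrid_incidence,
    subgrid_incidence_all,
    unsampled_area,
)

from conftest import make_occurrences

KM = 1000.0


class TestBuildGrid:
    def test_exact_tiling_50km(self, square_country_100km):
        grid = build_grid(square_country_100km, 50 * KM)
        assert len(grid.cell_area_km2) == 4
        assert all(a == pytest.approx(2500.0) for a in grid.cell_area_km2.values())

    def test_40km_cells_clip_to_country(self, square_country_100km):
        grid = build_grid(square_country_100km, 40 * KM)
        assert len(grid.cell_area_km2) == 9
        assert sum(grid.cell_area_km2.values()) == pytest.approx(10_000.0, rel=1e-9)
        # oracle: independent polygon-intersection areas
        for (c, r), a in grid.cell_area_km2.items():
            sq = box(c * 40 * KM, r * 40 * KM, (c + 1) * 40 * KM, (r + 1) * 40 * KM)
            assert a == pytest.approx(
                square_country_100km.intersection(sq).area / 1e6, rel=1e-9
            )

    def test_irregular_country_area_conserved(self):
        # L-shaped country
        country = Polygon(
            [(0, 0), (100 * KM, 0), (100 * KM, 40 * KM), (40 * KM, 40 * KM),
             (40 * KM, 100 * KM), (0, 100 * KM)]
        )
        grid = build_grid(country, 30 * KM)
        assert sum(grid.cell_area_km2.values()) == pytest.approx(
            country.area / 1e6, rel=1e-6
        )
        # fully-outside cells are absent
        for cell in grid.cells:
            assert grid.cell_polygon(cell).intersection(country).area > 0

    def test_empty_polygon_rejected(self):
        with pytest.raises(ValueError):
            build_grid(Polygon(), 10 * KM)
        with pytest.raises(ValueError):
            build_grid(box(0, 0, 1, 1), -5)


class TestAssign:
    @pytest.mark.parametrize(
        "xy,expected",
        [
            ((0.0, 0.0), (0, 0)),
            ((25 * KM, 0.0), (1, 0)),  # boundary belongs to the next cell
            ((24_999.999, 0.0), (0, 0)),
        ],
    )
    def test_half_open_convention(self, square_country_100km, xy, expected):
        grid = build_grid(square_country_100km, 25 * KM)
        occ = make_occurrences([("A", "Aves", xy[0], xy[1])])
        asn = assign(occ, grid)
        assert asn.labels()[0] == expected

    def test_point_outside_flagged(self, square_country_100km):
        grid = build_grid(square_country_100km, 25 * KM)
        occ = make_occurrences([("A", "Aves", -1.0, 0.0), ("B", "Aves", 1.0, 1.0)])
        asn = assign(occ, grid)
        assert asn.labels()[0] is None
        assert asn.n_outside == 1

    def test_crs_mismatch_rejected(self, square_country_100km):
        grid = build_grid(square_country_100km, 25 * KM, crs_tag="utm")
        occ = make_occurrences([("A", "Aves", 1, 1)], crs_tag="other")
        with pytest.raises(ValueError, match="CRS"):
            assign(occ, grid)

    def test_every_in_country_point_in_exactly_one_cell(self, rng):
        country = Point(50 * KM, 50 * KM).buffer(45 * KM)
        grid = build_grid(country, 20 * KM)
        pts = rng.uniform(0, 100 * KM, size=(400, 2))
        inside = [p for p in pts if country.contains(Point(p))]
        occ = make_occurrences(
            [("S", "Aves", p[0], p[1]) for p in inside]
        )
        asn = assign(occ, grid)
        assert asn.n_outside == 0
        assert asn.labels().notna().all()

    def test_refinement_consistency_25_vs_12p5(self, square_country_100km, rng):
        coarse = build_grid(square_country_100km, 25 * KM)
        fine = build_grid(square_country_100km, 12.5 * KM)
        pts = rng.uniform(0, 100 * KM, size=(500, 2))
        occ = make_occurrences([("S", "Aves", x, y) for x, y in pts])
        lab_c = assign(occ, coarse).labels()
        lab_f = assign(occ, fine).labels()
        counts_c = lab_c.value_counts()
        for cell, n in counts_c.items():
            c, r = cell
            children = [(2 * c + dc, 2 * r + dr) for dc in (0, 1) for dr in (0, 1)]
            assert sum((lab_f == ch).sum() for ch in children) == n


class TestSubgrid:
    def test_incidence_collapses_abundance(self, square_country_100km):
        grid = build_grid(square_country_100km, 25 * KM)
        occ = make_occurrences(
            [("A", "Aves", 100, 100), ("A", "Aves", 200, 300)]  # same 1km sub-cell
        )
        sub = subgrid_incidence(occ, grid, (0, 0))
        assert sub.incidence_counts() == {"A": 1}
        assert sub.n_units == 1

    def test_incidence_counts_distinct_subcells(self, square_country_100km):
        grid = build_grid(square_country_100km, 25 * KM)
        occ = make_occurrences(
            [
                ("A", "Aves", 500, 500),
                ("A", "Aves", 1500, 500),
                ("A", "Aves", 2500, 500),
                ("B", "Aves", 500, 500),
            ]
        )
        sub = subgrid_incidence(occ, grid, (0, 0))
        assert sub.incidence_counts() == {"A": 3, "B": 1}

    def test_empty_cell_empty_subgrid(self, square_country_100km):
        grid = build_grid(square_country_100km, 25 * KM)
        occ = make_occurrences([("A", "Aves", 30 * KM, 30 * KM)])
        sub = subgrid_incidence(occ, grid, (0, 0))
        assert sub.presence == {}

    def test_indivisible_sub_size_rejected(self, square_country_100km):
        grid = build_grid(square_country_100km, 12.5 * KM)
        occ = make_occurrences([("A", "Aves", 100, 100)])
        with pytest.raises(ValueError, match="divide"):
            subgrid_incidence(occ, grid, (0, 0), sub_size=1000)
        # an explicit divisor works
        sub = subgrid_incidence(occ, grid, (0, 0), sub_size=500)
        assert sub.incidence_counts() == {"A": 1}

    def test_all_cells_pass_matches_per_cell(self, square_country_100km, rng):
        grid = build_grid(square_country_100km, 25 * KM)
        pts = rng.uniform(0, 100 * KM, size=(200, 2))
        occ = make_occurrences(
            [(f"S{i % 7}", "Aves", x, y) for i, (x, y) in enumerate(pts)]
        )
        all_subs = subgrid_incidence_all(occ, grid, 1000)
        for cell, sub in all_subs.items():
            single = subgrid_incidence(occ, grid, cell, 1000)
            assert sub.incidence_counts() == single.incidence_counts()
            assert sub.n_units == single.n_units


class TestUnsampledArea:
    def test_one_empty_cell(self):
        country = box(0, 0, 20 * KM, 20 * KM)
        grid = build_grid(country, 10 * KM)  # 4 cells of 100 km2
        occ = make_occurrences(
            [("A", "Aves", 1, 1), ("A", "Aves", 11 * KM, 1), ("A", "Aves", 1, 11 * KM)]
        )
        km2, pct = unsampled_area(grid, assign(occ, grid))
        assert km2 == pytest.approx(100.0)
        assert pct == pytest.approx(25.0)

    def test_all_occupied_and_none_occupied(self):
        country = box(0, 0, 20 * KM, 10 * KM)
        grid = build_grid(country, 10 * KM)
        full = make_occurrences([("A", "Aves", 1, 1), ("A", "Aves", 11 * KM, 1)])
        km2, pct = unsampled_area(grid, assign(full, grid))
        assert (km2, pct) == (0.0, 0.0)
        empty = make_occurrences([])
        km2, pct = unsampled_area(grid, assign(empty, grid))
        assert km2 == pytest.approx(grid.country_area_km2)
        assert pct == pytest.approx(100.0)

    def test_sampled_plus_unsampled_is_country(self, small_city_sim):
        from divgrid.occurrences import deduplicate

        occ, _ = deduplicate(small_city_sim.occurrences)
        grid = build_grid(small_city_sim.country, 25 * KM, crs_tag=occ.crs_tag)
        asn = assign(occ, grid)
        km2, _ = unsampled_area(grid, asn)
        occupied = set(asn.labels().dropna())
        sampled = sum(grid.cell_area_km2[c] for c in occupied)
        assert sampled + km2 == pytest.approx(grid.country_area_km2, rel=1e-9)
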