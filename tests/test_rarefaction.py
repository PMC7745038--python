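"""Coverage-based rarefaction/extrapolation and coverage standardisation."""

import math

import numpy as np
import pytest

from divgrid.rarefaction import (
    IncidenceFrequencies,
    extrapolate_richness,
    extrapolated_coverage,
    include_cell,
    interpolated_coverage,
    rarefy_richness,
    reference_coverage,
    richness_at_coverage,
    standardise,
)

INC = IncidenceFrequencies(T=4, Y=(2, 1, 1))  # worked example: U=4, Q1=2, Q2=1


class TestInclusionFilter:
    @pytest.mark.parametrize(
        "T,Y,included",
        [
            (10, (4, 3, 3, 2, 2), False),      # S_obs = 5 < 6
            (8, (1,) * 8, False),              # U == S_obs, all singletons
            (5, (3, 2, 2, 1, 1, 1), False),    # T = 5 < 6
            (9, (4, 3, 2, 2, 2, 2), True),     # passes all three rules
        ],
    )
    def test_rules(self, T, Y, included):
        assert include_cell(IncidenceFrequencies(T=T, Y=Y)) is included

    def test_frequency_summaries(self):
        assert (INC.S_obs, INC.U, INC.Q1, INC.Q2) == (3, 4, 2, 1)
        with pytest.raises(ValueError):
            IncidenceFrequencies(T=2, Y=(3,))  # Y_j > T


class TestCoverage:
    def test_no_singletons_full_coverage(self):
        inc = IncidenceFrequencies(T=5, Y=(3, 2, 2))
        assert reference_coverage(inc) == 1.0

    def test_worked_example(self):
        assert reference_coverage(INC) == pytest.approx(0.625)

    def test_all_singletons_zero_coverage(self):
        inc = IncidenceFrequencies(T=6, Y=(1, 1, 1))
        assert reference_coverage(inc) == pytest.approx(0.0)

    def test_extrapolated_coverage(self):
        assert extrapolated_coverage(INC, 0) == pytest.approx(reference_coverage(INC))
        assert extrapolated_coverage(INC, 4) == pytest.approx(1 - 0.5 * 0.75**5)
        assert extrapolated_coverage(
            IncidenceFrequencies(T=5, Y=(3, 2)), 7
        ) == 1.0  # Q1 = 0

    def test_interpolated_meets_reference_and_is_monotone(self):
        inc = IncidenceFrequencies(T=8, Y=(5, 3, 2, 1, 1))
        cs = [interpolated_coverage(inc, t) for t in range(1, 9)]
        assert cs[-1] == pytest.approx(reference_coverage(inc))
        assert all(b >= a - 1e-12 for a, b in zip(cs, cs[1:]))


class TestRarefy:
    def test_identity_at_reference_size(self):
        assert rarefy_richness(INC, 4) == pytest.approx(3.0)

    def test_mean_per_unit_richness_at_one(self):
        inc = IncidenceFrequencies(T=6, Y=(4, 2, 2, 1))
        assert rarefy_richness(inc, 1) == pytest.approx(inc.U / inc.T)

    def test_worked_example_t2(self):
        assert rarefy_richness(INC, 2) == pytest.approx(11 / 6)

    def test_subsampling_oracle(self, rng):
        """S_hat(t) equals the mean richness over random unit subsets."""
        T = 10
        # incidence matrix: which units each species occupies
        occ = rng.random((6, T)) < rng.uniform(0.15, 0.8, size=(6, 1))
        occ[:, 0] |= ~occ.any(axis=1)  # no empty species
        Y = tuple(int(v) for v in occ.sum(axis=1))
        inc = IncidenceFrequencies(T=T, Y=Y)
        for t in (2, 5, 8):
            sims = []
            for _ in range(2000):
                pick = rng.choice(T, size=t, replace=False)
                sims.append(int(occ[:, pick].any(axis=1).sum()))
            mc = np.mean(sims)
            se = np.std(sims) / math.sqrt(len(sims))
            assert rarefy_richness(inc, t) == pytest.approx(mc, abs=max(4 * se, 0.02))

    def test_curve_concave_nondecreasing(self):
        inc = IncidenceFrequencies(T=12, Y=(7, 5, 4, 2, 2, 1, 1, 1))
        s = [rarefy_richness(inc, t) for t in range(1, 13)]
        diffs = np.diff(s)
        assert (diffs >= -1e-12).all()
        assert (np.diff(diffs) <= 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rarefy_richness(INC, 0)
        with pytest.raises(ValueError):
            rarefy_richness(INC, 5)


class TestExtrapolate:
    def test_boundary_and_worked_example(self):
        assert extrapolate_richness(INC, 0) == 3.0
        expected = 3 + 1.5 * (1 - (1 - 2 / 8) ** 4)
        assert extrapolate_richness(INC, 4) == pytest.approx(expected)

    def test_no_singletons_flat(self):
        inc = IncidenceFrequencies(T=5, Y=(3, 2, 2))
        assert extrapolate_richness(inc, 10) == 3.0

    def test_q2_zero_fallback(self):
        inc = IncidenceFrequencies(T=6, Y=(3, 1, 1))  # Q2 = 0, Q1 = 2
        s = extrapolate_richness(inc, 6)
        assert np.isfinite(s) and s > 3.0

    def test_continuity_at_reference_size(self):
        inc = IncidenceFrequencies(T=9, Y=(6, 4, 3, 2, 1, 1))
        assert extrapolate_richness(inc, 1e-9) == pytest.approx(
            rarefy_richness(inc, inc.T), abs=1e-6
        )


class TestCoverageTruth:
    def test_coverage_estimator_tracks_true_coverage(self, rng):
        """On data with known detection probabilities, the reference-coverage
        estimator is close to the true expected coverage on average."""
        T = 12
        pi = np.array([0.9, 0.7, 0.5, 0.3, 0.2, 0.1, 0.1, 0.05])
        est, truth = [], []
        for _ in range(400):
            occ = rng.random((len(pi), T)) < pi[:, None]
            detected = occ.any(axis=1)
            if detected.sum() == 0:
                continue
            # true coverage: share of total incidence probability detected
            truth.append(pi[detected].sum() / pi.sum())
            Y = occ.sum(axis=1)[detected]
            est.append(
                reference_coverage(
                    IncidenceFrequencies(T=T, Y=tuple(int(v) for v in Y))
                )
            )
        assert np.mean(est) == pytest.approx(np.mean(truth), abs=0.05)


class TestStandardise:
    def test_single_cell(self):
        inc = IncidenceFrequencies(T=9, Y=(4, 3, 2, 2, 2, 2))
        std = standardise({"c": inc})
        c2t = extrapolated_coverage(inc, inc.T)
        assert std.c_max == pytest.approx(c2t)
        assert std.c_5pct == pytest.approx(c2t)
        assert std.table.loc["c", "S_at_Cmax"] == pytest.approx(
            std.table.loc["c", "S_at_C5"]
        )

    def test_identical_cells_share_standardised_richness(self):
        inc = IncidenceFrequencies(T=10, Y=(6, 4, 3, 2, 2, 1, 1))
        std = standardise({"a": inc, "b": inc})
        assert std.table.loc["a", "S_at_Cmax"] == pytest.approx(
            std.table.loc["b", "S_at_Cmax"]
        )

    def test_target_inversion_consistency(self):
        """Richness at target coverage sits on the cell's own curve."""
        inc = IncidenceFrequencies(T=10, Y=(6, 4, 3, 2, 2, 1, 1))
        from divgrid.rarefaction import coverage_at, richness_at

        for target in (0.5, 0.75, reference_coverage(inc), 0.93):
            s, t, capped = richness_at_coverage(inc, target)
            if not capped:
                assert coverage_at(inc, t) == pytest.approx(target, abs=5e-3)
            assert s == pytest.approx(richness_at(inc, t), abs=1e-9)

    def test_unreachable_target_capped(self):
        inc = IncidenceFrequencies(T=10, Y=(6, 4, 3, 2, 2, 1, 1))
        s, t, capped = richness_at_coverage(inc, 0.99999)
        assert capped and t == pytest.approx(2 * inc.T)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            standardise({})
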