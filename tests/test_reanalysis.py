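import numpy as np
import pandas as pd
import pytest

from moralcan.can import CANParameters
from moralcan.data import Battery
from moralcan.mpt import cni_invert
from moralcan.reanalysis import (
    build_comparison_report,
    compare_groups_can,
    compare_groups_cni,
    correlate_traits,
    run_hypothesis_checks,
)
from moralcan.simulate import PopulationSpec, simulate_battery, \
    simulate_population, simulate_responses

from conftest import battery_from_counts


def two_group_battery(counts1, counts2, trials=6):
    groups = {}
    cell_actions = {}
    for k, a in enumerate(counts1):
        pid = f"g1_{k}"
        cell_actions[pid] = a
        groups[pid] = "g1"
    for k, a in enumerate(counts2):
        pid = f"g2_{k}"
        cell_actions[pid] = a
        groups[pid] = "g2"
    return battery_from_counts(cell_actions, trials_per_cell=trials,
                               group=groups)


class TestCompareGroupsCan:
    def test_identical_groups_null_result(self):
        patterns = [(4, 1, 5, 3), (3, 2, 4, 4), (5, 0, 6, 2)]
        battery = two_group_battery(patterns, patterns)
        results = compare_groups_can(battery)
        for param in ("C", "N", "A"):
            assert results[param].t == pytest.approx(0.0, abs=1e-12)
            assert results[param].p_value == pytest.approx(1.0)
            assert results[param].cohens_d == pytest.approx(0.0)

    def test_hand_computed_pooled_t(self):
        """Group C means (0.1,0.2,0.3) vs (0.4,0.5,0.6): pooled SD 0.1,
        t(4) = -3.674, d = -3."""
        # C = (p1-p2+p3-p4)/2 with p2=p4=0, p3=p1 gives C = p1; use
        # 10 trials/cell so 0.1-steps are representable
        g1 = [(1, 0, 1, 0), (2, 0, 2, 0), (3, 0, 3, 0)]
        g2 = [(4, 0, 4, 0), (5, 0, 5, 0), (6, 0, 6, 0)]
        battery = two_group_battery(g1, g2, trials=10)
        res = compare_groups_can(battery)["C"]
        assert res.means[0] == pytest.approx(0.2)
        assert res.means[1] == pytest.approx(0.5)
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.cohens_d == pytest.approx(-3.0, abs=1e-9)

    def test_more_than_two_groups_rejected(self):
        battery = battery_from_counts(
            {"a": (1, 1, 1, 1), "b": (2, 2, 2, 2), "c": (3, 3, 3, 3)},
            group={"a": "g1", "b": "g2", "c": "g3"},
        )
        with pytest.raises(ValueError, match="pair"):
            compare_groups_can(battery)


class TestHypothesisChecks:
    def test_noise_free_cni_battery_satisfies_identities(self):
        # all participants share exact CNI(0.3, 0.5, 0.4) cells; with 100
        # trials/cell at those (multiple-of-0.01) probabilities the observed
        # proportions are exact
        cells = (51, 21, 86, 56)
        battery = battery_from_counts(
            {f"s{k}": cells for k in range(20)}, trials_per_cell=100
        )
        hc = run_hypothesis_checks(battery)
        assert hc.evaluable
        assert hc.h1_discrepancy < 1e-3
        assert hc.h2_discrepancy < 1e-3
        assert hc.h3_reversed is True  # I = 0.4 < 0.5 < A = 0.535

    def test_random_battery_reports_boundary(self):
        battery = battery_from_counts(
            {f"s{k}": (3, 3, 3, 3) for k in range(10)}
        )
        hc = run_hypothesis_checks(battery)
        assert hc.evaluable
        assert hc.h3_reversed is None  # A = I = 0.5 exactly

    def test_dna_generated_battery_still_satisfies_h1_h2(self):
        # DNA cells (0.42, 0.10, 0.90, 0.58) -> C_CAN = D(1-N) = 0.32,
        # N_CAN = DN = 0.48; the CNI fit of the same cells must agree on C
        cells = (42, 10, 90, 58)
        battery = battery_from_counts(
            {f"s{k}": cells for k in range(10)}, trials_per_cell=100
        )
        hc = run_hypothesis_checks(battery)
        assert hc.evaluable
        assert hc.c_can == pytest.approx(0.32, abs=1e-9)
        assert hc.n_can == pytest.approx(0.48, abs=1e-9)
        assert hc.h1_discrepancy < 1e-3
        assert hc.h2_discrepancy < 1e-3


class TestCorrelateTraits:
    def test_exact_linear_trait_gives_unit_correlation(self, rng):
        cell_actions = {
            f"s{k}": tuple(rng.integers(0, 7, 4)) for k in range(30)
        }
        battery = battery_from_counts(cell_actions)
        # trait = 2*C + 1 computed from the realized scores
        from moralcan.can import can_scores

        scores = can_scores(battery).set_index("participant")
        trait = {pid: 2 * scores.loc[pid, "C"] + 1 for pid in scores.index}
        battery = battery_from_counts(cell_actions, trait=trait)
        res = correlate_traits(battery)
        assert res["C"].r == pytest.approx(1.0, abs=1e-9)
        assert res["C"].p_value < 1e-10

    def test_independent_trait_uncorrelated(self):
        spec = PopulationSpec(1000, "cni", (0.3, 0.5, 0.4), (0.5,) * 3, seed=31)
        latents = simulate_population(spec)
        rng = np.random.default_rng(32)
        battery = simulate_responses(latents, "cni", 6, seed=33,
                                     traits=rng.standard_normal(len(latents)))
        res = correlate_traits(battery)
        for param in ("C", "N", "A"):
            assert abs(res[param].r) < 0.1

    def test_planted_negative_trait_effect_on_n(self):
        """A trait built as -latent N + noise correlates negatively with the
        recovered individual N scores."""
        spec = PopulationSpec(300, "cni", (0.3, 0.5, 0.4), (0.8,) * 3, seed=41)
        latents = simulate_population(spec)
        rng = np.random.default_rng(42)
        traits = -latents["N"].to_numpy() + 0.1 * rng.standard_normal(300)
        battery = simulate_responses(latents, "cni", 6, seed=43, traits=traits)
        res = correlate_traits(battery)
        assert res["N"].r < -0.2
        assert res["N"].p_value < 0.001

    def test_zero_variance_trait_degenerate(self):
        battery = battery_from_counts(
            {f"s{k}": (4, 1, 5, 3) for k in range(5)},
            trait={f"s{k}": 1.0 for k in range(5)},
        )
        res = correlate_traits(battery)
        assert res["C"].degenerate


class TestComparisonReport:
    def test_planted_n_difference_flagged_in_both_frameworks(self):
        spec1 = PopulationSpec(120, "cni", (0.3, 0.30, 0.4), (0.3,) * 3,
                               seed=51, group="g1")
        spec2 = PopulationSpec(120, "cni", (0.3, 0.60, 0.4), (0.3,) * 3,
                               seed=52, group="g2")
        _, b1 = simulate_battery(spec1)
        _, b2 = simulate_battery(spec2)
        df2 = b2.df.assign(participant=b2.df.participant + "_b")
        battery = Battery(pd.concat([b1.df, df2], ignore_index=True))
        report = build_comparison_report(battery)
        by_param = {row.cni_parameter: row for row in report.rows}
        assert by_param["N"].p_cni < 0.01
        assert by_param["N"].p_can < 0.01
        assert by_param["N"].agreement
        text = report.to_text()
        assert "H1" in text and "g1 vs g2" in text

    def test_identical_groups_all_rows_agree(self):
        patterns = [(4, 1, 5, 3), (3, 2, 4, 4), (5, 0, 6, 2), (2, 1, 5, 4)]
        battery = two_group_battery(patterns, patterns)
        report = build_comparison_report(battery)
        for row in report.rows:
            assert row.p_cni > 0.05 and row.p_can > 0.05
            assert row.agreement

    def test_agreement_flag_symmetric_in_group_labels(self):
        g1 = [(4, 1, 5, 3), (3, 2, 4, 4), (5, 0, 6, 2)]
        g2 = [(2, 2, 3, 3), (1, 1, 4, 4), (3, 0, 5, 5)]
        forward = build_comparison_report(two_group_battery(g1, g2))
        swapped = build_comparison_report(two_group_battery(g2, g1))
        for a, b in zip(forward.rows, swapped.rows):
            assert a.agreement == b.agreement
            assert a.delta_g2 == pytest.approx(b.delta_g2, abs=1e-5)
            assert a.t == pytest.approx(-b.t, abs=1e-9)


def test_a_and_inverted_i_anticorrelated_across_participants():
    """With heterogeneous latents, individual A scores and the closed-form
    individual I estimates move in opposite directions."""
    spec = PopulationSpec(200, "cni", (0.3, 0.5, 0.4), (0.6,) * 3, seed=61)
    latents = simulate_population(spec)
    from moralcan.mpt import _cni_cells

    from moralcan.data import CellProbabilities

    theta = latents[["C", "N", "I"]].to_numpy().T
    cells = _cni_cells(theta).T
    a_scores = cells.mean(axis=1)
    i_est = np.array([cni_invert(CellProbabilities(*c)).I for c in cells])
    assert np.corrcoef(a_scores, i_est)[0, 1] < -0.5
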