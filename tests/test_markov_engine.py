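"""Transition matrices, cohort propagation, and discounted accrual."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bphcea import (
    STATES,
    LifeTable,
    accumulate,
    build_transition_matrix,
    cancer_probability,
    death_probability,
    rate_to_probability,
    run_arm,
    run_cohort,
)
from bphcea.markov_engine import InfeasibleParametersError, _IDX
from bphcea.synthetic_data import make_life_table, perturb_parameters


class TestRateToProbability:
    @pytest.mark.parametrize(
        "rate,t,expected",
        [(0.0, 1.0, 0.0), (0.18, 1.0, 0.1647298), (0.1, 2.0, 0.1812692)],
    )
    def test_closed_form(self, rate, t, expected):
        assert rate_to_probability(rate, t) == pytest.approx(expected, abs=1e-7)

    def test_saturates_toward_one(self):
        assert rate_to_probability(1e6) == pytest.approx(1.0)
        assert rate_to_probability(1e6) < 1.0 or rate_to_probability(1e6) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(rate=st.floats(0, 50), t=st.floats(0.01, 10))
    def test_always_a_probability(self, rate, t):
        p = rate_to_probability(rate, t)
        assert 0.0 <= p < 1.0 or p == pytest.approx(1.0)


class TestDeathProbability:
    lt = LifeTable(bands=[(40, 80, 0.04), (80, 90, 0.05)])

    def test_drug_state_uses_life_table_only(self, base_params):
        p = death_probability(72, self.lt, "drug_later", base_params.transitions)
        assert p == 0.04

    def test_first_surgical_year_adds_blended_addon(self, base_params):
        p = death_probability(
            70, self.lt, "surg_y1", base_params.transitions,
            blended_addon=base_params.blended_death_addon,
        )
        assert p == pytest.approx(0.04 + 0.8 * 0.001 + 0.2 * 0.002)

    def test_later_surgical_years_follow_the_first_year_only_flag(self, params):
        kwargs = dict(blended_addon=params.blended_death_addon)
        assert death_probability(
            70, self.lt, "surg_later", params.transitions, **kwargs
        ) == 0.04
        params.transitions.addon_first_year_only = False
        assert death_probability(
            70, self.lt, "surg_later", params.transitions, **kwargs
        ) == pytest.approx(0.0412)

    def test_cancer_states_add_excess_mortality(self, base_params):
        lt = LifeTable(bands=[(40, 90, 0.05)])
        p = death_probability(75, lt, "pc_y1", base_params.transitions)
        assert p == pytest.approx(0.23)

    def test_capped_at_one(self, base_params):
        lt = LifeTable(bands=[(40, 90, 0.95)])
        assert death_probability(75, lt, "pc_later", base_params.transitions) == 1.0


class TestCancerProbability:
    def test_chemoprevention_reduces_early_drug_cycles(self, base_params):
        t = base_params.transitions
        assert cancer_probability("drug_y1", 1, t) == pytest.approx(0.000627)
        assert cancer_probability("drug_later", 2, t) == pytest.approx(0.000627)
        assert cancer_probability("drug_later", 3, t) == 0.000836
        assert cancer_probability("drug_later", 5, t) == 0.000836

    def test_surgery_states_use_surgical_incidence(self, base_params):
        for cycle in (1, 5, 10):
            assert cancer_probability("surg_later", cycle,
                                      base_params.transitions) == 0.0011

    def test_disabled_chemoprevention(self, params):
        params.transitions.chemoprevention_enabled = False
        assert cancer_probability("drug_y1", 1, params.transitions) == 0.000836

    def test_no_cancer_transition_from_cancer_or_death(self, base_params):
        with pytest.raises(ValueError):
            cancer_probability("pc_y1", 1, base_params.transitions)


class TestTransitionMatrix:
    def test_rows_sum_to_one_every_cycle(self, base_params):
        for cycle in range(1, 11):
            m = build_transition_matrix(base_params, cycle)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all() and (m <= 1).all()

    def test_death_row_is_absorbing(self, base_params):
        m = build_transition_matrix(base_params, 1)
        expected = np.zeros(7)
        expected[_IDX["death"]] = 1.0
        np.testing.assert_array_equal(m[_IDX["death"]], expected)

    def test_drug_y1_residual_rule(self, base_params):
        m = build_transition_matrix(base_params, 1)
        mort = base_params.life_table.annual_probability(70)
        row = m[_IDX["drug_y1"]]
        assert row[_IDX["surg_y1"]] == 0.3
        assert row[_IDX["pc_y1"]] == pytest.approx(0.000627)
        assert row[_IDX["death"]] == mort
        assert row[_IDX["drug_later"]] == pytest.approx(1 - 0.3 - 0.000627 - mort)
        # topology: no flows outside the pathway diagram
        assert row[_IDX["drug_y1"]] == 0.0
        assert row[_IDX["surg_later"]] == 0.0
        assert row[_IDX["pc_later"]] == 0.0

    def test_transient_states_empty_after_one_cycle(self, base_params):
        m = build_transition_matrix(base_params, 3)
        for state in ("drug_y1", "surg_y1", "pc_y1"):
            assert m[_IDX[state], _IDX[state]] == 0.0

    def test_infeasible_row_raises_with_state_name(self, params):
        params.transitions.p_noncompliance_y1 = 0.99
        params.transitions.p_drug_to_pc = 0.05
        with pytest.raises(InfeasibleParametersError, match="drug_y1"):
            build_transition_matrix(params, 1)

    def test_ageing_updates_mortality_band(self, params):
        # 65-year-old cohort crosses into the 70-80 band at cycle 6
        params.settings.start_age = 65
        m5 = build_transition_matrix(params, 5)  # age 69
        m6 = build_transition_matrix(params, 6)  # age 70
        i = _IDX["drug_later"]
        assert m5[i, _IDX["death"]] == 0.018
        assert m6[i, _IDX["death"]] == 0.045
        params.settings.freeze_age = True
        m6f = build_transition_matrix(params, 6)
        assert m6f[i, _IDX["death"]] == 0.018


class TestCohortPropagation:
    def test_initialization_concentrates_cohort_in_entry_state(self, base_params):
        trace = run_cohort("pharmacotherapy", base_params)
        assert trace.occupancy[0, _IDX["drug_y1"]] == 1000
        assert trace.occupancy[0].sum() == 1000
        trace_s = run_cohort("surgery", base_params)
        assert trace_s.occupancy[0, _IDX["surg_y1"]] == 1000

    def test_identity_dynamics_without_events(self, params):
        params.life_table = make_life_table("zero-mortality")
        params.transitions.p_noncompliance_y1 = 0.0
        params.transitions.p_drug_to_surgery_later = 0.0
        params.transitions.p_drug_to_pc = 0.0
        trace = run_cohort("pharmacotherapy", params)
        # drug_y1 is transient by construction; everyone sits in drug_later
        np.testing.assert_allclose(trace.occupancy[1:, _IDX["drug_later"]], 1000)
        np.testing.assert_allclose(trace.occupancy[:, _IDX["death"]], 0.0)

    def test_conservation_and_death_monotonicity(self, base_params):
        for arm in ("pharmacotherapy", "surgery"):
            trace = run_cohort(arm, base_params)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1000,
                                       atol=1e-9)
            deaths = trace.occupancy[:, _IDX["death"]]
            assert (np.diff(deaths) > 0).all()  # strictly positive mortality
            assert (trace.occupancy >= 0).all()

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_under_perturbed_parameters(self, base_params, seed):
        p = perturb_parameters(base_params, 0.3, seed)
        for arm in ("pharmacotherapy", "surgery"):
            trace = run_cohort(arm, p)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1000,
                                       atol=1e-9)
            deaths = trace.occupancy[:, _IDX["death"]]
            assert (np.diff(deaths) >= -1e-12).all()

    def test_immediate_noncompliance_flag_moves_crossover_to_cycle_one(
        self, params
    ):
        params.settings.immediate_noncompliance = True
        trace = run_cohort("pharmacotherapy", params)
        assert trace.occupancy[0, _IDX["drug_y1"]] == pytest.approx(700)
        assert trace.occupancy[0, _IDX["surg_y1"]] == pytest.approx(300)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1000, atol=1e-9)


class TestAccumulation:
    def test_single_person_single_cycle_discounting(self, params):
        params.settings.cohort_size = 1
        params.settings.horizon = 1
        trace = run_cohort("pharmacotherapy", params)
        acc = accumulate(trace, params)
        assert acc.total_cost == pytest.approx(146.36 / 1.07)

    def test_zero_discount_equals_raw_sums(self, params):
        params.settings.discount_cost = 0.0
        params.settings.discount_utility = 0.0
        trace, acc = run_arm("surgery", params)
        from bphcea.markov_engine import cost_vector, utility_vector

        raw_cost = sum(
            float(trace.occupancy[t - 1] @ cost_vector(params))
            for t in range(1, 11)
        )
        raw_qaly = sum(
            float(trace.occupancy[t - 1] @ utility_vector(params, t))
            for t in range(1, 11)
        )
        assert acc.total_cost == pytest.approx(raw_cost)
        assert acc.total_qaly == pytest.approx(raw_qaly)

    def test_annuity_closed_form_for_static_cohort(self, params):
        # no deaths, no transitions: 1000 people held in drug_later
        params.life_table = make_life_table("zero-mortality")
        params.transitions.p_noncompliance_y1 = 0.0
        params.transitions.p_drug_to_surgery_later = 0.0
        params.transitions.p_drug_to_pc = 0.0
        params.utility.trajectory.slope = 0.0
        params.utility.trajectory.intercept = 12.0
        trace, acc = run_arm("pharmacotherapy", params)
        from bphcea import ipss_to_utility

        u1 = 0.8 * ipss_to_utility(params.utility, 16.7)  # cycle 1 observed
        u = 0.8 * ipss_to_utility(params.utility, 12.0)
        expected = 1000 * (
            u1 * 1.03**-1 + u * sum(1.03**-t for t in range(2, 11))
        )
        assert acc.total_qaly == pytest.approx(expected)

    def test_totals_equal_per_cycle_breakdown(self, base_params):
        _, acc = run_arm("pharmacotherapy", base_params)
        assert acc.total_cost == pytest.approx(acc.per_cycle["cost"].sum())
        assert acc.total_qaly == pytest.approx(acc.per_cycle["qaly"].sum())

    def test_discount_monotonicity(self, params):
        totals = []
        for rate in (0.0, 0.03, 0.07, 0.12):
            params.settings.discount_cost = rate
            params.settings.discount_utility = rate
            _, acc = run_arm("pharmacotherapy", params)
            totals.append((acc.total_cost, acc.total_qaly))
        costs, qalys = zip(*totals)
        assert all(a > b for a, b in zip(costs, costs[1:]))
        assert all(a > b for a, b in zip(qalys, qalys[1:]))

    def test_start_of_cycle_discounting_option(self, params):
        params.settings.cohort_size = 1
        params.settings.horizon = 1
        params.settings.discount_from = "year_0"
        _, acc = run_arm("pharmacotherapy", params)
        assert acc.total_cost == pytest.approx(146.36)


class TestChemopreventionToggle:
    def test_toggle_scales_drug_cancer_inflow_by_exactly_three_quarters(
        self, params
    ):
        params.transitions.chemoprevention_enabled = True
        on = [build_transition_matrix(params, c) for c in range(1, 11)]
        params.transitions.chemoprevention_enabled = False
        off = [build_transition_matrix(params, c) for c in range(1, 11)]
        d1, dl, pc1 = _IDX["drug_y1"], _IDX["drug_later"], _IDX["pc_y1"]
        for cycle0, (m_on, m_off) in enumerate(zip(on, off)):
            affected = cycle0 + 1 in (1, 2)
            for row in (d1, dl):
                if affected:
                    assert m_on[row, pc1] == pytest.approx(0.75 * m_off[row, pc1])
                else:
                    assert m_on[row, pc1] == m_off[row, pc1]
            # nothing but the drug-row cancer inflow and its residual moves
            mask = np.ones((7, 7), dtype=bool)
            mask[d1, pc1] = mask[dl, pc1] = False
            mask[d1, dl] = mask[dl, dl] = False  # residual absorbs the change
            np.testing.assert_array_equal(m_on[mask], m_off[mask])
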