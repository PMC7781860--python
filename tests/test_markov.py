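"""Markov engine: state mapping, occupancy dynamics, accrual, horizon arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tests.conftest import random_stochastic_matrix
from esacea.cohort import ArmProfile, generate_cohort
from esacea.exceptions import ValidationError
from esacea.markov import (MarkovSpec, build_states, default_states,
                           estimate_transitions_from_cohort,
                           lifetime_horizon_cycles, qalys, run_cohort,
                           state_for_hb, transition_matrix_from_hb,
                           validate_transition_matrix)

CYCLE_YEARS = 28.0 / 365.25


def simple_spec(P, cost=None, utility=None, **kw):
    states = default_states()
    n = len(states)
    return MarkovSpec(
        states=states,
        transitions=P,
        state_cost=np.zeros(n) if cost is None else np.asarray(cost, float),
        state_utility=np.ones(n) if utility is None else np.asarray(utility, float),
        **kw,
    )


def identity_spec(**kw):
    P = np.eye(5)
    return simple_spec(P, **kw)


class TestStates:
    @pytest.mark.parametrize("hb,state", [
        (9.5, "alive_anemia"),
        (13.5, "dying_anemia"),
        (10.0, "alive_other"),   # half-open boundary
        (12.0, "dying_other"),
        (8.0, "alive_anemia"),   # severe-anemia comparator band folds in
    ])
    def test_hb_band_mapping(self, hb, state):
        assert state_for_hb(hb) == state

    def test_nonpositive_hb_rejected(self):
        with pytest.raises(ValidationError):
            state_for_hb(0.0)

    def test_default_layout(self):
        states = build_states()
        assert [s.id for s in states] == [
            "alive_anemia", "alive_other", "dying_other", "dying_anemia", "death"]
        assert sum(s.is_terminal for s in states) == 1

    def test_overlapping_bands_rejected(self):
        cfg = {"states": [
            {"id": "a", "hb_low": 9, "hb_high": 11},
            {"id": "b", "hb_low": 10, "hb_high": 12},
            {"id": "death", "is_terminal": True},
        ]}
        with pytest.raises(ValidationError):
            build_states(cfg)

    def test_missing_death_state_rejected(self):
        cfg = {"states": [{"id": "a", "hb_low": 9, "hb_high": 11}]}
        with pytest.raises(ValidationError):
            build_states(cfg)


class TestTransitionValidation:
    def test_row_sum_violation_names_row(self):
        P = np.eye(5)
        P[2, 2] = 0.9
        with pytest.raises(ValidationError, match=r"\[2\]"):
            validate_transition_matrix(P, 5)

    def test_death_row_must_be_absorbing(self):
        P = np.eye(5)
        P[4] = [0.1, 0, 0, 0, 0.9]
        with pytest.raises(ValidationError, match="absorbing"):
            validate_transition_matrix(P, 5, terminal_index=4)

    def test_invalid_matrix_rejected_before_any_cycle(self):
        P = np.full((5, 5), 0.3)
        with pytest.raises(ValidationError):
            simple_spec(P)


class TestRunCohort:
    def test_identity_chain_accrues_closed_form(self):
        trace = run_cohort(identity_spec(), [0, 1, 0, 0, 0], max_cycles=13)
        expected = 13 * CYCLE_YEARS
        assert trace.total_life_years == pytest.approx(expected, abs=1e-12)
        assert trace.total_qalys == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9966, abs=5e-5)

    def test_all_to_death_stops_after_one_cycle(self):
        P = np.zeros((5, 5))
        P[:, 4] = 1.0
        trace = run_cohort(simple_spec(P, cost=[10, 10, 10, 10, 0]),
                           [0, 1, 0, 0, 0], max_cycles=100)
        assert trace.n_cycles == 1
        assert trace.occupancy[-1, 4] == pytest.approx(1.0)
        assert trace.total_cost == pytest.approx(10.0)  # only the first cycle accrues
        assert trace.total_life_years == pytest.approx(CYCLE_YEARS)

    def test_two_state_survival_is_geometric(self):
        # stay with p=0.9: start-state occupancy after k cycles is p^k
        P = np.eye(5)
        P[1, 1], P[1, 4] = 0.9, 0.1
        trace = run_cohort(simple_spec(P), [0, 1, 0, 0, 0], max_cycles=10)
        assert trace.occupancy[-1, 1] == pytest.approx(0.9 ** 10, abs=1e-12)
        assert 0.9 ** 10 == pytest.approx(0.3487, abs=5e-5)

    @pytest.mark.parametrize("seed", range(10))
    def test_engine_matches_matrix_power_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        P = random_stochastic_matrix(rng, n)
        init = rng.dirichlet(np.ones(n))
        k = int(rng.integers(1, 51))
        # minimal state scaffolding of matching size
        from esacea.markov import MarkovState
        states = [MarkovState(f"s{i}", f"s{i}", (float(i), float(i + 1)))
                  for i in range(n - 1)] + [MarkovState("death", "d", None, True)]
        P[-1] = 0.0
        P[-1, -1] = 1.0
        spec = MarkovSpec(states=states, transitions=P, state_cost=np.zeros(n),
                          state_utility=np.ones(n))
        trace = run_cohort(spec, init, max_cycles=k, absorption_tol=0.0)
        oracle = init @ np.linalg.matrix_power(P, trace.n_cycles)
        assert np.abs(trace.occupancy[-1] - oracle).max() < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_occupancy_conservation_and_monotone_absorption(self, seed):
        rng = np.random.default_rng(100 + seed)
        P = random_stochastic_matrix(rng, 5)
        P[4] = 0.0
        P[4, 4] = 1.0
        spec = simple_spec(P)
        trace = run_cohort(spec, [0.2, 0.3, 0.2, 0.2, 0.1], max_cycles=40)
        assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() < 1e-9
        assert (np.diff(trace.occupancy[:, 4]) >= -1e-12).all()
        for series in (trace.cum_cost, trace.cum_life_years, trace.cum_qalys):
            assert (np.diff(series) >= -1e-12).all()

    def test_discounting_at_zero_equals_undiscounted(self):
        rng = np.random.default_rng(3)
        P = random_stochastic_matrix(rng, 5)
        P[4] = 0.0
        P[4, 4] = 1.0
        cost = [100, 80, 120, 90, 0]
        t0 = run_cohort(simple_spec(P, cost=cost), [1, 0, 0, 0, 0], 20)
        t3 = run_cohort(simple_spec(P, cost=cost, discount_rate_annual=0.03),
                        [1, 0, 0, 0, 0], 20)
        undiscounted = sum(
            float(t0.occupancy[t] @ np.asarray(cost, float)) for t in range(t0.n_cycles))
        assert t0.total_cost == pytest.approx(undiscounted, abs=1e-9)
        assert t3.total_cost < t0.total_cost

    def test_unit_utilities_make_qalys_equal_life_years(self):
        rng = np.random.default_rng(4)
        P = random_stochastic_matrix(rng, 5)
        P[4] = 0.0
        P[4, 4] = 1.0
        # QALY weights 1 on alive states, 0 in death -> QALY == LY exactly
        trace = run_cohort(simple_spec(P, utility=[1, 1, 1, 1, 0]),
                           [0.5, 0.5, 0, 0, 0], 30)
        assert trace.total_qalys == pytest.approx(trace.total_life_years, abs=1e-12)

    def test_bad_initial_vector_rejected(self):
        with pytest.raises(ValidationError):
            run_cohort(identity_spec(), [0.5, 0.4, 0, 0, 0], 5)


class TestScalars:
    def test_qalys_product(self):
        assert qalys(1.0, 1.0) == 1.0
        assert qalys(2.0, 0.5) == 1.0
        assert qalys(0.9966, 0.6) == pytest.approx(0.5980, abs=5e-5)
        with pytest.raises(ValidationError):
            qalys(1.0, 1.2)

    def test_lifetime_horizon_cycles(self):
        assert lifetime_horizon_cycles(55, 100, 28) == 588
        assert lifetime_horizon_cycles(99, 100, 28) == 14
        assert lifetime_horizon_cycles(55, 55.0766, 28) == 1  # one 28-day cycle
        with pytest.raises(ValidationError):
            lifetime_horizon_cycles(100, 55, 28)


class TestTransitionEstimation:
    def test_hb_derived_matrix_is_stochastic_and_absorbing(self):
        P = transition_matrix_from_hb(10.68, 0.98)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-9
        assert P[4, 4] == 1.0
        assert P[2, 4] == 1.0 and P[3, 4] == 1.0  # dying states exit by default
        # alive rows carry the N(10.68, 0.98) band masses
        from scipy.stats import norm
        assert P[0, 1] == pytest.approx(
            norm.cdf(12, 10.68, 0.98) - norm.cdf(10, 10.68, 0.98), abs=1e-12)

    def test_cohort_estimate_approaches_band_masses(self):
        # i.i.d. monthly Hb: the estimated alive rows converge to band masses
        prof = ArmProfile("d", 3000, 10.68, 0.98, 0.1, 100.0)
        recs = generate_cohort(prof, seed=8)
        P_hat = estimate_transitions_from_cohort(recs)
        P_true = transition_matrix_from_hb(10.68, 0.98)
        assert np.abs(P_hat[:2] - P_true[:2]).max() < 0.02
        assert np.abs(P_hat.sum(axis=1) - 1.0).max() < 1e-9
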