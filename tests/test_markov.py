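"""Transition-matrix structure, cohort propagation and the path-enumeration oracle."""

import itertools

import numpy as np
import pytest

from oafiscal import (
    FiscalState,
    ModelConfig,
    build_transition_matrices,
    build_transition_matrix,
    initial_occupancy,
    life_years,
    run_cohort,
)
from oafiscal.markov import N_STATES, CohortTrace, InvariantViolation

E, U, L, D, ER, R, UNK, DEAD = range(8)

BASE_PROBS = {
    "employment": 0.718,
    "unemployment": 0.028,
    "lt_sickness": 0.031,
    "early_retirement": 0.017,
    "disability": 0.039,
}


def random_probs(rng):
    raw = rng.dirichlet(np.ones(6)) * rng.uniform(0.3, 1.0)
    return dict(zip(BASE_PROBS, raw[:5]))


class TestBuildTransitionMatrix:
    def test_certain_death_sends_every_row_to_dead(self):
        m = build_transition_matrix(55, BASE_PROBS, 1.0)
        expected = np.zeros(N_STATES)
        expected[DEAD] = 1.0
        for s in range(N_STATES):
            np.testing.assert_allclose(m[s], expected)

    def test_degenerate_probs_cycle_through_unknown_back_to_employment(self):
        zero = {k: 0.0 for k in BASE_PROBS}
        m = build_transition_matrix(55, zero, 0.0)
        assert m[E, UNK] == 1.0  # residual mass parks in the unknown state
        assert m[UNK, E] == 1.0  # and is sent back to employment next cycle
        two_step = m @ m
        assert two_step[E, E] == 1.0

    def test_no_unemployment_or_early_retirement_entries_after_spa(self):
        m = build_transition_matrix(66, BASE_PROBS, 0.01)
        assert not m[:, U].any()
        assert not m[:, ER].any()
        # early-retired occupants convert to the pensioned retired state
        assert m[ER, R] == pytest.approx(0.99)

    def test_no_employment_entries_above_max_working_age(self):
        m = build_transition_matrix(71, BASE_PROBS, 0.05)
        assert not m[:, E].any()

    def test_tunnel_states_forbid_self_transition(self):
        m = build_transition_matrix(55, BASE_PROBS, 0.0)
        assert m[U, U] == 0.0
        assert m[L, L] == 0.0
        # exits renormalised over permitted destinations
        assert m[U, E] == pytest.approx(0.718 / (1 - 0.028))

    def test_disability_and_early_retirement_absorbing_before_spa(self):
        m = build_transition_matrix(55, BASE_PROBS, 0.0)
        assert m[D, D] == 1.0
        assert m[ER, ER] == 1.0

    def test_overfull_probabilities_rejected(self):
        bad = dict(BASE_PROBS, employment=0.95, disability=0.2)
        with pytest.raises(InvariantViolation, match="sum"):
            build_transition_matrix(55, bad, 0.0)

    def test_row_stochastic_over_random_configurations(self):
        # mass conservation + DEAD monotonicity for 1000 random valid inputs
        rng = np.random.default_rng(20240917)
        config = ModelConfig()
        for _ in range(1000):
            age = int(rng.integers(50, 100))
            probs = random_probs(rng)
            death = float(rng.uniform(0.0, 1.0))
            m = build_transition_matrix(age, probs, death, config)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-10)
            assert ((m >= -1e-12) & (m <= 1 + 1e-12)).all()

    def test_vectorised_builder_matches_scalar(self):
        rng = np.random.default_rng(42)
        config = ModelConfig()
        ages = np.arange(50, 100)
        probs = np.stack(
            [list(random_probs(rng).values()) for _ in ages]
        )
        death = rng.uniform(0, 1, size=len(ages))
        fast = build_transition_matrices(ages, probs, death, config)
        for t, age in enumerate(ages):
            slow = build_transition_matrix(
                int(age),
                dict(zip(BASE_PROBS, probs[t])),
                float(death[t]),
                config,
            )
            np.testing.assert_allclose(fast[t], slow, atol=1e-15)


class TestRunCohort:
    def test_identity_matrices_leave_trace_constant(self):
        init = initial_occupancy(BASE_PROBS)
        matrices = np.stack([np.eye(N_STATES)] * 4)
        trace = run_cohort(init, matrices, 50)
        for t in range(5):
            np.testing.assert_allclose(trace.occupancy[t], init)

    def test_geometric_decay_two_state_toy(self):
        m = np.eye(N_STATES)
        m[E, E], m[E, DEAD] = 0.9, 0.1
        trace = run_cohort(
            np.eye(N_STATES)[E], np.stack([m] * 3), 50
        )
        np.testing.assert_allclose(
            trace.occupancy[1:, E], [0.9, 0.81, 0.729], atol=1e-12
        )

    def test_cycle_zero_echoes_participation_inputs(self):
        init = initial_occupancy(BASE_PROBS)
        assert init[E] == 0.718 and init[U] == 0.028 and init[L] == 0.031
        assert init[ER] == 0.017 and init[D] == 0.039
        assert init[UNK] == pytest.approx(1 - 0.833)

    def test_tunnel_entry_pulse_fully_redistributed_next_cycle(self):
        config = ModelConfig()
        m = build_transition_matrix(55, BASE_PROBS, 0.0, config)
        pulse = np.zeros(N_STATES)
        pulse[U] = 1.0
        trace = run_cohort(pulse, np.stack([m]), 50)
        assert trace.occupancy[1, U] == 0.0  # no mass dwells two cycles

    def test_mass_conservation_on_random_model_chains(self):
        rng = np.random.default_rng(7)
        config = ModelConfig()
        for _ in range(200):
            ages = np.arange(50, 50 + 10)
            matrices = np.stack(
                [
                    build_transition_matrix(
                        int(a), random_probs(rng), float(rng.uniform(0, 0.3)), config
                    )
                    for a in ages
                ]
            )
            trace = run_cohort(initial_occupancy(random_probs(rng)), matrices, 50)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert (np.diff(trace.occupancy[:, DEAD]) >= -1e-12).all()

    def test_matches_exhaustive_path_enumeration(self):
        """Independent oracle: sum probabilities over every explicit state path."""
        rng = np.random.default_rng(123)
        T = 4
        # random row-stochastic matrices with DEAD absorbing, mass confined
        # to 4 states so the enumeration is the honest brute force
        states = [E, U, D, DEAD]
        matrices = []
        for _ in range(T):
            m = np.zeros((N_STATES, N_STATES))
            for s in states:
                if s == DEAD:
                    m[s, DEAD] = 1.0
                else:
                    row = rng.dirichlet(np.ones(len(states)))
                    for j, dest in enumerate(states):
                        m[s, dest] = row[j]
            for s in range(N_STATES):
                if s not in states:
                    m[s, s] = 1.0
            matrices.append(m)
        matrices = np.stack(matrices)
        init = np.zeros(N_STATES)
        init[E], init[U] = 0.6, 0.4

        expected = np.zeros(N_STATES)
        for path in itertools.product(states, repeat=T + 1):
            p = init[path[0]]
            for t in range(T):
                p *= matrices[t][path[t], path[t + 1]]
            expected[path[-1]] += p

        trace = run_cohort(init, matrices, 50)
        np.testing.assert_allclose(trace.occupancy[T], expected, atol=1e-10)

    def test_invalid_initial_vector_rejected(self):
        with pytest.raises(InvariantViolation):
            run_cohort(np.ones(N_STATES), np.stack([np.eye(N_STATES)]), 50)


class TestLifeYears:
    def make_trace(self, occ):
        occ = np.asarray(occ, dtype=float)
        return CohortTrace(occ, 50 + np.arange(occ.shape[0]))

    def test_no_deaths_undiscounted(self):
        occ = np.zeros((16, N_STATES))
        occ[:, E] = 1.0
        assert life_years(self.make_trace(occ), 0.0) == pytest.approx(15.0)

    def test_two_cycles_discounted(self):
        occ = np.zeros((3, N_STATES))
        occ[:, E] = 1.0
        assert life_years(self.make_trace(occ), 0.035) == pytest.approx(
            1.0 + 1.0 / 1.035
        )

    def test_dead_occupancy_excluded(self):
        occ = np.zeros((3, N_STATES))
        occ[:, E] = [1.0, 0.5, 0.25]
        occ[:, DEAD] = [0.0, 0.5, 0.75]
        assert life_years(self.make_trace(occ), 0.0) == pytest.approx(1.5)
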