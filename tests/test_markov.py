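"""Markov engine: matrices, propagation, half-cycle, discounting."""

import math

import numpy as np
import pytest

from her2ce.markov import (ArmTransitionInputs, StateSpace, build_matrix,
                           build_matrix_sequence, combine_competing,
                           discount_factor, discount_factors,
                           half_cycle_effective_occupancy, microsim_oracle,
                           run_cohort)

SPACE = StateSpace()


def make_inputs(H=24, exit_p=0.02, q=0.001, seed=None, **kw):
    if seed is not None:
        rng = np.random.default_rng(seed)
        exit_probs = rng.uniform(0.005, 0.05, H)
        qs = rng.uniform(0.0005, 0.003, H)
    else:
        exit_probs = np.full(H, exit_p)
        qs = np.full(H, q)
    defaults = dict(
        df_exit_prob=exit_probs,
        share_locoregional=0.4, share_metastatic=0.45, share_death=0.15,
        remission_to_1l=0.0076, p_1l_to_2l=0.0428, p_2l_death=0.0315,
        background_q=qs, treatment_cycles=10,
    )
    defaults.update(kw)
    return ArmTransitionInputs(**defaults)


class TestBuildMatrix:
    def test_rows_stochastic_and_structural_zero(self):
        inputs = make_inputs(seed=5)
        for k in range(inputs.n_cycles):
            M = build_matrix(k, inputs)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            # no edge from any recurrence tunnel compartment to 1L mBC
            for j in SPACE.tunnel_states:
                assert M[j, SPACE.met_1l] == 0.0

    def test_remission_progression_value(self):
        # without background mortality the remission row carries the
        # monthly metastatic progression probability 0.0076 exactly
        inputs = make_inputs(q=0.0)
        M = build_matrix(0, inputs)
        assert M[SPACE.remission, SPACE.met_1l] == pytest.approx(0.0076)

    def test_death_absorbing(self):
        M = build_matrix(0, make_inputs())
        expected = np.zeros(len(SPACE))
        expected[SPACE.death] = 1.0
        np.testing.assert_array_equal(M[SPACE.death], expected)

    def test_zero_hazards_give_identity_rows(self):
        inputs = make_inputs(exit_p=0.0, q=0.0, remission_to_1l=0.0,
                             p_1l_to_2l=0.0, p_2l_death=0.0,
                             treatment_cycles=100)
        M = build_matrix(0, inputs)
        for s in (SPACE.residual_on, SPACE.remission, SPACE.met_1l,
                  SPACE.met_2l):
            assert M[s, s] == 1.0

    def test_tunnel_advances_and_exits_to_remission(self):
        M = build_matrix(0, make_inputs(q=0.0))
        for j in range(1, 12):
            assert M[SPACE.tunnel(j), SPACE.tunnel(j + 1)] == 1.0
        assert M[SPACE.tunnel(12), SPACE.remission] == 1.0

    def test_on_to_off_treatment_switch(self):
        inputs = make_inputs(treatment_cycles=10)
        before = build_matrix(0, inputs)
        after = build_matrix(9, inputs)  # cycle 9 -> state at cycle 10
        assert before[SPACE.residual_on, SPACE.residual_on] > 0
        assert after[SPACE.residual_on, SPACE.residual_on] == 0.0
        assert after[SPACE.residual_on, SPACE.residual_off] > 0

    def test_vectorised_sequence_matches_per_cycle(self):
        inputs = make_inputs(seed=17)
        seq = build_matrix_sequence(inputs)
        for k in range(inputs.n_cycles):
            np.testing.assert_array_equal(seq[k], build_matrix(k, inputs))

    def test_bad_shares_rejected(self):
        with pytest.raises(ValueError, match="shares"):
            make_inputs(share_locoregional=0.9)

    def test_combine_competing_validates(self):
        assert combine_competing([0.1, 0.2]) == pytest.approx(1 - 0.9 * 0.8)
        with pytest.raises(ValueError):
            combine_competing([0.5, 1.2])


class TestRunCohort:
    def test_identity_matrices_constant_trace(self):
        M = np.tile(np.eye(3), (10, 1, 1))
        init = np.array([0.5, 0.3, 0.2])
        trace = run_cohort(init, M)
        np.testing.assert_allclose(trace, np.tile(init, (11, 1)))

    def test_two_state_geometric_decay(self):
        p = 0.1
        M = np.tile(np.array([[1 - p, p], [0.0, 1.0]]), (30, 1, 1))
        trace = run_cohort(np.array([1.0, 0.0]), M)
        np.testing.assert_allclose(
            trace[:, 0], (1 - p) ** np.arange(31), atol=1e-12
        )

    def test_conservation_and_monotone_death_full_horizon(self):
        inputs = make_inputs(H=576, seed=3)
        trace = run_cohort(_init(), build_matrix_sequence(inputs))
        np.testing.assert_allclose(trace.sum(axis=1), 1.0, atol=1e-10)
        death = trace[:, SPACE.death]
        assert np.all(np.diff(death) >= -1e-14)
        assert 0.0 <= death[-1] <= 1.0

    def test_dimension_mismatch_rejected(self):
        M = np.tile(np.eye(3), (5, 1, 1))
        with pytest.raises(ValueError):
            run_cohort(np.array([1.0, 0.0]), M)


class TestHalfCycle:
    def test_constant_trace_unchanged(self):
        trace = np.tile([0.6, 0.4], (5, 1))
        np.testing.assert_array_equal(
            half_cycle_effective_occupancy(trace), trace[:-1]
        )

    def test_single_cycle_death_midpoint(self):
        trace = np.array([[1.0, 0.0], [0.0, 1.0]])
        eff = half_cycle_effective_occupancy(trace)
        np.testing.assert_allclose(eff, [[0.5, 0.5]])

    def test_matches_trapezoid_on_geometric_decay(self):
        p = 0.07
        alive = (1 - p) ** np.arange(21)
        trace = np.column_stack([alive, 1 - alive])
        eff = half_cycle_effective_occupancy(trace)
        expected = 0.5 * (alive[:-1] + alive[1:])
        np.testing.assert_allclose(eff[:, 0], expected, atol=1e-15)
        np.testing.assert_allclose(eff.sum(axis=1), 1.0, atol=1e-12)

    def test_disabled_uses_cycle_start(self):
        trace = np.array([[1.0, 0.0], [0.4, 0.6]])
        eff = half_cycle_effective_occupancy(trace, enabled=False)
        np.testing.assert_array_equal(eff, [[1.0, 0.0]])


class TestDiscounting:
    def test_anchor_values(self):
        assert discount_factor(0, 0.05) == 1.0
        assert discount_factor(12, 0.05) == pytest.approx(1 / 1.05, abs=1e-12)
        assert discount_factor(100, 0.0) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)

    def test_discounted_life_expectancy_closed_form(self):
        """Two-state constant-hazard discounted life expectancy matches
        the closed form sum (1-p)^k (1+r)^(-k/12)."""
        p, r, H = 0.02, 0.05, 240
        M = np.tile(np.array([[1 - p, p], [0.0, 1.0]]), (H, 1, 1))
        trace = run_cohort(np.array([1.0, 0.0]), M)
        eff = half_cycle_effective_occupancy(trace, enabled=False)
        df = discount_factors(H, r)
        model_value = float(np.sum(eff[:, 0] * df))
        closed = sum((1 - p) ** k * (1 + r) ** (-k / 12) for k in range(H))
        assert model_value == pytest.approx(closed, abs=1e-9)


class TestMicrosimOracle:
    def test_deterministic_matrix_exact(self):
        M = np.zeros((4, 3, 3))
        M[:, 0, 1] = 1.0
        M[:, 1, 2] = 1.0
        M[:, 2, 2] = 1.0
        init = np.array([1.0, 0.0, 0.0])
        emp = microsim_oracle(init, M, 1000, seed=1)
        np.testing.assert_array_equal(emp, run_cohort(init, M))

    def test_two_state_within_three_binomial_ses(self):
        p, n = 0.1, 50_000
        M = np.tile(np.array([[1 - p, p], [0.0, 1.0]]), (10, 1, 1))
        init = np.array([1.0, 0.0])
        trace = run_cohort(init, M)
        emp = microsim_oracle(init, M, n, seed=0)
        se = np.sqrt(trace * (1 - trace) / n)
        assert np.all(np.abs(emp - trace) <= 3 * se + 1e-12)
        assert emp[10, 0] == pytest.approx(0.9**10, abs=3 * se[10, 0])

    def test_full_state_space_agreement(self):
        """Cohort trace matches the micro-simulation within Monte-Carlo
        error on a randomized instance (3-SE bound per state-cycle, with
        the multiplicity allowance appropriate for hundreds of cells)."""
        inputs = make_inputs(H=24, seed=42)
        M = build_matrix_sequence(inputs)
        n = 50_000
        trace = run_cohort(_init(), M)
        emp = microsim_oracle(_init(), M, n, seed=0)
        se = np.sqrt(trace * (1 - trace) / n)
        z = np.abs(emp - trace) / np.where(se > 0, se, np.inf)
        exact = se == 0
        assert np.array_equal(emp[exact], trace[exact])
        assert (z <= 3.0).mean() >= 0.99
        assert np.all(z <= 4.5)

    def test_seed_determinism_bit_identical(self):
        M = np.tile(np.array([[0.9, 0.1], [0.0, 1.0]]), (10, 1, 1))
        init = np.array([1.0, 0.0])
        a = microsim_oracle(init, M, 5000, seed=7)
        b = microsim_oracle(init, M, 5000, seed=7)
        np.testing.assert_array_equal(a, b)


def _init():
    init = np.zeros(len(SPACE))
    init[SPACE.residual_on] = 1.0
    return init
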