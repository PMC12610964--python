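"""Transition-matrix estimation, renormalization, stationary analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import herdmark as hm


def seq2(labels):
    return hm.StateSequence(list(labels), space=hm.StateSpace(("A", "B")))


class TestSequenceEstimation:
    def test_alternating_sequence_gives_flip_chain(self):
        tm = hm.estimate_from_sequence(seq2("ABABA"))
        assert np.array_equal(tm.probs, [[0, 1], [1, 0]])
        assert tm.source == "sequence-mle"

    def test_dangling_terminal_state_needs_smoothing(self):
        with pytest.raises(ValueError, match="smoothing"):
            hm.estimate_from_sequence(seq2("AAAB"))

    def test_pseudo_count_regularizes_dangling_state(self):
        tm = hm.estimate_from_sequence(seq2("AAAB"), smoothing=1.0)
        assert np.allclose(tm.probs, [[0.6, 0.4], [0.5, 0.5]])

    def test_never_visited_state_gets_uniform_row(self):
        space = hm.StateSpace(("A", "B", "C"))
        tm = hm.estimate_from_sequence(
            hm.StateSequence(list("ABABA"), space=space))
        assert np.allclose(tm.probs[2], 1 / 3)
        assert "uniform" in tm.source

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="length >= 2"):
            hm.estimate_from_sequence(seq2("A"))

    def test_long_simulation_recovers_generator(self, prior_matrix):
        cfg = hm.SimulationConfig(n_iterations=100_000, burn_in=0, seed=21)
        seq = hm.simulate_direct(prior_matrix, cfg).sequence
        est = hm.estimate_from_sequence(seq)
        assert np.max(np.abs(est.probs - prior_matrix.probs)) <= 0.01

    def test_estimator_is_consistent(self, prior_matrix):
        errs = []
        for length in (1_000, 10_000, 100_000):
            cfg = hm.SimulationConfig(n_iterations=length, burn_in=0, seed=42)
            seq = hm.simulate_direct(prior_matrix, cfg).sequence
            est = hm.estimate_from_sequence(seq)
            errs.append(np.max(np.abs(est.probs - prior_matrix.probs)))
        assert errs[0] > errs[1] > errs[2]


class TestCompositionEstimation:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(rows, columns=list(hm.DEFAULT_STATE_SPACE.labels))

    @pytest.mark.parametrize("mode", ["lagged", "co-occurrence"])
    def test_uniform_records_give_uniform_matrix(self, mode):
        tab = self.frame(np.ones((2, 9)))
        tm = hm.estimate_from_compositions(tab, mode=mode)
        assert np.allclose(tm.probs, 1 / 9, atol=1e-12)

    @pytest.mark.parametrize("mode", ["lagged", "co-occurrence"])
    def test_identical_compositions_give_rank_one_rows(self, mode):
        v = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        tab = self.frame(np.tile(v, (5, 1)))
        tm = hm.estimate_from_compositions(tab, mode=mode)
        assert np.allclose(tm.probs, np.tile(v / v.sum(), (9, 1)), atol=1e-12)

    def test_sample_table_yields_stochastic_matrix(self, sample_table):
        tm = hm.estimate_from_compositions(sample_table, mode="lagged")
        assert tm.probs.shape == (9, 9)
        assert np.allclose(tm.probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(tm.probs >= 0)

    def test_all_zero_record_rejected(self):
        rows = np.ones((3, 9))
        rows[1] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            hm.estimate_from_compositions(self.frame(rows))

    def test_behavior_only_table_gives_subchain(self):
        frame = pd.DataFrame(np.ones((3, 6)),
                             columns=list(hm.BEHAVIORAL_STATE_SPACE.labels))
        tm = hm.estimate_from_compositions(frame)
        assert tm.states.labels == hm.BEHAVIORAL_STATE_SPACE.labels


class TestRenormalization:
    def test_simple_counts(self):
        tm = hm.renormalize_rows(np.array([[2.0, 2.0], [1.0, 3.0]]))
        assert np.allclose(tm.probs, [[0.5, 0.5], [0.25, 0.75]])
        assert np.allclose(tm.original_row_sums, [4.0, 4.0])

    def test_stochastic_matrix_unchanged(self):
        P = np.array([[0.3, 0.7], [0.6, 0.4]])
        assert np.allclose(hm.renormalize_rows(P).probs, P, atol=1e-15)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="absorbing-defective"):
            hm.renormalize_rows(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            hm.renormalize_rows(np.array([[-1.0, 2.0], [1.0, 1.0]]))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rows_always_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        M = rng.random((k, k)) + 1e-12
        tm = hm.renormalize_rows(M)
        assert np.allclose(tm.probs.sum(axis=1), 1.0, atol=1e-12)


class TestStationary:
    def test_prior_matrix_reproduces_reference_vector(self, prior_matrix,
                                                      prior_pi_printed):
        pi = hm.stationary_distribution(prior_matrix)
        assert pi["T"] == pytest.approx(0.108, abs=0.005)
        assert pi["L"] == pytest.approx(0.209, abs=0.005)
        assert np.mean(np.abs(pi.pi - prior_pi_printed)) <= 0.003

    def test_periodic_chain_handled_by_both_methods(self, flip_chain):
        for method in ("eigen", "power"):
            pi = hm.stationary_distribution(flip_chain, method=method)
            assert np.allclose(pi.pi, 0.5, atol=1e-9)

    def test_two_state_balance_equation(self):
        tm = hm.TransitionMatrix(np.array([[0.9, 0.1], [0.5, 0.5]]),
                                 states=hm.StateSpace(("A", "B")))
        pi = hm.stationary_distribution(tm)
        assert np.allclose(pi.pi, [5 / 6, 1 / 6], atol=1e-12)

    def test_reducible_chain_rejected(self):
        tm = hm.TransitionMatrix(np.eye(2), states=hm.StateSpace(("A", "B")))
        with pytest.raises(ValueError, match="not unique"):
            hm.stationary_distribution(tm)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_eigen_and_power_agree_on_random_chains(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 10))
        tm = hm.renormalize_rows(rng.random((k, k)) + 1e-3)
        a = hm.stationary_distribution(tm, method="eigen")
        b = hm.stationary_distribution(tm, method="power")
        assert np.max(np.abs(a.pi - b.pi)) < 1e-9

    def test_cumulative_is_monotone_and_ends_at_one(self, prior_matrix):
        pi = hm.stationary_distribution(prior_matrix)
        c = pi.cumulative
        assert np.all(np.diff(c) >= 0)
        assert c[-1] == 1.0
        assert c[0] == pytest.approx(pi.pi[0])


class TestNStep:
    def test_one_step_is_identity_of_the_operation(self, prior_matrix):
        assert np.allclose(hm.n_step_matrix(prior_matrix, 1).probs,
                           prior_matrix.probs, atol=1e-15)

    def test_period_two_chain_squares_to_identity(self, flip_chain):
        assert np.allclose(hm.n_step_matrix(flip_chain, 2).probs, np.eye(2))

    def test_ergodic_convergence_to_stationary_rows(self, prior_matrix):
        pi = hm.stationary_distribution(prior_matrix)
        P64 = hm.n_step_matrix(prior_matrix, 64).probs
        assert np.max(np.abs(P64 - pi.pi[None, :])) < 1e-6

    @pytest.mark.parametrize("n", [1, 2, 5, 17, 64])
    def test_rows_of_powers_remain_stochastic(self, prior_matrix, n):
        Pn = hm.n_step_matrix(prior_matrix, n).probs
        assert np.allclose(Pn.sum(axis=1), 1.0, atol=1e-12)

    def test_nonpositive_power_rejected(self, prior_matrix):
        with pytest.raises(ValueError):
            hm.n_step_matrix(prior_matrix, 0)
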