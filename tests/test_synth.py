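"""Synthetic herd generator: sequences, aggregates, environment, THI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import herdmark as hm


@pytest.fixture(scope="module")
def one_day_spec():
    return hm.HerdSpec(n_cows=1, days=1, seed=5)


class TestTHI:
    def test_humidity_term_vanishes_at_pivot(self):
        assert hm.thi(14.4, 50.0) == pytest.approx(57.92)
        assert hm.thi(14.4, 99.0) == pytest.approx(57.92)

    def test_origin_gives_constant_term(self):
        assert hm.thi(0.0, 0.0) == pytest.approx(46.4)

    def test_hot_humid_day(self):
        assert hm.thi(31.2, 88.7) == pytest.approx(86.2616, abs=1e-4)

    def test_humidity_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            hm.thi(25.0, 120.0)

    def test_vectorized(self):
        out = hm.thi([0.0, 14.4], [0.0, 50.0])
        assert np.allclose(out, [46.4, 57.92])


class TestSequences:
    def test_one_day_minute_resolution_length(self, one_day_spec):
        seq = hm.generate_cow_sequence(one_day_spec, 0)
        assert len(seq) == 1440
        assert set(seq.states) <= set(hm.BEHAVIORAL_STATE_SPACE.labels)

    def test_absorbing_state_pins_sequence(self):
        P = np.full((6, 6), 0.2)
        np.fill_diagonal(P, 0.0)
        P[2] = 0.0
        P[2, 2] = 1.0  # L absorbs
        gt = hm.renormalize_rows(P, states=hm.BEHAVIORAL_STATE_SPACE)
        spec = hm.HerdSpec(n_cows=1, days=1, ground_truth=gt,
                           initial_state="L", seed=0)
        seq = hm.generate_cow_sequence(spec, 0)
        assert set(seq.states) == {"L"}

    def test_per_cow_seeding_is_deterministic(self):
        spec = hm.HerdSpec(n_cows=2, days=1, seed=11)
        a = hm.generate_cow_sequence(spec, 0)
        b = hm.generate_cow_sequence(spec, 1)
        again = hm.generate_cow_sequence(spec, 0)
        assert a.states == again.states
        assert a.states != b.states

    def test_sequence_recovers_subchain(self):
        spec = hm.HerdSpec(n_cows=1, days=30, seed=3)
        seq = hm.generate_cow_sequence(spec, 0)
        est = hm.estimate_from_sequence(seq)
        sub = spec.behavioral_chain()
        assert np.max(np.abs(est.probs - sub.probs)) <= 0.02


class TestAggregation:
    def test_all_lying_day(self):
        seq = hm.StateSequence(["L"] * 1440, space=hm.BEHAVIORAL_STATE_SPACE)
        table = hm.aggregate_sequence(seq, 1440)
        rec = table.records[0]
        assert rec.durations == (0, 0, 1440, 0, 0, 0)

    def test_alternating_feed_move_day(self):
        seq = hm.StateSequence(["F", "M"] * 720,
                               space=hm.BEHAVIORAL_STATE_SPACE)
        rec = hm.aggregate_sequence(seq, 1440).records[0]
        assert (rec.F, rec.M) == (720, 720)
        assert rec.L == rec.S == rec.RS == rec.RL == 0

    def test_fifteen_minute_intervals(self, one_day_spec):
        seq = hm.generate_cow_sequence(one_day_spec, 0)
        table = hm.aggregate_sequence(seq, 15)
        assert len(table) == 96
        assert hm.validate_activity_table(table).ok

    def test_non_divisible_length_rejected(self):
        seq = hm.StateSequence(["L"] * 100, space=hm.BEHAVIORAL_STATE_SPACE)
        with pytest.raises(ValueError, match="divisible"):
            hm.aggregate_sequence(seq, 1440)

    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.sampled_from([15, 1440]))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_aggregates_always_validate(self, seed, interval):
        spec = hm.HerdSpec(n_cows=1, days=1, seed=seed)
        seq = hm.generate_cow_sequence(spec, 0)
        table = hm.aggregate_sequence(seq, interval)
        assert hm.validate_activity_table(table).ok


class TestEnvironment:
    def test_zero_spread_is_constant(self):
        spec = hm.HerdSpec(temp_sd=0.0, hum_sd=0.0, days=10, seed=1)
        env = hm.generate_environment(spec)
        assert np.allclose(env["T"], spec.temp_mean)
        assert np.allclose(env["H"], spec.hum_mean)

    def test_defaults_match_hot_season_ranges(self):
        spec = hm.HerdSpec(days=1000, seed=2)
        env = hm.generate_environment(spec)
        assert np.mean((env["T"] >= 29) & (env["T"] <= 33)) > 0.85
        assert np.mean((env["H"] >= 70) & (env["H"] <= 89)) > 0.85
        assert env["H"].between(0, 100).all()

    def test_thi_column_derived_from_same_row(self):
        spec = hm.HerdSpec(days=50, seed=3)
        env = hm.generate_environment(spec)
        assert np.allclose(env["THI"], hm.thi(env["T"], env["H"]))

    def test_day_to_day_autocorrelation_present(self):
        spec = hm.HerdSpec(days=2000, seed=4, env_autocorr=0.5)
        t = hm.generate_environment(spec)["T"].to_numpy()
        r1 = np.corrcoef(t[:-1], t[1:])[0, 1]
        assert 0.3 < r1 < 0.7


class TestFullPipeline:
    def test_roundtrip_recovers_subchain_stationary(self):
        """generate -> aggregate -> estimate -> stationary stays within
        AAE 0.02 of the ground-truth behavioral stationary vector."""
        spec = hm.HerdSpec(n_cows=1, days=30, seed=3)
        pi_true = hm.stationary_distribution(spec.behavioral_chain())
        seq = hm.generate_cow_sequence(spec, 0)
        table = hm.aggregate_sequence(seq, 15)
        est = hm.estimate_from_compositions(table, mode="lagged")
        pi_est = hm.stationary_distribution(est)
        assert np.mean(np.abs(pi_est.pi - pi_true.pi)) <= 0.02

    def test_generate_herd_full_schema(self):
        spec = hm.HerdSpec(n_cows=3, days=5, seed=8)
        herd = hm.generate_herd(spec)
        assert len(herd) == 3
        for cow_id, (seq, table) in herd.items():
            assert len(seq) == 5 * 1440
            assert len(table) == 5
            assert table.has_environment
            assert hm.validate_activity_table(table).ok

    def test_whole_generator_is_seed_deterministic(self):
        a = hm.generate_herd(hm.HerdSpec(n_cows=2, days=2, seed=7))
        b = hm.generate_herd(hm.HerdSpec(n_cows=2, days=2, seed=7))
        for cow in a:
            assert a[cow][0].states == b[cow][0].states
            assert a[cow][1].to_frame().equals(b[cow][1].to_frame())
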