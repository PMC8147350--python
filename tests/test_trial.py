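"""Tests of the defensive-event model: percept encoding, encounter sampling,
the sequential trial, kill accounting and the reward."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import stingsim as ss
from stingsim.trial import ConfigError

from conftest import make_forced_memory


class TestPerceptEncoder:
    def test_zero_concentration_is_percept_zero(self, encoder):
        assert encoder.encode(0) == 0

    def test_vision_overrides_olfaction(self, encoder):
        for c in (0, 1, 50, 100):
            assert encoder.encode(c, v_esc_active=True) == encoder.v_esc_index

    def test_log_binning_resolution(self, encoder):
        # fine at low concentrations, coarse at high ones
        assert encoder.bin_of(1) != encoder.bin_of(2)
        assert encoder.bin_of(64) == encoder.bin_of(100)

    def test_negative_concentration_rejected(self, encoder):
        with pytest.raises(ConfigError):
            encoder.bin_of(-1)

    @given(c=st.integers(min_value=0, max_value=500))
    def test_bins_monotone_and_total(self, c):
        enc = ss.PerceptEncoder()
        b = enc.bin_of(c)
        assert 0 <= b < enc.n_pheromone_bins
        if c > 0:
            assert enc.bin_of(c - 1) <= b

    def test_upper_edges(self, encoder):
        edges = encoder.bin_upper_edges(100)
        assert edges[0] == 0 and edges[1] == 1 and edges[2] == 3
        assert edges[-1] == 100  # top bin truncated at colony size


class TestSampleEncounter:
    def test_certain_false_alarm(self, rng):
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(16, 40), r_f=1.0)
        assert all(ss.sample_encounter(prof, rng) == 0 for _ in range(100))

    def test_uniform_range_chi_square(self, rng):
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(16, 40))
        draws = ss.sample_encounters(prof, rng, 100_000)
        counts = np.bincount(draws, minlength=41)[16:41]
        assert counts.sum() == 100_000
        res = stats.chisquare(counts)
        assert res.pvalue > 1e-4  # consistent with the uniform law

    def test_nonuniform_category_frequencies(self, rng):
        # weak predators appear four times as often as strong ones
        dist = ss.SthDistribution.mixture([((16, 26), 0.8), ((27, 40), 0.2)])
        prof = ss.PredatorProfile(dist)
        draws = ss.sample_encounters(prof, rng, 100_000)
        weak = np.mean(draws <= 26)
        assert weak == pytest.approx(0.8, abs=0.01)
        assert draws.min() >= 16 and draws.max() <= 40

    def test_false_alarm_rate_mixes_in(self, rng):
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(16, 40), r_f=0.3)
        draws = ss.sample_encounters(prof, rng, 100_000)
        assert np.mean(draws == 0) == pytest.approx(0.3, abs=0.01)

    def test_empty_range_rejected(self):
        with pytest.raises(ConfigError):
            ss.SthDistribution.uniform(10, 5)
        with pytest.raises(ConfigError):
            ss.SthDistribution(ranges=(), weights=())


class TestRunTrial:
    def test_hand_trace(self, encoder, rng):
        # forced stinging, s_th=3: stings at steps 0-2, kills at steps 0-2,
        # escape percept suppresses everything from step 3 on
        mem = make_forced_memory(p_pheromone=1.0, p_v_esc=0.0)
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(3, 3), k=1, t_att=0, dt_v=0)
        out = ss.run_trial(mem, encoder, prof, 3, rng, n_bees=10)
        assert (out.s, out.q, out.a) == (3, 3, 4)
        assert ss.reward_of(out, 10) == pytest.approx(0.4)

    def test_nobody_defends(self, encoder, rng):
        mem = make_forced_memory(p_pheromone=0.0, p_v_esc=0.0)
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(5, 5), k=1, t_att=0)
        out = ss.run_trial(mem, encoder, prof, 5, rng, n_bees=10)
        assert (out.s, out.q, out.a) == (0, 10, 0)
        assert out.t_stop == 10

    def test_false_alarm_has_no_kills_and_late_escape_percept(self, encoder, rng):
        mem = ss.Memory.initial(10)
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(16, 40), dt_v=10, r_f=1.0)
        out = ss.run_trial(mem, encoder, prof, 0, rng, n_bees=100, record_trace=True)
        assert out.q == 0 and out.t_stop == 0
        for step in out.trace:
            assert step.v_esc == (step.step >= 10)

    def test_determinism_under_seeding(self, encoder):
        mem = ss.Memory.initial(10)
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(16, 40))
        outs = [
            ss.run_trial(mem, encoder, prof, 20, np.random.default_rng(99), n_bees=100)
            for _ in range(2)
        ]
        assert outs[0].s == outs[1].s and outs[0].q == outs[1].q
        np.testing.assert_array_equal(outs[0].glow.g, outs[1].glow.g)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_glow_sums_to_colony_size_and_conservation(self, encoder, seed):
        rng = np.random.default_rng(seed)
        mem = ss.Memory.initial(10)
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(5, 30), k=2, t_att=3, dt_v=5)
        for s_th in (0, 5, 17, 30, 200):
            out = ss.run_trial(mem, encoder, prof, s_th, rng, n_bees=100)
            assert out.glow.total() == 100
            assert out.a >= 0
            assert out.s + out.q + out.a == 100  # q is capped so this always holds

    def test_deterrence_monotone_in_resistance(self, encoder, rng):
        # everyone stings: a tougher predator keeps killing for longer
        mem = make_forced_memory(p_pheromone=1.0, p_v_esc=1.0)
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(1, 99), k=1, t_att=0, dt_v=0)
        q_prev = -1
        for s_th in range(1, 60, 5):
            out = ss.run_trial(mem, encoder, prof, s_th, rng, n_bees=100)
            assert out.q >= q_prev
            q_prev = out.q

    def test_escape_percept_timing(self, encoder, rng):
        mem = ss.Memory.initial(10)
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(10, 10), dt_v=7)
        out = ss.run_trial(mem, encoder, prof, 10, rng, n_bees=100, record_trace=True)
        for step in out.trace:
            if step.step < out.t_stop + 7:
                assert not step.v_esc
        assert any(s.v_esc for s in out.trace if s.step >= out.t_stop + 7)

    def test_infinite_visibility_delay_disables_escape_percept(self, encoder, rng):
        mem = ss.Memory.initial(10)
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(5, 5), dt_v=math.inf)
        out = ss.run_trial(mem, encoder, prof, 5, rng, n_bees=100, record_trace=True)
        assert not any(step.v_esc for step in out.trace)

    def test_threshold_reached_before_attack_means_no_kills(self, encoder, rng):
        mem = make_forced_memory(p_pheromone=1.0, p_v_esc=0.0)
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(3, 3), k=5, t_att=50, dt_v=0)
        out = ss.run_trial(mem, encoder, prof, 3, rng, n_bees=100)
        assert out.q == 0

    def test_memory_is_not_modified(self, encoder, rng):
        mem = ss.Memory.initial(10)
        before = mem.h.copy()
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(16, 40))
        ss.run_trial(mem, encoder, prof, 20, rng, n_bees=100)
        np.testing.assert_array_equal(mem.h, before)


def exact_expected_reward(memory, encoder, n, s_th, k, t_att, dt_v):
    """Independent oracle: enumerate all 2^n action sequences, replaying the
    percept/threshold/kill rules step by step, and sum probability * reward."""
    p = memory.p_sting()
    total = 0.0
    for bits in range(2**n):
        actions = [(bits >> t) & 1 for t in range(n)]
        prob, s, t_stop = 1.0, 0, None
        for t, act in enumerate(actions):
            if t_stop is None and s >= s_th:
                t_stop = t
            if t_stop is not None and t - t_stop >= dt_v:
                percept = encoder.v_esc_index
            else:
                percept = encoder.bin_of(s)
            prob *= p[percept] if act else 1.0 - p[percept]
            s += act
        if t_stop is None:
            t_stop = n
        q = min(k * max(0, min(t_stop, n) - t_att), n - s)
        total += prob * (n - s - q) / n
    return total


@pytest.mark.parametrize(
    "n, s_th, k, t_att, dt_v",
    [(6, 3, 1, 1, 1), (5, 2, 2, 0, 0), (6, 7, 1, 0, 2)],
)
def test_monte_carlo_matches_exact_enumeration(n, s_th, k, t_att, dt_v):
    """Simulated mean reward agrees with the closed-form expectation from
    full enumeration, within 3 standard errors at 1e5 trials."""
    mem = make_forced_memory(p_pheromone=0.3, p_v_esc=0.2)
    enc = ss.PerceptEncoder()
    prof = ss.PredatorProfile(
        ss.SthDistribution.uniform(max(s_th, 1), max(s_th, 1)),
        k=k, t_att=t_att, dt_v=dt_v,
    )
    exact = exact_expected_reward(mem, enc, n, s_th, k, t_att, dt_v)
    rng = np.random.default_rng(2024)
    rewards = np.array(
        [ss.run_trial(mem, enc, prof, s_th, rng, n_bees=n).reward for _ in range(100_000)]
    )
    se = rewards.std(ddof=1) / np.sqrt(len(rewards))
    assert abs(rewards.mean() - exact) < 3 * se + 1e-12


class TestReward:
    def test_bounds(self, encoder, rng):
        prof = ss.PredatorProfile(ss.SthDistribution.uniform(1, 1), k=0)
        mem = make_forced_memory(p_pheromone=0.0, p_v_esc=0.0)
        out = ss.run_trial(mem, encoder, prof, 1, rng, n_bees=10)
        assert ss.reward_of(out, 10) == 1.0  # nobody dies with a harmless predator
        mem = make_forced_memory(p_pheromone=1.0, p_v_esc=1.0)
        out = ss.run_trial(mem, encoder, prof, 100, rng, n_bees=10)
        assert ss.reward_of(out, 10) == 0.0  # everyone stings and dies
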