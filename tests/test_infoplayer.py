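import hashlib
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ipdpop.games import Move, Outcome, donation_matrix
from ipdpop.infoplayer import (
    IPConfig,
    OpponentModel,
    OutcomeCounts,
    classify_infogain,
    estimate_m_bar,
    groupmax_objective,
    groupmax_optimize,
    hmm_update,
    infogain_move,
    md5_tiebreak,
    new_player_prior,
    posterior_mean,
    update_log_odds,
)
from ipdpop.memory_one import ALLC, ALLD, TFT, WSLS

MATRIX = donation_matrix(3, 1)


class TestPosteriorMean:
    @pytest.mark.parametrize("n,m,want", [(0, 0, 0.5), (8, 6, 0.7), (10, 10, 11 / 12)])
    def test_examples(self, n, m, want):
        assert posterior_mean(n, m) == pytest.approx(want)

    def test_rejects_m_above_n(self):
        with pytest.raises(ValueError):
            posterior_mean(3, 4)


class TestMD5Tiebreak:
    def test_empty_history_cooperates(self):
        # digest d41d8cd98f00b204e9800998ecf8427e ends in 0x7e, LSB 0
        assert md5_tiebreak("") == Move.C

    @given(st.text(alphabet="CD", max_size=20))
    @settings(max_examples=80, deadline=None)
    def test_bit_rule_and_determinism(self, hist):
        got = md5_tiebreak(hist)
        assert got == md5_tiebreak(hist)
        bit = hashlib.md5(hist.encode()).digest()[-1] & 1
        assert got == (Move.C if bit == 0 else Move.D)


class TestInfogainMove:
    def test_round_one_tie_resolved_by_md5(self):
        assert infogain_move(OutcomeCounts(), None, "") == md5_tiebreak("")

    def test_steers_toward_unseen_outcomes(self):
        # all observations are CC with the opponent always cooperating next:
        # cooperating again would revisit CC (expected count 30/7), while
        # defecting steers toward the unexplored DC/DD rows
        counts = OutcomeCounts(n=[5, 0, 0, 0], m=[5, 0, 0, 0])
        assert infogain_move(counts, int(Outcome.CC)) == Move.D

    @given(
        n=st.lists(st.integers(0, 30), min_size=4, max_size=4),
        extra=st.lists(st.integers(0, 1), min_size=4, max_size=4),
        last=st.sampled_from([None, 0, 1, 2, 3]),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_expectation(self, n, extra, last):
        m = [min(a, b) for a, b in zip(n, extra)]  # m <= n
        counts = OutcomeCounts(n=n, m=m)
        got = infogain_move(counts, last, "CC")
        pc = 0.5 if last is None else (m[last] + 1) / (n[last] + 2)
        e_c = pc * n[0] + (1 - pc) * n[1]
        e_d = pc * n[2] + (1 - pc) * n[3]
        if abs(e_c - e_d) > 1e-12:
            assert got == (Move.C if e_c < e_d else Move.D)
        else:
            assert got == md5_tiebreak("CC")


class TestClassifyInfogain:
    def test_examples(self):
        p, conf = classify_infogain(10, 0, 0.05)
        assert (p, conf) == (1.0, False)
        p, conf = classify_infogain(10, 3, 0.05)
        assert p == pytest.approx(0.0115, abs=2e-4)
        assert not conf
        p, conf = classify_infogain(5, 1, 0.0)
        assert (p, conf) == (0.0, True)

    @pytest.mark.parametrize("n,e,eps", [(10, 3, 0.05), (20, 5, 0.1), (7, 7, 0.3)])
    def test_matches_scipy_tail(self, n, e, eps):
        p, _ = classify_infogain(n, e, eps)
        assert p == pytest.approx(float(stats.binom.sf(e - 1, n, eps)), abs=1e-12)

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            classify_infogain(3, 4, 0.05)


class TestLogOddsAndHMM:
    def test_uninformative_update_is_identity(self):
        assert update_log_odds(1.23, 0.4, 0.4) == pytest.approx(1.23)

    def test_matching_infogain_move_update(self):
        assert update_log_odds(0.0, 0.95, 0.5) == pytest.approx(math.log(0.95 / 0.5))

    def test_clamped_against_zero_probability(self):
        assert np.isfinite(update_log_odds(0.0, 0.0, 1.0))

    def test_hmm_absorbing_consistent_state(self):
        post, lik = hmm_update(1.0, Move.C, 0.1, 0.0, switch=0.0)
        assert post == pytest.approx(1.0)
        assert lik == pytest.approx(1.0)

    def test_hmm_uninformative_emission(self):
        post, _ = hmm_update(0.5, Move.C, 1.0, 0.0, switch=0.0)
        assert post == pytest.approx(0.5)

    def test_hmm_defection_pushes_toward_groupmax_state(self):
        post, _ = hmm_update(0.5, Move.D, 0.1, 0.05, switch=0.01)
        assert post < 0.15

    @given(
        a=st.floats(0.01, 0.99), pg=st.floats(0.0, 1.0),
        eps=st.floats(0.0, 0.4), obs=st.sampled_from([Move.C, Move.D]),
    )
    @settings(max_examples=80, deadline=None)
    def test_hmm_matches_generic_forward_step(self, a, pg, eps, obs):
        """Cross-check against an explicit two-state forward recursion."""
        switch = 0.01
        T = np.array([[1 - switch, switch], [switch, 1 - switch]])
        em_c = np.array([1 - eps, (1 - 2 * eps) * pg + eps])
        em = em_c if obs == Move.C else 1 - em_c
        prior = np.array([a, 1 - a]) @ T
        post = prior * em
        post_allc, lik = hmm_update(a, obs, pg, eps, switch)
        assert lik == pytest.approx(post.sum(), abs=1e-12)
        if post.sum() > 0:
            assert post_allc == pytest.approx(post[0] / post.sum(), abs=1e-12)


class TestPopulationEstimates:
    def test_m_bar_examples(self):
        assert estimate_m_bar([-1e9] * 99) == pytest.approx(1.0)
        assert estimate_m_bar([1e9] * 99) == pytest.approx(100.0)
        assert estimate_m_bar([0.0] * 99) == pytest.approx(50.5)

    @given(st.floats(-30, 30), st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_m_bar_monotone(self, L, dL):
        assert estimate_m_bar([L + dL, 0.0]) > estimate_m_bar([L, 0.0])

    def test_new_player_prior(self):
        assert new_player_prior(100, 100) == pytest.approx(0.0)
        assert new_player_prior(1, 100) == pytest.approx(math.log(0.01))
        with pytest.raises(ValueError):
            new_player_prior(0, 100)


class TestGroupmaxOptimize:
    def test_defects_on_unconditional_cooperators(self):
        q = groupmax_optimize(ALLC, 1.0, 100, MATRIX, 0.05, use_cache=False)
        assert np.max(np.abs(np.asarray(q) - np.asarray(ALLD))) < 0.05

    def test_never_below_named_corner_strategies(self):
        pbar = (0.9, 0.65, 0.25, 0.0)
        q = groupmax_optimize(pbar, 5.0, 100, MATRIX, 0.05, use_cache=False)
        val = groupmax_objective(q, pbar, 5.0, 100, MATRIX, 0.05)
        for corner in (ALLC, ALLD, TFT, WSLS, pbar):
            cc = np.clip(corner, 1e-3, 1 - 1e-3)
            assert val >= groupmax_objective(cc, pbar, 5.0, 100, MATRIX, 0.05) - 1e-9

    def test_matches_grid_oracle_vs_tft_majority(self):
        """Objective within 1e-3 of an exhaustive 0.05-resolution grid scan
        refined around the incumbent optimum."""
        pbar, mbar = TFT, 99.0
        q = groupmax_optimize(pbar, mbar, 100, MATRIX, 0.05, use_cache=False)
        val = groupmax_objective(q, pbar, mbar, 100, MATRIX, 0.05)
        grid = np.arange(0.0, 1.0001, 0.1)
        best = -np.inf
        arg = None
        for a in grid:
            for b in grid:
                for c in grid:
                    for d in grid:
                        cand = np.clip([a, b, c, d], 1e-3, 1 - 1e-3)
                        v = groupmax_objective(cand, pbar, mbar, 100, MATRIX, 0.05)
                        if v > best:
                            best, arg = v, cand
        fine = np.arange(-0.05, 0.0501, 0.05)
        for da in fine:
            for db in fine:
                for dc in fine:
                    for dd in fine:
                        cand = np.clip(arg + np.array([da, db, dc, dd]), 1e-3, 1 - 1e-3)
                        best = max(best, groupmax_objective(cand, pbar, mbar, 100, MATRIX, 0.05))
        assert val >= best - 1e-3


class TestSelfRecognition:
    def test_self_play_closure_noise_free(self):
        """Two IP0s at eps=0 predict each other's infogain moves exactly."""
        cfg = IPConfig(epsilon=0.0, N=2)
        a = OpponentModel(prior_L=math.log(0.5))
        b = OpponentModel(prior_L=math.log(0.5))
        rng = np.random.default_rng(0)
        for _ in range(10):
            ma = int(a.choose(cfg, None, rng))
            mb = int(b.choose(cfg, None, rng))
            a.observe(ma, mb, cfg)
            b.observe(mb, ma, cfg)
        assert a.e == 0 and b.e == 0
        assert a.L > 0 and b.L > 0
        assert not a.confident_gp and not b.confident_gp

    def test_first_deviation_exposes_at_zero_noise(self):
        cfg = IPConfig(epsilon=0.0, N=100)
        model = OpponentModel()
        rng = np.random.default_rng(0)
        my = int(model.choose(cfg, None, rng))
        pred = int(infogain_move(model.mirror, None, ""))
        model.observe(my, 1 - pred, cfg)  # opponent deviates on round one
        assert model.p_value == 0.0
        assert model.confident_gp

    def test_groupmax_phase_choices(self):
        cfg = IPConfig(epsilon=0.05, N=100)
        rng = np.random.default_rng(1)
        model = OpponentModel(prior_L=5.0)
        model.rounds = cfg.infogain_length
        model.last_outcome = int(Outcome.DD)
        assert model.choose(cfg, (0.0, 0.0, 0.0, 0.0), rng) == Move.C  # L > 0
        model.L = -5.0
        assert model.choose(cfg, (1.0, 1.0, 1.0, 0.0), rng) == Move.D  # p4 = 0
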