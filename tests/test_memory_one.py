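import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipdpop.games import donation_matrix
from ipdpop.memory_one import (
    ALLC,
    ALLD,
    REPEAT,
    TFT,
    DegenerateChainError,
    StrategyVector,
    ZDParams,
    effective_vector,
    press_dyson_score,
    simulate_matches,
    stationary_scores,
    transition_matrix,
    zd_strategy,
)

MATRIX = donation_matrix(3, 1)


def eig_stationary(p, q):
    """Independent oracle: stationary distribution via eigendecomposition."""
    t = transition_matrix(p, q)
    w, v = np.linalg.eig(t.T)
    i = np.argmin(np.abs(w - 1.0))
    s = np.real(v[:, i])
    return s / s.sum()


class TestZDConstruction:
    @pytest.mark.parametrize(
        "kappa,expected",
        [
            (2.0, (1.0, 0.75, 0.35, 0.1)),
            (0.0, (0.9, 0.65, 0.25, 0.0)),
        ],
    )
    def test_printed_parameterisations(self, kappa, expected):
        vec = zd_strategy(ZDParams(kappa, 0.5, 0.1), MATRIX)
        assert np.allclose(vec, expected)

    def test_phi_zero_collapses_to_repeat(self):
        assert np.allclose(zd_strategy(ZDParams(2.0, 0.5, 0.0), MATRIX), REPEAT)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            zd_strategy(ZDParams(kappa=0.0, chi=0.5, phi=1.0), MATRIX)

    @pytest.mark.parametrize("kappa", [2.0, 0.0])
    def test_enforced_score_relation(self, kappa, rng):
        """s_opp - kappa = chi * (s_zd - kappa) against random opponents."""
        zd = zd_strategy(ZDParams(kappa, 0.5, 0.1), MATRIX)
        for _ in range(100):
            q = rng.uniform(0.05, 0.95, 4)
            r = stationary_scores(zd, q, MATRIX, 0.0)
            assert abs((r.score_opp - kappa) - 0.5 * (r.score_focal - kappa)) < 1e-8


class TestEffectiveVector:
    def test_examples(self):
        assert effective_vector(ALLC, 0.0) == ALLC
        assert np.allclose(effective_vector(ALLC, 0.05), [0.95] * 4)
        half = StrategyVector(0.5, 0.5, 0.5, 0.5)
        assert np.allclose(effective_vector(half, 0.3), half)


class TestTransitionMatrix:
    def test_pure_strategies(self):
        assert np.allclose(transition_matrix(ALLC, ALLC), np.tile([1, 0, 0, 0], (4, 1)))
        assert np.allclose(transition_matrix(ALLD, ALLC), np.tile([0, 0, 1, 0], (4, 1)))

    @given(st.lists(st.floats(0, 1), min_size=8, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_rows_sum_to_one(self, vals):
        t = transition_matrix(vals[:4], vals[4:])
        assert np.allclose(t.sum(axis=1), 1.0, atol=1e-12)

    def test_opponent_conditioning_is_perspective_swapped(self):
        # focal sees CD; opponent saw DC and plays its q3 component
        q = (0.1, 0.2, 0.9, 0.4)
        t = transition_matrix(ALLC, q)
        assert np.isclose(t[1, 0], 0.9)  # P(next CC | CD) = 1 * q3


class TestPressDyson:
    def test_normalisation(self):
        p = effective_vector(ALLC, 0.05)
        assert press_dyson_score(p, p, np.ones(4)) == pytest.approx(1.0)

    def test_matches_eigenvector_oracle(self, rng):
        for _ in range(200):
            p = rng.uniform(0.02, 0.98, 4)
            q = rng.uniform(0.02, 0.98, 4)
            f = rng.normal(size=4)
            assert press_dyson_score(p, q, f) == pytest.approx(
                float(eig_stationary(p, q) @ f), abs=1e-8
            )

    def test_degenerate_chain_raises(self):
        # noise-free TFT vs TFT has a 2-cycle and several stationary
        # distributions, so the denominator determinant vanishes
        with pytest.raises(DegenerateChainError):
            press_dyson_score(TFT, TFT, np.ones(4))


class TestStationaryScores:
    def test_absorbing_pairs_via_fallback(self):
        r = stationary_scores(ALLC, ALLC, MATRIX, 0.0)
        assert (r.score_focal, r.score_opp) == pytest.approx((2.0, 2.0))
        r = stationary_scores(ALLD, ALLC, MATRIX, 0.0)
        assert (r.score_focal, r.score_opp) == pytest.approx((3.0, -1.0))

    def test_distribution_properties(self, rng):
        p = rng.uniform(0, 1, 4)
        q = rng.uniform(0, 1, 4)
        r = stationary_scores(p, q, MATRIX, 0.05)
        assert np.all(r.dist >= 0)
        assert r.dist.sum() == pytest.approx(1.0, abs=1e-9)
        assert r.score_focal == pytest.approx(float(r.dist @ MATRIX.focal_payoffs))

    def test_perspective_consistency(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, 4)
            q = rng.uniform(0, 1, 4)
            a = stationary_scores(p, q, MATRIX, 0.05)
            b = stationary_scores(q, p, MATRIX, 0.05)
            assert a.score_focal == pytest.approx(b.score_opp, abs=1e-10)

    def test_noisy_tft_self_play_degrades(self):
        r = stationary_scores(TFT, TFT, MATRIX, 0.05)
        assert r.score_focal == pytest.approx(r.score_opp, abs=1e-10)
        assert r.score_focal < 2.0

    def test_matches_long_simulated_matches(self, rng):
        """Determinant scores agree with 10^5-round noisy matches (3 SE)."""
        n_pairs = 20
        ps = rng.uniform(0.05, 0.95, (n_pairs, 4))
        qs = rng.uniform(0.05, 0.95, (n_pairs, 4))
        rounds = 100_000
        sim_f, sim_o = simulate_matches(ps, qs, MATRIX, 0.05, rounds, rng)
        # conservative per-round payoff sd ~ 1.5; matches are autocorrelated,
        # so inflate the independent-rounds SE by a generous factor
        se = 3 * 1.5 / np.sqrt(rounds) * 3
        for k in range(n_pairs):
            r = stationary_scores(ps[k], qs[k], MATRIX, 0.05)
            assert abs(r.score_focal - sim_f[k]) < se
            assert abs(r.score_opp - sim_o[k]) < se
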