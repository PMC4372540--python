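"""Memory-one strategy algebra: ZD construction and stationary scores.

A memory-one strategy is a vector ``p = (p1, p2, p3, p4)`` of cooperation
probabilities conditioned on the previous joint outcome ``(CC, CD, DC,
DD)``, read from the player's own perspective. A match between two
memory-one players is a Markov chain on the four outcomes; its stationary
mean of any per-outcome quantity ``f`` is computed here through the
Press-Dyson determinant identity

    <f> = D(p, q, f) / D(p, q, 1)

with an eigenvector/power-iteration fallback for the (measure-zero,
noise-free) degenerate chains where the denominator vanishes.

Zero-determinant (ZD) strategies are built from ``(kappa, chi, phi)`` so
that, against any ergodic opponent at zero noise, the opponent's score
``s_q`` is pinned to the line ``s_q - kappa = chi * (s_p - kappa)``.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .games import SWAP, GameMatrix

__all__ = [
    "StrategyVector",
    "ZDParams",
    "StationaryResult",
    "DegenerateChainError",
    "ALLC",
    "ALLD",
    "TFT",
    "WSLS",
    "REPEAT",
    "zd_strategy",
    "zdr_strategy",
    "zd_chi_strategy",
    "effective_vector",
    "transition_matrix",
    "press_dyson_score",
    "stationary_scores",
    "simulate_matches",
]


class StrategyVector(NamedTuple):
    """Cooperation probabilities after outcomes CC, CD, DC, DD."""

    p_cc: float
    p_cd: float
    p_dc: float
    p_dd: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    def validate(self) -> "StrategyVector":
        if any(not (0.0 <= x <= 1.0) for x in self):
            raise ValueError(f"strategy components outside [0,1]: {tuple(self)}")
        return self


ALLC = StrategyVector(1.0, 1.0, 1.0, 1.0)
ALLD = StrategyVector(0.0, 0.0, 0.0, 0.0)
TFT = StrategyVector(1.0, 0.0, 1.0, 0.0)
WSLS = StrategyVector(1.0, 0.0, 0.0, 1.0)
#: Repeat-own-last-move; the phi=0 limit of the ZD family.
REPEAT = StrategyVector(1.0, 1.0, 0.0, 0.0)


class ZDParams(NamedTuple):
    """Zero-determinant parameters.

    ``kappa`` is the baseline score the strategy pins (``kappa = R`` gives a
    generous/robust strategy, ``kappa = P`` an extortionate one), ``chi`` in
    ``(0, 1]`` the slope of the enforced score line, and ``phi > 0`` an
    overall scale that must be small enough for the construction to yield
    probabilities.
    """

    kappa: float
    chi: float
    phi: float


class DegenerateChainError(ValueError):
    """The pair Markov chain is not ergodic (vanishing denominator)."""


def zd_strategy(params: ZDParams, matrix: GameMatrix) -> StrategyVector:
    """Construct the memory-one vector of a ZD strategy.

    ``p = (1,1,0,0) + phi * [chi * (Sx - kappa) - (Sy - kappa)]`` with
    ``Sx = (R,S,T,P)`` the focal and ``Sy = (R,T,S,P)`` the opponent
    payoff vectors. Raises ``ValueError`` when the parameters do not give
    a valid probability vector.

    With this sign convention the strategy enforces, at zero noise against
    any ergodic opponent, ``s_opp - kappa = chi * (s_zd - kappa)``.
    """
    kappa, chi, phi = params
    sx = matrix.focal_payoffs
    sy = matrix.opponent_payoffs
    p = np.array([1.0, 1.0, 0.0, 0.0]) + phi * (chi * (sx - kappa) - (sy - kappa))
    # tolerate float dust at the corners
    p[np.abs(p) < 1e-12] = 0.0
    p[np.abs(p - 1.0) < 1e-12] = 1.0
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError(
            f"ZD parameters {params} give non-probability vector {tuple(p)}"
        )
    return StrategyVector(*p)


def zdr_strategy(matrix: GameMatrix, chi: float = 0.5, phi: float = 0.1) -> StrategyVector:
    """The generous ("robust") ZD strategy: ``kappa = R``."""
    return zd_strategy(ZDParams(kappa=matrix.R, chi=chi, phi=phi), matrix)


def zd_chi_strategy(matrix: GameMatrix, chi: float = 0.5, phi: float = 0.1) -> StrategyVector:
    """The extortionate ZD strategy: ``kappa = P``."""
    return zd_strategy(ZDParams(kappa=matrix.P, chi=chi, phi=phi), matrix)


def effective_vector(p: Sequence[float], epsilon: float) -> StrategyVector:
    """Noise-adjusted cooperation probabilities ``(1 - 2 eps) p + eps``.

    When each realised move flips independently with probability
    ``epsilon``, a memory-one player intending ``p`` plays, in
    distribution, the memory-one strategy returned here; all stationary
    quantities "under noise" are computed on effective vectors.
    """
    if not (0.0 <= epsilon <= 0.5):
        raise ValueError(f"noise rate must be in [0, 1/2], got {epsilon}")
    arr = (1.0 - 2.0 * epsilon) * np.asarray(p, dtype=float) + epsilon
    return StrategyVector(*arr)


def transition_matrix(p: Sequence[float], q: Sequence[float]) -> np.ndarray:
    """4x4 outcome-to-outcome transition matrix, focal perspective.

    Row = current outcome; the focal player cooperates with probability
    ``p[row]`` while the opponent, who sees the perspective-swapped
    outcome, cooperates with probability ``q[swap(row)]``.
    """
    pa = np.asarray(p, dtype=float)
    qa = np.asarray(q, dtype=float)[SWAP]
    t = np.empty((4, 4))
    t[:, 0] = pa * qa
    t[:, 1] = pa * (1.0 - qa)
    t[:, 2] = (1.0 - pa) * qa
    t[:, 3] = (1.0 - pa) * (1.0 - qa)
    return t


def _pd_matrix(p: np.ndarray, q: np.ndarray, f: np.ndarray) -> np.ndarray:
    """The 4x4 Press-Dyson matrix whose determinant is ``D(p, q, f)``."""
    p1, p2, p3, p4 = p
    q1, q2, q3, q4 = q
    return np.array(
        [
            [-1.0 + p1 * q1, -1.0 + p1, -1.0 + q1, f[0]],
            [p2 * q3, -1.0 + p2, q3, f[1]],
            [p3 * q2, p3, -1.0 + q2, f[2]],
            [p4 * q4, p4, q4, f[3]],
        ]
    )


def press_dyson_score(
    p: Sequence[float], q: Sequence[float], f: Sequence[float]
) -> float:
    """Stationary mean of ``f`` for the (p, q) match, ``D(p,q,f)/D(p,q,1)``.

    ``f`` is any per-outcome 4-vector in the focal player's outcome order;
    with ``f = (R, S, T, P)`` this is the focal player's long-run score.
    Raises :class:`DegenerateChainError` when ``|D(p, q, 1)| < 1e-12``
    (non-ergodic chain).
    """
    pa = np.asarray(p, dtype=float)
    qa = np.asarray(q, dtype=float)
    fa = np.asarray(f, dtype=float)
    d1 = np.linalg.det(_pd_matrix(pa, qa, np.ones(4)))
    if abs(d1) < 1e-12:
        raise DegenerateChainError(
            f"non-ergodic chain for p={tuple(pa)}, q={tuple(qa)}"
        )
    return float(np.linalg.det(_pd_matrix(pa, qa, fa)) / d1)


def _stationary_power_iteration(
    t: np.ndarray, max_iter: int = 10_000, tol: float = 1e-13
) -> np.ndarray:
    """Stationary (or Cesaro-limit) distribution by averaged power iteration.

    Starts from mutual cooperation (both players open with C), so that
    absorbing noise-free chains return the initial-condition-dependent
    limit documented for the degenerate branch.
    """
    v = np.array([1.0, 0.0, 0.0, 0.0])
    avg = v.copy()
    for k in range(1, max_iter + 1):
        v = v @ t
        new_avg = avg + (v - avg) / (k + 1)
        if np.max(np.abs(new_avg - avg)) < tol:
            avg = new_avg
            break
        avg = new_avg
    return avg / avg.sum()


class StationaryResult(NamedTuple):
    """Stationary outcome distribution and the two long-run scores."""

    dist: np.ndarray
    score_focal: float
    score_opp: float


def stationary_scores(
    p: Sequence[float],
    q: Sequence[float],
    matrix: GameMatrix,
    epsilon: float = 0.0,
) -> StationaryResult:
    """Long-run scores of a noisy match between memory-one strategies.

    Applies :func:`effective_vector` to both players, then evaluates the
    stationary distribution through the Press-Dyson determinant (falling
    back to averaged power iteration from mutual cooperation when the
    chain is degenerate, which can happen only at ``epsilon = 0``).
    """
    pe = np.asarray(effective_vector(p, epsilon), dtype=float)
    qe = np.asarray(effective_vector(q, epsilon), dtype=float)
    d1 = np.linalg.det(_pd_matrix(pe, qe, np.ones(4)))
    if abs(d1) < 1e-12:
        dist = _stationary_power_iteration(transition_matrix(pe, qe))
    else:
        dist = np.array(
            [np.linalg.det(_pd_matrix(pe, qe, np.eye(4)[i])) / d1 for i in range(4)]
        )
    dist = np.clip(dist, 0.0, None)
    dist = dist / dist.sum()
    return StationaryResult(
        dist=dist,
        score_focal=float(dist @ matrix.focal_payoffs),
        score_opp=float(dist @ matrix.opponent_payoffs),
    )


# ---------------------------------------------------------------------------
# batched determinant scores (hot path for the groupmax optimiser)


def batched_scores(
    ps: np.ndarray, qs: np.ndarray, matrix: GameMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Focal and opponent stationary scores for a batch of (p, q) rows.

    ``ps``/``qs`` have shape ``(B, 4)`` and must already be effective
    (noise-adjusted, interior) vectors so that every chain is ergodic.
    """
    ps = np.atleast_2d(np.asarray(ps, dtype=float))
    qs = np.atleast_2d(np.asarray(qs, dtype=float))
    b = max(len(ps), len(qs))
    ps = np.broadcast_to(ps, (b, 4))
    qs = np.broadcast_to(qs, (b, 4))
    m = np.empty((b, 4, 4))
    m[:, 0, 0] = -1.0 + ps[:, 0] * qs[:, 0]
    m[:, 0, 1] = -1.0 + ps[:, 0]
    m[:, 0, 2] = -1.0 + qs[:, 0]
    m[:, 1, 0] = ps[:, 1] * qs[:, 2]
    m[:, 1, 1] = -1.0 + ps[:, 1]
    m[:, 1, 2] = qs[:, 2]
    m[:, 2, 0] = ps[:, 2] * qs[:, 1]
    m[:, 2, 1] = ps[:, 2]
    m[:, 2, 2] = -1.0 + qs[:, 1]
    m[:, 3, 0] = ps[:, 3] * qs[:, 3]
    m[:, 3, 1] = ps[:, 3]
    m[:, 3, 2] = qs[:, 3]

    dets = {}
    for name, f in (
        ("one", np.ones(4)),
        ("sx", matrix.focal_payoffs),
        ("sy", matrix.opponent_payoffs),
    ):
        m[:, :, 3] = f
        dets[name] = np.linalg.det(m)
    d1 = dets["one"]
    return dets["sx"] / d1, dets["sy"] / d1


# ---------------------------------------------------------------------------
# Monte-Carlo match oracle


def simulate_matches(
    ps: np.ndarray,
    qs: np.ndarray,
    matrix: GameMatrix,
    epsilon: float,
    rounds: int,
    rng: np.random.Generator,
    first_moves: tuple[int, int] = (0, 0),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-round scores of simulated noisy matches.

    Plays ``rounds`` rounds for each strategy pair (vectorised across
    pairs), flipping each intended move independently with probability
    ``epsilon``, and returns the empirical mean payoffs ``(focal, opp)``.
    Serves as a sampling-based cross-check of the determinant scores.
    """
    ps = np.atleast_2d(np.asarray(ps, dtype=float))
    qs = np.atleast_2d(np.asarray(qs, dtype=float))
    n = max(len(ps), len(qs))
    ps = np.broadcast_to(ps, (n, 4))
    qs = np.broadcast_to(qs, (n, 4))
    sx = matrix.focal_payoffs
    sy = matrix.opponent_payoffs
    total_f = np.zeros(n)
    total_o = np.zeros(n)
    idx = np.arange(n)
    # first round: fixed opening moves, then noise
    a = np.full(n, first_moves[0])
    b = np.full(n, first_moves[1])
    for r in range(rounds):
        if r > 0:
            pc = ps[idx, out]
            qc = qs[idx, SWAP[out]]
            a = (rng.random(n) >= pc).astype(np.int64)
            b = (rng.random(n) >= qc).astype(np.int64)
        if epsilon > 0:
            a = a ^ (rng.random(n) < epsilon)
            b = b ^ (rng.random(n) < epsilon)
        out = 2 * a + b
        total_f += sx[out]
        total_o += sy[out]
    return total_f / rounds, total_o / rounds
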