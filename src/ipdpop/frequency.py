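"""Frequency-dependent fitness analysis.

In a well-mixed population of ``N`` players holding ``m`` invaders of type
I among residents of type G, the difference in mean stationary payoff
between the two types is

    S_I - S_G = (m-1)/(N-1) S_II + (N-m)/(N-1) S_IG
                - m/(N-1) S_GI - (N-m-1)/(N-1) S_GG

where ``S_XY`` is the stationary pairwise score of an X player against a Y
player. For ``N -> inf`` this tends to ``f (S_II - S_GI) + (1-f) (S_IG -
S_GG)`` with ``f = m/N``; for ``N = 2`` it collapses to the head-to-head
difference ``S_IG - S_GI``. The sign of this difference as a function of
``m`` is what makes optimal play frequency dependent: e.g. against a
resident TFT population it is optimal to cooperate while rare but to
defect once in the majority.

Tag-based idealisations are supported through :class:`TagStrategyPair`: a
player that knows the true type of every opponent and plays one vector
against its own type and another against the opposing type (ConDef =
(ALLC, ALLD); ZD_t = (ALLC, some ZD vector)).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence, Union

from .games import GameMatrix
from .memory_one import StrategyVector, stationary_scores

__all__ = [
    "FrequencyProfile",
    "TagStrategyPair",
    "StrategySpec",
    "mean_score_difference",
    "pairwise_scores",
    "score_difference_curve",
    "best_response_at_fraction",
]


class TagStrategyPair(NamedTuple):
    """Play ``vs_self`` against one's own type and ``vs_other`` otherwise."""

    vs_self: StrategyVector
    vs_other: StrategyVector


StrategySpec = Union[StrategyVector, TagStrategyPair, Sequence[float]]


class FrequencyProfile(NamedTuple):
    """The four pairwise stationary scores at a population mixture (m of N)."""

    S_II: float
    S_IG: float
    S_GI: float
    S_GG: float
    N: int
    m: int


def mean_score_difference(profile: FrequencyProfile) -> float:
    """Mean stationary payoff difference ``S_I - S_G`` at mixture (m, N)."""
    s_ii, s_ig, s_gi, s_gg, n, m = profile
    if n < 2:
        raise ValueError(f"population size must be >= 2, got {n}")
    if not (1 <= m <= n - 1):
        raise ValueError(f"invader count must be in [1, N-1], got m={m}, N={n}")
    w = n - 1
    return ((m - 1) * s_ii + (n - m) * s_ig - m * s_gi - (n - m - 1) * s_gg) / w


def _as_pair(spec: StrategySpec) -> TagStrategyPair:
    if isinstance(spec, TagStrategyPair):
        return spec
    vec = StrategyVector(*spec)
    return TagStrategyPair(vs_self=vec, vs_other=vec)


def pairwise_scores(
    inv: StrategySpec,
    res: StrategySpec,
    matrix: GameMatrix,
    epsilon: float = 0.0,
) -> tuple[float, float, float, float]:
    """Stationary ``(S_II, S_IG, S_GI, S_GG)`` for invader vs resident.

    Tag pairs use ``vs_self`` in like-type games and ``vs_other`` in
    cross-type games; a plain vector plays itself everywhere.
    """
    ipair = _as_pair(inv)
    gpair = _as_pair(res)
    s_ii = stationary_scores(ipair.vs_self, ipair.vs_self, matrix, epsilon).score_focal
    s_gg = stationary_scores(gpair.vs_self, gpair.vs_self, matrix, epsilon).score_focal
    cross = stationary_scores(ipair.vs_other, gpair.vs_other, matrix, epsilon)
    return s_ii, cross.score_focal, cross.score_opp, s_gg


def score_difference_curve(
    inv: StrategySpec,
    res: StrategySpec,
    matrix: GameMatrix,
    epsilon: float = 0.0,
    N: int = 100,
) -> list[tuple[int, float]]:
    """``S_I - S_G`` at every invader count ``m = 1 .. N-1``.

    The four pairwise scores are stationary quantities (no transient), so
    the curve is the analytic frequency-dependence of fitness, not a
    simulation.
    """
    s_ii, s_ig, s_gi, s_gg = pairwise_scores(inv, res, matrix, epsilon)
    return [
        (m, mean_score_difference(FrequencyProfile(s_ii, s_ig, s_gi, s_gg, N, m)))
        for m in range(1, N)
    ]


def best_response_at_fraction(
    candidates: Sequence[StrategySpec],
    res: StrategySpec,
    matrix: GameMatrix,
    epsilon: float,
    N: int,
    m: int,
) -> StrategySpec:
    """The candidate maximising ``S_I - S_G`` at mixture (m, N).

    Ties break toward the earlier candidate in the list.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    best, best_val = None, None
    for cand in candidates:
        s = pairwise_scores(cand, res, matrix, epsilon)
        val = mean_score_difference(FrequencyProfile(*s, N, m))
        if best_val is None or val > best_val:
            best, best_val = cand, val
    return best
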