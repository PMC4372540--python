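"""Experiment drivers: identification ROC curves, fixation tables, sweeps.

These functions wrap the engine in reproducible, seedable protocols:

* :func:`roc_identification` measures how well the infogain phase's
  binomial mismatch test separates a given opponent strategy from a
  fellow IP0 (positives = non-IP0 opponents, negatives = IP0 opponents),
  sweeping the classification threshold over the p-value statistic;
* :func:`fixation_table` and :func:`invasion_vs_noise` estimate empirical
  fixation probabilities (odds ratios against the neutral ``m0/N``) from
  repeated invasion simulations;
* :func:`self_score_vs_noise` evaluates a memory-one strategy's
  stationary self-score across noise levels (how noise erodes a
  strategy's ability to cooperate with itself).
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .games import SWAP, DEFAULT_MATRIX, GameMatrix
from .infoplayer import IPConfig, OpponentModel
from .memory_one import stationary_scores
from .population import (
    FixationRecord,
    NonTerminationError,
    PlayerSpec,
    run_to_fixation,
)

__all__ = [
    "ROCResult",
    "ExperimentConfig",
    "infogain_match_pvalue",
    "roc_identification",
    "birth_death_fixation_prob",
    "fixation_estimate",
    "fixation_table",
    "invasion_vs_noise",
    "self_score_vs_noise",
]


class ROCResult(NamedTuple):
    """Empirical ROC: false/true positive rates per threshold, and AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def tp_at_fp(self, fp: float) -> float:
        """True-positive rate at a given false-positive rate (interpolated)."""
        return float(np.interp(fp, self.fpr, self.tpr))


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared knobs of the simulation experiments."""

    n_sims: int = 1000
    N: int = 100
    m0: int = 1
    epsilon: float = 0.05
    sigma: float = 1.0
    rule: str = "imitation"
    matrix: GameMatrix = DEFAULT_MATRIX
    base_seed: int = 0
    max_generations: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


def _opponent_driver(spec: PlayerSpec, config: IPConfig):
    """A closure producing the scripted opponent's intended move.

    The opponent conditions on the previous outcome *from its own
    perspective*; an IP0 opponent runs its own infogain model of the
    focal player.
    """
    if spec.kind == "ip0":
        model = OpponentModel(prior_L=np.log(1.0 / config.N))

        def choose(last_out_focal, rng):
            return int(model.choose(config, None, rng))

        def observe(my_focal, opp_focal):
            # from the opponent's perspective the moves swap roles
            model.observe(opp_focal, my_focal, config)

        return choose, observe
    if spec.vector is None:
        raise ValueError("scripted opponents must be memory-one or ip0")
    vec = np.asarray(spec.vector, dtype=float)
    first = int(spec.first_move)

    def choose(last_out_focal, rng):
        if last_out_focal is None:
            return first
        pc = vec[int(SWAP[last_out_focal])]
        return 0 if rng.random() < pc else 1

    def observe(my_focal, opp_focal):
        return None

    return choose, observe


def infogain_match_pvalue(
    opponent: PlayerSpec,
    rounds: int,
    epsilon: float,
    rng: np.random.Generator,
    config: Optional[IPConfig] = None,
) -> float:
    """Binomial mismatch p-value after an infogain head-to-head sequence.

    The focal IP0 plays ``rounds`` infogain rounds against ``opponent``
    under noise ``epsilon`` and returns the tail probability that the
    observed mismatches against the predicted infogain moves arose from
    noise alone (small p-value = confident the opponent is not IP0).
    """
    cfg = config or IPConfig()
    cfg = dataclasses.replace(
        cfg, epsilon=epsilon, infogain_length=max(rounds, cfg.infogain_length)
    )
    focal = OpponentModel(prior_L=np.log(1.0 / cfg.N))
    opp_choose, opp_observe = _opponent_driver(opponent, cfg)
    last_out = None
    for _ in range(rounds):
        my = int(focal.choose(cfg, None, rng))
        opp = opp_choose(last_out, rng)
        if epsilon > 0.0:
            if rng.random() < epsilon:
                my ^= 1
            if rng.random() < epsilon:
                opp ^= 1
        focal.observe(my, opp, cfg)
        opp_observe(my, opp)
        last_out = 2 * my + opp
    return focal.p_value


def roc_identification(
    opponent: PlayerSpec,
    rounds: int,
    epsilon: float,
    n_replicates: int = 2000,
    rng: Union[np.random.Generator, int, None] = None,
    config: Optional[IPConfig] = None,
) -> ROCResult:
    """Empirical ROC for discriminating ``opponent`` from a fellow IP0.

    Simulates ``n_replicates`` positive sequences (IP0 vs the opponent)
    and as many negative sequences (IP0 vs IP0), sweeps the threshold on
    the binomial mismatch p-value, and integrates the curve by trapezoid.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    from .population import ip0_player  # local import to avoid cycle

    twin = ip0_player()
    pos = np.array(
        [infogain_match_pvalue(opponent, rounds, epsilon, rng, config) for _ in range(n_replicates)]
    )
    neg = np.array(
        [infogain_match_pvalue(twin, rounds, epsilon, rng, config) for _ in range(n_replicates)]
    )
    # smaller p-value => flagged as non-IP0; sweep thresholds over observed values
    thresholds = np.unique(np.concatenate([pos, neg]))
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(float(np.mean(pos <= t)))
        fpr.append(float(np.mean(neg <= t)))
    tpr.append(1.0)
    fpr.append(1.0)
    fpr_arr = np.asarray(fpr)
    tpr_arr = np.asarray(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return ROCResult(fpr=fpr_arr, tpr=tpr_arr, auc=auc)


def _strategy_payload(spec: PlayerSpec):
    if spec.tag_pair is not None:
        return spec.tag_pair
    if spec.vector is not None:
        return spec.vector
    raise ValueError(
        f"{spec.type_name}: analytic fate resolution needs a fixed strategy"
    )


def birth_death_fixation_prob(
    invader: PlayerSpec,
    resident: PlayerSpec,
    matrix: GameMatrix,
    epsilon: float,
    N: int,
    m: int,
    sigma: float = 1.0,
) -> float:
    """Fixation probability of the stationary-score birth-death chain.

    The per-step up/down ratio of every one-replacement update rule here
    is ``exp(sigma * (S_I - S_G))`` evaluated at the current mixture, so
    the embedded chain with ``gamma_m = exp(-sigma * diff(m))`` gives the
    idealised (noise-free-fitness) fixation probability from ``m``
    invaders. Used to resolve the eventual fate of runs parked on a
    metastable interior equilibrium.
    """
    from .frequency import FrequencyProfile, mean_score_difference, pairwise_scores

    s = pairwise_scores(
        _strategy_payload(invader), _strategy_payload(resident), matrix, epsilon
    )
    diffs = np.array(
        [
            mean_score_difference(FrequencyProfile(*s, N, mm))
            for mm in range(1, N)
        ]
    )
    log_gamma = np.clip(-sigma * diffs, -500, 500)
    cum = np.cumsum(log_gamma)
    # phi(m) = sum_{k<m} prod gamma / sum_{k<N} prod gamma, with the k=0 term = 1
    terms = np.concatenate([[0.0], cum])  # log of prefix products, k = 0..N-1
    mx = terms.max()
    w = np.exp(terms - mx)
    return float(w[:m].sum() / w.sum())


def fixation_estimate(
    invader: PlayerSpec,
    resident: PlayerSpec,
    config: ExperimentConfig,
    epsilon: Optional[float] = None,
    verbose: bool = False,
    resolve_metastable: bool = False,
    on_unresolved: str = "raise",
) -> FixationRecord:
    """Empirical fixation record over ``config.n_sims`` seeded invasions.

    With ``resolve_metastable`` (memory-one / tag-pair types only), runs
    still unresolved at ``config.max_generations`` — parked on an interior
    fitness equilibrium whose absorption time far exceeds any reasonable
    budget — have their eventual fate sampled from the analytic
    birth-death fixation probability at the run's final invader count.
    Otherwise ``on_unresolved`` decides whether a capped run raises or is
    censored (counted as not fixed).
    """
    eps = config.epsilon if epsilon is None else epsilon
    seeds = np.random.SeedSequence(config.base_seed).spawn(config.n_sims)
    k = 0
    n_unresolved = 0
    for rep, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        rec: list = []
        try:
            fixed = run_to_fixation(
                invader,
                resident,
                m0=config.m0,
                N=config.N,
                epsilon=eps,
                sigma=config.sigma,
                rule=config.rule,
                rng=rng,
                matrix=config.matrix,
                max_generations=config.max_generations,
                record=rec,
            )
        except NonTerminationError:
            if not resolve_metastable:
                if on_unresolved == "raise":
                    raise
                # censor: count the run as not fixed but keep the tally
                n_unresolved += 1
                fixed = False
            else:
                m_final = rec[-1][1]
                phi = birth_death_fixation_prob(
                    invader, resident, config.matrix, eps, config.N, m_final,
                    config.sigma,
                )
                fixed = rng.random() < phi
        k += int(fixed)
        if verbose and (rep + 1) % 100 == 0:
            print(
                f"  {invader.type_name} vs {resident.type_name} eps={eps}: "
                f"{rep + 1}/{config.n_sims} sims, {k} fixations",
                file=sys.stderr,
                flush=True,
            )
    return FixationRecord.from_counts(k, config.n_sims, config.N, config.m0)


def fixation_table(
    pairs: Sequence[tuple[PlayerSpec, PlayerSpec]],
    config: ExperimentConfig,
    verbose: bool = False,
) -> pd.DataFrame:
    """Fixation records for a list of (invader, resident) pairs.

    Runs that hit the generation cap are censored (counted as non-fixed)
    rather than aborting the table.
    """
    rows = []
    for invader, resident in pairs:
        rec = fixation_estimate(
            invader, resident, config, verbose=verbose, on_unresolved="censor"
        )
        rows.append(
            {
                "invader": invader.type_name,
                "resident": resident.type_name,
                "n_sims": rec.n_sims,
                "k": rec.k,
                "rho": rec.rho,
                "odds_ratio": rec.odds_ratio,
                "p_value": rec.p_value,
            }
        )
    return pd.DataFrame(rows)


def invasion_vs_noise(
    invader: PlayerSpec,
    resident: PlayerSpec,
    epsilon_grid: Sequence[float],
    config: ExperimentConfig,
    verbose: bool = False,
) -> list[tuple[float, FixationRecord]]:
    """One fixation estimate per noise level (odds ratio 1.0 = neutral)."""
    return [
        (eps, fixation_estimate(invader, resident, config, epsilon=eps, verbose=verbose))
        for eps in epsilon_grid
    ]


def self_score_vs_noise(
    strategy: Union[PlayerSpec, Sequence[float]],
    epsilon_grid: Sequence[float],
    matrix: GameMatrix = DEFAULT_MATRIX,
) -> list[tuple[float, float]]:
    """Stationary self-score of a memory-one strategy per noise level."""
    if isinstance(strategy, PlayerSpec):
        if strategy.vector is None:
            raise ValueError("self-score sweep needs a memory-one strategy")
        vec = strategy.vector
    else:
        vec = list(strategy)
    return [
        (eps, stationary_scores(vec, vec, matrix, eps).score_focal)
        for eps in epsilon_grid
    ]
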