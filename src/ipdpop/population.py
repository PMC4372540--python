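"""Evolutionary population dynamics with persistent player identities.

Protocol (per generation): every player plays exactly one move against
every other player, conditioned on the pair's previous-generation outcome
(players meeting for the first time use their standard first move); every
realised move is independently flipped with probability ``epsilon``;
payoffs come from the game matrix and fitness is the mean payoff over the
``N - 1`` games; then one death/birth event occurs, by the exponential
imitation dynamic (uniform death, model drawn with weight
``exp(sigma * fitness)``) or the Moran-style alternative (reproducer drawn
with weight ``exp(sigma * fitness)``, uniform death). A replaced slot gets
a fresh identity and empty internal state; information players are
notified of deaths (archiving counts of confidently identified opponents)
and births (prior log-odds ``log(m_bar / N)``).

Implementation notes: play between memory-one / tag-based players, and
between information players past their infogain phase, is vectorised over
the pair matrix; only pairs inside an infogain window run the per-round
scalar model from :mod:`ipdpop.infoplayer`. Both paths apply identical
update formulas.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .frequency import TagStrategyPair
from .games import SWAP, DEFAULT_MATRIX, GameMatrix, Move
from .infoplayer import (
    IPConfig,
    OpponentModel,
    estimate_m_bar,
    groupmax_optimize_many,
    new_player_prior,
)
from .memory_one import StrategyVector

__all__ = [
    "PlayerSpec",
    "PopulationState",
    "FixationRecord",
    "NonTerminationError",
    "memory_one_player",
    "tag_player",
    "ip0_player",
    "conswitch_player",
    "play_generation",
    "imitation_update",
    "moran_update",
    "run_to_fixation",
    "fixation_pvalue",
]

_LOG_EPS = 1e-12


class NonTerminationError(RuntimeError):
    """A fixation run exceeded its generation safety cap."""


def _quantise_estimate(theta: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Round an opponent-strategy estimate to its own evidence scale.

    A component backed by few observations has a wide posterior, so the
    groupmax optimisation is only re-run when the estimate moves by more
    than a fraction of its own uncertainty: grid 0.25 below 10
    observations, 0.1 below 50, 0.05 below 500, 0.02 beyond.
    """
    step = np.where(
        counts < 10, 0.25, np.where(counts < 50, 0.1, np.where(counts < 500, 0.05, 0.02))
    )
    return np.clip(np.round(theta / step) * step, 0.0, 1.0)


@dataclass(frozen=True)
class PlayerSpec:
    """Immutable description of a player type.

    ``kind`` is one of ``memory_one`` (plays ``vector`` everywhere),
    ``tag_based`` (true type tags: plays ``tag_pair.vs_self`` against its
    own type name and either ``tag_pair.vs_other`` or — for the ConSwitch
    variant, signalled by a ``ip_config`` payload instead of a pair — its
    current groupmax-optimised vector against the rest), or ``ip0`` (full
    inference machinery, no tags).
    """

    type_name: str
    kind: str
    vector: Optional[StrategyVector] = None
    tag_pair: Optional[TagStrategyPair] = None
    ip_config: Optional[IPConfig] = None
    first_move: Move = Move.C

    def __post_init__(self) -> None:
        if self.kind not in ("memory_one", "tag_based", "ip0"):
            raise ValueError(f"unknown player kind {self.kind!r}")
        if self.kind == "memory_one" and self.vector is None:
            raise ValueError("memory_one spec needs a vector")
        if self.kind == "tag_based" and self.tag_pair is None and self.ip_config is None:
            raise ValueError("tag_based spec needs a tag_pair or ip_config")

    @property
    def is_conswitch(self) -> bool:
        return self.kind == "tag_based" and self.ip_config is not None


def memory_one_player(
    name: str, vector: Sequence[float], first_move: Move = Move.C
) -> PlayerSpec:
    return PlayerSpec(
        type_name=name,
        kind="memory_one",
        vector=StrategyVector(*vector).validate(),
        first_move=first_move,
    )


def tag_player(
    name: str, pair: TagStrategyPair, first_move: Move = Move.C
) -> PlayerSpec:
    return PlayerSpec(type_name=name, kind="tag_based", tag_pair=pair, first_move=first_move)


def ip0_player(name: str = "IP0", config: Optional[IPConfig] = None) -> PlayerSpec:
    return PlayerSpec(type_name=name, kind="ip0", ip_config=config or IPConfig())


def conswitch_player(
    name: str = "ConSwitch", config: Optional[IPConfig] = None, first_move: Move = Move.C
) -> PlayerSpec:
    """Tag-based information player: groupmax machinery, no infogain."""
    return PlayerSpec(
        type_name=name,
        kind="tag_based",
        ip_config=config or IPConfig(),
        first_move=first_move,
    )


class FixationRecord(NamedTuple):
    """Tally of a batch of invasion simulations."""

    n_sims: int
    k: int
    rho: float
    rho_neutral: float
    odds_ratio: float
    p_value: float

    @classmethod
    def from_counts(cls, k: int, n_sims: int, N: int, m0: int = 1) -> "FixationRecord":
        rho = k / n_sims
        rho_neutral = m0 / N
        return cls(
            n_sims=n_sims,
            k=k,
            rho=rho,
            rho_neutral=rho_neutral,
            odds_ratio=rho / rho_neutral,
            p_value=fixation_pvalue(k, n_sims, N),
        )


def fixation_pvalue(k: int, n_sims: int, N: int) -> float:
    """Binomial tail ``P(K >= k)`` under the neutral rate ``theta = 1/N``."""
    if not (0 <= k <= n_sims):
        raise ValueError(f"need 0 <= k <= n_sims, got k={k}, n_sims={n_sims}")
    return float(stats.binom.sf(k - 1, n_sims, 1.0 / N))


def _first_move_prob(spec: PlayerSpec) -> float:
    return 1.0 if spec.first_move == Move.C else 0.0


class PopulationState:
    """Mutable state of one evolving population."""

    def __init__(
        self,
        specs: Sequence[PlayerSpec],
        matrix: GameMatrix = DEFAULT_MATRIX,
        epsilon: float = 0.05,
        sigma: float = 1.0,
        rng: Union[np.random.Generator, int, None] = None,
    ):
        if not (0.0 <= epsilon <= 0.5):
            raise ValueError(f"noise rate must be in [0, 1/2], got {epsilon}")
        self.N = len(specs)
        if self.N < 2:
            raise ValueError("population needs at least two players")
        self.matrix = matrix
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.generation = 0
        self.specs: list[PlayerSpec] = list(specs)
        self.ids = np.arange(self.N, dtype=np.int64)
        self._next_id = self.N
        self.fitness = np.zeros(self.N)
        self.last_out = np.full((self.N, self.N), -1, dtype=np.int8)

        # shared IP configuration (epsilon_assumed = ambient epsilon)
        base_cfg = next(
            (s.ip_config for s in specs if s.ip_config is not None), IPConfig()
        )
        self.ip_cfg = dataclasses.replace(base_cfg, epsilon=self.epsilon, N=self.N)

        self._type_codes_map: dict[str, int] = {}
        self.type_code = np.zeros(self.N, dtype=np.int32)
        self.is_ip0 = np.zeros(self.N, dtype=bool)
        self.is_cs = np.zeros(self.N, dtype=bool)
        self.v_same = np.zeros((self.N, 5))
        self.v_diff = np.zeros((self.N, 5))
        self._same = np.zeros((self.N, self.N), dtype=bool)
        self._is_tag = np.zeros(self.N, dtype=bool)
        self._rows = np.arange(self.N)[:, None]

        n = self.N
        self.ipL = np.zeros((n, n))
        self.iphmm = np.full((n, n), 0.5)
        self.ipn = np.zeros((n, n, 4), dtype=np.int32)
        self.ipm = np.zeros((n, n, 4), dtype=np.int32)
        self.ipconf = np.zeros((n, n), dtype=bool)
        self.mature = np.zeros((n, n), dtype=bool)
        self.young: dict[tuple[int, int], OpponentModel] = {}
        self.deadpool_n = np.zeros((n, 4), dtype=np.int64)
        self.deadpool_m = np.zeros((n, 4), dtype=np.int64)
        self.csn = np.zeros((n, 4), dtype=np.int64)
        self.csm = np.zeros((n, 4), dtype=np.int64)
        self.pgm = np.full((n, 4), 0.5)
        self._pp = np.full((n, 4), 0.5)
        self._has_pooled = np.zeros(n, dtype=bool)

        for i, spec in enumerate(self.specs):
            self._install_slot(i, spec, fresh_id=False)
        prior0 = new_player_prior(1.0, self.N)
        for i in np.flatnonzero(self.is_ip0):
            for j in range(self.N):
                if j != i:
                    self.young[(int(i), j)] = OpponentModel(prior_L=prior0)

    # -- roster bookkeeping -------------------------------------------------

    def _code_for(self, name: str) -> int:
        if name not in self._type_codes_map:
            self._type_codes_map[name] = len(self._type_codes_map)
        return self._type_codes_map[name]

    def _install_slot(self, i: int, spec: PlayerSpec, fresh_id: bool = True) -> None:
        self.specs[i] = spec
        if fresh_id:
            self.ids[i] = self._next_id
            self._next_id += 1
        self.type_code[i] = self._code_for(spec.type_name)
        self.is_ip0[i] = spec.kind == "ip0"
        self.is_cs[i] = spec.is_conswitch
        fm = _first_move_prob(spec)
        if spec.kind == "memory_one":
            row = list(spec.vector) + [fm]
            self.v_same[i] = row
            self.v_diff[i] = row
        elif spec.is_conswitch:
            self.v_same[i] = [1.0, 1.0, 1.0, 1.0, 1.0]
            self.v_diff[i] = [0.5, 0.5, 0.5, 0.5, fm]
        elif spec.kind == "tag_based":
            self.v_same[i] = list(spec.tag_pair.vs_self) + [fm]
            self.v_diff[i] = list(spec.tag_pair.vs_other) + [fm]
        else:  # ip0: row is overwritten pair-by-pair each generation
            self.v_same[i] = 0.5
            self.v_diff[i] = 0.5
        self._is_tag[i] = spec.kind == "tag_based"
        self._same[i, :] = self.type_code[i] == self.type_code
        self._same[:, i] = self._same[i, :]

    def type_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for spec in self.specs:
            out[spec.type_name] = out.get(spec.type_name, 0) + 1
        return out

    # -- information-player helpers ------------------------------------------

    def _young_by_owner(self) -> dict[int, list[OpponentModel]]:
        by_owner: dict[int, list[OpponentModel]] = {}
        for (o, _), model in self.young.items():
            by_owner.setdefault(o, []).append(model)
        return by_owner

    def _owner_m_bar(self, i: int, young: Sequence[OpponentModel]) -> float:
        lmat = np.clip(self.ipL[i][self.mature[i]], -36.0, 36.0)
        total = 1.0 + float(np.sum(1.0 / (np.exp(-lmat) + 1.0)))
        for m in young:
            lc = min(max(m.L, -36.0), 36.0)
            total += 1.0 / (math.exp(-lc) + 1.0)
        return min(total, float(self.N))

    def _begin_generation(self) -> None:
        """Refresh groupmax vectors and pooled predictive state."""
        eps = self.epsilon
        young_by_owner = self._young_by_owner()
        owners = [int(i) for i in np.flatnonzero(self.is_ip0 | self.is_cs)]
        if not owners:
            return
        log_alpha = math.log(self.ip_cfg.alpha)
        if self.is_ip0.any():
            # vectorised per-owner aggregates over mature pairs
            lclip = np.clip(self.ipL, -36.0, 36.0)
            sig = np.where(self.mature, 1.0 / (np.exp(-lclip) + 1.0), 0.0)
            m_bar_mat = 1.0 + sig.sum(axis=1)
            conf = self.mature & (self.ipconf | (self.ipL < log_alpha))
            cf = conf.astype(np.float64)
            pool_n = self.deadpool_n + np.einsum("ij,ijk->ik", cf, self.ipn)
            pool_m = self.deadpool_m + np.einsum("ij,ijk->ik", cf, self.ipm)
            any_conf = conf.any(axis=1) | (self.deadpool_n.sum(axis=1) > 0)
            gp_mask = self.mature & (self.ipL <= 0.0)
            gf = gp_mask.astype(np.float64)
            gp_n = np.einsum("ij,ijk->ik", gf, self.ipn)
            gp_m = np.einsum("ij,ijk->ik", gf, self.ipm)
            gp_any = gp_mask.any(axis=1)

        ests, mbars = [], []
        for i in owners:
            if self.is_cs[i]:
                m_bar = float(np.sum(self.type_code == self.type_code[i]))
                theta = (self.csm[i] + 1.0) / (self.csn[i] + 2.0)
                est = _quantise_estimate(theta[SWAP], self.csn[i][SWAP])
            else:
                yi = young_by_owner.get(i, ())
                m_bar = m_bar_mat[i]
                n = pool_n[i]
                m = pool_m[i]
                confident = bool(any_conf[i])
                for model in yi:
                    lc = min(max(model.L, -36.0), 36.0)
                    m_bar += 1.0 / (math.exp(-lc) + 1.0)
                    if model.confident_gp or model.L < log_alpha:
                        n = n + np.asarray(model.counts.n)
                        m = m + np.asarray(model.counts.m)
                        confident = True
                m_bar = min(m_bar, float(self.N))
                self._has_pooled[i] = confident
                theta = (m + 1.0) / (n + 2.0)
                self._pp[i] = theta
                if confident:
                    est = _quantise_estimate(theta[SWAP], n[SWAP])
                elif gp_any[i]:
                    est = _quantise_estimate(
                        ((gp_m[i] + 1.0) / (gp_n[i] + 2.0))[SWAP], gp_n[i][SWAP]
                    )
                else:
                    est = np.full(4, 0.5)
            ests.append(est)
            mbars.append(max(m_bar, 1.0))
        optima = groupmax_optimize_many(
            np.array(ests), np.array(mbars), self.N, self.matrix, eps,
            prevs=[self.pgm[i] for i in owners],
        )
        for j, i in enumerate(owners):
            self.pgm[i] = optima[j]
            if self.is_cs[i]:
                self.v_diff[i, :4] = self.pgm[i]

    # -- one generation of play ----------------------------------------------

    def play_generation(self) -> "PopulationState":
        n = self.N
        eps = self.epsilon
        cfg = self.ip_cfg
        self._begin_generation()

        o_prev = self.last_out.copy()
        idx5 = np.where(o_prev >= 0, o_prev, 4).astype(np.intp)
        rows = self._rows
        same = self._same
        prob_c = self.v_diff[rows, idx5]
        tag = np.flatnonzero(self._is_tag)
        if len(tag):
            prob_c[tag] = np.where(
                same[tag], self.v_same[tag[:, None], idx5[tag]], prob_c[tag]
            )

        # information players past infogain: cooperate with believed IP0,
        # otherwise play the groupmax vector (own-frame conditioning)
        mat = self.mature
        if mat.any():
            mi, mj = np.nonzero(mat)
            o_m = o_prev[mi, mj].astype(np.intp)
            prob_c[mi, mj] = np.where(
                self.ipL[mi, mj] > 0.0, 1.0, self.pgm[mi, o_m]
            )

        if eps == 0.0:
            # noise-free: only genuinely stochastic entries need a draw, so
            # absorbed pairs (e.g. mutual cooperators locked on CC) are free
            defect = np.empty((n, n), dtype=np.int8)
            interior = (prob_c > 0.0) & (prob_c < 1.0)
            det = ~interior
            defect[det] = prob_c[det] < 0.5
            n_act = int(interior.sum())
            if n_act:
                defect[interior] = self.rng.random(n_act) >= prob_c[interior]
        else:
            u = self.rng.random((2, n, n))
            defect = (u[0] >= prob_c).astype(np.int8)
        # infogain-phase moves are deterministic given shared history
        for (i, j), model in self.young.items():
            defect[i, j] = int(model.choose(cfg, None, self.rng))
        if eps > 0.0:
            defect ^= u[1] < eps

        out = (2 * defect + defect.T).astype(np.int8)
        np.fill_diagonal(out, -1)
        pay = self.matrix.focal_payoffs[np.clip(out, 0, 3)]
        np.fill_diagonal(pay, 0.0)
        self.fitness = pay.sum(axis=1) / (n - 1)

        # --- learning ---------------------------------------------------------
        # ConSwitch pooled counts about the opposing group
        for i in np.flatnonzero(self.is_cs):
            i = int(i)
            mask = (~same[i]) & (o_prev[i] >= 0)
            mask[i] = False
            if mask.any():
                o_sel = o_prev[i][mask]
                b_sel = defect[mask, i]
                self.csn[i] += np.bincount(o_sel, minlength=4)
                self.csm[i] += np.bincount(o_sel[b_sel == 0], minlength=4)

        # IP0, vectorised mature pairs (same formulas as OpponentModel.observe)
        if mat.any():
            b = defect[mj, mi].astype(np.int64)  # opponent's realised move
            o_m64 = o_m.astype(np.int64)
            pg = self.pgm[mi, SWAP[o_m64]]
            pge = (1.0 - 2.0 * eps) * pg + eps
            e1 = np.where(b == 0, 1.0 - eps, eps)
            e2 = np.where(b == 0, pge, 1.0 - pge)
            sw = cfg.hmm_switch
            ap = self.iphmm[mi, mj] * (1.0 - sw) + (1.0 - self.iphmm[mi, mj]) * sw
            lik = ap * e1 + (1.0 - ap) * e2
            self.iphmm[mi, mj] = ap * e1 / np.maximum(lik, _LOG_EPS)
            p_pair = (self.ipm[mi, mj, o_m64] + 1.0) / (self.ipn[mi, mj, o_m64] + 2.0)
            p_pool = self._pp[mi, o_m64]
            p_gp = np.where(self._has_pooled[mi], p_pool, p_pair)
            p_gpe = (1.0 - 2.0 * eps) * p_gp + eps
            p_obs = np.where(b == 0, p_gpe, 1.0 - p_gpe)
            self.ipL[mi, mj] += np.log(np.clip(lik, _LOG_EPS, None)) - np.log(
                np.clip(p_obs, _LOG_EPS, 1.0 - _LOG_EPS)
            )
            self.ipn[mi, mj, o_m64] += 1
            self.ipm[mi, mj, o_m64] += (b == 0).astype(np.int32)

        # IP0, infogain-phase pairs
        matured: list[tuple[int, int]] = []
        for (i, j), model in self.young.items():
            pooled = self._pp[i] if self._has_pooled[i] else None
            model.observe(int(defect[i, j]), int(defect[j, i]), cfg, pooled, self.pgm[i])
            if not model.in_infogain(cfg):
                matured.append((i, j))
        for (i, j) in matured:
            model = self.young.pop((i, j))
            self.ipL[i, j] = model.L
            self.iphmm[i, j] = model.hmm_allc
            self.ipn[i, j] = model.counts.n
            self.ipm[i, j] = model.counts.m
            self.ipconf[i, j] = model.confident_gp
            self.mature[i, j] = True

        self.last_out = out
        self.generation += 1
        return self

    # -- death / birth ---------------------------------------------------------

    def _replace_slot(self, dead: int, new_spec: PlayerSpec) -> None:
        log_alpha = math.log(self.ip_cfg.alpha)
        # incumbents archive what they learned about the departed player
        for i in np.flatnonzero(self.is_ip0):
            i = int(i)
            if i == dead:
                continue
            model = self.young.pop((i, dead), None)
            if model is not None:
                if model.confident_gp or model.L < log_alpha:
                    self.deadpool_n[i] += model.counts.n
                    self.deadpool_m[i] += model.counts.m
            elif self.mature[i, dead]:
                if self.ipconf[i, dead] or self.ipL[i, dead] < log_alpha:
                    self.deadpool_n[i] += self.ipn[i, dead]
                    self.deadpool_m[i] += self.ipm[i, dead]

        if self.is_ip0[dead]:
            self.young = {k: v for k, v in self.young.items() if k[0] != dead}
        # reset pair state involving the slot
        for arr in (self.ipn, self.ipm):
            arr[dead, :, :] = 0
            arr[:, dead, :] = 0
        self.ipL[dead, :] = 0.0
        self.ipL[:, dead] = 0.0
        self.iphmm[dead, :] = 0.5
        self.iphmm[:, dead] = 0.5
        self.ipconf[dead, :] = False
        self.ipconf[:, dead] = False
        self.mature[dead, :] = False
        self.mature[:, dead] = False
        self.deadpool_n[dead] = 0
        self.deadpool_m[dead] = 0
        self.csn[dead] = 0
        self.csm[dead] = 0
        self.pgm[dead] = 0.5
        self.last_out[dead, :] = -1
        self.last_out[:, dead] = -1

        self._install_slot(dead, new_spec)

        # incumbents open a fresh model on the newborn
        prior_self = new_player_prior(1.0, self.N)
        young_by_owner = self._young_by_owner()
        for i in np.flatnonzero(self.is_ip0):
            i = int(i)
            if i == dead:
                continue
            prior = new_player_prior(
                max(self._owner_m_bar(i, young_by_owner.get(i, ())), 1.0), self.N
            )
            self.young[(i, dead)] = OpponentModel(prior_L=prior, prior_L_self=prior_self)
        if self.is_ip0[dead]:
            for j in range(self.N):
                if j != dead:
                    self.young[(dead, j)] = OpponentModel(prior_L=prior_self)

    def _softmax_fitness(self) -> np.ndarray:
        w = np.exp(self.sigma * (self.fitness - self.fitness.max()))
        return w / w.sum()

    def _weighted_draw(self, probs: np.ndarray) -> int:
        c = np.cumsum(probs)
        return int(np.searchsorted(c, self.rng.random() * c[-1], side="right"))

    def imitation_update(self) -> "PopulationState":
        """One step of the exponential (Fermi) imitation dynamic.

        A focal player and a model player are drawn uniformly at random;
        the focal player dies and is reborn as a copy of the model with
        probability ``1 / (1 + exp(sigma * (f_focal - f_model)))`` — the
        pairwise comparison rule with exponential dependence on the score
        difference. When imitation does not occur the roster is unchanged
        (no death that generation).
        """
        focal = int(self.rng.integers(self.N))
        model = int(self.rng.integers(self.N - 1))
        if model >= focal:
            model += 1
        z = self.sigma * (self.fitness[focal] - self.fitness[model])
        # guard exp overflow; sigmoid(-z)
        p_adopt = 1.0 / (1.0 + math.exp(min(max(z, -700.0), 700.0)))
        if self.rng.random() < p_adopt:
            self._replace_slot(focal, self.specs[model])
        return self

    def softmax_imitation_update(self) -> "PopulationState":
        """Alternative reading: uniform death, model drawn with weight
        ``exp(sigma * fitness)`` over the whole population (self included,
        making self-imitation a possible no-op replacement)."""
        dead = int(self.rng.integers(self.N))
        model = self._weighted_draw(self._softmax_fitness())
        self._replace_slot(dead, self.specs[model])
        return self

    def moran_update(self) -> "PopulationState":
        """Reproducer drawn with weight ``exp(sigma * fitness)`` (exponential
        weighting keeps negative donation-game payoffs valid), replaced slot
        uniform."""
        repro = self._weighted_draw(self._softmax_fitness())
        dead = int(self.rng.integers(self.N))
        self._replace_slot(dead, self.specs[repro])
        return self


# ---------------------------------------------------------------------------
# module-level operations


def play_generation(state: PopulationState) -> PopulationState:
    """One round-robin of single moves, with noise, payoffs and learning."""
    return state.play_generation()


def imitation_update(state: PopulationState) -> PopulationState:
    return state.imitation_update()


def moran_update(state: PopulationState) -> PopulationState:
    return state.moran_update()


def run_to_fixation(
    invader: PlayerSpec,
    resident: PlayerSpec,
    m0: int = 1,
    N: int = 100,
    epsilon: float = 0.05,
    sigma: float = 1.0,
    rule: str = "imitation",
    rng: Union[np.random.Generator, int, None] = None,
    matrix: GameMatrix = DEFAULT_MATRIX,
    max_generations: int = 1_000_000,
    record: Optional[list] = None,
) -> bool:
    """Simulate until one type is extinct; True if the invader fixed.

    Starts with ``m0`` invaders among ``N - m0`` residents and alternates
    :func:`play_generation` with one death/birth update per generation.
    ``record``, if given, accumulates ``(generation, invader_count)``
    pairs. Raises :class:`NonTerminationError` past ``max_generations``.
    """
    if not (1 <= m0 <= N - 1):
        raise ValueError(f"need 1 <= m0 <= N-1, got m0={m0}, N={N}")
    if rule not in ("imitation", "moran", "softmax_imitation"):
        raise ValueError(f"unknown update rule {rule!r}")
    if invader.type_name == resident.type_name:
        raise ValueError("invader and resident must have distinct type names")
    specs = [invader] * m0 + [resident] * (N - m0)
    state = PopulationState(specs, matrix=matrix, epsilon=epsilon, sigma=sigma, rng=rng)
    inv_name = invader.type_name
    while state.generation < max_generations:
        state.play_generation()
        if rule == "imitation":
            state.imitation_update()
        elif rule == "softmax_imitation":
            state.softmax_imitation_update()
        else:
            state.moran_update()
        m = sum(1 for s in state.specs if s.type_name == inv_name)
        if record is not None:
            record.append((state.generation, m))
        if m == 0:
            return False
        if m == N:
            return True
    raise NonTerminationError(
        f"no fixation after {max_generations} generations "
        f"({invader.type_name} vs {resident.type_name})"
    )
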