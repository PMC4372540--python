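"""Payoff matrices, move/outcome encodings, and the noise model.

Everything downstream (strategy algebra, the information player, the
evolutionary engine) shares the conventions fixed here:

* a move is cooperate (``C``) or defect (``D``);
* a joint outcome is always read from the focal player's perspective and
  indexed in the canonical order ``CC, CD, DC, DD`` = ``0, 1, 2, 3``;
* payoffs come from a :class:`GameMatrix` ``(R, S, T, P)``, by default the
  donation game built from a benefit ``b`` and cost ``c``.
"""

from __future__ import annotations

import enum
from typing import NamedTuple

import numpy as np

__all__ = [
    "Move",
    "Outcome",
    "GameMatrix",
    "donation_matrix",
    "payoff_pair",
    "apply_noise",
    "OUTCOMES",
    "swap_outcome",
    "SWAP",
]


class Move(enum.IntEnum):
    """A single play: cooperate or defect.

    The integer values (C=0, D=1) are used directly by the numeric engine;
    ``str(move)`` gives the canonical one-character form.
    """

    C = 0
    D = 1

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name

    def flipped(self) -> "Move":
        return Move(1 - self.value)

    @classmethod
    def from_char(cls, ch: str) -> "Move":
        try:
            return cls[ch]
        except KeyError:
            raise ValueError(f"not a move: {ch!r}") from None


class Outcome(enum.IntEnum):
    """Joint outcome of one round, from the focal player's perspective.

    The first letter is the focal player's move, the second the opponent's.
    The integer value is the canonical index used by all vectors/matrices.
    """

    CC = 0
    CD = 1
    DC = 2
    DD = 3

    @property
    def self_move(self) -> Move:
        return Move(self.value >> 1)

    @property
    def opp_move(self) -> Move:
        return Move(self.value & 1)

    @classmethod
    def from_moves(cls, self_move: Move, opp_move: Move) -> "Outcome":
        return cls(2 * int(self_move) + int(opp_move))

    def swapped(self) -> "Outcome":
        """The same round seen from the opponent's perspective (CD <-> DC)."""
        return Outcome(SWAP[self.value])


OUTCOMES = (Outcome.CC, Outcome.CD, Outcome.DC, Outcome.DD)

#: Perspective swap on outcome indices: CC, DC, CD, DD.
SWAP = np.array([0, 2, 1, 3])


def swap_outcome(index: int) -> int:
    """Perspective-swap an outcome *index* (CD <-> DC, CC/DD fixed)."""
    return int(SWAP[index])


class GameMatrix(NamedTuple):
    """Symmetric 2x2 game payoffs ``(R, S, T, P)``.

    ``R`` reward for mutual cooperation, ``S`` sucker's payoff, ``T``
    temptation, ``P`` punishment for mutual defection.
    """

    R: float
    S: float
    T: float
    P: float

    def is_prisoners_dilemma(self) -> bool:
        """Strict PD ordering ``T > R > P > S``."""
        return self.T > self.R > self.P > self.S

    @property
    def focal_payoffs(self) -> np.ndarray:
        """Payoff to the focal player per outcome ``(R, S, T, P)``."""
        return np.array([self.R, self.S, self.T, self.P], dtype=float)

    @property
    def opponent_payoffs(self) -> np.ndarray:
        """Payoff to the opponent per focal outcome ``(R, T, S, P)``."""
        return np.array([self.R, self.T, self.S, self.P], dtype=float)


def donation_matrix(b: float, c: float) -> GameMatrix:
    """Donation-game payoffs ``(R, S, T, P) = (b - c, -c, b, 0)``.

    A cooperator pays a cost ``c`` to confer a benefit ``b`` on its
    partner; ``0 < c < b`` is required for the game to be a Prisoner's
    Dilemma. The default game used throughout is ``donation_matrix(3, 1)``
    = ``(2, -1, 3, 0)``.
    """
    if not (0 < c < b):
        raise ValueError(f"donation game requires 0 < c < b, got b={b}, c={c}")
    return GameMatrix(R=b - c, S=-c, T=b, P=0.0)


#: Default game used across the package.
DEFAULT_MATRIX = donation_matrix(3, 1)


def payoff_pair(outcome: Outcome, matrix: GameMatrix) -> tuple[float, float]:
    """Payoffs ``(focal, opponent)`` for one round.

    ``CC -> (R, R)``, ``CD -> (S, T)``, ``DC -> (T, S)``, ``DD -> (P, P)``.
    """
    i = int(outcome)
    return (float(matrix.focal_payoffs[i]), float(matrix.opponent_payoffs[i]))


def apply_noise(move: Move, epsilon: float, rng: np.random.Generator) -> Move:
    """Flip ``move`` with probability ``epsilon``.

    Models the ambient execution error: a player's intended move is
    realised incorrectly with probability ``epsilon``. Consumes exactly one
    uniform draw from ``rng`` regardless of ``epsilon``.
    """
    if not (0.0 <= epsilon <= 0.5):
        raise ValueError(f"noise rate must be in [0, 1/2], got {epsilon}")
    flip = rng.random() < epsilon
    return Move(1 - int(move)) if flip else Move(int(move))
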