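"""Run-configuration parsing and the named strategy roster.

A run configuration (YAML or JSON) specifies the game matrix either as a
4-list ``[R, S, T, P]`` or as a donation-game ``{b, c}`` pair, and a
roster mapping strategy names to memory-one probability 4-lists, ZD
parameter triples ``{kappa, chi, phi}``, or builtin named players.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

import yaml

from .frequency import TagStrategyPair
from .games import DEFAULT_MATRIX, GameMatrix, Move, donation_matrix
from .infoplayer import IPConfig
from .memory_one import ALLC, ALLD, TFT, WSLS, ZDParams, zd_strategy
from .population import (
    PlayerSpec,
    conswitch_player,
    ip0_player,
    memory_one_player,
    tag_player,
)

__all__ = ["parse_matrix", "named_player", "parse_roster", "load_run_config", "BUILTIN_NAMES"]

BUILTIN_NAMES = ("ALLC", "ALLD", "TFT", "WSLS", "ZDR", "ZDX", "ConDef", "ZDT", "ConSwitch", "IP0")


def parse_matrix(obj) -> GameMatrix:
    """Game matrix from a 4-list ``[R, S, T, P]`` or a ``{b, c}`` mapping."""
    if obj is None:
        return DEFAULT_MATRIX
    if isinstance(obj, Mapping):
        return donation_matrix(float(obj["b"]), float(obj["c"]))
    vals = [float(x) for x in obj]
    if len(vals) != 4:
        raise ValueError(f"matrix must have 4 payoffs (R,S,T,P), got {vals}")
    return GameMatrix(*vals)


def named_player(name: str, matrix: GameMatrix = DEFAULT_MATRIX) -> PlayerSpec:
    """Builtin player by conventional name.

    ZDR is the generous zero-determinant strategy (kappa = R), ZDX the
    extortionate one (kappa = P), both with chi = 1/2, phi = 0.1. ConDef
    and ZDT are tag-based idealisations; ConSwitch is the tag-based
    information player; IP0 the full inference player.
    """
    key = name.upper()
    if key == "ALLC":
        return memory_one_player("ALLC", ALLC, Move.C)
    if key == "ALLD":
        return memory_one_player("ALLD", ALLD, Move.D)
    if key == "TFT":
        return memory_one_player("TFT", TFT, Move.C)
    if key == "WSLS":
        return memory_one_player("WSLS", WSLS, Move.C)
    if key == "ZDR":
        return memory_one_player(
            "ZDR", zd_strategy(ZDParams(matrix.R, 0.5, 0.1), matrix), Move.C
        )
    if key in ("ZDX", "ZD_CHI", "ZDCHI"):
        return memory_one_player(
            "ZDX", zd_strategy(ZDParams(matrix.P, 0.5, 0.1), matrix), Move.C
        )
    if key == "CONDEF":
        return tag_player("ConDef", TagStrategyPair(vs_self=ALLC, vs_other=ALLD), Move.C)
    if key in ("ZDT", "ZD_T"):
        zd = zd_strategy(ZDParams(matrix.R, 0.5, 0.1), matrix)
        return tag_player("ZDT", TagStrategyPair(vs_self=ALLC, vs_other=zd), Move.C)
    if key == "CONSWITCH":
        return conswitch_player("ConSwitch")
    if key == "IP0":
        return ip0_player("IP0")
    raise KeyError(f"unknown builtin player {name!r}")


def parse_roster(obj: Mapping, matrix: GameMatrix) -> dict[str, PlayerSpec]:
    """Roster mapping: name -> 4-list, ZD triple, builtin alias, or kind tag."""
    roster: dict[str, PlayerSpec] = {}
    for name, payload in obj.items():
        if payload is None or payload == "builtin":
            roster[name] = named_player(name, matrix)
        elif isinstance(payload, str):
            spec = named_player(payload, matrix)
            roster[name] = PlayerSpec(
                type_name=name,
                kind=spec.kind,
                vector=spec.vector,
                tag_pair=spec.tag_pair,
                ip_config=spec.ip_config,
                first_move=spec.first_move,
            )
        elif isinstance(payload, Mapping):
            if "kappa" in payload:
                params = ZDParams(
                    float(payload["kappa"]), float(payload["chi"]), float(payload["phi"])
                )
                roster[name] = memory_one_player(name, zd_strategy(params, matrix))
            elif payload.get("kind") == "ip0":
                roster[name] = ip0_player(name, _ip_config(payload))
            elif payload.get("kind") == "conswitch":
                roster[name] = conswitch_player(name, _ip_config(payload))
            else:
                raise ValueError(f"cannot parse roster entry {name}: {payload}")
        else:
            first = Move.D if name.upper() == "ALLD" else Move.C
            roster[name] = memory_one_player(name, [float(x) for x in payload], first)
    return roster


def _ip_config(payload: Mapping) -> IPConfig:
    kwargs = {
        k: payload[k]
        for k in ("infogain_length", "alpha", "hmm_switch", "epsilon", "N")
        if k in payload
    }
    return IPConfig(**kwargs)


def load_run_config(path: Union[str, Path]) -> dict:
    """Load a YAML/JSON run configuration file.

    Returns a dict with keys ``matrix`` (GameMatrix), ``roster`` (name ->
    PlayerSpec), and the scalar run parameters with defaults filled in
    (``N`` 100, ``epsilon`` 0.05, ``sigma`` 1.0, ``rule`` imitation,
    ``n_sims`` 1000, ``m0`` 1, ``seed`` 0, ``max_generations`` 1e6).
    """
    raw = yaml.safe_load(Path(path).read_text())
    matrix = parse_matrix(raw.get("matrix"))
    roster = parse_roster(raw.get("roster", {}), matrix)
    return {
        "matrix": matrix,
        "roster": roster,
        "N": int(raw.get("N", 100)),
        "m0": int(raw.get("m0", 1)),
        "epsilon": float(raw.get("epsilon", 0.05)),
        "sigma": float(raw.get("sigma", 1.0)),
        "rule": raw.get("rule", "imitation"),
        "n_sims": int(raw.get("n_sims", 1000)),
        "seed": int(raw.get("seed", 0)),
        "max_generations": int(raw.get("max_generations", 1_000_000)),
    }
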