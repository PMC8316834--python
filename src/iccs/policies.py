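"""Decision policies (agents) for the simulator.

A policy is any callable ``(state, rng, params) -> Decision``.  The rng a
policy receives is a stream independent of the environment's, so policy
randomness never shifts environmental sampling.

Three built-ins are provided:

* :class:`RandomPolicy` — the benchmark agent of the Monte-Carlo
  comparison: each insurance scheme is bought with probability 0.5, then a
  uniformly random fraction of the post-premium income goes to mitigation.
* :class:`ConstantPolicy` — invests a fixed fraction every trial; handy for
  closed-form checks (fraction 0 forces p = 1, fraction 1 forces p = 1 - m).
* :class:`ScriptedPolicy` — replays an explicit per-trial decision table,
  e.g. the decision columns of a previously written game log.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .model import Decision, GameState
from .params import ModelParams, SCHEMES

_AFFORD_TOL = 1e-9

#: Decision columns a scripted policy needs, in the game-log schema.
DECISION_COLUMNS = ("mitigation_amount", "buy_health", "buy_life", "buy_property")


class RandomPolicy:
    """Buy each scheme with probability 0.5, then mitigate U(0, remaining).

    Schemes are considered in the fixed order health, life, property; a
    successful coin flip whose premium is unaffordable is skipped (the draw
    is still consumed, keeping the draw-count contract simple).  Exactly
    four uniform draws are consumed per call.
    """

    def __call__(
        self, state: GameState, rng: np.random.Generator, params: ModelParams
    ) -> Decision:
        remaining = state.annual_income
        buys = []
        for premium in params.premiums:
            wants = rng.random() < 0.5
            if wants and premium <= remaining + _AFFORD_TOL:
                buys.append(True)
                remaining -= premium
            else:
                buys.append(False)
        mitigation = rng.random() * max(remaining, 0.0)
        return Decision(mitigation, *buys)


class ConstantPolicy:
    """Invest a fixed fraction of post-premium income every trial.

    ``fraction`` must lie in [0, 1].  Requested schemes are bought whenever
    affordable, in the order health, life, property.  Deterministic: the
    rng argument is accepted but never drawn from.
    """

    def __init__(
        self,
        fraction: float,
        *,
        buy_health: bool = False,
        buy_life: bool = False,
        buy_property: bool = False,
    ) -> None:
        if not (0.0 <= fraction <= 1.0):
            raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
        self.fraction = float(fraction)
        self.buy_flags = (bool(buy_health), bool(buy_life), bool(buy_property))

    def __call__(
        self, state: GameState, rng: np.random.Generator, params: ModelParams
    ) -> Decision:
        remaining = state.annual_income
        buys = []
        for flag, premium in zip(self.buy_flags, params.premiums):
            if flag and premium <= remaining + _AFFORD_TOL:
                buys.append(True)
                remaining -= premium
            else:
                buys.append(False)
        return Decision(self.fraction * max(remaining, 0.0), *buys)


class ScriptedPolicy:
    """Replay an explicit decision table, one row per trial (1-based order).

    The table must carry the game-log decision columns
    ``mitigation_amount, buy_health, buy_life, buy_property``.  If
    ``params`` is given at construction, the row count is checked against
    ``total_trials`` immediately; affordability is enforced per trial by
    the simulator, which reports the offending trial index.
    """

    def __init__(
        self, table: pd.DataFrame, params: ModelParams | None = None
    ) -> None:
        missing = [c for c in DECISION_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"decision table is missing column(s): {', '.join(missing)}")
        if params is not None and len(table) != params.total_trials:
            raise ValueError(
                f"decision table has {len(table)} rows but the game has "
                f"{params.total_trials} trials"
            )
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_gamelog(cls, log, params: ModelParams | None = None) -> "ScriptedPolicy":
        """Replay the decisions of a previously recorded game log."""
        return cls(log.table[list(DECISION_COLUMNS)].copy(), params)

    def __call__(
        self, state: GameState, rng: np.random.Generator, params: ModelParams
    ) -> Decision:
        i = state.trial_index - 1
        if i >= len(self.table):
            raise ValueError(
                f"decision table has {len(self.table)} rows but trial "
                f"{state.trial_index} was requested"
            )
        row = self.table.iloc[i]
        return Decision(
            float(row["mitigation_amount"]),
            bool(row["buy_health"]),
            bool(row["buy_life"]),
            bool(row["buy_property"]),
        )


# -- spec-style factory functions -------------------------------------------


def random_policy() -> RandomPolicy:
    return RandomPolicy()


def constant_policy(
    mitigation_fraction: float,
    buy_health: bool = False,
    buy_life: bool = False,
    buy_property: bool = False,
) -> ConstantPolicy:
    return ConstantPolicy(
        mitigation_fraction,
        buy_health=buy_health,
        buy_life=buy_life,
        buy_property=buy_property,
    )


def scripted_policy(
    decision_table: pd.DataFrame, params: ModelParams | None = None
) -> ScriptedPolicy:
    return ScriptedPolicy(decision_table, params)


def make_policy(name: str, options: Mapping[str, str] | None = None):
    """Build a named policy from string options (the CLI entry point).

    ``random`` takes no options; ``constant`` takes ``fraction`` and the
    three ``buy_*`` flags; ``scripted`` takes ``path`` to a decision CSV.
    """
    options = dict(options or {})
    if name == "random":
        if options:
            raise ValueError(f"random policy takes no options, got {sorted(options)}")
        return RandomPolicy()
    if name == "constant":
        fraction = float(options.pop("fraction", 0.0))
        flags = {}
        for key in ("buy_health", "buy_life", "buy_property"):
            if key in options:
                flags[key] = options.pop(key).lower() in ("1", "true", "yes")
        if options:
            raise ValueError(f"unknown constant-policy option(s): {sorted(options)}")
        return ConstantPolicy(fraction, **flags)
    if name == "scripted":
        path = options.pop("path", None)
        if path is None or options:
            raise ValueError("scripted policy requires exactly one option: path=FILE")
        return ScriptedPolicy(pd.read_csv(path, comment="#"))
    raise ValueError(f"unknown policy {name!r}; available: random, constant, scripted")
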