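"""Investment-ratio metrics derived from game logs.

Six per-trial dependent variables, each a fraction of the money available
to invest at that instance (the trial's annual income before any spend):

* ``mitigation_ratio`` — mitigation spend / available income
* ``total_insurance_ratio`` — premiums paid / available income
* ``total_investment_ratio`` — (mitigation + premiums) / available income
* ``health_insurance_ratio``, ``life_insurance_ratio``,
  ``property_insurance_ratio`` — 0/1 buy flags per trial

The three monetary ratios share the same denominator within a trial, so
``total_investment_ratio = mitigation_ratio + total_insurance_ratio``
holds exactly up to floating-point round-off.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import GameLog
from .params import ModelParams

RATIO_COLUMNS = (
    "total_investment_ratio",
    "mitigation_ratio",
    "total_insurance_ratio",
    "property_insurance_ratio",
    "health_insurance_ratio",
    "life_insurance_ratio",
)

_TOL = 1e-6


class IntegrityError(ValueError):
    """A log's spending is inconsistent with its available income."""


def compute_ratios(
    log: GameLog | pd.DataFrame,
    params: ModelParams | None = None,
    *,
    game_id: str | int | None = None,
) -> pd.DataFrame:
    """Per-trial ratio table for one game.

    Accepts a :class:`GameLog` (parameters and identifiers taken from its
    metadata) or a bare log table plus ``params``.  Raises
    :class:`IntegrityError` if any trial spends more than its available
    income, or spends with zero income available.
    """
    if isinstance(log, GameLog):
        table = log.table
        if params is None:
            params = ModelParams.from_dict(log.meta["params"])
        if game_id is None:
            game_id = log.meta.get("seed", 0)
        condition = log.meta.get("condition", "")
    else:
        table = log
        if params is None:
            raise ValueError("params required when passing a bare log table")
        if game_id is None:
            game_id = 0
        condition = str(table["condition"].iloc[0]) if "condition" in table else ""

    income = table["annual_income"].to_numpy(dtype=float)
    mitigation = table["mitigation_amount"].to_numpy(dtype=float)
    premiums = table["premiums_paid"].to_numpy(dtype=float)
    spend = mitigation + premiums

    bad = spend > income + _TOL
    if bad.any():
        t = int(table["trial"].to_numpy()[bad][0])
        raise IntegrityError(
            f"trial {t}: spend {spend[bad][0]:.2f} EC exceeds available income "
            f"{income[bad][0]:.2f} EC"
        )
    zero_spend = (income <= 0) & (spend > 0)
    if zero_spend.any():
        t = int(table["trial"].to_numpy()[zero_spend][0])
        raise IntegrityError(f"trial {t}: nonzero spend with zero available income")

    safe_income = np.where(income > 0, income, 1.0)
    mit_ratio = np.where(income > 0, mitigation / safe_income, 0.0)
    ins_ratio = np.where(income > 0, premiums / safe_income, 0.0)
    return pd.DataFrame(
        {
            "game_id": game_id,
            "condition": condition,
            "trial": table["trial"].to_numpy(),
            "total_investment_ratio": np.where(
                income > 0, spend / safe_income, 0.0
            ),
            "mitigation_ratio": mit_ratio,
            "total_insurance_ratio": ins_ratio,
            "property_insurance_ratio": table["buy_property"].to_numpy(dtype=float),
            "health_insurance_ratio": table["buy_health"].to_numpy(dtype=float),
            "life_insurance_ratio": table["buy_life"].to_numpy(dtype=float),
        }
    )


def summarize(
    tables: Iterable[pd.DataFrame] | pd.DataFrame,
    *,
    by: str = "condition",
    labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate ratio tables into condition means.

    Returns ``(group_means, per_trial_means)``:

    * ``group_means`` — one row per group; each ratio is the mean over
      games of that game's mean over trials (games weigh equally even if
      trial counts differ).
    * ``per_trial_means`` — per group and trial index, the mean ratio over
      games, for trajectory plots.

    ``labels`` optionally restricts (and validates) the groups.
    """
    if isinstance(tables, pd.DataFrame):
        data = tables
    else:
        tables = list(tables)
        if not tables:
            raise ValueError("no ratio tables given")
        data = pd.concat(tables, ignore_index=True)
    if data.empty:
        raise ValueError("ratio data is empty")
    if by not in data.columns:
        raise ValueError(f"grouping column {by!r} not present in ratio data")
    if labels is not None:
        available = sorted(map(str, data[by].unique()))
        missing = [l for l in labels if l not in available]
        if missing:
            raise KeyError(
                f"group label(s) {missing} not found; available: {available}"
            )
        data = data[data[by].astype(str).isin(labels)]

    cols = list(RATIO_COLUMNS)
    per_game = data.groupby([by, "game_id"], sort=True)[cols].mean()
    group_means = per_game.groupby(level=0, sort=True).mean().reset_index()
    per_trial_means = (
        data.groupby([by, "trial"], sort=True)[cols].mean().reset_index()
    )
    return group_means, per_trial_means


def investment_anova(
    ratios: pd.DataFrame, dv: str = "total_investment_ratio"
) -> pd.DataFrame:
    """Convenience mixed-design ANOVA (between: condition, within: trial).

    Thin wrapper over ``pingouin.mixed_anova``; requires the ``stats``
    extra.  Provided for exploratory reports on simulated cohorts only.
    """
    import pingouin  # deferred: optional dependency

    return pingouin.mixed_anova(
        data=ratios, dv=dv, within="trial", subject="game_id", between="condition"
    )
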