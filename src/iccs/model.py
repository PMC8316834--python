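"""Core state machine of the climate-risk microworld.

A single participant plays ``T`` yearly trials.  Each year they split an
annual income between mitigation (which lowers the endogenous probability
of a climate disaster), insurance premiums (which attenuate the monetary
loss if a disaster strikes), and uninvested cash.  The disaster probability
is a function of the cumulative mitigation share:

    p = 1 - m * (sum of mitigation investments / sum of incomes) ** k

so a player who never mitigates faces ``p = 1`` and a player who invests
every EC faces ``p = 1 - m``.  A disaster, once sampled, takes one of three
types (cyclone, drought, flood) and can inflict injury, fatality, and
property damage independently; droughts never cause property damage.
Uninsured losses are fixed fractions of the current income (injury 12.5%,
fatality 25%) or of the property wealth (property 50%).  If the matching
insurance is active, the loss percentage is instead

    r = min((100 / T) * number of purchases so far, cap)

with per-mode caps — buying insurance early in the game attenuates losses
strongly, and the attenuated percentage grows with every further purchase.

The randomness contract is explicit: every stochastic step consumes a fixed,
documented number of ``rng.random()`` draws (one for occurrence; if a
disaster occurs, one for its type, then one per applicable damage mode in
the order injury, fatality, property — property is skipped for droughts).
Seeded runs are therefore bit-reproducible and replayable.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .params import DAMAGE_MODES, DISASTER_TYPES, MODE_INDEX, SCHEMES, ModelParams

#: Versioned game-log schema: bump when LOG_COLUMNS changes.
GAMELOG_SCHEMA_VERSION = 1

#: Fixed column order of a game log (one row per trial).
LOG_COLUMNS = (
    "trial",
    "p",
    "mitigation_amount",
    "buy_health",
    "buy_life",
    "buy_property",
    "premiums_paid",
    "occurred",
    "disaster_type",
    "damage_injury",
    "damage_fatality",
    "damage_property",
    "loss_injury",
    "loss_fatality",
    "loss_property",
    "annual_income",
    "property_wealth",
    "uninvested_cash",
    "total_wealth",
    "seed",
    "condition",
)

_AFFORD_TOL = 1e-9


class InvalidStateError(ValueError):
    """The game state violates a precondition (e.g. zero cumulative income)."""


class BudgetError(ValueError):
    """A decision spends more than the remaining annual income allows."""


@dataclasses.dataclass
class GameState:
    """Evolving per-participant state.

    ``annual_income`` is the current year's income budget; injury and
    fatality losses reduce it permanently, so later years are granted the
    reduced amount.  ``cum_income`` accumulates each year's budget at the
    moment it is granted and is the denominator of the probability curve.
    """

    trial_index: int
    annual_income: float
    uninvested_cash: float
    property_wealth: float
    cum_mitigation_investment: float
    cum_income: float
    insurance_purchase_counts: tuple[int, int, int]
    insured_this_trial: tuple[bool, bool, bool]

    @property
    def total_wealth(self) -> float:
        return self.uninvested_cash + self.property_wealth

    def copy(self) -> "GameState":
        return dataclasses.replace(self)


@dataclasses.dataclass(frozen=True)
class Decision:
    """One trial's investment choice: a mitigation amount plus three
    insurance buy flags (health, life, property)."""

    mitigation_amount: float
    buy_health: bool = False
    buy_life: bool = False
    buy_property: bool = False

    @property
    def buys(self) -> tuple[bool, bool, bool]:
        return (bool(self.buy_health), bool(self.buy_life), bool(self.buy_property))

    def premium_total(self, params: ModelParams) -> float:
        return float(sum(p for p, b in zip(params.premiums, self.buys) if b))


@dataclasses.dataclass(frozen=True)
class TrialOutcome:
    """Everything sampled and deducted in one trial."""

    probability: float
    occurred: bool
    disaster_type: str  # one of DISASTER_TYPES or "none"
    damages: tuple[bool, bool, bool]  # (injury, fatality, property)
    losses: tuple[float, float, float]  # EC deducted per mode
    loss_percent_applied: tuple[float, float, float]  # percent used per damaged mode


@dataclasses.dataclass
class GameLog:
    """Full per-trial record of one game: a tidy table plus provenance."""

    table: pd.DataFrame
    meta: dict

    def __len__(self) -> int:
        return len(self.table)


def initial_state(params: ModelParams) -> GameState:
    """Fresh state with year 1's income already granted into ``cum_income``."""
    return GameState(
        trial_index=1,
        annual_income=float(params.initial_annual_income),
        uninvested_cash=0.0,
        property_wealth=float(params.initial_property_wealth),
        cum_mitigation_investment=0.0,
        cum_income=float(params.initial_annual_income),
        insurance_purchase_counts=(0, 0, 0),
        insured_this_trial=(False, False, False),
    )


# ---------------------------------------------------------------------------
# Probability and attenuation
# ---------------------------------------------------------------------------


def climate_probability(state: GameState, params: ModelParams) -> float:
    """Endogenous disaster probability ``p = 1 - m * share**k``.

    ``share`` is the cumulative mitigation investment divided by the
    cumulative income granted so far.  The result is clamped to [0, 1]
    defensively; with valid parameters it already lies in [1 - m, 1].
    """
    if state.cum_income <= 0.0:
        raise InvalidStateError(
            "cumulative income is zero; the year-1 income must be granted "
            "before the first probability computation"
        )
    share = state.cum_mitigation_investment / state.cum_income
    p = 1.0 - params.mitigation_return * share**params.probability_exponent
    return min(1.0, max(0.0, p))


def attenuated_loss_percent(
    purchase_count: int, params: ModelParams, mode: str
) -> float:
    """Insured loss percentage: ``min((100 / T) * purchases, cap[mode])``.

    The percentage *grows* with the number of times the scheme was bought:
    5 property purchases in a 36-year game give (5/36)*100 = 13.888...%
    of the property wealth lost instead of the uninsured 50%.
    """
    if purchase_count < 0:
        raise ValueError(f"purchase_count must be >= 0, got {purchase_count}")
    cap = params.insured_loss_caps_percent[MODE_INDEX[mode]]
    return min((100.0 / params.total_trials) * purchase_count, cap)


# ---------------------------------------------------------------------------
# Sampling (each call consumes a documented number of uniform draws)
# ---------------------------------------------------------------------------


def sample_occurrence(p: float, rng: np.random.Generator) -> bool:
    """One uniform draw; a disaster occurs iff ``p >= u``."""
    u = rng.random()
    return p >= u


def sample_disaster_type(rng: np.random.Generator, params: ModelParams) -> str:
    """One uniform draw against cumulative thresholds in the fixed order
    cyclone, drought, flood (u < 0.33 -> cyclone, u < 0.66 -> drought, ...)."""
    u = rng.random()
    acc = 0.0
    for dtype, prob in zip(DISASTER_TYPES, params.disaster_type_probs):
        acc += prob
        if u < acc:
            return dtype
    return DISASTER_TYPES[-1]  # guard against float round-off at u ~ 1


def sample_damages(
    disaster_type: str, rng: np.random.Generator, params: ModelParams
) -> tuple[bool, bool, bool]:
    """Sample damage flags independently per mode, order injury/fatality/property.

    A mode is damaged iff ``u <= damage_prob``.  Droughts never cause
    property damage and consume no draw for it (two draws instead of three).
    """
    if disaster_type not in DISASTER_TYPES:
        raise ValueError(f"unknown disaster_type {disaster_type!r}")
    flags = []
    for i, mode in enumerate(DAMAGE_MODES):
        if mode == "property" and disaster_type == "drought":
            flags.append(False)
            continue
        u = rng.random()
        flags.append(u <= params.damage_probs[i])
    return tuple(flags)


# ---------------------------------------------------------------------------
# Loss accounting
# ---------------------------------------------------------------------------


def apply_losses(
    state: GameState,
    damages: Sequence[bool],
    params: ModelParams,
) -> tuple[GameState, tuple[float, float, float], tuple[float, float, float]]:
    """Deduct monetary losses for each damaged mode; mutates ``state``.

    Injury and fatality losses are percentages of the *same* pre-loss annual
    income; both are deducted from uninvested cash and permanently lower the
    income level for all later years.  Property losses are a percentage of
    the current property wealth.  If the matching insurance is active this
    trial, the attenuated percentage replaces the base one.

    Returns ``(state, losses, percents_applied)``.
    """
    income_base = state.annual_income
    losses = [0.0, 0.0, 0.0]
    pcts = [0.0, 0.0, 0.0]
    income_loss = 0.0
    for i, mode in enumerate(DAMAGE_MODES):
        if not damages[i]:
            continue
        if state.insured_this_trial[i]:
            pct = attenuated_loss_percent(
                state.insurance_purchase_counts[i], params, mode
            )
        else:
            pct = params.base_loss_fractions[i] * 100.0
        base = state.property_wealth if mode == "property" else income_base
        loss = (pct / 100.0) * base
        losses[i] = loss
        pcts[i] = pct
        if mode == "property":
            state.property_wealth -= loss
        else:
            state.uninvested_cash -= loss
            income_loss += loss
    state.annual_income = income_base - income_loss
    return state, tuple(losses), tuple(pcts)


# ---------------------------------------------------------------------------
# Trial transition and full game
# ---------------------------------------------------------------------------


def validate_decision(
    decision: Decision, state: GameState, params: ModelParams
) -> None:
    """Affordability check: mitigation + premiums <= remaining annual income."""
    if decision.mitigation_amount < 0 or not np.isfinite(decision.mitigation_amount):
        raise BudgetError(
            f"mitigation_amount must be finite and >= 0, got {decision.mitigation_amount}"
        )
    cost = decision.mitigation_amount + decision.premium_total(params)
    if cost > state.annual_income + _AFFORD_TOL:
        raise BudgetError(
            f"decision costs {cost:.2f} EC but only {state.annual_income:.2f} EC "
            f"of annual income remains (shortfall {cost - state.annual_income:.2f} EC)"
        )


def step_trial(
    state: GameState,
    decision: Decision,
    rng: np.random.Generator,
    params: ModelParams,
) -> tuple[GameState, TrialOutcome]:
    """Execute one year and return ``(new_state, outcome)``.

    Order of operations: (1) pay premiums, increment purchase counts, set
    coverage; (2) invest in mitigation; (3) bank the remaining income;
    (4) compute the disaster probability; (5) sample occurrence, type, and
    damages; (6) deduct losses; (7) advance the year, grant next year's
    (possibly reduced) income, and roll the coverage window.
    The input state is not modified.
    """
    validate_decision(decision, state, params)
    s = state.copy()
    buys = decision.buys

    # (1) insurance purchases
    premiums_paid = decision.premium_total(params)
    s.insurance_purchase_counts = tuple(
        c + int(b) for c, b in zip(s.insurance_purchase_counts, buys)
    )
    if params.coverage_window == "current":
        s.insured_this_trial = buys
    # "next": coverage flags were set from the previous trial's purchases

    # (2) mitigation, (3) bank the rest
    s.cum_mitigation_investment += decision.mitigation_amount
    s.uninvested_cash += s.annual_income - premiums_paid - decision.mitigation_amount

    # (4) endogenous probability, (5) environmental sampling
    p = climate_probability(s, params)
    occurred = sample_occurrence(p, rng)
    if occurred:
        dtype = sample_disaster_type(rng, params)
        damages = sample_damages(dtype, rng, params)
    else:
        dtype = "none"
        damages = (False, False, False)

    # (6) losses
    s, losses, pcts = apply_losses(s, damages, params)
    outcome = TrialOutcome(
        probability=p,
        occurred=occurred,
        disaster_type=dtype,
        damages=damages,
        losses=losses,
        loss_percent_applied=pcts,
    )

    # (7) next year
    s.trial_index += 1
    s.insured_this_trial = buys if params.coverage_window == "next" else (False, False, False)
    if s.trial_index <= params.total_trials:
        s.cum_income += s.annual_income
    return s, outcome


Policy = Callable[[GameState, np.random.Generator, ModelParams], Decision]


def run_game(
    policy: Policy,
    params: ModelParams,
    seed: int | np.random.SeedSequence,
    *,
    condition: str = "",
    seed_label: str | int | None = None,
) -> GameLog:
    """Play a full game and return its :class:`GameLog`.

    ``seed`` spawns two independent sub-streams: one for the environment
    (occurrence/type/damage sampling) and one for the policy, so policy
    randomness never perturbs environmental sampling.  ``seed_label`` is
    what gets written into the log's seed column (defaults to ``seed``).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    env_ss, pol_ss = ss.spawn(2)
    env_rng = np.random.default_rng(env_ss)
    pol_rng = np.random.default_rng(pol_ss)
    if seed_label is None:
        seed_label = seed if isinstance(seed, int) else str(ss.entropy)

    state = initial_state(params)
    rows = []
    for trial in range(1, params.total_trials + 1):
        budget = state.annual_income
        try:
            decision = policy(state, pol_rng, params)
            state, outcome = step_trial(state, decision, env_rng, params)
        except (BudgetError, InvalidStateError, ValueError) as exc:
            raise type(exc)(f"trial {trial}: {exc}") from exc
        rows.append(
            {
                "trial": trial,
                "p": outcome.probability,
                "mitigation_amount": decision.mitigation_amount,
                "buy_health": int(decision.buy_health),
                "buy_life": int(decision.buy_life),
                "buy_property": int(decision.buy_property),
                "premiums_paid": decision.premium_total(params),
                "occurred": int(outcome.occurred),
                "disaster_type": outcome.disaster_type,
                "damage_injury": int(outcome.damages[0]),
                "damage_fatality": int(outcome.damages[1]),
                "damage_property": int(outcome.damages[2]),
                "loss_injury": outcome.losses[0],
                "loss_fatality": outcome.losses[1],
                "loss_property": outcome.losses[2],
                "annual_income": budget,
                "property_wealth": state.property_wealth,
                "uninvested_cash": state.uninvested_cash,
                "total_wealth": state.total_wealth,
                "seed": seed_label,
                "condition": condition,
            }
        )
    table = pd.DataFrame(rows, columns=list(LOG_COLUMNS))
    meta = {
        "schema_version": GAMELOG_SCHEMA_VERSION,
        "seed": seed_label,
        "condition": condition,
        "params": params.to_dict(),
    }
    return GameLog(table=table, meta=meta)
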