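"""Model parameters for the climate-risk microworld.

All fixed constants of the simulator live in :class:`ModelParams`: the
probability-curve parameters (mitigation return ``m`` and exponent ``k``),
the disaster-type and damage-mode probabilities, the uninsured loss
fractions, the insured-loss caps, and the insurance premiums.  Defaults are
the study conditions of the 36-year game: an annual income of 8,760 EC, a
property wealth of 5,000,000 EC, disaster chances of 33/33/34% for
cyclone/drought/flood, and damage chances of 30/9/50% for
injury/fatality/property.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any

#: Disaster types, in the fixed categorical-sampling order.
DISASTER_TYPES = ("cyclone", "drought", "flood")

#: Damage modes, in the fixed sampling order.  Index-aligned with SCHEMES:
#: health insurance covers injury, life covers fatality, property covers
#: property damage.
DAMAGE_MODES = ("injury", "fatality", "property")

#: Insurance schemes, index-aligned with DAMAGE_MODES.
SCHEMES = ("health", "life", "property")

MODE_INDEX = {m: i for i, m in enumerate(DAMAGE_MODES)}
SCHEME_INDEX = {s: i for i, s in enumerate(SCHEMES)}

COVERAGE_WINDOWS = ("current", "next")

_PROB_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Immutable bundle of every model constant.

    Parameters
    ----------
    total_trials
        Number of game years ``T`` (default 36).
    mitigation_return
        Return on mitigation ``m`` in (0, 1]; default 0.85.
    probability_exponent
        Exponent ``k`` of the probability curve; 1 gives the linear (low
        probability) condition, 3 the cubic (high probability) one.
    initial_annual_income
        Starting yearly income budget in EC; default 8,760.
    initial_property_wealth
        Starting property wealth in EC; default 5,000,000.
    disaster_type_probs
        (cyclone, drought, flood) occurrence chances given a disaster;
        must sum to 1.
    damage_probs
        (injury, fatality, property) per-mode damage chances given a
        disaster.
    base_loss_fractions
        Uninsured loss fractions (injury: of current annual income,
        fatality: of current annual income, property: of property wealth).
    insured_loss_caps_percent
        Upper limits on the attenuated loss percentage per mode.
    premiums
        (health, life, property) premium in EC per scheme per trial.
    coverage_window
        "current": a scheme bought in trial t covers trial t's outcome;
        "next": it covers trial t+1's outcome instead.
    """

    total_trials: int = 36
    mitigation_return: float = 0.85
    probability_exponent: float = 1.0
    initial_annual_income: float = 8760.0
    initial_property_wealth: float = 5_000_000.0
    disaster_type_probs: tuple[float, float, float] = (0.33, 0.33, 0.34)
    damage_probs: tuple[float, float, float] = (0.30, 0.09, 0.50)
    base_loss_fractions: tuple[float, float, float] = (0.125, 0.25, 0.50)
    insured_loss_caps_percent: tuple[float, float, float] = (10.0, 20.0, 50.0)
    premiums: tuple[float, float, float] = (365.0, 365.0, 365.0)
    coverage_window: str = "current"

    def __post_init__(self) -> None:
        for name in (
            "disaster_type_probs",
            "damage_probs",
            "base_loss_fractions",
            "insured_loss_caps_percent",
            "premiums",
        ):
            value = tuple(float(v) for v in getattr(self, name))
            if len(value) != 3:
                raise ValueError(f"{name} must have exactly 3 entries, got {len(value)}")
            object.__setattr__(self, name, value)
        object.__setattr__(self, "total_trials", int(self.total_trials))
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated invariant."""
        if self.total_trials < 1:
            raise ValueError(f"total_trials must be >= 1, got {self.total_trials}")
        if not (0.0 < self.mitigation_return <= 1.0):
            raise ValueError(
                f"mitigation_return must be in (0, 1], got {self.mitigation_return}"
            )
        if not (self.probability_exponent > 0):
            raise ValueError(
                f"probability_exponent must be > 0, got {self.probability_exponent}"
            )
        for name in ("initial_annual_income", "initial_property_wealth"):
            if not (getattr(self, name) >= 0) or not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("disaster_type_probs", "damage_probs"):
            for v in getattr(self, name):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name} entries must lie in [0, 1], got {v}")
        if abs(sum(self.disaster_type_probs) - 1.0) > 1e-6:
            raise ValueError(
                "disaster_type_probs must sum to 1, got "
                f"{sum(self.disaster_type_probs)!r}"
            )
        for v in self.base_loss_fractions:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"base_loss_fractions entries must lie in [0, 1], got {v}")
        for v in self.insured_loss_caps_percent:
            if not (0.0 <= v <= 100.0):
                raise ValueError(
                    f"insured_loss_caps_percent entries must lie in [0, 100], got {v}"
                )
        for v in self.premiums:
            if v < 0:
                raise ValueError(f"premiums must be >= 0, got {v}")
        if self.coverage_window not in COVERAGE_WINDOWS:
            raise ValueError(
                f"coverage_window must be one of {COVERAGE_WINDOWS}, "
                f"got {self.coverage_window!r}"
            )

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParams":
        """Build from a mapping (e.g. a parsed YAML/JSON file).

        Unknown keys are rejected so typos in config files fail loudly.
        """
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown parameter key(s): {', '.join(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields changed (unknown keys rejected)."""
        known = {f.name for f in dataclasses.fields(self)}
        unknown = sorted(set(changes) - known)
        if unknown:
            raise ValueError(f"unknown parameter key(s): {', '.join(unknown)}")
        return dataclasses.replace(self, **changes)

    # -- convenience constructors for the two study conditions ----------------

    @classmethod
    def linear(cls, **changes: Any) -> "ModelParams":
        """Default parameters with the linear (k=1) probability curve."""
        return cls(**{"probability_exponent": 1.0, **changes})

    @classmethod
    def cubic(cls, **changes: Any) -> "ModelParams":
        """Default parameters with the cubic (k=3) probability curve."""
        return cls(**{"probability_exponent": 3.0, **changes})
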