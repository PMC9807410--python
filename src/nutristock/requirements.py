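"""Scenario configuration and demographically weighted nutrient requirements.

The required amount of a nutrient for a stockpile scenario is the
population-weighted mean of the per-day reference values over the
municipality's sex × age-group strata,

    r_n = Σ_s c_s · DRI[n, s] / Σ_s c_s ,

multiplied by the estimated number of victims and the number of days the
stockpile must cover:

    R_n = r_n · V · D ,   V = rounding(f · P)

with affected fraction f (default 20 %), days D (default 3) and total
population P.  The rounding rule for V defaults to ceiling — conservative
for relief planning — and is configurable because real deployments differ.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError, ProfileError
from .reference_data import DemographicTable, DRITable

#: The five nutrients singled out for shelter meal provision after a
#: disaster: energy, protein and the B1/B2/C vitamins (B1 and B2 are
#: needed to metabolize the carbohydrate-heavy diets typical of shelters).
SHELTER5_NUTRIENTS = ("energy", "protein", "vitamin_b1", "vitamin_b2", "vitamin_c")

PROFILE_NAMES = ("full", "shelter5")
_ROUNDINGS = ("ceil", "round", "floor")
_MARK_BOUNDARIES = ("inclusive", "exclusive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Tunable scenario knobs with the simulator's published defaults.

    ``mark_boundary`` is an escape hatch for the pass mark at exactly
    100 %: "inclusive" (the default rule) awards the passing mark at
    100.0 %, "exclusive" requires strictly more.
    """

    affected_fraction: float = 0.20
    days: int = 3
    profile: str = "full"
    victim_rounding: str = "ceil"
    mark_boundary: str = "inclusive"

    def __post_init__(self) -> None:
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ConfigError(
                f"affected_fraction must be in [0, 1], got {self.affected_fraction}"
            )
        if int(self.days) != self.days or self.days < 1:
            raise ConfigError(f"days must be a positive integer, got {self.days}")
        if self.profile not in PROFILE_NAMES:
            raise ConfigError(
                f"unknown profile {self.profile!r}; expected one of {PROFILE_NAMES}"
            )
        if self.victim_rounding not in _ROUNDINGS:
            raise ConfigError(
                f"victim_rounding must be one of {_ROUNDINGS}, got {self.victim_rounding!r}"
            )
        if self.mark_boundary not in _MARK_BOUNDARIES:
            raise ConfigError(
                f"mark_boundary must be one of {_MARK_BOUNDARIES}, "
                f"got {self.mark_boundary!r}"
            )

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        """Load a config from a YAML or JSON file; absent keys keep defaults."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "affected_fraction": self.affected_fraction,
            "days": self.days,
            "profile": self.profile,
            "victim_rounding": self.victim_rounding,
            "mark_boundary": self.mark_boundary,
        }


@dataclass(frozen=True)
class RequirementResult:
    """Victim count plus per-capita and whole-scenario required amounts."""

    victims: int
    per_capita_daily: Mapping[str, float]
    total_required: Mapping[str, float]
    days: int = 1


def estimate_victims(demo: DemographicTable, config: ScenarioConfig) -> int:
    """Number of people the public stockpile must cover:
    rounding(affected_fraction × population)."""
    raw = config.affected_fraction * demo.total_population
    if config.victim_rounding == "ceil":
        return math.ceil(raw)
    if config.victim_rounding == "floor":
        return math.floor(raw)
    return math.floor(raw + 0.5)  # round half-up


def per_capita_daily_requirement(
    dri: DRITable, demo: DemographicTable, nutrient: str
) -> float:
    """Population-weighted mean reference value for one nutrient
    (amount per person per day)."""
    num = 0.0
    den = 0
    for s in demo.strata:
        c = demo.counts[s]
        num += c * dri.value(nutrient, s)
        den += c
    return num / den


def nutrient_profile(name: str, dri: DRITable) -> list[str]:
    """Resolve a profile name to a list of nutrient ids in table order.

    ``full`` is every nutrient in the DRI table; ``shelter5`` is the five
    shelter-reference nutrients and errors if any is absent.
    """
    table_ids = [n.id for n in dri.nutrients]
    if name == "full":
        return table_ids
    if name == "shelter5":
        missing = [n for n in SHELTER5_NUTRIENTS if n not in table_ids]
        if missing:
            raise ProfileError(
                f"shelter5 profile needs nutrients {list(SHELTER5_NUTRIENTS)}; "
                f"DRI table lacks {missing}"
            )
        return [n for n in table_ids if n in SHELTER5_NUTRIENTS]
    raise ProfileError(f"unknown profile {name!r}; expected one of {PROFILE_NAMES}")


def total_required(
    dri: DRITable, demo: DemographicTable, config: ScenarioConfig
) -> RequirementResult:
    """Whole-scenario required amount per profile nutrient:
    per-capita daily × victims × days."""
    victims = estimate_victims(demo, config)
    nutrients = nutrient_profile(config.profile, dri)
    per_capita = {n: per_capita_daily_requirement(dri, demo, n) for n in nutrients}
    totals = {n: per_capita[n] * victims * config.days for n in nutrients}
    return RequirementResult(
        victims=victims,
        per_capita_daily=per_capita,
        total_required=totals,
        days=config.days,
    )
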