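"""Model inputs: state space, arms, base-case parameter set, scenarios.

The model has seven health states — first/later years of dutasteride
therapy, first/later years after surgery, first/later years of prostate
cancer, and death — and two strategy arms that differ only in their entry
state. All inputs are plain pydantic models, loadable from a YAML/JSON
configuration document with strict validation; omitted fields take the
base-case values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .effectiveness import IpssTrajectory, UtilityModel, fit_ipss_regression

#: Canonical state order used by every matrix and trace.
STATES: tuple[str, ...] = (
    "drug_y1",
    "drug_later",
    "surg_y1",
    "surg_later",
    "pc_y1",
    "pc_later",
    "death",
)
DEATH_STATE = "death"
#: States occupied for at most one cycle by any entrant cohort fraction.
TRANSIENT_STATES = ("drug_y1", "surg_y1", "pc_y1")

ARM_ENTRY_STATE = {"pharmacotherapy": "drug_y1", "surgery": "surg_y1"}

#: Assumed sector-specific surgery tariffs (USD). The blended defaults are
#: consistent with an 84% public / 16% private mix of these values; they are
#: configuration placeholders, not published tariffs.
SECTOR_SURGERY_COSTS: dict[str, dict[str, float]] = {
    "public": {"surg_y1": 190.0, "surg_later": 4.0},
    "private": {"surg_y1": 4260.0, "surg_later": 35.0},
}


class CoverageError(ValueError):
    """An age fell outside the life table's bands."""


class StateSpace(BaseModel):
    """The ordered seven-state space; death is absorbing and last."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    states: tuple[str, ...] = STATES

    @field_validator("states")
    @classmethod
    def _check(cls, states: tuple[str, ...]) -> tuple[str, ...]:
        if len(states) != 7 or len(set(states)) != 7:
            raise ValueError("exactly seven distinct states required")
        if states[-1] != DEATH_STATE:
            raise ValueError("death must be the last state")
        return states

    def index(self, state: str) -> int:
        return self.states.index(state)


class ArmSpec(BaseModel):
    """A strategy arm and the state its cohort starts in."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: Literal["pharmacotherapy", "surgery"]
    entry_state: str = ""

    @model_validator(mode="after")
    def _entry(self) -> "ArmSpec":
        expected = ARM_ENTRY_STATE[self.name]
        if self.entry_state == "":
            object.__setattr__(self, "entry_state", expected)
        elif self.entry_state != expected:
            raise ValueError(f"{self.name} must enter {expected}")
        return self


ARMS = {name: ArmSpec(name=name) for name in ARM_ENTRY_STATE}


class ModelSettings(BaseModel):
    """Run-level settings: cohort, horizon, discounting, decision threshold."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    cohort_size: int = 1000
    horizon: int = 10
    cycle_length: float = 1.0
    start_age: int = 70
    discount_cost: float = 0.07
    discount_utility: float = 0.03
    wtp: float = 3701.0
    #: end-of-cycle ("year_1") or start-of-cycle ("year_0") discounting
    discount_from: Literal["year_1", "year_0"] = "year_1"
    half_cycle_correction: bool = False
    #: crossover timing for year-1 noncompliers: end of cycle 1 (default)
    #: or immediately on entry (they then never accrue drug-state values)
    immediate_noncompliance: bool = False
    #: look mortality up at start_age every cycle instead of ageing
    freeze_age: bool = False

    @field_validator("cohort_size")
    @classmethod
    def _cohort(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("cohort_size must be positive")
        return v

    @field_validator("horizon")
    @classmethod
    def _horizon(cls, v: int) -> int:
        if v < 1:
            raise ValueError("horizon must be >= 1")
        return v

    @field_validator("discount_cost", "discount_utility")
    @classmethod
    def _discount(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError("discount rates must lie in [0, 1)")
        return v


class TransitionSpec(BaseModel):
    """Cycle- and arm-independent transition inputs (age hooks excluded)."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    p_noncompliance_y1: float = 0.3
    p_drug_to_surgery_later: float = 0.005
    p_drug_to_pc: float = 0.000836
    p_surgery_to_pc: float = 0.0011
    pc_excess_death: float = 0.18
    surgery_death_addon_turp: float = 0.001
    surgery_death_addon_op: float = 0.002
    #: relative reduction in cancer incidence during early dutasteride use
    chemoprevention_rr: float = 0.25
    chemoprevention_cycles: tuple[int, ...] = (1, 2)
    chemoprevention_enabled: bool = True
    #: add the surgical death risk only in the first post-surgical year
    addon_first_year_only: bool = True

    @field_validator(
        "p_noncompliance_y1",
        "p_drug_to_surgery_later",
        "p_drug_to_pc",
        "p_surgery_to_pc",
        "pc_excess_death",
        "surgery_death_addon_turp",
        "surgery_death_addon_op",
        "chemoprevention_rr",
    )
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        return v


class SurgeryMix(BaseModel):
    """Shares of the two surgical techniques among operated patients."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    share_turp: float = 0.8
    share_op: float = 0.2

    @model_validator(mode="after")
    def _shares(self) -> "SurgeryMix":
        if self.share_turp < 0 or self.share_op < 0:
            raise ValueError("surgery shares must be >= 0")
        if abs(self.share_turp + self.share_op - 1.0) > 1e-9:
            raise ValueError("surgery shares must sum to 1")
        return self


class CostSet(BaseModel):
    """Per-state direct medical costs, USD per annual cycle."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    drug_y1: float = 146.36
    drug_later: float = 146.36
    surg_y1: float = 840.96
    surg_later: float = 9.0
    pc_y1: float = 6141.0
    pc_later: float = 2303.0
    death: float = 0.0
    #: reference cost of managing a moderate infection (already folded into
    #: the surgery-state costs; never added on top)
    infection_management: float = 0.71
    tariff_sector: Literal["blended", "public", "private"] = "blended"

    @field_validator(
        "drug_y1", "drug_later", "surg_y1", "surg_later",
        "pc_y1", "pc_later", "death", "infection_management",
    )
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("costs must be >= 0")
        return v

    def with_sector(self, sector: str) -> "CostSet":
        """Return a copy with the surgery-pathway costs of ``sector``."""
        if sector == "blended":
            return self.model_copy(update={"tariff_sector": "blended"})
        if sector not in SECTOR_SURGERY_COSTS:
            raise KeyError(f"unknown tariff sector {sector!r}")
        update: dict[str, Any] = dict(SECTOR_SURGERY_COSTS[sector])
        update["tariff_sector"] = sector
        return self.model_copy(update=update)


class LifeTable(BaseModel):
    """Age-banded annual all-cause death probabilities."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    bands: list[tuple[float, float, float]]

    @field_validator("bands")
    @classmethod
    def _bands(cls, bands):
        if not bands:
            raise ValueError("life table needs at least one band")
        bands = sorted(bands)
        for low, high, q in bands:
            if high <= low:
                raise ValueError(f"empty band [{low}, {high})")
            if not 0.0 <= q < 1.0:
                raise ValueError(f"death probability {q} outside [0, 1)")
        for (_, h1, _), (l2, _, _) in zip(bands, bands[1:]):
            if l2 < h1:
                raise ValueError("life-table bands overlap")
        return bands

    def annual_probability(self, age: float) -> float:
        for low, high, q in self.bands:
            if low <= age < high:
                return q
        raise CoverageError(f"age {age} not covered by life table")

    def covers(self, low: float, high: float) -> bool:
        try:
            for age in range(int(low), int(high)):
                self.annual_probability(age)
        except CoverageError:
            return False
        return True


class ScenarioConfig(BaseModel):
    """A named variant of the base case (all overrides optional)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    chemoprevention_enabled: Optional[bool] = None
    surgery_mix_override: Optional[SurgeryMix] = None
    tariff_sector_override: Optional[Literal["public", "private"]] = None
    #: (start age, baseline utility) of an alternative age band
    age_band: Optional[tuple[int, float]] = None


class ModelParameters(BaseModel):
    """The complete, validated input set for one model run."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    settings: ModelSettings = Field(default_factory=ModelSettings)
    transitions: TransitionSpec = Field(default_factory=TransitionSpec)
    surgery_mix: SurgeryMix = Field(default_factory=SurgeryMix)
    costs: CostSet = Field(default_factory=CostSet)
    life_table: LifeTable
    utility: UtilityModel = Field(default_factory=UtilityModel)

    @model_validator(mode="after")
    def _finalize(self) -> "ModelParameters":
        if self.utility.trajectory.slope is None:
            fit_ipss_regression(self.utility.trajectory)
        low = min(40, self.settings.start_age)
        high = self.settings.start_age + self.settings.horizon
        if not self.settings.freeze_age and not self.life_table.covers(low, high):
            raise ValueError(
                f"life table must cover ages [{low}, {high}) for this run"
            )
        return self

    # -- derived, mix-weighted quantities ---------------------------------
    @property
    def blended_death_addon(self) -> float:
        """Mix-weighted first-year surgical/anaesthetic death add-on."""
        t = self.transitions
        m = self.surgery_mix
        return (
            m.share_turp * t.surgery_death_addon_turp
            + m.share_op * t.surgery_death_addon_op
        )

    @property
    def blended_disutility(self) -> float:
        """Mix-weighted annual complication disutility for surgery states."""
        d = self.utility.disutility
        m = self.surgery_mix
        return m.share_turp * d["turp"] + m.share_op * d["op"]

    @property
    def baseline_utility(self) -> float:
        """Age-band baseline utility at the cohort's starting age."""
        return self.utility.baseline_for_age(self.settings.start_age)


def default_parameters() -> ModelParameters:
    """The base case: 1000 men aged 70, ten annual cycles."""
    from . import synthetic_data  # circular at module level

    return ModelParameters(life_table=synthetic_data.make_life_table())


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_model(source: str | Path | dict | None = None) -> ModelParameters:
    """Build a parameter set from a config document (YAML/JSON path or dict).

    Omitted fields take their base-case defaults; unknown keys and
    out-of-range values raise pydantic validation errors naming the field.
    ``None`` returns the base case.
    """
    if source is None:
        return default_parameters()
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
        if data is None:
            data = {}
    elif isinstance(source, dict):
        data = source
    else:
        raise TypeError(f"cannot load model from {type(source).__name__}")
    base = default_parameters().model_dump(mode="python")
    _deep_update(base, data)
    return ModelParameters.model_validate(base)


def scenario_catalog() -> list[ScenarioConfig]:
    """The base case plus the eight named scenario variants."""
    return [
        ScenarioConfig(name="base"),
        ScenarioConfig(name="public_tariff", tariff_sector_override="public"),
        ScenarioConfig(name="private_tariff", tariff_sector_override="private"),
        ScenarioConfig(name="no_chemoprevention", chemoprevention_enabled=False),
        ScenarioConfig(
            name="op_only",
            surgery_mix_override=SurgeryMix(share_turp=0.0, share_op=1.0),
        ),
        ScenarioConfig(
            name="turp_only",
            surgery_mix_override=SurgeryMix(share_turp=1.0, share_op=0.0),
        ),
        ScenarioConfig(name="age_40_50", age_band=(40, 1.0)),
        ScenarioConfig(name="age_50_60", age_band=(50, 0.94)),
        ScenarioConfig(name="age_60_70", age_band=(60, 0.88)),
    ]


def export_config_schema(path: str | Path) -> None:
    """Write the JSON schema of the configuration document."""
    Path(path).write_text(
        json.dumps(ModelParameters.model_json_schema(), indent=2) + "\n"
    )
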