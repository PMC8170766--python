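"""Per-state utilities for the BPH treatment model.

The drug arm's symptom trajectory is an International Prostate Symptom
Score (IPSS) time series observed over four years of dutasteride therapy
and extrapolated by ordinary least squares; surgery delivers a fixed IPSS
improvement. IPSS maps to a utility weight through a tabulated score ->
utility function, which is multiplied by an age-band baseline utility.
Prostate-cancer states override the IPSS-derived utility with a flat
cancer utility, and surgical complications subtract a small annual
disutility.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

DATA_DIR = Path(__file__).parent / "data"

#: Age-band baseline utilities (EQ-5D-style population norms by decade).
DEFAULT_AGE_BASELINE = {"40-50": 1.0, "50-60": 0.94, "60-70": 0.88, "70-80": 0.8}


class InsufficientDataError(ValueError):
    """Fewer than two usable points for the IPSS regression."""


class UnfittedTrajectoryError(RuntimeError):
    """The trajectory has not been fitted yet."""


def load_utility_table(path: str | Path | None = None) -> dict[int, float]:
    """Read the IPSS -> utility table from its version-pinned CSV."""
    path = Path(path) if path is not None else DATA_DIR / "ipss_utility.csv"
    table: dict[int, float] = {}
    with open(path, newline="") as fh:
        rows = (r for r in csv.reader(fh) if r and not r[0].startswith("#"))
        header = next(rows)
        if header != ["ipss", "utility"]:
            raise ValueError(f"unexpected utility table header: {header}")
        for score, utility in rows:
            table[int(score)] = float(utility)
    return table


def _default_disutility() -> dict[str, float]:
    # Lazy import: synthetic_data provides the complication fixture.
    from . import synthetic_data

    return synthetic_data.weighted_disutility(
        synthetic_data.load_complication_profiles()
    )


class IpssTrajectory(BaseModel):
    """Observed IPSS under dutasteride plus a fitted linear extrapolation.

    ``observed`` holds (year, IPSS) pairs; years in ``exclude_years`` are
    dropped from the fit (the first-year score reflects pre-response
    symptoms and is off the later trend). Extrapolated scores are clamped
    to [floor, ceiling].
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    observed: list[tuple[int, float]] = Field(
        default=[(1, 16.7), (2, 12.3), (3, 11.3), (4, 10.6)]
    )
    exclude_years: set[int] = Field(default={1})
    floor: float = 1.0
    ceiling: float = 35.0
    slope: float | None = None
    intercept: float | None = None
    #: if True, years with an observed value return it instead of the fit
    use_observed: bool = False

    @property
    def fit_points(self) -> list[tuple[int, float]]:
        return [(y, s) for y, s in self.observed if y not in self.exclude_years]


class UtilityModel(BaseModel):
    """Everything needed to turn a health state and cycle into a utility."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    ipss_utility: dict[int, float] = Field(default_factory=load_utility_table)
    age_baseline: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_AGE_BASELINE)
    )
    pc_utility: float = 0.62
    baseline_ipss: float = 16.7
    surgical_improvement: float = 8.5
    #: per-surgery-type incidence-weighted annual utility decrement
    disutility: dict[str, float] = Field(default_factory=_default_disutility)
    #: round non-integer IPSS to the nearest table row instead of interpolating
    integer_rounding: bool = False
    trajectory: IpssTrajectory = Field(default_factory=IpssTrajectory)

    @field_validator("ipss_utility")
    @classmethod
    def _table_valid(cls, table: dict[int, float]) -> dict[int, float]:
        if sorted(table) != list(range(1, 36)):
            raise ValueError("IPSS utility table must cover scores 1..35")
        vals = [table[k] for k in range(1, 36)]
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("utilities must lie in [0, 1]")
        if any(b >= a for a, b in zip(vals, vals[1:])):
            raise ValueError("utilities must be strictly decreasing in IPSS")
        return table

    @field_validator("age_baseline")
    @classmethod
    def _baseline_valid(cls, m: dict[str, float]) -> dict[str, float]:
        for band, v in m.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"baseline utility for {band} outside [0, 1]")
        return m

    @field_validator("pc_utility")
    @classmethod
    def _pc_valid(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("pc_utility outside [0, 1]")
        return v

    def baseline_for_age(self, age: float) -> float:
        """Baseline utility of the decade band containing ``age``."""
        for band, value in self.age_baseline.items():
            low, high = (float(x) for x in band.split("-"))
            if low <= age < high:
                return value
        raise KeyError(f"no age-baseline band covers age {age}")


def fit_ipss_regression(trajectory: IpssTrajectory) -> tuple[float, float]:
    """Ordinary least squares IPSS-on-year fit over the non-excluded points.

    Returns ``(slope, intercept)`` and stores them on the trajectory.
    """
    pts = trajectory.fit_points
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need at least 2 non-excluded points, got {len(pts)}"
        )
    years = np.array([y for y, _ in pts], dtype=float)
    scores = np.array([s for _, s in pts], dtype=float)
    slope, intercept = np.polyfit(years, scores, 1)
    trajectory.slope = float(slope)
    trajectory.intercept = float(intercept)
    return trajectory.slope, trajectory.intercept


def ipss_at(trajectory: IpssTrajectory, year: int) -> float:
    """IPSS in a given year of dutasteride therapy.

    Year 1 always returns the observed pre-response score; later years use
    the fitted line (clamped to [floor, ceiling]) unless ``use_observed``
    is set and an observation exists for that year.
    """
    observed = dict(trajectory.observed)
    if year == 1 and 1 in observed:
        return observed[1]
    if trajectory.use_observed and year in observed:
        return observed[year]
    if trajectory.slope is None or trajectory.intercept is None:
        raise UnfittedTrajectoryError("fit_ipss_regression has not been run")
    value = trajectory.intercept + trajectory.slope * year
    return float(min(max(value, trajectory.floor), trajectory.ceiling))


def ipss_to_utility(model: UtilityModel, ipss: float) -> float:
    """Map an IPSS score to a utility weight.

    Integer scores return the exact table value; non-integer scores are
    linearly interpolated between adjacent rows (or rounded to the nearest
    row when ``integer_rounding`` is set).
    """
    if not 1.0 <= ipss <= 35.0:
        raise ValueError(f"IPSS {ipss} outside [1, 35]")
    if model.integer_rounding:
        return model.ipss_utility[int(np.floor(ipss + 0.5))]
    scores = np.arange(1, 36, dtype=float)
    utilities = np.array([model.ipss_utility[k] for k in range(1, 36)])
    return float(np.interp(ipss, scores, utilities))


def post_surgery_ipss(model: UtilityModel) -> float:
    """IPSS after the fixed surgical improvement, clamped at the floor."""
    value = model.baseline_ipss - model.surgical_improvement
    floor = model.trajectory.floor
    if value < floor:
        warnings.warn(
            f"post-surgical IPSS {value:.2f} below floor {floor}; clamped",
            stacklevel=2,
        )
        return floor
    return value


def state_utility(
    model: UtilityModel,
    state: str,
    cycle: int,
    baseline_utility: float,
    complication_disutility: float = 0.0,
) -> float:
    """Annual utility for one health state in one cycle.

    Drug states: baseline x utility(IPSS in that therapy year).
    Surgery states: baseline x utility(post-surgical IPSS) minus the
    incidence-weighted complication disutility. Prostate-cancer states
    return the flat cancer utility; death returns 0. Clamped to [0, 1].
    """
    if complication_disutility < 0:
        raise ValueError("complication disutility must be >= 0")
    if state == "death":
        return 0.0
    if state.startswith("pc"):
        return model.pc_utility
    if state.startswith("drug"):
        value = baseline_utility * ipss_to_utility(model, ipss_at(model.trajectory, cycle))
    elif state.startswith("surg"):
        value = (
            baseline_utility * ipss_to_utility(model, post_surgery_ipss(model))
            - complication_disutility
        )
    else:
        raise ValueError(f"unknown state {state!r}")
    return float(min(max(value, 0.0), 1.0))
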