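"""One-way deterministic sensitivity analysis and the scenario runner.

The DSA moves one parameter at a time to the low and high end of its
range, reruns the full two-arm comparison, and records the ICER at each
end; entries sorted by swing give the tornado ordering. Scenarios apply
the named overrides from the catalogue (tariff sector, surgery mix,
chemoprevention, age band) and rerun the comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from pydantic import ValidationError

from .economics import ComparisonResult, compare_arms
from .markov_engine import InfeasibleParametersError
from .parameters import (
    ModelParameters,
    ScenarioConfig,
    scenario_catalog,
)

#: Aliases expanding one conceptual parameter to several config paths.
#: Callables receive the parameter set and return the paths to move.
ALIASES: dict[str, Callable[[ModelParameters], tuple[str, ...]]] = {
    "drug_annual_cost": lambda p: ("costs.drug_y1", "costs.drug_later"),
    "baseline_utility": lambda p: (
        "utility.age_baseline." + _band_key(p.settings.start_age),
    ),
}


def _band_key(start_age: int) -> str:
    return f"{start_age // 10 * 10}-{start_age // 10 * 10 + 10}"


def _resolve_paths(params: ModelParameters, name: str) -> tuple[str, ...]:
    if name in ALIASES:
        return ALIASES[name](params)
    return (name,)


def get_parameter(params: ModelParameters, name: str) -> float:
    """Current value of a (possibly aliased) dotted parameter path."""
    path = _resolve_paths(params, name)[0]
    node = params.model_dump(mode="python")
    for part in path.split("."):
        node = node[part]
    return float(node)


def set_parameter(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """Return a new parameter set with one (aliased) parameter replaced."""
    data = params.model_dump(mode="python")
    for path in _resolve_paths(params, name):
        node = data
        parts = path.split(".")
        for part in parts[:-1]:
            node = node[part]
        node[parts[-1]] = value
    return ModelParameters.model_validate(data)


@dataclass(frozen=True)
class DsaRange:
    """Low/high bounds for one parameter in the one-way DSA."""

    parameter: str
    low: float
    high: float

    @classmethod
    def relative(
        cls,
        params: ModelParameters,
        parameter: str,
        fraction: float = 0.2,
        cap: float | None = None,
    ) -> "DsaRange":
        """+/- fraction around the current value, optionally capped above."""
        base = get_parameter(params, parameter)
        low = base * (1.0 - fraction)
        high = base * (1.0 + fraction)
        if cap is not None:
            high = min(high, cap)
        if not low <= base <= high:
            raise ValueError(f"{parameter}: range [{low}, {high}] excludes base {base}")
        return cls(parameter=parameter, low=low, high=high)


def default_dsa_ranges(
    params: ModelParameters, fraction: float = 0.2
) -> list[DsaRange]:
    """+/-20% ranges on the headline cost, probability, utility and
    discount inputs, with caps keeping probabilities and utilities valid."""
    spec = [
        ("drug_annual_cost", None),
        ("costs.surg_y1", None),
        ("transitions.p_noncompliance_y1", 1.0),
        ("transitions.p_drug_to_pc", 1.0),
        ("transitions.p_surgery_to_pc", 1.0),
        ("utility.pc_utility", 1.0),
        ("baseline_utility", 1.0),
        ("settings.discount_cost", 0.99),
        ("settings.discount_utility", 0.99),
    ]
    return [
        DsaRange.relative(params, name, fraction, cap)
        for name, cap in spec
    ]


@dataclass(frozen=True)
class TornadoEntry:
    """ICER at the two ends of one parameter's range."""

    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    swing: float


def _icer_value(result: ComparisonResult) -> float:
    return result.icer.value if result.icer.value is not None else float("nan")


def _nmb_value(result: ComparisonResult) -> float:
    return result.wtp * result.inc_qaly - result.inc_cost


def one_way_dsa(
    params: ModelParameters,
    ranges: Iterable[DsaRange] | None = None,
    outcome: str = "icer",
) -> list[TornadoEntry]:
    """One-way DSA over the given ranges, sorted by swing (descending).

    ``outcome`` is "icer" (default) or "nmb" (net monetary benefit of the
    alternative, sign-stable when the quadrant flips). Ranges producing
    invalid parameter sets are skipped with a warning.
    """
    if ranges is None:
        ranges = default_dsa_ranges(params)
    measure = _icer_value if outcome == "icer" else _nmb_value
    if outcome not in ("icer", "nmb"):
        raise ValueError("outcome must be 'icer' or 'nmb'")
    entries = []
    for rng in ranges:
        try:
            at_low = measure(compare_arms(set_parameter(params, rng.parameter, rng.low)))
            at_high = measure(
                compare_arms(set_parameter(params, rng.parameter, rng.high))
            )
        except (ValidationError, InfeasibleParametersError, ValueError) as exc:
            warnings.warn(
                f"DSA range for {rng.parameter!r} skipped: {exc}", stacklevel=2
            )
            continue
        entries.append(
            TornadoEntry(
                parameter=rng.parameter,
                low=rng.low,
                high=rng.high,
                icer_at_low=at_low,
                icer_at_high=at_high,
                swing=abs(at_high - at_low),
            )
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def apply_scenario(
    params: ModelParameters, scenario: ScenarioConfig
) -> ModelParameters:
    """Return a parameter set with the scenario's overrides applied."""
    data = params.model_dump(mode="python")
    if scenario.chemoprevention_enabled is not None:
        data["transitions"]["chemoprevention_enabled"] = (
            scenario.chemoprevention_enabled
        )
    if scenario.surgery_mix_override is not None:
        data["surgery_mix"] = scenario.surgery_mix_override.model_dump()
    if scenario.tariff_sector_override is not None:
        data["costs"] = params.costs.with_sector(
            scenario.tariff_sector_override
        ).model_dump()
    if scenario.age_band is not None:
        start_age, baseline = scenario.age_band
        data["settings"]["start_age"] = start_age
        data["utility"]["age_baseline"][_band_key(start_age)] = baseline
    return ModelParameters.model_validate(data)


def run_scenarios(
    params: ModelParameters,
    catalog: Iterable[ScenarioConfig] | None = None,
) -> list[ComparisonResult]:
    """Rerun the full comparison for every scenario in the catalogue."""
    if catalog is None:
        catalog = scenario_catalog()
    return [
        compare_arms(apply_scenario(params, sc), scenario=sc.name)
        for sc in catalog
    ]


def tornado_dataframe(entries: list[TornadoEntry]):
    import pandas as pd

    return pd.DataFrame([e.__dict__ for e in entries])


def plot_tornado(entries: list[TornadoEntry], path=None, base_icer: float | None = None):
    """Horizontal-bar tornado diagram of the DSA results."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = list(entries)
    if base_icer is None:
        base_icer = float(
            np.median([0.5 * (e.icer_at_low + e.icer_at_high) for e in entries])
        )
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(entries) + 1.5))
    ys = np.arange(len(entries))[::-1]
    for y, e in zip(ys, entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.axvline(base_icer, color="k", lw=1, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels([e.parameter for e in entries])
    ax.set_xlabel("ICER (USD/QALY)")
    ax.set_title("One-way sensitivity analysis")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
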