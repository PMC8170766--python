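"""Cohort engine: transition matrices, propagation, discounted accrual.

Matrices are cycle-dependent (ageing mortality, early-cycle
chemoprevention) but arm-independent: the two strategies differ only in
their entry state. Occupancy row ``t`` holds the distribution after ``t``
transitions; the cohort occupies row ``t-1`` DURING cycle ``t`` and
accrues that row's costs and utilities, discounted at ``(1+d)^-t`` under
the default end-of-cycle convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import effectiveness
from .parameters import (
    ARMS,
    STATES,
    ArmSpec,
    LifeTable,
    ModelParameters,
    TransitionSpec,
)

_IDX = {s: i for i, s in enumerate(STATES)}


class InfeasibleParametersError(ValueError):
    """Outgoing probabilities of a row exceed 1 before the residual."""


def rate_to_probability(rate: float, t: float = 1.0) -> float:
    """Convert a constant event rate (events/yr) into a probability over t.

    Uses ``1 - exp(-rate * t)``; the standard exponential-hazard
    conversion for Markov cycle lengths.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if t <= 0:
        raise ValueError("t must be > 0")
    return float(-np.expm1(-rate * t))


def death_probability(
    age: float,
    life_table: LifeTable,
    state: str,
    spec: TransitionSpec,
    blended_addon: float = 0.0,
    pc_excess: float | None = None,
) -> float:
    """Annual death probability for one state at one age.

    The life-table base is augmented by the mix-weighted
    surgical/anaesthetic add-on in the first post-surgical year (and in
    later years only if ``addon_first_year_only`` is off) and by the
    prostate-cancer excess mortality in cancer states. Capped at 1.
    """
    p = life_table.annual_probability(age)
    if state == "surg_y1":
        p += blended_addon
    elif state == "surg_later" and not spec.addon_first_year_only:
        p += blended_addon
    elif state in ("pc_y1", "pc_later"):
        p += spec.pc_excess_death if pc_excess is None else pc_excess
    return min(p, 1.0)


def cancer_probability(state: str, cycle: int, spec: TransitionSpec) -> float:
    """Annual prostate-cancer incidence out of a living, cancer-free state.

    Dutasteride users get a relative reduction during the chemoprevention
    cycles (early therapy); surgery states use the surgical pathway's
    incidence.
    """
    if state.startswith("drug"):
        p = spec.p_drug_to_pc
        if spec.chemoprevention_enabled and cycle in spec.chemoprevention_cycles:
            p *= 1.0 - spec.chemoprevention_rr
        return p
    if state.startswith("surg"):
        return spec.p_surgery_to_pc
    raise ValueError(f"no cancer transition out of state {state!r}")


def build_transition_matrix(
    params: ModelParameters,
    cycle: int,
    zero_noncompliance: bool = False,
) -> np.ndarray:
    """The 7x7 transition matrix for one cycle.

    Residual (remain/progress-to-'later') probabilities are one minus the
    modelled outflows; a negative residual raises
    :class:`InfeasibleParametersError` naming the row.
    ``zero_noncompliance`` supports the immediate-crossover timing, where
    the year-1 noncompliance flow is applied before the first cycle
    instead of inside the matrix.
    """
    if not 1 <= cycle <= params.settings.horizon:
        raise ValueError(f"cycle {cycle} outside 1..{params.settings.horizon}")
    t = params.transitions
    age = params.settings.start_age
    if not params.settings.freeze_age:
        age += cycle - 1
    addon = params.blended_death_addon

    m = np.zeros((7, 7))
    for state in STATES:
        i = _IDX[state]
        if state == "death":
            m[i, i] = 1.0
            continue
        death = death_probability(
            age, params.life_table, state, t, blended_addon=addon
        )
        row = {"death": death}
        if state == "drug_y1":
            row["surg_y1"] = 0.0 if zero_noncompliance else t.p_noncompliance_y1
            row["pc_y1"] = cancer_probability(state, cycle, t)
            residual_to = "drug_later"
        elif state == "drug_later":
            row["surg_y1"] = t.p_drug_to_surgery_later
            row["pc_y1"] = cancer_probability(state, cycle, t)
            residual_to = "drug_later"
        elif state == "surg_y1":
            row["pc_y1"] = cancer_probability(state, cycle, t)
            residual_to = "surg_later"
        elif state == "surg_later":
            row["pc_y1"] = cancer_probability(state, cycle, t)
            residual_to = "surg_later"
        elif state == "pc_y1":
            residual_to = "pc_later"
        else:  # pc_later
            residual_to = "pc_later"
        outflow = sum(row.values())
        residual = 1.0 - outflow
        if residual < -1e-12:
            raise InfeasibleParametersError(
                f"row {state!r}: outgoing probabilities sum to {outflow:.6f} > 1"
            )
        row[residual_to] = row.get(residual_to, 0.0) + max(residual, 0.0)
        for target, p in row.items():
            m[i, _IDX[target]] = p
    assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
    return m


@dataclass
class CohortTrace:
    """State occupancy (persons) per cycle for one arm."""

    arm: str
    occupancy: np.ndarray  # (horizon+1) x 7
    states: tuple[str, ...] = STATES

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.index.name = "cycle"
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass
class OutcomeAccumulator:
    """Discounted totals and per-cycle breakdown for one arm."""

    arm: str
    total_cost: float
    total_qaly: float
    per_cycle: pd.DataFrame = field(repr=False)
    settings_fingerprint: str = ""

    def to_csv(self, path) -> None:
        self.per_cycle.to_csv(path, index=False)


def cost_vector(params: ModelParameters) -> np.ndarray:
    """Per-state annual cost (USD), in canonical state order."""
    c = params.costs.with_sector(params.costs.tariff_sector)
    return np.array(
        [c.drug_y1, c.drug_later, c.surg_y1, c.surg_later, c.pc_y1, c.pc_later, c.death]
    )


def utility_vector(params: ModelParameters, cycle: int) -> np.ndarray:
    """Per-state annual utility for one cycle, in canonical state order."""
    baseline = params.baseline_utility
    dis = params.blended_disutility
    return np.array(
        [
            effectiveness.state_utility(params.utility, s, cycle, baseline, dis)
            for s in STATES
        ]
    )


def discount_factor(rate: float, cycle: int, convention: str = "year_1") -> float:
    exponent = cycle if convention == "year_1" else cycle - 1
    return (1.0 + rate) ** -exponent


def run_cohort(arm: str | ArmSpec, params: ModelParameters) -> CohortTrace:
    """Propagate the cohort through the horizon for one arm."""
    arm = ARMS[arm] if isinstance(arm, str) else arm
    settings = params.settings
    horizon = settings.horizon
    occ = np.zeros((horizon + 1, 7))
    start = np.zeros(7)
    entry = _IDX[arm.entry_state]
    immediate = (
        settings.immediate_noncompliance and arm.entry_state == "drug_y1"
    )
    if immediate:
        p_nc = params.transitions.p_noncompliance_y1
        start[entry] = settings.cohort_size * (1.0 - p_nc)
        start[_IDX["surg_y1"]] = settings.cohort_size * p_nc
    else:
        start[entry] = settings.cohort_size
    occ[0] = start
    for t in range(1, horizon + 1):
        m = build_transition_matrix(params, t, zero_noncompliance=immediate)
        occ[t] = occ[t - 1] @ m
    return CohortTrace(arm=arm.name, occupancy=occ)


def _fingerprint(params: ModelParameters) -> str:
    s = params.settings
    return (
        f"h{s.horizon}|n{s.cohort_size}|a{s.start_age}|dc{s.discount_cost}"
        f"|du{s.discount_utility}|{s.discount_from}|hc{s.half_cycle_correction}"
    )


def accumulate(trace: CohortTrace, params: ModelParameters) -> OutcomeAccumulator:
    """Discounted cost and QALY totals for a completed trace."""
    s = params.settings
    costs = cost_vector(params)
    rows = []
    for t in range(1, s.horizon + 1):
        occ = trace.occupancy[t - 1]
        if s.half_cycle_correction:
            occ = 0.5 * (trace.occupancy[t - 1] + trace.occupancy[t])
        utils = utility_vector(params, t)
        cost_t = float(occ @ costs) * discount_factor(
            s.discount_cost, t, s.discount_from
        )
        qaly_t = float(occ @ utils) * discount_factor(
            s.discount_utility, t, s.discount_from
        )
        rows.append({"cycle": t, "cost": cost_t, "qaly": qaly_t})
    per_cycle = pd.DataFrame(rows)
    return OutcomeAccumulator(
        arm=trace.arm,
        total_cost=float(per_cycle["cost"].sum()),
        total_qaly=float(per_cycle["qaly"].sum()),
        per_cycle=per_cycle,
        settings_fingerprint=_fingerprint(params),
    )


def run_arm(
    arm: str | ArmSpec, params: ModelParameters
) -> tuple[CohortTrace, OutcomeAccumulator]:
    """Convenience: propagate one arm and accumulate its outcomes."""
    trace = run_cohort(arm, params)
    return trace, accumulate(trace, params)
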