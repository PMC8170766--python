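"""Synthetic fixtures and the microsimulation oracle.

Two model inputs are not published as usable tables — the Iranian 2011
age-specific male mortality schedule and the surgical complication
probabilities/disutilities — so this module ships documented, assumed
stand-ins as CSV fixtures, plus an individual-level microsimulation that
serves as an independent brute-force oracle for the cohort engine: it
samples each patient's path from the same per-cycle matrices and accrues
the same discounted costs and utilities, so its means must agree with the
cohort expectation within Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markov_engine
from .effectiveness import DATA_DIR
from .parameters import ARMS, STATES, ArmSpec, LifeTable, ModelParameters

LIFE_TABLE_FILE = DATA_DIR / "life_table_iran2011_male_synthetic.csv"
COMPLICATIONS_FILE = DATA_DIR / "complications_synthetic.csv"

DEFAULT_LIFE_TABLE_PRESET = "iran-2011-male-synthetic"


def _read_life_table_csv() -> LifeTable:
    df = pd.read_csv(LIFE_TABLE_FILE, comment="#")
    bands = [
        (float(r.age_low), float(r.age_high), float(r.annual_death_probability))
        for r in df.itertuples()
    ]
    return LifeTable(bands=bands)


def make_life_table(preset: str = DEFAULT_LIFE_TABLE_PRESET) -> LifeTable:
    """Return a named life-table preset.

    ``iran-2011-male-synthetic`` is the pinned default fixture (assumed
    values, see the CSV header); ``zero-mortality`` sets every band to 0
    for identity-dynamics checks.
    """
    if preset == DEFAULT_LIFE_TABLE_PRESET:
        return _read_life_table_csv()
    if preset == "zero-mortality":
        base = _read_life_table_csv()
        return LifeTable(bands=[(lo, hi, 0.0) for lo, hi, _ in base.bands])
    raise LookupError(f"unknown life-table preset {preset!r}")


def life_table_grid(low: float, high: float, step: float) -> list[LifeTable]:
    """Default preset with the 70-80 band swept over a value grid."""
    tables = []
    for q in np.arange(low, high + step / 2, step):
        base = _read_life_table_csv()
        bands = [
            (lo, hi, float(q)) if lo == 70.0 else (lo, hi, p)
            for lo, hi, p in base.bands
        ]
        tables.append(LifeTable(bands=bands))
    return tables


def load_complication_profiles() -> pd.DataFrame:
    """The per-surgery-type complication fixture (assumed magnitudes)."""
    return pd.read_csv(COMPLICATIONS_FILE, comment="#")


def weighted_disutility(profiles: pd.DataFrame) -> dict[str, float]:
    """Incidence-weighted annual utility decrement per surgery type."""
    out = {}
    for kind, grp in profiles.groupby("surgery_type"):
        out[str(kind)] = float(
            (grp["annual_probability"] * grp["utility_decrement"]).sum()
        )
    return out


@dataclass
class MicrosimResult:
    """Mean discounted outcomes from the individual-level simulation."""

    arm: str
    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    state_counts: np.ndarray  # (horizon+1) x 7 individuals per state


def microsim_oracle(
    params: ModelParameters,
    arm: str | ArmSpec = "pharmacotherapy",
    n: int = 10_000,
    seed: int = 0,
) -> MicrosimResult:
    """Simulate ``n`` independent patients through the same matrices.

    Each cycle a patient accrues the cost and utility of the state they
    occupy (discounted exactly as the cohort engine does) and then draws
    the next state from the corresponding matrix row. Bit-for-bit
    reproducible given (n, seed, parameters). Half-cycle correction is
    not supported here.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    arm = ARMS[arm] if isinstance(arm, str) else arm
    s = params.settings
    if s.half_cycle_correction:
        raise NotImplementedError("microsim oracle models whole cycles only")
    rng = np.random.default_rng(seed)
    idx = {name: i for i, name in enumerate(STATES)}

    state = np.full(n, idx[arm.entry_state], dtype=np.int64)
    immediate = s.immediate_noncompliance and arm.entry_state == "drug_y1"
    if immediate:
        crossover = rng.random(n) < params.transitions.p_noncompliance_y1
        state[crossover] = idx["surg_y1"]
    cost = np.zeros(n)
    qaly = np.zeros(n)
    counts = np.zeros((s.horizon + 1, 7), dtype=np.int64)
    counts[0] = np.bincount(state, minlength=7)

    costs = markov_engine.cost_vector(params)
    for t in range(1, s.horizon + 1):
        utils = markov_engine.utility_vector(params, t)
        dfc = markov_engine.discount_factor(s.discount_cost, t, s.discount_from)
        dfu = markov_engine.discount_factor(s.discount_utility, t, s.discount_from)
        cost += costs[state] * dfc
        qaly += utils[state] * dfu
        matrix = markov_engine.build_transition_matrix(
            params, t, zero_noncompliance=immediate
        )
        cum = matrix.cumsum(axis=1)
        draws = rng.random(n)
        state = (cum[state] < draws[:, None]).sum(axis=1)
        counts[t] = np.bincount(state, minlength=7)

    return MicrosimResult(
        arm=arm.name,
        n=n,
        seed=seed,
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_qaly=float(qaly.mean()),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        state_counts=counts,
    )


#: (dotted path, upper clamp) pairs jittered by perturb_parameters, in order.
_PERTURB_FIELDS: tuple[tuple[str, float | None], ...] = (
    ("transitions.p_noncompliance_y1", 0.9),
    ("transitions.p_drug_to_surgery_later", 0.9),
    ("transitions.p_drug_to_pc", 0.9),
    ("transitions.p_surgery_to_pc", 0.9),
    ("transitions.pc_excess_death", 0.9),
    ("transitions.surgery_death_addon_turp", 0.9),
    ("transitions.surgery_death_addon_op", 0.9),
    ("transitions.chemoprevention_rr", 0.9),
    ("costs.drug_y1", None),
    ("costs.drug_later", None),
    ("costs.surg_y1", None),
    ("costs.surg_later", None),
    ("costs.pc_y1", None),
    ("costs.pc_later", None),
    ("utility.pc_utility", 1.0),
    ("utility.disutility.turp", 0.2),
    ("utility.disutility.op", 0.2),
)


def perturb_parameters(
    base: ModelParameters, magnitude: float, seed: int
) -> ModelParameters:
    """Jitter the scalar inputs multiplicatively within +/- magnitude.

    Probabilities and utilities are clamped so every invariant still
    holds; magnitude 0 returns an identical parameter set. Deterministic
    given (magnitude, seed).
    """
    if not 0.0 <= magnitude <= 0.5:
        raise ValueError("magnitude must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    data = base.model_dump(mode="python")
    for path, cap in _PERTURB_FIELDS:
        node = data
        parts = path.split(".")
        for part in parts[:-1]:
            node = node[part]
        value = node[parts[-1]] * (1.0 + rng.uniform(-magnitude, magnitude))
        if cap is not None:
            value = min(value, cap)
        node[parts[-1]] = max(value, 0.0)
    return ModelParameters.model_validate(data)
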