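"""Incremental analysis: ICER, cost-effectiveness plane, WTP verdict.

Incrementals are signed alternative-minus-reference; the standard
pipeline signs pharmacotherapy-versus-surgery (alternative =
pharmacotherapy), so a strategy that is cheaper and less effective lands
in the southwest (SW) quadrant of the cost-effectiveness plane. In SW the
ICER is the saving per QALY forgone, and the cheaper strategy is
preferred when that saving meets the willingness-to-pay threshold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .markov_engine import OutcomeAccumulator, run_arm
from .parameters import ModelParameters


class ComparisonSettingsError(ValueError):
    """Arm totals were computed under different run settings."""


def incremental(
    ref_totals: tuple[float, float] | OutcomeAccumulator,
    alt_totals: tuple[float, float] | OutcomeAccumulator,
) -> tuple[float, float]:
    """Alternative-minus-reference (cost, QALY) differences."""
    def unpack(x):
        if isinstance(x, OutcomeAccumulator):
            return x.total_cost, x.total_qaly, x.settings_fingerprint
        return x[0], x[1], None

    rc, rq, rfp = unpack(ref_totals)
    ac, aq, afp = unpack(alt_totals)
    if rfp is not None and afp is not None and rfp != afp:
        raise ComparisonSettingsError(
            f"arm totals computed under different settings: {rfp} vs {afp}"
        )
    return ac - rc, aq - rq


def quadrant(inc_cost: float, inc_qaly: float) -> str:
    """Cost-effectiveness plane quadrant; zero treated as non-negative."""
    if inc_qaly >= 0:
        return "NE" if inc_cost >= 0 else "SE"
    return "NW" if inc_cost >= 0 else "SW"


@dataclass(frozen=True)
class IcerResult:
    """An ICER value or a dominance/equivalence marker, plus the quadrant."""

    value: float | None
    quadrant: str
    marker: str | None = None


def icer(inc_cost: float, inc_qaly: float) -> IcerResult:
    """Incremental cost-effectiveness ratio with degenerate cases marked."""
    q = quadrant(inc_cost, inc_qaly)
    if inc_qaly != 0:
        return IcerResult(value=inc_cost / inc_qaly, quadrant=q)
    if inc_cost != 0:
        marker = "cheaper-equal" if inc_cost < 0 else "costlier-equal"
        return IcerResult(value=None, quadrant=q, marker=marker)
    return IcerResult(value=None, quadrant=q, marker="equivalent")


def decide(
    result: IcerResult,
    wtp: float,
    alternative: str = "pharmacotherapy",
    reference: str = "surgery",
) -> str:
    """Preferred strategy under a willingness-to-pay threshold.

    NE (alternative costlier, more effective): alternative preferred iff
    ICER <= WTP. SW (alternative cheaper, less effective): alternative
    preferred iff the saving per QALY forgone (the ICER) >= WTP. SE:
    alternative dominant; NW: alternative dominated.
    """
    if wtp <= 0:
        raise ValueError("wtp must be positive")
    if result.marker == "equivalent":
        return "equivalent"
    if result.marker == "cheaper-equal":
        return alternative
    if result.marker == "costlier-equal":
        return reference
    q = result.quadrant
    if q == "SE":
        return alternative
    if q == "NW":
        return reference
    if q == "NE":
        return alternative if result.value <= wtp else reference
    # SW: ICER = saving per QALY forgone (positive ratio of two negatives)
    return alternative if result.value >= wtp else reference


@dataclass
class ComparisonResult:
    """Full two-arm comparison for one scenario."""

    scenario: str
    reference: str
    alternative: str
    ref_cost: float
    ref_qaly: float
    alt_cost: float
    alt_qaly: float
    inc_cost: float
    inc_qaly: float
    icer: IcerResult
    wtp: float
    verdict: str


def compare_arms(
    params: ModelParameters,
    scenario: str = "base",
    reference: str = "surgery",
    alternative: str = "pharmacotherapy",
) -> ComparisonResult:
    """Run both arms under one parameter set and compare them."""
    _, ref_acc = run_arm(reference, params)
    _, alt_acc = run_arm(alternative, params)
    inc_cost, inc_qaly = incremental(ref_acc, alt_acc)
    result = icer(inc_cost, inc_qaly)
    verdict = decide(result, params.settings.wtp, alternative, reference)
    return ComparisonResult(
        scenario=scenario,
        reference=reference,
        alternative=alternative,
        ref_cost=ref_acc.total_cost,
        ref_qaly=ref_acc.total_qaly,
        alt_cost=alt_acc.total_cost,
        alt_qaly=alt_acc.total_qaly,
        inc_cost=inc_cost,
        inc_qaly=inc_qaly,
        icer=result,
        wtp=params.settings.wtp,
        verdict=verdict,
    )


def _fmt(value: float, paren: bool, decimals: int = 2) -> str:
    if paren and value < 0:
        return f"({abs(value):,.{decimals}f})"
    return f"{value:,.{decimals}f}"


def arm_table(result: ComparisonResult, paren_negatives: bool = False) -> pd.DataFrame:
    """Two-row per-arm summary (totals, incrementals, ICER)."""
    icer_display = (
        _fmt(result.icer.value, paren_negatives, 1)
        if result.icer.value is not None
        else result.icer.marker
    )
    rows = [
        {
            "treatment": result.alternative,
            "total_cost": _fmt(result.alt_cost, paren_negatives),
            "total_qaly": _fmt(result.alt_qaly, paren_negatives),
            "inc_cost": _fmt(result.inc_cost, paren_negatives),
            "inc_qaly": _fmt(result.inc_qaly, paren_negatives),
            "icer": icer_display,
        },
        {
            "treatment": result.reference,
            "total_cost": _fmt(result.ref_cost, paren_negatives),
            "total_qaly": _fmt(result.ref_qaly, paren_negatives),
            "inc_cost": "",
            "inc_qaly": "",
            "icer": "",
        },
    ]
    return pd.DataFrame(rows)


def scenario_table(
    results: list[ComparisonResult], paren_negatives: bool = False
) -> pd.DataFrame:
    """One row per scenario: incrementals, ICER, quadrant, verdict."""
    rows = []
    for r in results:
        rows.append(
            {
                "scenario": r.scenario,
                "inc_cost": _fmt(r.inc_cost, paren_negatives),
                "inc_qaly": _fmt(r.inc_qaly, paren_negatives),
                "icer": (
                    _fmt(r.icer.value, paren_negatives, 1)
                    if r.icer.value is not None
                    else r.icer.marker
                ),
                "quadrant": r.icer.quadrant,
                "preferred": r.verdict,
            }
        )
    return pd.DataFrame(rows)


def render_report(
    results: list[ComparisonResult],
    out_dir: str | Path | None = None,
    paren_negatives: bool = False,
) -> dict[str, object]:
    """Emit the arm summary, scenario table, and a full-precision JSON dump.

    The first result is treated as the headline (base-case) comparison.
    Returns the tables; writes ``arms.csv``, ``scenarios.csv`` and
    ``comparison.json`` when ``out_dir`` is given.
    """
    if not results:
        raise ValueError("need at least one comparison result")
    arms = arm_table(results[0], paren_negatives)
    scenarios = scenario_table(results, paren_negatives)
    payload = [asdict(r) for r in results]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arms.to_csv(out / "arms.csv", index=False)
        scenarios.to_csv(out / "scenarios.csv", index=False)
        (out / "comparison.json").write_text(json.dumps(payload, indent=2) + "\n")
    return {"arms": arms, "scenarios": scenarios, "json": payload}
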