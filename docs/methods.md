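# Methods

## The decision problem

`bphcea` implements a cost-utility comparison of two strategies for
moderate benign prostatic hyperplasia (BPH, IPSS 7–19) in men from age
40 upward: continuous pharmacotherapy with dutasteride (a
5-alpha-reductase inhibitor) versus immediate surgery, itself a mix of
transurethral resection of the prostate (TURP) and open prostatectomy
(OP). The perspective is a health provider paying direct medical costs
in USD; effectiveness is measured in quality-adjusted life years (QALY).

## Model structure

Each strategy arm enters a seven-state Markov cohort model with annual
cycles over a ten-year horizon:

| # | state        | meaning                               |
|---|--------------|---------------------------------------|
| 0 | `drug_y1`    | first year of dutasteride therapy     |
| 1 | `drug_later` | subsequent therapy years              |
| 2 | `surg_y1`    | the surgical year                     |
| 3 | `surg_later` | post-surgical follow-up years         |
| 4 | `pc_y1`      | first year of prostate cancer         |
| 5 | `pc_later`   | subsequent cancer years               |
| 6 | `death`      | absorbing                             |

First-year and later states are separated because their probabilities,
costs and utilities differ. The `_y1` states are transient: every
occupant leaves after one cycle. The pharmacotherapy arm starts in
`drug_y1`, the surgery arm in `surg_y1`; the transition matrices are
otherwise identical between arms, so the strategies differ only through
their entry state.

Per cycle, a patient in `drug_y1` may cross over to surgery through
noncompliance (0.3 in year one; 0.005 per year thereafter from
`drug_later`), develop prostate cancer (annual probability 0.000836,
reduced by 25% in therapy years 1–2 — the chemoprevention effect of
dutasteride), or die; `surg_*` states feed cancer at 0.0011/yr; cancer
states add an excess death probability of 0.18/yr on top of background
mortality. Background mortality is an age-band lookup that advances one
year per cycle (a `freeze_age` flag reproduces the simpler frozen-age
reading). The surgical year adds an operative/anaesthetic death risk of
0.001 (TURP) or 0.002 (OP); at the default 80/20 TURP/OP mix the
blended add-on is 0.0012. By default the add-on applies only to the
surgical year itself (`addon_first_year_only=True`); a flag extends it
to later years. Remaining-in-state probabilities are residuals (one
minus the modelled outflows); a negative residual is reported as an
infeasible parameter set, never silently clipped.

Rates quoted per unit time convert to per-cycle probabilities through
the exponential-hazard formula `p = 1 − exp(−r·t)`
(`rate_to_probability`).

Noncompliant patients cross over at the end of cycle 1: they accrue
drug-state cost and utility in cycle 1 and surgical-year cost and
utility in cycle 2. The alternative reading (crossover before any drug
cost accrues) is available via `settings.immediate_noncompliance`.

## Effectiveness

Symptom burden under dutasteride is the observed IPSS series
16.7, 12.3, 11.3, 10.6 at years 1–4. Year 1 is excluded as a
pre-response outlier and an ordinary least-squares line is fitted to
the remaining three points (slope −0.85 IPSS/yr, intercept 13.95),
extrapolated over the horizon and clamped to [1, 35]. Year 1 uses the
observed 16.7; by default years 2–4 also use the fitted line so that
the trajectory is one consistent model (`use_observed` restores the
trial values). Surgery delivers a fixed improvement of 8.5 IPSS units
from the shared baseline 16.7, hence a post-surgical score of 8.2,
identical for TURP and OP.

IPSS maps to a utility weight through a strictly decreasing table over
integer scores 1–35 (shipped as a version-pinned CSV). Non-integer
scores interpolate linearly between adjacent rows; rounding to the
nearest row is available behind `integer_rounding` because the
interpolated reading is continuous in sensitivity analyses while the
rounded one is not. The state utility is the age-band baseline utility
(1.0 / 0.94 / 0.88 / 0.8 for the decades from 40–50 to 70–80)
multiplied by the IPSS utility; surgery states additionally subtract an
incidence-weighted annual complication disutility; prostate-cancer
states override everything with a flat 0.62; death is 0. All state
utilities are clamped to [0, 1].

The drug arm's cycle-1 utility uses the pre-response IPSS 16.7 — the
trajectory offers no earlier response information.

## Costs

Annual per-state direct medical costs (USD): dutasteride 146.36 in
every therapy year; the surgical year 840.96 including complication
management; post-surgical years 9 (ongoing complication management);
prostate cancer 6,141 in the first year and 2,303 thereafter; death 0.
The 0.71 USD moderate-infection management cost is carried as a
reference field; it is already folded into the surgery-state costs and
never added on top. Public-only and private-only tariff variants swap
the two surgery-state costs; the shipped sector values (public 190/4,
private 4,260/35) are assumed placeholders chosen so that an 84%
public / 16% private blend recovers the blended defaults — sector
scenario outputs exercise the machinery and are not reproductions of
published sector results.

## Accrual and discounting

During cycle *t* the cohort occupies the state distribution after
*t−1* transitions; that row accrues the cycle's costs and utilities,
discounted at `(1+d)^−t` with d = 0.07/yr for costs and 0.03/yr for
utilities (differential discounting). This end-of-cycle convention is a
deliberate choice where the source material is silent;
`discount_from="year_0"` switches to start-of-cycle discounting, and an
optional half-cycle correction (off by default, as none is described
for the original model) averages adjacent occupancy rows.

## Decision rule

Incrementals are signed alternative-minus-reference with
pharmacotherapy as the alternative. The ICER is `Δcost/ΔQALY` whenever
`ΔQALY ≠ 0`; `ΔQALY = 0` yields a cheaper-equal/costlier-equal/
equivalent marker instead of a division. Quadrants of the
cost-effectiveness plane classify the signs (zero counted as
non-negative): NE costlier-and-more-effective, SE dominant, NW
dominated, SW cheaper-and-less-effective. Against the
willingness-to-pay threshold (WTP, 3,701 USD/QALY): in NE the more
effective strategy is preferred iff ICER ≤ WTP; in SW — where the ICER
is the saving per QALY forgone — the cheaper strategy is preferred iff
that saving ≥ WTP. ICERs are displayed to one decimal; full precision
is kept internally.

## Sensitivity and scenario analysis

The one-way deterministic sensitivity analysis moves one parameter at a
time to the ends of its range and reruns the whole comparison; entries
sorted by ICER swing give the tornado ordering. The default ranges are
±20% on the drug annual cost (both therapy phases together), the
surgical-year cost, year-1 noncompliance, both cancer probabilities,
the cancer utility, the start-age baseline utility, and the two
discount rates, capped so probabilities and utilities stay valid. The
surgical-improvement parameter is exposed to the DSA machinery but not
in the default list: a ±20% move crosses the large utility step between
IPSS 7 and 8 and flips the sign of the (small) incremental QALY, which
makes the ICER swing degenerate; net monetary benefit
(`outcome="nmb"`) is the sign-stable alternative for such cases.

The scenario catalogue contains the base case plus eight variants:
public-only and private-only tariffs, chemoprevention off, OP-only and
TURP-only surgery mixes, and start ages 40/50/60 with their age-band
baseline utilities (1.0, 0.94, 0.88). Age-band scenarios start the
cohort at the band's lower bound and let the life-table lookup follow
it; the mix scenarios keep the blended state costs (per-type costs are
not published) and act through the per-type death add-on and
complication profile.

## Synthetic fixtures

Two required inputs have no published values and are shipped as
clearly-labelled synthetic stand-ins:

* **Life table** (`life_table_iran2011_male_synthetic.csv`): assumed
  annual male death probabilities by decade, 0.003 at 40–50 rising to
  0.10 at 80–90 — plausible in level and monotone in age, but not
  estimated from census data.
* **Complication profiles** (`complications_synthetic.csv`): per
  surgery type, annual probabilities and utility decrements for the
  classic TURP complication list (strictures, bladder-neck stenosis,
  recurrence, fever, infection, transfusion, revision) and a shorter OP
  list. Incidence-weighted annual decrements: TURP 0.00495, OP 0.00060
  — small by construction so surgery-state utility stays near its
  IPSS-derived value, and deliberately TURP-heavy, which is what gives
  the OP-only scenario its larger QALY gap.

Because these two inputs are assumed, the absolute cohort totals,
incremental costs, and scenario ICERs the package computes are internal
model outputs, not reproductions of published numbers; what the tests
pin down instead are the exact arithmetic of every published input, the
engine's structural invariants, agreement with an independent
individual-level microsimulation, and the directional findings
(chemoprevention removal lowers the ICER; OP-only widens the QALY gap
relative to TURP-only; the drug unit cost dominates the tornado).
Under the shipped fixtures the base case lands in the NW quadrant
(pharmacotherapy slightly costlier and slightly less effective than
surgery) rather than SW: the pharmacotherapy arm pays both the drug
stream and the surgical costs of its 30% crossover, so its relative
cost depends strongly on the assumed mortality level. Passing tests
therefore certify the machinery and the qualitative structure, not
Iranian point estimates.

The microsimulation oracle (`microsim_oracle`) samples individual
patient paths from the same per-cycle matrices (through the public
matrix constructor only) and accrues the same discounted values, so its
means estimate exactly what the cohort engine computes; the acceptance
suite requires agreement within three standard errors at n = 200,000 on
the base case and on five seeded ±20% parameter perturbations.

## Numerical choices and edge cases

* Transition-matrix rows are built to sum to 1 by construction and
  asserted to 1e-12; traces conserve the cohort to 1e-9.
* Death probabilities are capped at 1 after add-ons; if the cap makes a
  row infeasible the row is named in the error.
* `perturb_parameters` jitters scalars multiplicatively and clamps
  probabilities (≤0.9) and utilities (≤1) so every invariant still
  holds; magnitude 0 is the exact identity.
* A post-surgical IPSS below the table floor clamps to the floor with a
  warning rather than failing.
* Problem sizes: cohort 1000, horizon 10 cycles, microsimulation
  n = 200,000 in tests and 100,000 in the acceptance script — the whole
  validation battery runs in seconds.

## Known limitations

* No probabilistic sensitivity analysis and no two-way DSA — out of
  scope by design.
* Cancer onset age does not modify cancer costs or utilities beyond the
  flat 0.62 utility and the two-phase cost.
* The microsimulation oracle does not support the half-cycle
  correction (it simulates whole cycles); the cohort engine's optional
  correction is therefore validated only structurally.
* Sector tariffs and the two synthetic fixtures are configuration
  placeholders; any real-world use must replace them with jurisdiction-
  specific inputs via the config document.
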