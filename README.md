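# bphcea

Cost-utility analysis of dutasteride pharmacotherapy versus surgery
(TURP/open prostatectomy) for moderate benign prostatic hyperplasia
(BPH), as a tested, reusable Python pipeline.

The package is aimed at health-economics analysts who want a
transparent, scriptable implementation of this decision problem: a
seven-state annual-cycle Markov cohort model with decision-tree entry,
IPSS-based utilities, differential discounting, ICER/willingness-to-pay
decision logic, one-way deterministic sensitivity analysis (tornado),
a nine-scenario catalogue, and an individual-level microsimulation
oracle for validating the cohort engine.

## The model in brief

A cohort of 1000 men aged 70 enters either *pharmacotherapy*
(dutasteride, state `drug_y1`) or *surgery* (80% TURP / 20% OP, state
`surg_y1`) and is propagated for 10 annual cycles through the states
{drug_y1, drug_later, surg_y1, surg_later, pc_y1, pc_later, death}.
Key inputs: year-1 noncompliance 0.3 (crossover to surgery), later
crossover 0.005/yr, prostate-cancer incidence 0.000836/yr on drug
(×0.75 in therapy years 1–2, the chemoprevention effect) and 0.0011/yr
after surgery, cancer excess mortality +0.18/yr, surgical death add-on
0.001 (TURP) / 0.002 (OP), blended +0.0012.

Effectiveness: the IPSS trajectory on dutasteride (16.7, 12.3, 11.3,
10.6 at years 1–4; year 1 excluded as pre-response) is extrapolated by
OLS, `IPSS(t) = 13.95 − 0.85·t`; surgery improves IPSS by 8.5 units to
8.2. IPSS maps to utility through a tabulated decreasing function,
multiplied by an age-band baseline (0.8 at 70–80); cancer states carry
utility 0.62. Costs (USD/yr): drug 146.36, surgical year 840.96,
follow-up 9, cancer 6,141 then 2,303. Costs discount at 7%/yr,
utilities at 3%/yr. With pharmacotherapy as the alternative and surgery
as the reference,

    ICER = (C_pharm − C_surg) / (Q_pharm − Q_surg),

classified on the cost-effectiveness plane and judged against a
willingness-to-pay threshold of 3,701 USD/QALY (in the SW quadrant the
ICER is the saving per QALY forgone and the cheaper strategy wins iff
it meets the threshold).

Two inputs have no published values — the age-specific mortality
schedule and the surgical complication probabilities/disutilities —
and are shipped as documented synthetic stand-ins (see
`docs/methods.md`); absolute totals computed with them are model
outputs of this implementation, not reproductions of published totals.

## Worked example

```python
import bphcea

params = bphcea.load_model(None)          # base case
result = bphcea.compare_arms(params)      # pharmacotherapy vs surgery
print(round(result.inc_cost, 2), round(result.inc_qaly, 2))
print(result.icer.quadrant, round(result.icer.value, 1), result.verdict)
```

prints, under the shipped synthetic fixtures:

```
26090.96 -41.74
NW -625.1 surgery
```

i.e. over ten years the pharmacotherapy arm costs 26,091 USD more and
yields 41.7 QALY less than the surgery arm (per 1000 patients), so it
is dominated here and surgery is preferred — a verdict that hinges on
the assumed mortality level, as the drug arm also pays for its 30%
noncompliance crossover surgeries. The same pipeline from the shell:

```bash
bphcea run --out results/ --paren-negatives
bphcea scenarios --out scenarios.csv
bphcea dsa --out tornado.csv --plot tornado.png
bphcea fixtures --list
```

`bphcea run` writes `arms.csv`, `scenarios.csv` and `comparison.json`;
custom inputs go in a YAML/JSON config validated against
`docs/config.schema.json`, e.g.

```yaml
settings: {start_age: 60, wtp: 5000}
transitions: {chemoprevention_enabled: false}
```

with `bphcea run --config my.yaml`. Scenario analysis covers the base
case plus eight variants (public/private tariffs, chemoprevention off,
OP-only, TURP-only, start ages 40/50/60); the tornado ranks ±20%
parameter ranges by ICER swing — the dutasteride unit cost dominates.

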