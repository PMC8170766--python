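# SYNTHETIC life table: age-specific annual death probabilities for Iranian
# men circa 2011. These are assumed, plausible values chosen for realism
# (monotone increasing with age), NOT estimates derived from census data.
# Totals computed with this schedule are not comparable to published results.
age_low,age_high,annual_death_probability
40,50,0.003
50,60,0.008
60,70,0.018
70,80,0.045
80,90,0.10
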