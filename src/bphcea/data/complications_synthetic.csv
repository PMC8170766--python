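# SYNTHETIC surgical complication profiles per surgery type.
# annual_probability and utility_decrement are assumed, plausible magnitudes
# (not taken from any published source); the per-type weighted annual utility
# decrement (sum of probability x decrement) is 0.00495 for TURP and 0.00060
# for open prostatectomy, kept small so surgery-state utility stays near the
# value implied by the IPSS-utility table. management_cost_usd is recorded for
# reference; state costs already include complication management and are not
# incremented by it.
surgery_type,complication,annual_probability,utility_decrement,management_cost_usd
turp,urethral_stricture,0.030,0.040,9.00
turp,meatal_stenosis,0.010,0.030,2.00
turp,bladder_neck_stenosis,0.020,0.040,9.00
turp,turp_recurrence,0.020,0.050,0.00
turp,postoperative_fever,0.040,0.010,0.71
turp,infection,0.040,0.020,0.71
turp,transfusion,0.020,0.010,0.00
turp,surgical_revision,0.005,0.050,0.00
op,bladder_neck_contracture,0.005,0.040,9.00
op,urethral_stricture,0.005,0.040,9.00
op,infection,0.010,0.020,0.71
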