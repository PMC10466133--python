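# Canonical in-silico trial: closed-loop propofol delivery to the effect site.
#
# 1000 demographically identical virtual subjects (36-year-old women, 70 kg,
# 170 cm), effect-site target 6 mg/L, one plasma measurement every 30 s with a
# 15 s value delay.  Population constants are literature values for a
# reference adult under a broadly-applicable propofol PK model; volumes in L,
# clearances in L/min, ke0 in 1/min, omegas are log-scale SDs.
population:
  means: {CL: 2.10, V1: 6.28, V2: 25.5, V3: 273.0, Q2: 1.75, Q3: 1.11, ke0: 0.146}
  omegas: {CL: 0.515, V1: 0.781, V2: 0.752, V3: 0.773, Q2: 0.588, Q3: 0.457}
  prop: 0.2        # proportional residual term (dimensionless)
  add: 0.02        # additive residual term, mg/L

trial:
  n_subjects: 1000
  seed: 20260101
  target_mg_per_L: 6.0
  duration: 15 min
  mode: effect_site
  arms: [open_loop, closed_loop]

sensor:
  period: 30 s
  delay: 15 s

failure:
  probability: 0.0   # occasional out-of-distribution failures, off by default

actuator:
  max_rate_mg_per_min: 200.0
  syringe_volume_mg: 2000.0
  low_reservoir_fraction: 0.1
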