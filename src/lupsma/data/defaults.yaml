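# Default model parameterization for [177Lu]Lu-PSMA-I&T population PKPD.
# Values carry the units in which they are conventionally reported; unit
# conversions into the internal hour/MBq system happen at load time.
pk:
  structural:
    k10: {value: 0.253, units: "1/h"}            # renal excretion from central
    k12: {value: 0.0105, units: "1/h"}           # central -> salivary glands
    k21: {value: 0.0629, units: "1/h"}
    k13: {value: 0.0321, units: "1/h"}           # central -> kidneys
    k31: {value: 0.0625, units: "1/h"}
    k14: {value: 0.00967, units: "1/h"}          # central -> tumor
    k41: {value: 0.0150, units: "1/h"}
    k15: {value: 0.275, units: "1/h"}            # central -> remaining tissue
    k51: {value: 0.0247, units: "1/h"}
    B_MAX_sal: {value: 134.0, units: "MBq"}      # salivary saturable capacity
    V1: {value: 10.3, units: "L", fixed: true}   # central volume
  covariates:
    theta_TV_k12: {value: 0.0910, units: "-"}    # power of TV on k12 (tumor sink)
    theta_TV_k14: {value: 1.08, units: "-"}      # power of TV on k14
    cycle_fractions:                              # fraction of cycle-1 k14
      cycle2: 0.731
      cycle3: 0.498
      cycle4_7: 0.436
    WT_median: {value: 79.0, units: "kg"}
    TV_median: {value: 0.0443, units: "L"}
    allometric_exponent_k: -0.25
    allometric_exponent_V: 1.0
  iiv_cv_percent:
    k10: 33.1
    k13: 33.4
    k14: 63.4
    k15: 29.1
    B_MAX_sal: 67.0
  iov_cv_percent:
    k14: 37.8
  residual_error:
    central: {kind: combined, prop_cv_percent: 55.5, add_sd: 9.57, units: "MBq/L"}
    salivary: {kind: proportional, prop_cv_percent: 39.7}
    kidneys: {kind: proportional, prop_cv_percent: 31.9}
    tumor: {kind: proportional, prop_cv_percent: 32.7}
  physical_half_life_h: 159.528                  # 177Lu, 6.647 days

pd:
  structural:
    PSA0: {value: 140.0, units: "ug/L", fixed: true}
    theta_TV_PSA0: {value: 57.5, units: "ug/L"}  # linear TV covariate on baseline
    kG: {value: 0.000408, units: "1/h"}          # exponential PSA growth
    kD_direct: {value: 0.00335, units: "L/day/GBq"}
    ke0: {value: 0.00128, units: "1/h"}          # effect-compartment rate
    kD_delay: {value: 0.0000328, units: "L/day/MBq"}
    boxcox_shape: {value: -0.822, units: "-"}
  iiv_cv_percent:
    PSA0: 179.0
    kG: 90.9
    kD_direct: 140.0
    kD_delay: 87.5
  residual_error:
    psa: {kind: proportional, prop_cv_percent: 29.3}

population:
  WT: {median: 79.0, low: 61.0, high: 116.0, units: "kg"}
  TV: {median: 0.0443, low: 0.000122, high: 0.546, units: "L"}

schedule:
  scan_offsets_h:
    means: [4.6, 23.8, 163.2]
    sds: [0.95, 4.5, 11.0]
  psa_interval_weeks: 4
  baseline_psa_window_weeks: 6

blood_correction:
  intercept: 6.27      # MBq/L
  slope: 0.828

flags:
  cv_to_omega: direct          # direct: omega = CV/100; lognormal_exact: sqrt(ln(1+CV^2))
  baseline_psa_covariate: literal   # literal: PSA0 + theta*(TV/TVmed); centered: PSA0 + theta*(TV/TVmed - 1)
  decay_mode: physical
  salivary_cycle_effect: false # optional scenario (0.846 cycle 2, 0.981 cycle 3)

solver:
  rtol: 1.0e-8
  atol: 1.0e-10
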