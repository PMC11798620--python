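# Sequential Organ Failure Assessment component thresholds (standard dialect).
# Each numeric system lists breakpoints mapping a measurement to a 0-4 subscore.
# direction: "lower_worse" scores rise as the measurement falls below each
# breakpoint; "higher_worse" scores rise as it meets/exceeds each breakpoint.
# Cardiovascular vasopressor dose tiers (ug/kg/min) are listed separately.
version: 1
systems:
  respiration:
    measurement: pao2_fio2_ratio
    units: mmHg
    direction: lower_worse
    # score s if measurement < breakpoints[s-1]; scores 3-4 assume
    # ventilatory support per the standard table
    breakpoints: [400, 300, 200, 100]
  coagulation:
    measurement: platelets
    units: 10^3/uL
    direction: lower_worse
    breakpoints: [150, 100, 50, 20]
  liver:
    measurement: bilirubin
    units: mg/dL
    direction: higher_worse
    # score s if measurement >= breakpoints[s-1]
    breakpoints: [1.2, 2.0, 6.0, 12.0]
  cns:
    measurement: glasgow_coma_scale
    units: points
    direction: lower_worse
    # GCS 15 -> 0, 13-14 -> 1, 10-12 -> 2, 6-9 -> 3, <6 -> 4
    breakpoints: [15, 13, 10, 6]
  renal:
    measurement: creatinine
    units: mg/dL
    direction: higher_worse
    breakpoints: [1.2, 2.0, 3.5, 5.0]
    # urine output (mL/day) criterion; the worse of the two governs
    urine_output:
      units: mL/day
      thresholds: {3: 500, 4: 200}
  cardiovascular:
    measurement: mean_arterial_pressure
    units: mmHg
    direction: lower_worse
    # MAP >= 70 -> 0, MAP < 70 -> 1; vasopressor tiers override upward
    hypotension_map: 70
    vasopressor_tiers:
      2: "dopamine <= 5 or any dobutamine"
      3: "dopamine > 5, or epinephrine <= 0.1, or norepinephrine <= 0.1"
      4: "dopamine > 15, or epinephrine > 0.1, or norepinephrine > 0.1"
    dose_cutoffs:
      dopamine_low: 5.0
      dopamine_high: 15.0
      epi_norepi: 0.1
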