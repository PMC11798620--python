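# PA — multi-principle point system without exclusion criteria.
# SOFA scored in four bands plus points for severe life-limiting
# comorbidities (dementia deliberately scored 0 — not treated as a
# qualifying comorbidity); age and frontline status count only in ties,
# with a randomized lottery as the final resolution step.
# Point values reconstructed by calibration against the reference
# nine-patient allocation.
id: PA
name: University of Pittsburgh Medical Center protocol (Pennsylvania)
sofa_bands:
  - {lo: 0, hi: 5, points: 1}
  - {lo: 6, hi: 8, points: 2}
  - {lo: 9, hi: 11, points: 3}
  - {lo: 12, points: 4}
comorbidity_points: {severe_life_limiting: 4}
comorbidity_point_overrides: {dementia: 0}
frontline_policy: tiebreak_only
tiebreak_chain: [younger_age, frontline, lottery]
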