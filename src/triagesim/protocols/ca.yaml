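# CA — multi-principle point system with a frontline exemption.
# No exclusion criteria; healthcare workers and first responders are
# temporarily exempted from scoring and receive ventilators first;
# remaining patients score SOFA bands plus graded age points, with a
# pregnancy subtraction; ties resolved by randomized lottery.
# Point values reconstructed by calibration against the reference
# nine-patient allocation.
id: CA
name: California Department of Health guideline
sofa_bands:
  - {lo: 0, hi: 5, points: 1}
  - {lo: 6, hi: 8, points: 2}
  - {lo: 9, hi: 11, points: 3}
  - {lo: 12, points: 4}
age_bands:
  - {lo: 0, hi: 49, points: 0}
  - {lo: 50, hi: 69, points: 1}
  - {lo: 70, hi: 84, points: 2}
  - {lo: 85, points: 3}
pregnancy_modifier: -3
frontline_policy: exemption
tiebreak_chain: [lottery]
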