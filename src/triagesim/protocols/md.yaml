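# MD — multi-principle point system with exclusion screening.
# Excludes severe life-limiting comorbidities and SOFA > 14 (strict);
# scores SOFA in three bands, adds an age point at 50+, subtracts points
# for pregnancy; ties resolved by younger age, then first-come-first-served.
# Point values reconstructed by calibration against the reference
# nine-patient allocation (metastatic cancer is NOT excluded here: the
# reference outcomes allocate the metastatic-cancer patient under MD).
id: MD
name: American College of Chest Physicians framework (Maryland)
sofa_exclusion: {comparator: ">", cutoff: 14}
excluded_comorbidities: [esrd, ms_late_stage, hf_nyha_iv]
sofa_bands:
  - {lo: 0, hi: 5, points: 1}
  - {lo: 6, hi: 9, points: 2}
  - {lo: 10, hi: 14, points: 3}
age_bands:
  - {lo: 0, hi: 49, points: 0}
  - {lo: 50, points: 1}
pregnancy_modifier: -2
frontline_policy: ignored
tiebreak_chain: [younger_age, fcfs]
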