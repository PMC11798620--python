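# NY — SOFA-only priority groups with an exclusion ceiling.
# Excludes SOFA > 11 (strict); two qualitative priority bands
# (SOFA <= 7 highest, 8-11 second); no age, pregnancy or occupation
# consideration; ties broken first-come-first-served.
# Band cut reconstructed by calibration against the reference
# nine-patient allocation.
id: NY
name: New York State Department of Health guideline
sofa_exclusion: {comparator: ">", cutoff: 11}
sofa_bands:
  - {lo: 0, hi: 7, points: 1}
  - {lo: 8, hi: 11, points: 2}
frontline_policy: ignored
tiebreak_chain: [fcfs]
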