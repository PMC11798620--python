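# FL — exclusion screening plus raw-SOFA ranking.
# Excludes all severe life-limiting comorbidities and SOFA >= 10
# (inclusive); eligible patients are ranked by their raw SOFA total
# (lower = higher priority); ties broken first-come-first-served.
# Cutoff reconstructed by calibration against the reference
# nine-patient allocation.
id: FL
name: Baptist Health System protocol (Florida)
sofa_exclusion: {comparator: ">=", cutoff: 10}
excluded_comorbidities: [esrd, metastatic_cancer, ms_late_stage, hf_nyha_iv]
sofa_bands: raw
frontline_policy: ignored
tiebreak_chain: [fcfs]
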