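# NE — qualification-only screening with no tie-breaking mechanism.
# Patients qualify iff SOFA < 10; the protocol specifies no severity
# scoring among qualifiers and no tie-break or lottery, so when demand
# exceeds capacity every qualifying patient's allocation is left
# undetermined.  Cutoff reconstructed by calibration against the
# reference nine-patient allocation.
id: NE
name: Nebraska Medical Emergency Operations Center guidance
qualification_sofa_cutoff: 10
frontline_policy: ignored
tiebreak_chain: []
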