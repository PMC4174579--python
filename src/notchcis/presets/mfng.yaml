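# Manic Fringe: strengthens Notch1-Dll1 cis and trans association,
# weakens Notch1-Jag1 cis and trans association; enhances binding of the
# Dll1-Fc detection reagent to modified Notch1.
identity: Mfng
cis_factor: {Dll1: 2.0, Jag1: 0.2}
trans_factor: {Dll1: 2.0, Jag1: 0.2}
detection_gain: 1.5
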