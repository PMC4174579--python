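# No Fringe expression: all interaction factors unity.
identity: none
cis_factor: {Dll1: 1.0, Jag1: 1.0}
trans_factor: {Dll1: 1.0, Jag1: 1.0}
detection_gain: 1.0
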