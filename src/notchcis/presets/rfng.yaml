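# Radical Fringe: preserves or enhances Notch1 interactions with both
# ligands, in cis and in trans.
identity: Rfng
cis_factor: {Dll1: 1.5, Jag1: 1.5}
trans_factor: {Dll1: 1.5, Jag1: 1.5}
detection_gain: 1.5
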