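# Drosophila Fringe (wing-disc boundary model): strengthens Delta-Notch
# interactions and weakens Serrate-Notch interactions.  The large Delta
# trans factor encodes the observation that Delta signals poorly to
# Fringe-negative receivers relative to Fringe-positive ones.
identity: fng
cis_factor: {Delta: 2.0, Serrate: 0.2}
trans_factor: {Delta: 5.0, Serrate: 0.1}
detection_gain: 1.5
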