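# Regular-train summation of one NMDAR synapse (closing time 80 ms).
freqs: [5.0, 10.0, 15.0, 20.0, 25.0, 40.0, 60.0, 100.0]
n_spikes: 40
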