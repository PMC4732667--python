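# Generic HH population: feedback sweep (nS/synapse) + canonical on/off run
# (excitation at 100/600 ms, inhibitory 10x7ms bursts at 300/1400 ms, 3 nS).
g_grid: [0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0, 1.5, 2.0]
seeds: [1, 2, 3]
duration: 1100.0
canonical_g: 0.6
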