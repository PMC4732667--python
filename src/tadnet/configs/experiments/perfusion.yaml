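# NMDA perfusion of the 30-dIN column: conductance grid (nS), run length.
g_grid: [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0]
duration: 1200.0
seed: 0
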