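# Sensory start: feedback NMDA g_peak sweep (nS/synapse), 3 seeds.
g_grid: [0.05, 0.07, 0.09, 0.11, 0.13, 0.15, 0.2, 0.25]
seeds: [1, 2, 3]
duration: 1400.0
canonical_g: 0.11
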