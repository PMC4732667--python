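# MHR stop: burst grid (1-5 spikes x 10/15/20 ms ISI), GABA-A 2 nS,
# inhibition at 700 ms on the 0.11 nS/synapse canonical rhythm (~25 Hz).
n_spikes_grid: [1, 2, 3, 4, 5]
isi_grid: [10.0, 15.0, 20.0]
n_trials: 3
nmda_g_peak: 0.11
gaba_g_peak: 2.0
inhibition_onset: 700.0
seed: 0
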