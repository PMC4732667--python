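# Generic single-compartment neuron: the canonical squid-axon channel set
# (rest ~ -65 mV), used for the 30-neuron generalization network.
# Densities are mS/cm^2.

geometry:
  soma_length: 20.0   # um
  soma_diameter: 16.0 # um

passive:
  cm: 1.0
  axial_resistivity: 100.0

soma_channels:
  hh_na: 120.0
  hh_k: 36.0
  hh_leak: 0.3

channels:
  - name: hh_na
    reversal_potential: 50.0
    gates:
      - name: m
        exponent: 3
        mode: alpha_beta
        alpha: {form: linoid, a: 0.1, b: -40.0, c: 10.0}
        beta: {form: exponential, a: 4.0, b: -65.0, c: -18.0}
      - name: h
        exponent: 1
        mode: alpha_beta
        alpha: {form: exponential, a: 0.07, b: -65.0, c: -20.0}
        beta: {form: sigmoid, a: 1.0, b: -35.0, c: -10.0}
  - name: hh_k
    reversal_potential: -77.0
    gates:
      - name: n
        exponent: 4
        mode: alpha_beta
        alpha: {form: linoid, a: 0.01, b: -55.0, c: 10.0}
        beta: {form: exponential, a: 0.125, b: -65.0, c: -80.0}
  - name: hh_leak
    reversal_potential: -54.387
    gates: []
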