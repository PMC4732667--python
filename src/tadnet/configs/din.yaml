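# Default dIN parameter set.
#
# The channel kinetics below are the package's own parameter set (shifted
# Traub-Miles style Na/K rates, a fast-activating slow-decaying K gate that
# builds the after-spike hyperpolarization, and a small GHK calcium
# channel), tuned once to the behavioural constraints of the modelled cell:
# stable rest near -60 mV, high input resistance, conditional pacemaker
# firing at 10-30 Hz under ~1-2 nS of sustained Mg-blocked NMDAR drive with
# a saturating frequency-conductance curve, depolarization block under
# strong unblocked (Mg-free) drive, and reliable spike propagation along
# the fine descending axon.
# Densities are mS/cm^2 (GHK: permeability, cm/s).

geometry:
  soma_length: 12.0        # um
  soma_diameter: 12.0      # um
  axon_span: 1000.0        # um (descending, caudal)
  axon_comp_length: 20.0   # um
  axon_diameter: 0.4       # um

passive:
  cm: 1.0                  # uF/cm^2
  axial_resistivity: 100.0 # Ohm cm

soma_channels:
  din_na: 40.0
  din_kf: 8.0
  din_ks: 1.5
  din_ca: 1.5e-6
  din_leak: 0.05

axon_channels:
  din_na: 80.0
  din_kf: 12.0
  din_leak: 0.03

channels:
  - name: din_na
    reversal_potential: 50.0
    gates:
      - name: m
        exponent: 3
        mode: alpha_beta
        alpha: {form: linoid, a: 0.32, b: -47.0, c: 4.0}
        beta: {form: linoid, a: -0.28, b: -20.0, c: -5.0}
      - name: h
        exponent: 1
        mode: inf_tau
        v_half: -55.0
        slope: -6.0
        tau_base: 1.0
        tau_amp: 24.0
        tau_vmid: -55.0
        tau_sigma: 20.0
  - name: din_kf
    reversal_potential: -80.0
    gates:
      - name: n
        exponent: 4
        mode: alpha_beta
        alpha: {form: linoid, a: 0.032, b: -43.0, c: 5.0}
        beta: {form: exponential, a: 0.5, b: -48.0, c: -40.0}
  - name: din_ks
    reversal_potential: -80.0
    gates:
      - name: q
        exponent: 1
        mode: inf_tau
        v_half: -30.0
        slope: 5.0
        tau_base: 3.0
        tau_amp: 11.0
        tau_vmid: -62.0
        tau_sigma: 12.0
  - name: din_ca
    ghk:
      permeability: 1.0e-6   # placeholder; per-region value is authoritative
      ca_in: 1.0e-4          # mM
      ca_out: 10.0           # mM
      temperature: 293.15    # K
      valence: 2
    gates:
      - name: c
        exponent: 2
        mode: inf_tau
        v_half: -22.0
        slope: 6.0
        tau_base: 2.0
  - name: din_leak
    reversal_potential: -63.0
    gates: []
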