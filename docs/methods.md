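# Methods

## Scope and units

`tadnet` simulates one side of the tadpole hindbrain swimming circuit: a
column of 30 electrically coupled reticulospinal dINs with glutamatergic
feedback, its sensory start (tIN) and inhibitory stop (MHR) pathways, and a
generalization network of 30 classic Hodgkin–Huxley neurons.  The internal
unit system is {mV, ms, nF, µS, nA, MΩ}, which is closed under Ohm's law
and the membrane equation; user-facing synaptic strengths are nS, channel
densities mS/cm², GHK permeabilities cm/s, geometry µm.

Sign convention, applied everywhere: outward membrane current is positive
and `C dV/dt = −Σ i_ion − i_syn + i_inj`.

## Membrane model

Gated currents are Hodgkin–Huxley type, `i = ḡ Π x_k^{p_k} (V − E)`.  Gate
kinetics are given either as α/β rate functions (exponential, sigmoid, or
exp-linear "linoid" forms; the linoid's removable singularity is evaluated
by series expansion) or as a sigmoidal steady state with a Gaussian-bell
voltage-dependent time constant.  The calcium current uses the
Goldman–Hodgkin–Katz constant-field equation with z = 2, R = 8.314 J/(mol·K),
F = 96485 C/mol, fixed internal/external Ca²⁺ (0.1 µM / 10 mM) and
T = 293.15 K; the 0/0 form at V = 0 is replaced by its series limit.
Intracellular calcium dynamics, Q10 scaling and stochastic gating are out
of scope.

### The dIN parameter set

The experimental literature establishes dIN *behaviour* (stable rest near
−60 mV, high input resistance, single spike to local current injection when
electrically coupled, conditional pacemaker firing at swimming frequencies
under sustained NMDAR drive) but not voltage-clamped channel kinetics, so
the channel parameters in `configs/din.yaml` are this package's own set,
calibrated once against those behavioural constraints and then frozen:

* **Na** (m³h): shifted Traub–Miles-style activation; inactivation is an
  inf/τ gate with V½ = −55 mV (slope −6), fast at spike voltages
  (τ ≈ 1 ms) and slow around the inter-spike trough (τ ≈ 25 ms at −55 mV).
  The steep, slow recovery is what gives the cell a limited maximum firing
  rate and makes sustained unblocked (Mg-free) NMDAR conductance produce
  depolarization block.
* **K fast** (n⁴): Traub–Miles-style delayed rectifier, spike
  repolarization.
* **K slow** (q¹): the rate-limiting after-spike current.  Activation is
  sigmoidal (V½ = −30 mV) with a strongly voltage-dependent τ: ~3 ms at
  spike voltages and ~14 ms near −62 mV.  Each spike therefore loads a
  deep, brief AHP whose relaxation sets the pacemaker period; its
  saturation with rate flattens the frequency–conductance curve (~13 Hz at
  0.8 nS, ~2× that at 2 nS, plateauing near 55–70 Hz).
* **Ca (GHK)** (c²): small permeability (1.5·10⁻⁶ cm/s); spike-shape
  contribution only.
* **Leak**: E = −63 mV; densities chosen for a several-hundred-MΩ input
  resistance.

Geometry: 12 µm soma/dendrite cylinder (electrotonically compact, carries
all chemical synapses) and a 1000 µm descending axon of fifty 20 µm
compartments, 0.4 µm diameter, with Na density double the somatic value to
secure propagation against the coupling shunt.  Axon length, compartment
size and densities are config-exposed; the real axon geometry is unknown.

The generic neuron is the canonical squid-axon set (120/36/0.3 mS/cm²,
rest ≈ −65 mV) on a single 20×16 µm compartment.

## Synapses

Dual-exponential kinetics: between events `dA/dt = −A/τ_o`,
`dB/dt = −B/τ_c`; a delivery steps A and B by 1; conductance is
`g_peak (B−A)/norm` with `norm = e^{−t_p/τ_c} − e^{−t_p/τ_o}` and
`t_p = τ_o τ_c/(τ_c−τ_o) · ln(τ_c/τ_o)`, so a single event peaks at exactly
`g_peak`.  Deliveries are queued 1 ms after an upward 0 mV crossing of the
presynaptic soma (hysteresis: no re-detection until the trace falls below
−10 mV), with per-spike Bernoulli transmission where unreliability is
modelled.  NMDAR current is multiplied by the magnesium-block sigmoid
`1/(1 + η[Mg]ₒ e^{−γV})` (η = 0.1 mM⁻¹, γ = 0.08 mV⁻¹, [Mg]ₒ = 0.5 mM);
"zero-Mg" runs set the factor to 1.  Shipped kinetics: feedback NMDA
τ_o 5 / τ_c 80 ms, feedback AMPA 0.1 / 3 ms, GABA-A 1.5 / 20 ms at
−70 mV.  Excitatory reversal is 0 mV.  Receptor desensitization,
short-term plasticity and NMDAR saturation are not modelled.

Two ratios are free choices (the source literature gives components but not
amplitudes) and were fixed during the one-time calibration: feedback
AMPA g_peak = 0.4 × the NMDA g_peak, and sensory tIN contacts of
0.6 nS AMPA + 0.15 nS NMDA, which make a threshold-level volley recruit the
whole population without over-driving the post-volley rhythm.

## Populations

dIN somata sit at 0, −10, …, −290 µm (rostral = larger coordinate).  For
every ordered rostral→caudal pair whose axon reaches the caudal soma, one
600 MΩ gap junction joins the rostral neuron's axon compartment nearest
that soma to the caudal neuron's most proximal axon compartment
(deterministic placement — the simplest rule consistent with dense local
axo-axonal coupling; a per-pair probability can be configured).  Feedback
synapses are sampled per ordered pair at p = 0.2 and land on the soma.
Synaptic peak conductances carry multiplicative truncated-normal noise with
relative variance 0.1 in both populations (read as *relative* variance:
absolute nS² variance would dwarf the 0.1 nS-scale strengths).  The generic
population uses 100 MΩ soma–soma junctions sampled per unordered pair at
p = 0.2 and channel-density noise of 10% relative s.d.  Self-synapses are
excluded.

## Stimuli

* **tIN generative model**: spike count n ∈ {0..5} drawn from a piecewise
  linear-in-s distribution pinned to the measured anchors P(1|95%) = 0.5,
  P(1|100%) = 1, P(1|>120%) = 0.3 with the residual high-stimulus mass
  spread geometrically (ratio 0.5) over counts 2–5; spike k is timed
  normal(µ_k, σ_k) with defaults µ_k = 10+8(k−1) ms, σ_k = 2+1.5(k−1) ms.
  Anchors are measured constraints; the interpolation, the geometric tail
  and the timing parameters are package defaults.  20 tINs contact every
  dIN (AMPA+NMDA) with 50% per-spike transmission per contact.
* **MHR stop burst**: n spikes at a fixed interval; duration (n−1)·ISI.
* **NMDA perfusion**: a clamped conductance ramped linearly to its target
  and held, applied identically to every soma, with the Mg factor
  switchable.  The clamp replaces integrating the perfused receptor's own
  τ_c = 10 s kinetics: once activation is externally controlled only the
  conductance level matters, and the steady level equals the target
  exactly.
* **Step currents** into arbitrary compartments.

## Integration

Fixed-step (default dt = 0.025 ms).  Gates advance by exponential
(Rush–Larsen) updates using steady states and time constants tabulated on a
0.05 mV grid, staggered half a step against the voltage.  The voltage step
is a Crank–Nicolson (θ = ½) solve of the compartment system: ohmic channel
and synaptic conductances enter the linear system; GHK current, the Mg
factor and gap-junction neighbour voltages are held at their start-of-step
values.  Ordering compartments per neuron keeps the matrix tridiagonal
(axial coupling), with gap-junction conductance lumped onto the diagonal,
so one Thomas solve per step covers the whole network.  The loop is
compiled with numba.  Spike times are interpolated at the 0 mV upward
crossing; feedback deliveries are snapped to the step nearest the crossing
time plus the 1 ms delay; external events to the step nearest their time.
Integration aborts with a diagnostic if any |V| exceeds 200 mV.

**Convergence.**  Halving dt from 0.025 to 0.0125 ms moves single-neuron
spike times by < 0.5 ms over a 1 s run, and network *onset* (first-spike)
times by ~0.1 ms.  Individual late spike times in the 30-neuron recurrent
network do not converge at any practical step — small perturbations grow
roughly tenfold per 300 ms of network time — so convergence there is
assessed on the well-posed observables: onset spikes, sustained-phase
firing rate, and the sustained/dies-out outcome.  This is a property of
recurrent spiking dynamics, not of the integrator.

Randomness is split into independent seeded streams (connectivity, weight
noise, density noise, tIN volley, transmission, in-kernel feedback
transmission), all derived from user-visible seeds, so every experiment is
bit-for-bit reproducible from (config, seed).

## Analysis conventions

Sustained-phase windows start 300 ms after the sensory volley; a run is
*sustained* if any neuron spikes in its final 300 ms, and *reliable* means
sustained in ≥ 90% of seeds.  Swimming bands: 10–25 Hz (whole animal),
15–30 Hz (half-CNS); sweep points classify as dies-out / sustained /
sustained-fast relative to the half-CNS band.  The synchrony index bins the
population spike train at 5 ms and compares its Fano factor against
same-rate Poisson surrogates, mapped to [0, 1]; perfectly coincident trains
score ≈ 0.9 (exactly 1 is unreachable at non-zero rates), independent
trains < 0.2.  Stop probability is the fraction of seeded trials with no
spike later than 200 ms after the inhibition ends.

## Experiment scales

The shipped protocols are sized for a single CPU: perfusion uses a 9-point
conductance grid × {Mg, no-Mg} with 0.6 s (steady-state) and 1.2 s
(firing) runs; the start sweep 7–8 grid points × 3 seeds × 1.4 s; the stop
grid 5×3 cells × 3 trials; the generic sweep 10–11 points × 3 seeds ×
1.1 s.  All grids, seeds and durations are arguments or config entries.

## What the model does and does not show

Passing tests demonstrate the mechanisms — conditional pacemaking under
voltage-dependent NMDAR feedback, range-widening by the Mg block,
synchronization by electrical coupling, switch-on/switch-off by brief
input — in a model whose dIN channel kinetics are calibrated, not measured.
Quantities tied to those kinetics (exact conductance thresholds, the
plateau frequency, stop reliabilities) are model-specific; the qualitative
orderings are the robust claims.  Known limitations: one-sided network
only (no commissural inhibition or anti-phase coordination), no A-type
potassium current, no synaptic depression or NMDAR saturation, fixed ionic
concentrations, and an idealized axon geometry.
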