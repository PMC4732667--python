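"""External drive generators.

* the tIN sensory pathway: a generative spike-time model for a population of
  20 trigeminal interneurons responding to graded head-skin stimulation,
  whose spikes drive unreliable (50%) glutamatergic EPSPs in every dIN;
* the MHR stopping pathway: a short GABAergic burst delivered to all
  neurons simultaneously;
* NMDA perfusion: a clamped conductance ramp applied to every soma;
* step current injections.

Stimulus strength s is expressed as % of the swimming threshold stimulus:
at s = 100 every tIN fires exactly one spike; at s = 95 half do; above
s = 120, 30% fire a single spike and the rest fire 2-5 spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .synapses import SynapseKinetics, sensory_ampa, sensory_nmda

__all__ = [
    "TinSpikeModel", "sample_tin_spike_count", "sample_tin_spike_times",
    "generate_sensory_volley", "MhrBurst", "mhr_burst_times",
    "PerfusionProtocol", "perfusion_drive", "StepCurrent",
    "ExternalSynapticDrive", "StimulusProtocol", "sensory_drive", "mhr_drive",
]

MAX_TIN_SPIKES = 5


@dataclass(frozen=True)
class TinSpikeModel:
    """Generative model of tIN spiking under graded skin stimulation.

    The spike-count distribution p(N = n | s) is piecewise linear in s and
    pinned to the measured anchors: P(N=1 | s=95) = 0.5, P(N=1 | s=100) = 1,
    P(N=1 | s>120) = 0.3 with the residual mass spread geometrically over
    counts 2..5.  Spike k is timed as normal(mu_k, sigma_k) ms after the
    stimulus; the defaults below are package choices (the anchors above are
    the measured constraints).
    """

    s_zero: float = 85.0       # below this, no spikes
    s_half: float = 95.0       # P(one spike) = 0.5
    s_full: float = 100.0      # P(one spike) = 1
    s_multi: float = 120.0     # above this, P(one spike) = 0.3
    p_single_high: float = 0.3
    multi_ratio: float = 0.5   # geometric decay over counts 2..5
    mu: tuple[float, ...] = (10.0, 18.0, 26.0, 34.0, 42.0)
    sigma: tuple[float, ...] = (2.0, 3.5, 5.0, 6.5, 8.0)

    def __post_init__(self):
        if not (self.s_zero < self.s_half < self.s_full < self.s_multi):
            raise ValueError("stimulus anchors must be increasing")
        if len(self.mu) != MAX_TIN_SPIKES or len(self.sigma) != MAX_TIN_SPIKES:
            raise ValueError(f"need {MAX_TIN_SPIKES} spike-time slots")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma_k must be positive")
        if any(b <= a for a, b in zip(self.mu, self.mu[1:])):
            raise ValueError("mu_k must be increasing")

    def pmf(self, s: float) -> np.ndarray:
        """Probability of firing n = 0..5 spikes at stimulus strength s."""
        if s < 0:
            raise ValueError("stimulus strength must be non-negative")
        p = np.zeros(MAX_TIN_SPIKES + 1)
        w = np.array([self.multi_ratio ** k for k in range(4)])
        w /= w.sum()
        if s <= self.s_zero:
            p[0] = 1.0
        elif s <= self.s_half:
            p1 = 0.5 * (s - self.s_zero) / (self.s_half - self.s_zero)
            p[1], p[0] = p1, 1.0 - p1
        elif s <= self.s_full:
            p1 = 0.5 + 0.5 * (s - self.s_half) / (self.s_full - self.s_half)
            p[1], p[0] = p1, 1.0 - p1
        else:
            frac = min(1.0, (s - self.s_full) / (self.s_multi - self.s_full))
            p1 = 1.0 + (self.p_single_high - 1.0) * frac
            p[1] = p1
            p[2:] = (1.0 - p1) * w
        return p


DEFAULT_TIN_MODEL = TinSpikeModel()


def sample_tin_spike_count(s: float, model: TinSpikeModel = DEFAULT_TIN_MODEL,
                           rng: np.random.Generator | None = None) -> int:
    """Draw the number of spikes (0..5) a tIN fires at stimulus s."""
    rng = np.random.default_rng() if rng is None else rng
    return int(rng.choice(MAX_TIN_SPIKES + 1, p=model.pmf(s)))


def sample_tin_spike_times(n: int, model: TinSpikeModel = DEFAULT_TIN_MODEL,
                           rng: np.random.Generator | None = None
                           ) -> np.ndarray:
    """Draw spike times (ms, sorted ascending) for an n-spike response."""
    if n > MAX_TIN_SPIKES:
        raise ValueError(f"tINs fire at most {MAX_TIN_SPIKES} spikes")
    if n < 0:
        raise ValueError("spike count must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    times = np.array([rng.normal(model.mu[k], model.sigma[k])
                      for k in range(n)])
    return np.sort(times)


def generate_sensory_volley(s: float, n_tins: int = 20,
                            rng: np.random.Generator | None = None,
                            model: TinSpikeModel = DEFAULT_TIN_MODEL,
                            onset: float = 0.0) -> list[np.ndarray]:
    """Spike-time lists for a population of n_tins independent tINs."""
    rng = np.random.default_rng() if rng is None else rng
    volley = []
    for _ in range(n_tins):
        n = sample_tin_spike_count(s, model, rng)
        volley.append(onset + sample_tin_spike_times(n, model, rng))
    return volley


@dataclass(frozen=True)
class MhrBurst:
    """A burst of stopping-pathway spikes: n_spikes at a fixed interval."""

    n_spikes: int
    isi: float        # ms
    onset: float = 0.0

    def __post_init__(self):
        if self.n_spikes < 1:
            raise ValueError("burst needs at least one spike")
        if self.isi <= 0:
            raise ValueError("inter-spike interval must be positive")

    @property
    def duration(self) -> float:
        """Duration of the inhibition: (n_spikes - 1) * ISI."""
        return (self.n_spikes - 1) * self.isi

    def times(self) -> np.ndarray:
        return self.onset + self.isi * np.arange(self.n_spikes)


def mhr_burst_times(burst: MhrBurst) -> np.ndarray:
    return burst.times()


@dataclass(frozen=True)
class PerfusionProtocol:
    """Clamped NMDAR activation applied identically to every soma.

    The conductance ramps linearly from the onset over ``ramp_duration`` to
    ``target_g`` (nS) and is then held, so the steady conductance equals the
    target exactly.  ``mg`` switches the voltage-dependent Mg block of the
    resulting current on or off.
    """

    target_g: float             # nS
    onset: float = 0.0          # ms
    ramp_duration: float = 200.0  # ms
    mg: bool = True
    e_rev: float = 0.0

    def __post_init__(self):
        if self.target_g < 0:
            raise ValueError("target conductance must be non-negative")
        if self.ramp_duration < 0:
            raise ValueError("ramp duration must be non-negative")

    def drive(self, t):
        """NMDAR conductance (nS) at time t (scalar or array)."""
        t = np.asarray(t, dtype=float)
        if self.ramp_duration > 0:
            frac = np.clip((t - self.onset) / self.ramp_duration, 0.0, 1.0)
        else:
            frac = (t >= self.onset).astype(float)
        out = self.target_g * frac
        return out if out.ndim else float(out)


def perfusion_drive(protocol: PerfusionProtocol, t):
    return protocol.drive(t)


@dataclass(frozen=True)
class StepCurrent:
    """Constant current injection into one compartment."""

    neuron: int
    amplitude: float   # nA, depolarizing positive
    t_on: float
    t_off: float
    compartment: int = 0  # local compartment index (0 = soma)

    def __post_init__(self):
        if self.t_off <= self.t_on:
            raise ValueError("t_off must exceed t_on")


@dataclass
class ExternalSynapticDrive:
    """A presynaptic spike train driving one synapse per target neuron.

    ``targets=None`` targets every neuron.  Transmission unreliability and
    the synaptic delay of ``kinetics`` apply per spike per target synapse.
    """

    spike_times: np.ndarray
    kinetics: SynapseKinetics
    targets: list[int] | None = None

    def __post_init__(self):
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))


@dataclass
class StimulusProtocol:
    """All timed external events of one simulation."""

    drives: list[ExternalSynapticDrive] = field(default_factory=list)
    perfusion: PerfusionProtocol | None = None
    step_currents: list[StepCurrent] = field(default_factory=list)


def sensory_drive(s: float, rng: np.random.Generator,
                  n_tins: int = 20, onset: float = 100.0,
                  ampa_kin: SynapseKinetics | None = None,
                  nmda_kin: SynapseKinetics | None = None,
                  model: TinSpikeModel = DEFAULT_TIN_MODEL,
                  ) -> list[ExternalSynapticDrive]:
    """Sensory volley: each tIN connects to every neuron (100% connectivity)
    through an AMPA and an NMDA synapse with 50% per-spike transmission."""
    ampa_kin = sensory_ampa() if ampa_kin is None else ampa_kin
    nmda_kin = sensory_nmda() if nmda_kin is None else nmda_kin
    drives = []
    for times in generate_sensory_volley(s, n_tins, rng, model, onset):
        if len(times) == 0:
            continue
        drives.append(ExternalSynapticDrive(times, ampa_kin))
        drives.append(ExternalSynapticDrive(times, nmda_kin))
    return drives


def mhr_drive(burst: MhrBurst, kinetics: SynapseKinetics
              ) -> ExternalSynapticDrive:
    """The stopping pathway: one inhibitory synapse per neuron, all driven
    by the same burst."""
    return ExternalSynapticDrive(burst.times(), kinetics)
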