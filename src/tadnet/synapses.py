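"""Chemical synapse kinetics.

Conductance at a synapse is the difference of two decaying exponentials,
an opening state A (time constant tau_open) and a closing state B
(tau_close):

    dA/dt = -A / tau_open      dB/dt = -B / tau_close

A presynaptic spike (upward 0 mV crossing at the presynaptic soma) queues a
delivery ``delay`` ms later; at delivery A and B each step up by 1.  The
conductance is

    g_syn(t) = g_peak * (B - A) / norm

where ``norm`` scales the single-event waveform so that its maximum equals
exactly 1, letting all synaptic strengths be expressed as peak conductances.
NMDA-type synapses additionally carry a voltage-dependent magnesium-block
factor

    vdep(V) = 1 / (1 + eta * [Mg]_o * exp(-gamma * V))

which multiplies the synaptic current ``i = g_syn * (V - E_syn) * vdep(V)``.

Units: ms, mV, nS, nA.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class MgBlockParams:
    """Magnesium block of the NMDAR pore (sigmoidal, no temporal dynamics)."""

    eta: float = 0.1       # mM^-1
    gamma: float = 0.08    # mV^-1
    mg_out: float = 0.5    # mM, extracellular [Mg2+]

    def __post_init__(self):
        if self.eta < 0 or self.gamma < 0 or self.mg_out < 0:
            raise ValueError("Mg-block parameters must be non-negative")

    def to_dict(self):
        return {"eta": self.eta, "gamma": self.gamma, "mg_out": self.mg_out}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def mg_vdep(v, p: MgBlockParams | None):
    """Voltage-dependent Mg-block factor in (0, 1]; 1 when block absent."""
    v = np.asarray(v, dtype=float)
    if p is None or p.mg_out == 0 or p.eta == 0:
        out = np.ones_like(v)
        return out if out.ndim else float(out)
    out = 1.0 / (1.0 + p.eta * p.mg_out * np.exp(-p.gamma * v))
    return out if out.ndim else float(out)


def peak_time_and_norm(tau_open: float, tau_close: float):
    """Time-to-peak and normalization of the unit dual-exponential waveform.

    For a single unit event the waveform ``B - A`` with
    ``B = exp(-t/tau_close)``, ``A = exp(-t/tau_open)`` peaks at

        t_peak = tau_open * tau_close / (tau_close - tau_open)
                 * ln(tau_close / tau_open)

    with value ``norm = exp(-t_peak/tau_close) - exp(-t_peak/tau_open)``
    in (0, 1).  Dividing by ``norm`` makes the single-event maximum exactly 1.
    """
    if tau_open <= 0 or tau_close <= 0:
        raise ValueError("time constants must be positive")
    if tau_open == tau_close:
        raise ValueError("degenerate alpha-function (tau_open == tau_close) "
                         "is not supported")
    t_peak = (tau_open * tau_close / (tau_close - tau_open)
              * math.log(tau_close / tau_open))
    norm = math.exp(-t_peak / tau_close) - math.exp(-t_peak / tau_open)
    return t_peak, norm


@dataclass(frozen=True)
class SynapseKinetics:
    """Kinetic constants and strength of one synapse type."""

    tau_open: float              # ms
    tau_close: float             # ms
    g_peak: float                # nS
    e_rev: float                 # mV
    mg_block: MgBlockParams | None = None
    delay: float = 1.0           # ms after presynaptic threshold crossing
    presyn_threshold: float = 0.0  # mV
    transmission_p: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.tau_open <= 0 or self.tau_close <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_open == self.tau_close:
            raise ValueError("tau_open must differ from tau_close")
        if self.g_peak < 0:
            raise ValueError("g_peak must be non-negative")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if not 0.0 <= self.transmission_p <= 1.0:
            raise ValueError("transmission_p must lie in [0, 1]")

    @property
    def norm(self) -> float:
        return peak_time_and_norm(self.tau_open, self.tau_close)[1]

    @property
    def t_peak(self) -> float:
        return peak_time_and_norm(self.tau_open, self.tau_close)[0]

    def with_g_peak(self, g_peak: float) -> "SynapseKinetics":
        return replace(self, g_peak=g_peak)

    def to_dict(self):
        d = {"tau_open": self.tau_open, "tau_close": self.tau_close,
             "g_peak": self.g_peak, "e_rev": self.e_rev,
             "delay": self.delay, "presyn_threshold": self.presyn_threshold,
             "transmission_p": self.transmission_p, "label": self.label}
        if self.mg_block is not None:
            d["mg_block"] = self.mg_block.to_dict()
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "mg_block" in d and d["mg_block"] is not None:
            d["mg_block"] = MgBlockParams.from_dict(d["mg_block"])
        return cls(**d)


def synaptic_current(g_syn, v, kin: SynapseKinetics):
    """Synaptic current i = g_syn * (V - E_syn) * vdep(V) in nA.

    ``g_syn`` in nS, voltages in mV (nS * mV = 1e-3 nA, hence the scale
    factor).  Outward (hyperpolarizing at V > E) current is positive.
    """
    i = np.asarray(g_syn, dtype=float) * (np.asarray(v, dtype=float)
                                          - kin.e_rev)
    i = i * mg_vdep(v, kin.mg_block) * 1e-3
    return i if np.ndim(i) else float(i)


class SynapseState:
    """Event-driven state of one synapse: the (A, B) pair plus a queue of
    pending delivery times (ms)."""

    __slots__ = ("a", "b", "t", "pending")

    def __init__(self):
        self.a = 0.0
        self.b = 0.0
        self.t = 0.0
        self.pending: list[float] = []

    def _decay_to(self, t: float, kin: SynapseKinetics):
        if t < self.t - 1e-12:
            raise ValueError("cannot evolve synapse state backwards in time")
        dt = t - self.t
        if dt > 0:
            self.a *= math.exp(-dt / kin.tau_open)
            self.b *= math.exp(-dt / kin.tau_close)
        self.t = t

    def evolve_to(self, t: float, kin: SynapseKinetics):
        """Advance to time t, applying any deliveries that fall due."""
        while self.pending and self.pending[0] <= t:
            td = self.pending.pop(0)
            self._decay_to(td, kin)
            self.a += 1.0
            self.b += 1.0
        self._decay_to(t, kin)
        return self

    def conductance(self, kin: SynapseKinetics, t: float | None = None):
        """g_syn = g_peak * (B - A) / norm in nS at time t (>= state time)."""
        if t is not None:
            self.evolve_to(t, kin)
        return kin.g_peak * (self.b - self.a) / kin.norm


def conductance(state: SynapseState, kin: SynapseKinetics, t: float):
    """Functional form of :meth:`SynapseState.conductance`."""
    return state.conductance(kin, t)


def on_presynaptic_spike(state: SynapseState, kin: SynapseKinetics,
                         t_detect: float, rng: np.random.Generator | None = None):
    """Queue a delivery at ``t_detect + delay`` with probability
    ``transmission_p`` (unreliable transmission); returns the state."""
    p = kin.transmission_p
    if p < 1.0:
        if rng is None:
            raise ValueError("rng required when transmission_p < 1")
        if rng.random() >= p:
            return state
    bisect.insort(state.pending, t_detect + kin.delay)
    return state


def steady_state_summation_ratio(kin: SynapseKinetics, freq: float,
                                 n_spikes: int) -> float:
    """Maximum summed conductance of a regular spike train, relative to the
    single-event peak.

    Events at interval 1000/freq ms; between events the (A, B) pair decays
    analytically and the within-interval maximum of ``B e^{-t/tc} -
    A e^{-t/to}`` is located in closed form.  Returns
    ``max_t g_syn(t) / g_peak``; equals 1 for a single spike and grows with
    frequency as closing-phase conductance summates.
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if freq <= 0:
        raise ValueError("freq must be positive")
    to, tc = kin.tau_open, kin.tau_close
    interval = 1000.0 / freq
    _, norm = peak_time_and_norm(to, tc)

    a = b = 0.0
    best = 0.0
    for k in range(n_spikes):
        a += 1.0
        b += 1.0
        # search horizon: next event, or full decay after the last one
        horizon = interval if k < n_spikes - 1 else 20.0 * max(to, tc)
        # interior stationary point of b e^{-t/tc} - a e^{-t/to}
        candidates = [0.0, horizon]
        ratio = (a * tc) / (b * to)
        if ratio > 0:
            t_star = math.log(ratio) / (1.0 / to - 1.0 / tc)
            if 0.0 < t_star < horizon:
                candidates.append(t_star)
        for t in candidates:
            val = b * math.exp(-t / tc) - a * math.exp(-t / to)
            if val > best:
                best = val
        a *= math.exp(-horizon / to)
        b *= math.exp(-horizon / tc)
    return best / norm


# ---------------------------------------------------------------------------
# Shipped synapse types.  Excitatory reversal is 0 mV (standard convention);
# glutamatergic feedback has a fast AMPA and a slow, Mg-blocked NMDA
# component; the descending inhibitory (GABA-A) synapse is fitted to
# recorded stopping-pathway IPSPs.
# ---------------------------------------------------------------------------

DEFAULT_MG_BLOCK = MgBlockParams()


def feedback_nmda(g_peak=0.11, mg=True):
    return SynapseKinetics(5.0, 80.0, g_peak, 0.0,
                           DEFAULT_MG_BLOCK if mg else None,
                           label="fb_nmda")


def feedback_ampa(g_peak=0.11):
    return SynapseKinetics(0.1, 3.0, g_peak, 0.0, label="fb_ampa")


def sensory_nmda(g_peak=0.15, transmission_p=0.5, mg=True):
    return SynapseKinetics(5.0, 80.0, g_peak, 0.0,
                           DEFAULT_MG_BLOCK if mg else None,
                           transmission_p=transmission_p, label="sens_nmda")


def sensory_ampa(g_peak=0.6, transmission_p=0.5):
    return SynapseKinetics(0.1, 3.0, g_peak, 0.0,
                           transmission_p=transmission_p, label="sens_ampa")


def inhibitory_gaba(g_peak=2.0):
    """Stopping-pathway GABA-A synapse (tau_o 1.5 ms, tau_c 20 ms, E -70)."""
    return SynapseKinetics(1.5, 20.0, g_peak, -70.0, label="inh")
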