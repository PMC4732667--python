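"""Voltage-gated membrane currents.

Hodgkin-Huxley-type gated currents plus a Goldman-Hodgkin-Katz (GHK)
constant-field calcium current.  All voltages are in mV, time in ms, rates
in ms^-1, conductance densities in mS/cm^2 and current densities in uA/cm^2.

Sign convention (used package-wide): outward membrane current is positive,
and the membrane equation is ``C dV/dt = -sum(i_ion) - i_syn + i_inj``.

Rate functions are built from three primitive forms:

``exponential``  a * exp((V - b) / c)
``sigmoid``      a / (1 + exp((V - b) / c))
``linoid``       a * (V - b) / (1 - exp(-(V - b) / c))

The linoid form has a removable singularity at ``V = b`` where its limit is
``a * c``; it is evaluated by series expansion near that point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# Physical constants (GHK flux).  Temperature is config-overridable.
GAS_CONSTANT = 8.314        # J / (mol K)
FARADAY = 96485.0           # C / mol
DEFAULT_TEMPERATURE = 293.15  # K

RATE_FORMS = ("exponential", "sigmoid", "linoid")
_FORM_CODE = {name: i for i, name in enumerate(RATE_FORMS)}


@dataclass(frozen=True)
class RateFunction:
    """One voltage-dependent transition rate alpha(V) or beta(V)."""

    form: str
    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.form not in RATE_FORMS:
            raise ValueError(f"unknown rate form {self.form!r}")
        if self.c == 0:
            raise ValueError("rate function slope c must be nonzero")

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage must be finite")
        if self.form == "exponential":
            out = self.a * np.exp((v - self.b) / self.c)
        elif self.form == "sigmoid":
            out = self.a / (1.0 + np.exp((v - self.b) / self.c))
        else:  # linoid
            x = (v - self.b) / self.c
            with np.errstate(invalid="ignore", over="ignore"):
                out = np.where(
                    np.abs(x) < 1e-5,
                    # series of x / (1 - exp(-x)) about x = 0
                    self.a * self.c * (1.0 + x / 2.0 + x * x / 12.0),
                    self.a * self.c * x / (1.0 - np.exp(-np.clip(x, -500, 500))),
                )
        return out if out.ndim else float(out)

    def to_dict(self):
        return {"form": self.form, "a": self.a, "b": self.b, "c": self.c}

    @classmethod
    def from_dict(cls, d):
        return cls(d["form"], float(d["a"]), float(d["b"]), float(d["c"]))


@dataclass(frozen=True)
class GateKinetics:
    """Kinetics of one activation/inactivation gate.

    Two parameterizations are supported:

    * ``mode="alpha_beta"`` - forward/backward rates alpha(V), beta(V);
    * ``mode="inf_tau"`` - a sigmoidal steady state
      ``x_inf = 1 / (1 + exp(-(V - v_half) / slope))`` together with a time
      constant ``tau(V) = tau_base + tau_amp * exp(-((V - tau_vmid)/tau_sigma)^2)``
      (set ``tau_amp = 0`` for a voltage-independent tau).

    ``exponent`` is the power of the gate in the channel open fraction.
    """

    name: str
    exponent: int = 1
    mode: str = "alpha_beta"
    alpha: RateFunction | None = None
    beta: RateFunction | None = None
    v_half: float = 0.0
    slope: float = 1.0
    tau_base: float = 1.0
    tau_amp: float = 0.0
    tau_vmid: float = 0.0
    tau_sigma: float = 1.0

    def __post_init__(self):
        if self.exponent < 1:
            raise ValueError("gate exponent must be >= 1")
        if self.mode == "alpha_beta":
            if self.alpha is None or self.beta is None:
                raise ValueError("alpha_beta gate needs alpha and beta rates")
        elif self.mode == "inf_tau":
            if self.slope == 0 or self.tau_base <= 0:
                raise ValueError("inf_tau gate needs slope != 0 and tau_base > 0")
        else:
            raise ValueError(f"unknown gate mode {self.mode!r}")

    def steady_state(self, v):
        v = np.asarray(v, dtype=float)
        if self.mode == "alpha_beta":
            a, b = self.alpha(v), self.beta(v)
            out = a / (a + b)
        else:
            out = 1.0 / (1.0 + np.exp(-(v - self.v_half) / self.slope))
        return out if np.ndim(out) else float(out)

    def time_constant(self, v):
        v = np.asarray(v, dtype=float)
        if self.mode == "alpha_beta":
            a, b = self.alpha(v), self.beta(v)
            out = 1.0 / (a + b)
        else:
            x = (v - self.tau_vmid) / self.tau_sigma
            out = self.tau_base + self.tau_amp * np.exp(-x * x)
            out = out * np.ones_like(v)
        return out if np.ndim(out) else float(out)

    def rates(self, v):
        """Forward/backward rates (alpha, beta) in ms^-1 at voltage v."""
        if self.mode == "alpha_beta":
            return self.alpha(v), self.beta(v)
        inf = self.steady_state(v)
        tau = self.time_constant(v)
        return inf / tau, (1.0 - inf) / tau

    def to_dict(self):
        d = {"name": self.name, "exponent": self.exponent, "mode": self.mode}
        if self.mode == "alpha_beta":
            d["alpha"] = self.alpha.to_dict()
            d["beta"] = self.beta.to_dict()
        else:
            d.update(
                v_half=self.v_half, slope=self.slope, tau_base=self.tau_base,
                tau_amp=self.tau_amp, tau_vmid=self.tau_vmid,
                tau_sigma=self.tau_sigma,
            )
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if d.get("mode", "alpha_beta") == "alpha_beta":
            d["alpha"] = RateFunction.from_dict(d["alpha"])
            d["beta"] = RateFunction.from_dict(d["beta"])
        return cls(**d)


def gate_rates(kinetics: GateKinetics, v):
    """Evaluate (alpha, beta) in ms^-1; rejects non-finite voltages."""
    v_arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v_arr)):
        raise ValueError("voltage must be finite")
    return kinetics.rates(v)


@dataclass(frozen=True)
class GHKParams:
    """Constant-field flux parameters for the calcium current."""

    permeability: float           # cm/s
    ca_in: float = 1e-4           # mM
    ca_out: float = 10.0          # mM
    temperature: float = DEFAULT_TEMPERATURE  # K
    valence: int = 2

    def __post_init__(self):
        if self.ca_in <= 0 or self.ca_out <= 0:
            raise ValueError("ion concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.permeability < 0:
            raise ValueError("permeability must be non-negative")

    def to_dict(self):
        return {
            "permeability": self.permeability, "ca_in": self.ca_in,
            "ca_out": self.ca_out, "temperature": self.temperature,
            "valence": self.valence,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass(frozen=True)
class ChannelSpec:
    """One membrane channel: either ohmic (density + reversal) or GHK."""

    name: str
    conductance_density: float = 0.0   # mS/cm^2 (ignored for GHK channels)
    reversal_potential: float | None = None  # mV
    ghk: GHKParams | None = None
    gates: tuple[GateKinetics, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if (self.reversal_potential is None) == (self.ghk is None):
            raise ValueError(
                "exactly one of reversal_potential / ghk must be given")
        if self.conductance_density < 0:
            raise ValueError("conductance density must be non-negative")
        object.__setattr__(self, "gates", tuple(self.gates))

    @property
    def is_ghk(self) -> bool:
        return self.ghk is not None

    def with_density_factor(self, factor: float) -> "ChannelSpec":
        """Scaled copy (used for density noise and axonal scaling)."""
        if self.is_ghk:
            ghk = GHKParams(self.ghk.permeability * factor, self.ghk.ca_in,
                            self.ghk.ca_out, self.ghk.temperature,
                            self.ghk.valence)
            return ChannelSpec(self.name, 0.0, None, ghk, self.gates)
        return ChannelSpec(self.name, self.conductance_density * factor,
                           self.reversal_potential, None, self.gates)

    def to_dict(self):
        d = {"name": self.name, "gates": [g.to_dict() for g in self.gates]}
        if self.is_ghk:
            d["ghk"] = self.ghk.to_dict()
        else:
            d["conductance_density"] = self.conductance_density
            d["reversal_potential"] = self.reversal_potential
        return d

    @classmethod
    def from_dict(cls, d):
        gates = tuple(GateKinetics.from_dict(g) for g in d.get("gates", ()))
        if "ghk" in d:
            return cls(d["name"], 0.0, None, GHKParams.from_dict(d["ghk"]),
                       gates)
        return cls(d["name"], float(d.get("conductance_density", 0.0)),
                   float(d["reversal_potential"]), None, gates)


def hh_current(spec: ChannelSpec, gates, v):
    """Ohmic gated current density i = g * prod(x^exp) * (V - E) in uA/cm^2.

    ``gates`` is a sequence of gate states matching ``spec.gates`` order.
    Outward current is positive.
    """
    if spec.is_ghk:
        raise ValueError("hh_current is for ohmic channels; use "
                         "ghk_calcium_current for GHK channels")
    gates = [np.asarray(x, dtype=float) for x in gates]
    if len(gates) != len(spec.gates):
        raise ValueError("gate state count does not match channel gates")
    for x in gates:
        if np.any((x < 0) | (x > 1)):
            raise ValueError("gate states must lie in [0, 1]")
    open_frac = 1.0
    for x, kin in zip(gates, spec.gates):
        open_frac = open_frac * x ** kin.exponent
    out = spec.conductance_density * open_frac * (
        np.asarray(v, dtype=float) - spec.reversal_potential)
    return out if np.ndim(out) else float(out)


def ghk_flux_factor(p: GHKParams, v):
    """GHK current density per unit permeability and open fraction (uA/cm^2
    per cm/s), i.e. ``i = P * open * ghk_flux_factor``.

    The 0/0 form at V = 0 is replaced by its series limit.
    """
    v = np.asarray(v, dtype=float)
    z = float(p.valence)
    # mM -> mol/cm^3
    ci = p.ca_in * 1e-6
    co = p.ca_out * 1e-6
    u = z * FARADAY * (v * 1e-3) / (GAS_CONSTANT * p.temperature)
    u = np.clip(u, -500, 500)
    with np.errstate(over="ignore", invalid="ignore"):
        small = np.abs(u) < 1e-8
        safe_u = np.where(small, 1.0, u)
        f = np.where(
            small,
            (ci - co) + u * (ci + co) / 2.0,
            safe_u * (ci - co * np.exp(-safe_u)) / (1.0 - np.exp(-safe_u)),
        )
    out = z * FARADAY * f * 1e6  # A/cm^2 per (cm/s) -> uA/cm^2
    return out if np.ndim(out) else float(out)


def ghk_calcium_current(p: GHKParams, v, open_fraction=1.0):
    """GHK calcium current density in uA/cm^2 (outward positive)."""
    out = p.permeability * np.asarray(open_fraction, dtype=float) * \
        ghk_flux_factor(p, v)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Shipped channel sets.
# ---------------------------------------------------------------------------

def classic_hh_channels(g_na=120.0, g_k=36.0, g_leak=0.3,
                        e_na=50.0, e_k=-77.0, e_leak=-54.387):
    """The canonical squid-axon channel set (resting potential ~ -65 mV).

    Used for the generic single-compartment population.
    """
    m = GateKinetics(
        "m", 3, alpha=RateFunction("linoid", 0.1, -40.0, 10.0),
        beta=RateFunction("exponential", 4.0, -65.0, -18.0))
    h = GateKinetics(
        "h", 1, alpha=RateFunction("exponential", 0.07, -65.0, -20.0),
        beta=RateFunction("sigmoid", 1.0, -35.0, -10.0))
    n = GateKinetics(
        "n", 4, alpha=RateFunction("linoid", 0.01, -55.0, 10.0),
        beta=RateFunction("exponential", 0.125, -65.0, -80.0))
    return [
        ChannelSpec("hh_na", g_na, e_na, gates=(m, h)),
        ChannelSpec("hh_k", g_k, e_k, gates=(n,)),
        ChannelSpec("hh_leak", g_leak, e_leak),
    ]
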