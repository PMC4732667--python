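"""Neuron models.

Two cell types are built here:

* the reticulospinal dIN: a single electrotonically compact soma/dendrite
  compartment carrying all chemical synapses, plus a multicompartment
  descending axon.  The soma carries leak, Na, fast K, slow K and a GHK
  calcium channel; the axon carries leak, Na (at higher density, to support
  propagation against the shunt of electrical coupling) and fast K.
* a generic single-compartment neuron with the classic squid Na/K/leak
  channel set.

Geometry is in um, specific capacitance in uF/cm^2, axial resistivity in
Ohm cm.  Internally, compartment capacitances are nF, axial couplings uS.

Coordinate convention: the rostro-caudal axis is in um with rostral =
larger coordinate, so descending axons run towards smaller coordinates.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .channels import ChannelSpec

__all__ = [
    "Compartment", "NeuronModel", "build_din", "build_generic_hh",
    "apply_density_noise", "din_config", "generic_config", "load_config",
]


@dataclass
class Compartment:
    """One cylindrical electrical compartment."""

    length: float                 # um
    diameter: float               # um
    cm: float = 1.0               # uF/cm^2
    axial_resistivity: float = 100.0  # Ohm cm
    channels: dict[str, ChannelSpec] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("compartment geometry must be strictly positive")
        if self.cm <= 0 or self.axial_resistivity <= 0:
            raise ValueError("passive properties must be strictly positive")

    @property
    def area_um2(self) -> float:
        return math.pi * self.diameter * self.length

    @property
    def area_cm2(self) -> float:
        return self.area_um2 * 1e-8

    @property
    def capacitance_nF(self) -> float:
        return self.cm * self.area_cm2 * 1e3

    @property
    def half_axial_MOhm(self) -> float:
        """Axial resistance from the compartment centre to its end."""
        l_cm = self.length * 1e-4 / 2.0
        d_cm = self.diameter * 1e-4
        return 4.0 * self.axial_resistivity * l_cm / (math.pi * d_cm**2) / 1e6


@dataclass
class NeuronModel:
    """An ordered chain of compartments (soma first, axon descending)."""

    compartments: list[Compartment]
    soma_index: int = 0
    position: float = 0.0         # rostro-caudal soma position, um
    kind: str = "neuron"
    axon_comp_length: float = 0.0

    def __post_init__(self):
        if not self.compartments:
            raise ValueError("neuron needs at least one compartment")
        if not 0 <= self.soma_index < len(self.compartments):
            raise ValueError("soma index out of range")

    @property
    def n_comp(self) -> int:
        return len(self.compartments)

    @property
    def n_axon(self) -> int:
        return self.n_comp - 1

    @property
    def axon_span(self) -> float:
        return self.n_axon * self.axon_comp_length

    def axial_couplings_uS(self) -> np.ndarray:
        """Symmetric coupling conductance between adjacent compartments."""
        out = np.zeros(max(self.n_comp - 1, 0))
        for i in range(self.n_comp - 1):
            r = (self.compartments[i].half_axial_MOhm
                 + self.compartments[i + 1].half_axial_MOhm)
            out[i] = 1.0 / r
        return out

    def axon_comp_position(self, k: int) -> float:
        """Rostro-caudal position (um) of the centre of axon compartment k
        (k = 1 .. n_axon; the axon descends caudally from the soma)."""
        return self.position - (k - 0.5) * self.axon_comp_length

    def nearest_axon_comp(self, x: float) -> int:
        """Index of the axon compartment whose centre is closest to x."""
        if self.n_axon == 0:
            return 0
        k = round((self.position - x) / self.axon_comp_length + 0.5)
        return int(min(max(k, 1), self.n_axon))


# ---------------------------------------------------------------------------
# Config handling.  The shipped YAML files under tadnet/configs are the
# authoritative default parameter sets.
# ---------------------------------------------------------------------------

_CONFIG_CACHE: dict[str, dict] = {}


def load_config(name: str) -> dict:
    """Load a shipped YAML config (e.g. 'din', 'generic_hh') by name."""
    if name not in _CONFIG_CACHE:
        ref = resources.files("tadnet").joinpath(f"configs/{name}.yaml")
        _CONFIG_CACHE[name] = yaml.safe_load(ref.read_text())
    return copy.deepcopy(_CONFIG_CACHE[name])


def _merge(base: dict, override: dict | None) -> dict:
    if not override:
        return base
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def din_config(overrides: dict | None = None) -> dict:
    return _merge(load_config("din"), overrides)


def generic_config(overrides: dict | None = None) -> dict:
    return _merge(load_config("generic_hh"), overrides)


def _channel_table(cfg: dict) -> dict[str, ChannelSpec]:
    return {d["name"]: ChannelSpec.from_dict(d) for d in cfg["channels"]}


def _region_channels(table: dict[str, ChannelSpec],
                     densities: dict[str, float]) -> dict[str, ChannelSpec]:
    """Instantiate channels for one region given name -> density map.

    For GHK channels the mapped value is the permeability (cm/s); for ohmic
    channels it is the conductance density (mS/cm^2).
    """
    out = {}
    for name, value in densities.items():
        base = table[name]
        if base.is_ghk:
            scale = value / base.ghk.permeability if base.ghk.permeability \
                else 0.0
            out[name] = base.with_density_factor(scale) if scale else \
                ChannelSpec(base.name, 0.0, None,
                            base.ghk.__class__(value, base.ghk.ca_in,
                                               base.ghk.ca_out,
                                               base.ghk.temperature,
                                               base.ghk.valence), base.gates)
        else:
            out[name] = ChannelSpec(base.name, float(value),
                                    base.reversal_potential, None, base.gates)
    return out


def build_din(config: dict | None = None, position: float = 0.0,
              overrides: dict | None = None) -> NeuronModel:
    """Build one dIN at the given rostro-caudal position.

    The soma/dendrite compartment carries all five channel types; axon
    compartments carry leak, Na and fast K, with axonal Na density at least
    the somatic density.
    """
    cfg = config if config is not None else din_config(overrides)
    geom, passive = cfg["geometry"], cfg["passive"]
    n_axon = int(round(geom["axon_span"] / geom["axon_comp_length"]))
    if n_axon <= 0:
        raise ValueError("axon must have a positive number of compartments")

    table = _channel_table(cfg)
    soma = Compartment(
        geom["soma_length"], geom["soma_diameter"], passive["cm"],
        passive["axial_resistivity"],
        _region_channels(table, cfg["soma_channels"]), name="soma")
    comps = [soma]
    axon_channels = _region_channels(table, cfg["axon_channels"])
    for k in range(n_axon):
        comps.append(Compartment(
            geom["axon_comp_length"], geom["axon_diameter"], passive["cm"],
            passive["axial_resistivity"], dict(axon_channels),
            name=f"axon{k}"))
    return NeuronModel(comps, 0, position, "din", geom["axon_comp_length"])


def build_generic_hh(config: dict | None = None,
                     overrides: dict | None = None) -> NeuronModel:
    """Build one generic single-compartment neuron (classic Na/K/leak)."""
    cfg = config if config is not None else generic_config(overrides)
    geom, passive = cfg["geometry"], cfg["passive"]
    table = _channel_table(cfg)
    soma = Compartment(
        geom["soma_length"], geom["soma_diameter"], passive["cm"],
        passive["axial_resistivity"],
        _region_channels(table, cfg["soma_channels"]), name="soma")
    return NeuronModel([soma], 0, 0.0, "generic_hh", 0.0)


def apply_density_noise(model: NeuronModel, sigma_rel: float,
                        rng: np.random.Generator) -> NeuronModel:
    """Multiply every channel density (or GHK permeability) by an
    independent normal(1, sigma_rel) draw truncated at zero."""
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    out = copy.deepcopy(model)
    if sigma_rel == 0:
        return out
    for comp in out.compartments:
        for name in list(comp.channels):
            factor = max(0.0, 1.0 + sigma_rel * rng.standard_normal())
            comp.channels[name] = comp.channels[name].with_density_factor(
                factor)
    return out
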