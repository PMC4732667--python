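"""Population construction.

Two populations are built:

* 30 dINs arranged in a rostro-caudal column (10 um soma spacing) whose
  descending axons are electrically coupled by 600 MOhm gap junctions placed
  where a rostral neuron's axon overlaps a more caudal neuron's soma;
  glutamatergic (AMPA + NMDA) feedback synapses are sampled between ordered
  pairs with probability 0.2 and land on the soma/dendrite compartment.
* 30 generic single-compartment neurons with 100 MOhm soma-to-soma gap
  junctions (probability 0.2 per unordered pair) and the same feedback
  synapse sampling.

Synaptic peak conductances carry multiplicative normal noise with relative
variance sigma^2 = 0.1, truncated at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .neurons import (NeuronModel, build_din, build_generic_hh,
                      apply_density_noise, din_config, generic_config)
from .synapses import (SynapseKinetics, feedback_ampa, feedback_nmda)

__all__ = [
    "GapJunction", "ChemicalSynapse", "NetworkGraph", "sample_connectivity",
    "build_din_population", "build_generic_population",
    "gap_junction_current",
]


@dataclass(frozen=True)
class GapJunction:
    """Ohmic electrical coupling between two compartments."""

    neuron_a: int
    comp_a: int
    neuron_b: int
    comp_b: int
    resistance: float  # MOhm

    def __post_init__(self):
        if self.resistance <= 0:
            raise ValueError("gap junction resistance must be positive")

    @property
    def conductance_uS(self) -> float:
        return 1.0 / self.resistance


@dataclass(frozen=True)
class ChemicalSynapse:
    """Directed chemical synapse; always targets the postsynaptic soma."""

    pre: int
    post: int
    kinetics: SynapseKinetics

    def __post_init__(self):
        if self.pre == self.post:
            raise ValueError("self-synapses are excluded")


@dataclass
class NetworkGraph:
    """Neurons plus chemical and electrical edges, with its build recipe."""

    neurons: list[NeuronModel]
    synapses: list[ChemicalSynapse] = field(default_factory=list)
    gap_junctions: list[GapJunction] = field(default_factory=list)
    seed: int | None = None
    builder: str = ""
    builder_kwargs: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def validate(self):
        keys = set()
        for gj in self.gap_junctions:
            key = tuple(sorted([(gj.neuron_a, gj.comp_a),
                                (gj.neuron_b, gj.comp_b)]))
            if key in keys:
                raise ValueError(f"duplicate gap junction {key}")
            keys.add(key)
        for syn in self.synapses:
            if not (0 <= syn.pre < self.n_neurons
                    and 0 <= syn.post < self.n_neurons):
                raise ValueError("synapse endpoint out of range")
        return self

    # -- serialization for exact replay -----------------------------------
    def to_json(self, path=None):
        doc = {
            "builder": self.builder,
            "builder_kwargs": self.builder_kwargs,
            "seed": self.seed,
            "n_neurons": self.n_neurons,
            "synapses": [
                {"pre": s.pre, "post": s.post,
                 "kinetics": s.kinetics.to_dict()} for s in self.synapses],
            "gap_junctions": [asdict(g) for g in self.gap_junctions],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path):
        try:
            doc = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        builder = {"build_din_population": build_din_population,
                   "build_generic_population": build_generic_population}[
                       doc["builder"]]
        return builder(seed=doc["seed"], **doc["builder_kwargs"])

    def edges_dataframe(self):
        import pandas as pd
        rows = [{"kind": "chemical", "pre": s.pre, "post": s.post,
                 "label": s.kinetics.label, "g_peak_nS": s.kinetics.g_peak}
                for s in self.synapses]
        rows += [{"kind": "electrical", "pre": g.neuron_a, "post": g.neuron_b,
                  "label": f"gj[{g.comp_a},{g.comp_b}]",
                  "g_peak_nS": 1e3 / g.resistance} for g in self.gap_junctions]
        return pd.DataFrame(rows)


def sample_connectivity(n: int, p: float, rng: np.random.Generator,
                        directed: bool = True) -> list[tuple[int, int]]:
    """Bernoulli(p) sampling of non-self pairs; ordered pairs if directed."""
    if n < 2:
        raise ValueError("need at least two neurons")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    edges = []
    for i in range(n):
        for j in range((i + 1) if not directed else 0, n):
            if i == j:
                continue
            if rng.random() < p:
                edges.append((i, j))
    return edges


def _truncnorm_factor(rng: np.random.Generator, sd: float) -> float:
    return max(0.0, 1.0 + sd * rng.standard_normal())


def _feedback_edges(n, p_syn, nmda_kin, ampa_kin, weight_sd, rng_conn,
                    rng_weight):
    synapses = []
    for pre, post in sample_connectivity(n, p_syn, rng_conn, directed=True):
        f = _truncnorm_factor(rng_weight, weight_sd)
        if nmda_kin is not None:
            synapses.append(ChemicalSynapse(
                pre, post, nmda_kin.with_g_peak(nmda_kin.g_peak * f)))
        if ampa_kin is not None:
            synapses.append(ChemicalSynapse(
                pre, post, ampa_kin.with_g_peak(ampa_kin.g_peak * f)))
    return synapses


def build_din_population(n: int = 30, spacing: float = 10.0,
                         gj_resistance: float = 600.0, p_syn: float = 0.2,
                         nmda_g_peak: float = 0.11,
                         ampa_g_peak: float | None = None,
                         mg: bool = True, weight_sigma2: float = 0.1,
                         density_noise: float = 0.0,
                         electrical_coupling: bool = True,
                         din_overrides: dict | None = None,
                         seed: int | None = 0) -> NetworkGraph:
    """The electrically coupled dIN column with glutamatergic feedback.

    Somata sit at 0, -spacing, -2*spacing, ... um (rostral = larger
    coordinate).  For every ordered rostral->caudal pair whose descending
    axon reaches the caudal soma, one gap junction of ``gj_resistance``
    MOhm couples the rostral neuron's axon compartment nearest the caudal
    soma to the caudal neuron's most proximal axon compartment.  Feedback
    AMPA+NMDA synapses are sampled at ``p_syn`` per ordered pair and target
    the soma; their peak conductances carry truncated-normal noise with
    relative variance ``weight_sigma2``.
    """
    ss = np.random.SeedSequence(seed if seed is not None else None)
    rng_conn, rng_weight, rng_density = (
        np.random.default_rng(s) for s in ss.spawn(3))

    cfg = din_config(din_overrides)
    neurons = []
    for k in range(n):
        nm = build_din(cfg, position=-spacing * k)
        if density_noise > 0:
            nm = apply_density_noise(nm, density_noise, rng_density)
        neurons.append(nm)

    gap_junctions = []
    if electrical_coupling:
        for i in range(n):          # i rostral of j
            for j in range(i + 1, n):
                xi, xj = neurons[i].position, neurons[j].position
                if xi - neurons[i].axon_span <= xj:
                    ka = neurons[i].nearest_axon_comp(xj)
                    gap_junctions.append(GapJunction(
                        i, ka, j, min(1, neurons[j].n_comp - 1),
                        gj_resistance))

    if ampa_g_peak is None:
        ampa_g_peak = 0.4 * nmda_g_peak
    nmda_kin = feedback_nmda(nmda_g_peak, mg=mg) if nmda_g_peak > 0 else None
    ampa_kin = feedback_ampa(ampa_g_peak) if ampa_g_peak > 0 else None
    synapses = _feedback_edges(n, p_syn, nmda_kin, ampa_kin,
                               np.sqrt(weight_sigma2), rng_conn, rng_weight)

    return NetworkGraph(
        neurons, synapses, gap_junctions, seed, "build_din_population",
        dict(n=n, spacing=spacing, gj_resistance=gj_resistance, p_syn=p_syn,
             nmda_g_peak=nmda_g_peak, ampa_g_peak=ampa_g_peak, mg=mg,
             weight_sigma2=weight_sigma2, density_noise=density_noise,
             electrical_coupling=electrical_coupling,
             din_overrides=din_overrides)).validate()


def build_generic_population(n: int = 30, gj_resistance: float = 100.0,
                             p_gj: float = 0.2, p_syn: float = 0.2,
                             nmda_g_peak: float = 0.6,
                             ampa_g_peak: float | None = None,
                             mg: bool = True, sigma2: float = 0.1,
                             density_noise: float = 0.1,
                             electrical_coupling: bool = True,
                             hh_overrides: dict | None = None,
                             seed: int | None = 0) -> NetworkGraph:
    """The 30-neuron generic population: soma-to-soma gap junctions sampled
    per unordered pair at ``p_gj`` (100 MOhm), AMPA+NMDA feedback at
    ``p_syn``, synaptic weights with relative variance ``sigma2`` and
    channel-density noise ``density_noise`` (relative s.d.)."""
    ss = np.random.SeedSequence(seed if seed is not None else None)
    rng_conn, rng_weight, rng_density, rng_gj = (
        np.random.default_rng(s) for s in ss.spawn(4))

    cfg = generic_config(hh_overrides)
    neurons = []
    for _ in range(n):
        nm = build_generic_hh(cfg)
        if density_noise > 0:
            nm = apply_density_noise(nm, density_noise, rng_density)
        neurons.append(nm)

    gap_junctions = []
    if electrical_coupling:
        for i, j in sample_connectivity(n, p_gj, rng_gj, directed=False):
            gap_junctions.append(GapJunction(i, 0, j, 0, gj_resistance))

    if ampa_g_peak is None:
        ampa_g_peak = nmda_g_peak
    nmda_kin = feedback_nmda(nmda_g_peak, mg=mg) if nmda_g_peak > 0 else None
    ampa_kin = feedback_ampa(ampa_g_peak) if ampa_g_peak > 0 else None
    synapses = _feedback_edges(n, p_syn, nmda_kin, ampa_kin, np.sqrt(sigma2),
                               rng_conn, rng_weight)

    return NetworkGraph(
        neurons, synapses, gap_junctions, seed, "build_generic_population",
        dict(n=n, gj_resistance=gj_resistance, p_gj=p_gj, p_syn=p_syn,
             nmda_g_peak=nmda_g_peak, ampa_g_peak=ampa_g_peak, mg=mg,
             sigma2=sigma2, density_noise=density_noise,
             electrical_coupling=electrical_coupling,
             hh_overrides=hh_overrides)).validate()


def gap_junction_current(v_a, v_b, resistance: float):
    """Ohmic junction currents (i_into_a, i_into_b) in nA; they sum to zero.

    ``i_into_a = (V_b - V_a) / R`` with R in MOhm and voltages in mV.
    """
    if resistance <= 0:
        raise ValueError("resistance must be positive")
    i_a = (np.asarray(v_b, dtype=float) - np.asarray(v_a, dtype=float)) \
        / resistance
    return (i_a, -i_a) if np.ndim(i_a) else (float(i_a), float(-i_a))
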