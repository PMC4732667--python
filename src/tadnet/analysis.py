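"""Spike-train and population statistics.

These are the measures behind every figure-level result: sustained-phase
firing frequency, the sustained/dies-out classification, a population
synchrony index, stop probability over the inhibition-protocol grid, and
the feedback-strength sweep.

Conventions (package choices, stated once): the sustained phase of a
started run begins 300 ms after the sensory volley; a run is "sustained"
if any neuron spikes in its final 300 ms; "reliable" means sustained in at
least 90% of seeds.  The whole-animal swimming band is 10-25 Hz, the
half-CNS band 15-30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "firing_frequency", "sustained_flag", "synchrony_index",
    "stop_probability", "frequency_vs_conductance_sweep", "SweepResult",
    "SWIM_BAND_WHOLE", "SWIM_BAND_HALF", "SUSTAINED_QUIET_TAIL",
    "SUSTAINED_PHASE_DELAY", "RELIABLE_FRACTION",
]

SWIM_BAND_WHOLE = (10.0, 25.0)   # Hz, whole animal
SWIM_BAND_HALF = (15.0, 30.0)    # Hz, one side of the CNS
SUSTAINED_QUIET_TAIL = 300.0     # ms
SUSTAINED_PHASE_DELAY = 300.0    # ms after the sensory volley
RELIABLE_FRACTION = 0.9


def firing_frequency(spikes, window) -> float:
    """Spike count in [t0, t1) divided by the window length, in Hz."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have t1 > t0")
    spikes = np.asarray(spikes, dtype=float)
    n = int(((spikes >= t0) & (spikes < t1)).sum())
    return n / ((t1 - t0) / 1000.0)


def sustained_flag(spikes, duration: float,
                   quiet_tail: float = SUSTAINED_QUIET_TAIL) -> bool:
    """True iff at least one spike falls in the final ``quiet_tail`` ms."""
    spikes = np.asarray(spikes, dtype=float)
    return bool((spikes >= duration - quiet_tail).sum() > 0)


def synchrony_index(spike_trains, window, bin_ms: float = 5.0,
                    n_surrogates: int = 20, seed: int = 0) -> float:
    """Normalized population-coincidence index in [0, 1].

    The population spike count is binned at ``bin_ms``; its Fano factor
    (variance over mean) is compared against a same-rate homogeneous
    Poisson surrogate ensemble.  Independent trains give an index near 0;
    N identical trains approach 1 (exactly 1 is unattainable at non-zero
    rates because even perfectly coincident binary trains have Fano factor
    N(1-p) < N).
    """
    trains = [np.asarray(s, dtype=float) for s in spike_trains]
    if len(trains) < 2:
        raise ValueError("need at least two spike trains")
    t0, t1 = window
    edges = np.arange(t0, t1 + bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1)
    total = 0
    for s in trains:
        c, _ = np.histogram(s, edges)
        counts += c
        total += int(((s >= t0) & (s < t1)).sum())
    if total == 0:
        return 0.0
    mean = counts.mean()
    fano = counts.var() / mean

    # same-rate Poisson surrogate ensemble -> baseline Fano
    rng = np.random.default_rng(seed)
    lam = total / len(counts)
    f0 = np.mean([
        (lambda c: c.var() / max(c.mean(), 1e-12))(
            rng.poisson(lam, size=len(counts)))
        for _ in range(n_surrogates)])
    n = len(trains)
    return float(np.clip((fano - f0) / (n - f0), 0.0, 1.0))


@dataclass
class SweepResult:
    """Outcome of a feedback-conductance sweep."""

    g_values: np.ndarray                 # nS per synapse
    frequencies: np.ndarray              # (n_g, n_seeds) mean Hz
    sustained: np.ndarray                # (n_g, n_seeds) bool
    synchrony: np.ndarray                # (n_g, n_seeds)
    seeds: list[int] = field(default_factory=list)

    @property
    def mean_frequency(self) -> np.ndarray:
        return self.frequencies.mean(axis=1)

    @property
    def reliable(self) -> np.ndarray:
        """Per g: sustained in >= 90% of seeds."""
        return self.sustained.mean(axis=1) >= RELIABLE_FRACTION

    def sustained_range(self) -> tuple[float, float] | None:
        """(min g, max g) over the reliably sustained grid points."""
        g = self.g_values[self.reliable]
        if len(g) == 0:
            return None
        return float(g.min()), float(g.max())

    def classify(self, band=SWIM_BAND_HALF) -> list[str]:
        """Per g: 'dies_out', 'sustained' (within band) or
        'sustained_fast' (above the band)."""
        out = []
        for rel, f in zip(self.reliable, self.mean_frequency):
            if not rel:
                out.append("dies_out")
            elif f <= band[1]:
                out.append("sustained")
            else:
                out.append("sustained_fast")
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "g_peak_nS": self.g_values,
            "mean_freq_Hz": self.mean_frequency,
            "reliable": self.reliable,
            "mean_synchrony": self.synchrony.mean(axis=1),
            "classification": self.classify(),
        })


def frequency_vs_conductance_sweep(run_one, g_values, seeds,
                                   ) -> SweepResult:
    """Run ``run_one(g, seed) -> (mean_freq, sustained, synchrony)`` over a
    conductance grid and seed list."""
    g_values = np.asarray(g_values, dtype=float)
    freqs = np.zeros((len(g_values), len(seeds)))
    sus = np.zeros((len(g_values), len(seeds)), dtype=bool)
    sync = np.zeros((len(g_values), len(seeds)))
    for i, g in enumerate(g_values):
        for j, seed in enumerate(seeds):
            freqs[i, j], sus[i, j], sync[i, j] = run_one(float(g), int(seed))
    return SweepResult(g_values, freqs, sus, sync, list(seeds))


def stop_probability(run_trial, n_spikes_grid, isi_grid, n_trials: int,
                     master_seed: int = 0) -> pd.DataFrame:
    """Fraction of seeded trials stopped for each (n_spikes, ISI) cell.

    ``run_trial(n_spikes, isi, seed) -> bool`` runs one start+inhibition
    simulation and reports whether the network emitted no spikes after the
    end of inhibition plus 200 ms.  The returned table carries the
    inhibition duration (n_spikes - 1) * ISI per row.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rows = []
    ss = np.random.SeedSequence(master_seed)
    for ns in n_spikes_grid:
        for isi in isi_grid:
            seeds = [int(s.generate_state(1)[0] % (2**31))
                     for s in ss.spawn(n_trials)]
            stopped = sum(bool(run_trial(int(ns), float(isi), s))
                          for s in seeds)
            rows.append({"n_spikes": int(ns), "isi_ms": float(isi),
                         "duration_ms": (int(ns) - 1) * float(isi),
                         "stop_fraction": stopped / n_trials,
                         "n_trials": n_trials})
    return pd.DataFrame(rows)
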