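"""The five in-silico experiments.

Each driver reproduces one figure-level protocol:

* ``run_perfusion`` - clamped NMDAR activation of the coupled dIN column,
  with and without Mg-block voltage dependence: steady-state depolarization
  (Na removed) and firing frequency vs conductance.
* ``run_summation`` - conductance summation of a single NMDAR synapse
  driven by regular spike trains.
* ``run_start``   - sensory (tIN) volley switching on sustained rhythm,
  swept over feedback NMDA strength.
* ``run_stop``    - the started rhythm terminated by a GABAergic (MHR)
  burst over an (n_spikes x ISI) grid.
* ``run_generic`` - the generalization network of 30 classic
  single-compartment neurons with the same feedback architecture.

Every experiment is reproducible from (config, seed) and can write CSV
tables, JSON spike rasters and a manifest to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .analysis import (SUSTAINED_PHASE_DELAY, SweepResult, firing_frequency,
                       frequency_vs_conductance_sweep, stop_probability,
                       sustained_flag, synchrony_index)
from .engine import Recording, SimulationConfig, simulate
from .network import build_din_population, build_generic_population
from .stimuli import (MhrBurst, PerfusionProtocol, StimulusProtocol,
                      mhr_drive, sensory_drive)
from .synapses import (SynapseKinetics, inhibitory_gaba, sensory_ampa,
                       sensory_nmda, steady_state_summation_ratio,
                       feedback_nmda)

# Estimated total NMDAR conductance to one dIN during swimming, from
# voltage-clamp holding-current measurements (nS).
PHYSIOLOGICAL_BAND_NS = (0.6, 1.5)

EXPERIMENT_NAMES = ("perfusion", "summation", "start", "stop", "generic")


def _seed_from(master: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master), *tags]))


# ---------------------------------------------------------------------------
# Protocol builders shared by start/stop experiments.
# ---------------------------------------------------------------------------

def din_start_protocol(seed: int, stimulus_pct: float = 100.0,
                       onset: float = 100.0) -> StimulusProtocol:
    """The canonical sensory start: a 20-tIN volley onto every dIN."""
    rng = _seed_from(seed, 77)
    return StimulusProtocol(drives=sensory_drive(stimulus_pct, rng,
                                                 onset=onset))


def din_start_recording(nmda_g_peak: float, seed: int,
                        duration: float = 1400.0, mg: bool = True,
                        electrical_coupling: bool = True,
                        dt: float = 0.025, onset: float = 100.0,
                        extra_drives=None,
                        record_conductances: bool = False) -> Recording:
    net = build_din_population(nmda_g_peak=nmda_g_peak, mg=mg,
                               electrical_coupling=electrical_coupling,
                               seed=seed)
    proto = din_start_protocol(seed, onset=onset)
    if extra_drives:
        proto.drives.extend(extra_drives)
    cfg = SimulationConfig(duration=duration, dt=dt, seed=seed,
                           record_conductances=record_conductances)
    return simulate(net, proto, cfg)


def _start_metrics(rec: Recording, duration: float, onset: float = 100.0):
    t0 = onset + SUSTAINED_PHASE_DELAY
    freq = float(np.mean([firing_frequency(s, (t0, duration))
                          for s in rec.spikes]))
    sus = any(sustained_flag(s, duration) for s in rec.spikes)
    sync = synchrony_index(rec.spikes, (t0, duration)) if sus else 0.0
    return freq, sus, sync


# ---------------------------------------------------------------------------
# Experiment 1: NMDA perfusion.
# ---------------------------------------------------------------------------

def run_perfusion(g_grid=None, seed: int = 0, duration: float = 1200.0,
                  n: int = 30, dt: float = 0.025) -> dict:
    """Clamped NMDAR activation of the dIN population.

    Returns a dict with two tables: ``steady_state`` (mean somatic voltage
    per conductance with Na channels removed, with/without Mg block) and
    ``firing`` (sustained-phase frequency and sustained flag, with/without
    Mg block), plus the physiological conductance band annotation.
    """
    if g_grid is None:
        g_grid = [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0]

    na_free = {"soma_channels": {"din_na": 0.0},
               "axon_channels": {"din_na": 0.0}}
    rows_ss, rows_fire = [], []
    for mg in (True, False):
        for g in g_grid:
            perf = PerfusionProtocol(float(g), onset=100.0,
                                     ramp_duration=200.0, mg=mg)
            proto = StimulusProtocol(perfusion=perf)
            # (i) steady state without firing
            net = build_din_population(nmda_g_peak=0.0, ampa_g_peak=0.0,
                                       seed=seed, din_overrides=na_free)
            rec = simulate(net, proto, SimulationConfig(
                duration=600.0, dt=dt, seed=seed))
            rows_ss.append({"g_nS": g, "mg": mg,
                            "v_steady_mV": float(rec.v[:, -1].mean())})
            # (ii) firing with Na intact (no feedback: perfusion only)
            net = build_din_population(nmda_g_peak=0.0, ampa_g_peak=0.0,
                                       seed=seed)
            rec = simulate(net, proto, SimulationConfig(
                duration=duration, dt=dt, seed=seed))
            freq = float(np.mean([
                firing_frequency(s, (duration / 2, duration))
                for s in rec.spikes]))
            sus = any(sustained_flag(s, duration) for s in rec.spikes)
            rows_fire.append({"g_nS": g, "mg": mg, "freq_Hz": freq,
                              "sustained": sus})
    return {
        "steady_state": pd.DataFrame(rows_ss),
        "firing": pd.DataFrame(rows_fire),
        "physiological_band_nS": PHYSIOLOGICAL_BAND_NS,
    }


# ---------------------------------------------------------------------------
# Experiment 2: NMDAR summation.
# ---------------------------------------------------------------------------

def run_summation(freqs=(5.0, 10.0, 15.0, 20.0, 25.0, 40.0, 60.0, 100.0),
                  n_spikes: int = 40,
                  kinetics: SynapseKinetics | None = None) -> dict:
    """Summed conductance of a feedback NMDAR synapse vs train frequency."""
    kin = feedback_nmda(1.0) if kinetics is None else kinetics
    rows = [{"freq_Hz": f,
             "max_over_single_peak":
                 steady_state_summation_ratio(kin, float(f), n_spikes)}
            for f in freqs]
    df = pd.DataFrame(rows)
    swim = df[(df.freq_Hz >= 10) & (df.freq_Hz <= 25)]
    return {"summation": df,
            "swim_band_max_ratio": float(swim.max_over_single_peak.max())}


# ---------------------------------------------------------------------------
# Experiment 3: sensory start.
# ---------------------------------------------------------------------------

def run_start(g_grid=None, seeds=(1, 2, 3), duration: float = 1400.0,
              canonical_g: float = 0.11, dt: float = 0.025,
              mg: bool = True, electrical_coupling: bool = True) -> dict:
    """Feedback-strength sweep of the sensory-started dIN rhythm."""
    if g_grid is None:
        g_grid = [0.05, 0.07, 0.09, 0.11, 0.13, 0.15, 0.2, 0.25]

    def run_one(g, seed):
        rec = din_start_recording(g, seed, duration, mg=mg,
                                  electrical_coupling=electrical_coupling,
                                  dt=dt)
        return _start_metrics(rec, duration)

    sweep = frequency_vs_conductance_sweep(run_one, g_grid, list(seeds))
    canonical = din_start_recording(canonical_g, int(seeds[0]), duration,
                                    mg=mg,
                                    electrical_coupling=electrical_coupling,
                                    dt=dt, record_conductances=True)
    return {"sweep": sweep, "sweep_table": sweep.to_dataframe(),
            "canonical_recording": canonical, "canonical_g": canonical_g}


# ---------------------------------------------------------------------------
# Experiment 4: inhibitory stop.
# ---------------------------------------------------------------------------

def stop_trial(n_spikes: int, isi: float, seed: int,
               nmda_g_peak: float = 0.11, gaba_g_peak: float = 2.0,
               inhibition_onset: float = 700.0, dt: float = 0.025,
               settle: float = 500.0) -> bool:
    """One start+inhibition run; True iff no spikes occur later than
    200 ms after the inhibition ends."""
    burst = MhrBurst(n_spikes, isi, inhibition_onset)
    inh_end = inhibition_onset + burst.duration
    duration = inh_end + 200.0 + settle
    rec = din_start_recording(
        nmda_g_peak, seed, duration, dt=dt,
        extra_drives=[mhr_drive(burst, inhibitory_gaba(gaba_g_peak))])
    post = sum(int((s > inh_end + 200.0).sum()) for s in rec.spikes)
    return post == 0


def run_stop(n_spikes_grid=(1, 2, 3, 4, 5), isi_grid=(10.0, 15.0, 20.0),
             n_trials: int = 3, seed: int = 0, nmda_g_peak: float = 0.11,
             gaba_g_peak: float = 2.0, inhibition_onset: float = 700.0,
             dt: float = 0.025) -> dict:
    """Stop-probability table over the burst grid plus the canonical
    5-IPSP run."""
    table = stop_probability(
        lambda ns, isi, s: stop_trial(ns, isi, s, nmda_g_peak, gaba_g_peak,
                                      inhibition_onset, dt),
        n_spikes_grid, isi_grid, n_trials, master_seed=seed)
    burst = MhrBurst(5, 15.0, inhibition_onset)
    canonical = din_start_recording(
        nmda_g_peak, 1, inhibition_onset + 600.0, dt=dt,
        extra_drives=[mhr_drive(burst, inhibitory_gaba(gaba_g_peak))],
        record_conductances=True)
    return {"stop_table": table, "canonical_recording": canonical,
            "canonical_burst": burst}


# ---------------------------------------------------------------------------
# Experiment 5: generic Hodgkin-Huxley population.
# ---------------------------------------------------------------------------

def generic_recording(nmda_g_peak: float, seed: int, duration: float,
                      excitation_onsets=(100.0,), inhibition_onsets=(),
                      stimulus_pct: float = 130.0,
                      electrical_coupling: bool = True,
                      dt: float = 0.025,
                      record_conductances: bool = False) -> Recording:
    net = build_generic_population(nmda_g_peak=nmda_g_peak,
                                   electrical_coupling=electrical_coupling,
                                   seed=seed)
    drives = []
    rng = _seed_from(seed, 55)
    for onset in excitation_onsets:
        drives.extend(sensory_drive(stimulus_pct, rng, onset=onset))
    for onset in inhibition_onsets:
        drives.append(mhr_drive(MhrBurst(10, 7.0, onset),
                                inhibitory_gaba(3.0)))
    cfg = SimulationConfig(duration=duration, dt=dt, seed=seed,
                           record_conductances=record_conductances)
    return simulate(net, StimulusProtocol(drives=drives), cfg)


def run_generic(g_grid=None, seeds=(1, 2, 3), duration: float = 1100.0,
                canonical_g: float = 0.6, dt: float = 0.025,
                electrical_coupling: bool = True) -> dict:
    """Feedback sweep of the generic population (volley at 100 ms, no
    inhibition) plus the canonical on/off run (excitation at 100 and
    600 ms, inhibitory bursts at 300 and 1400 ms)."""
    if g_grid is None:
        g_grid = [0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0, 1.5, 2.0]

    def run_one(g, seed):
        rec = generic_recording(g, seed, duration, dt=dt,
                                electrical_coupling=electrical_coupling)
        return _start_metrics(rec, duration)

    sweep = frequency_vs_conductance_sweep(run_one, g_grid, list(seeds))
    canonical = generic_recording(
        canonical_g, int(seeds[0]), 1800.0,
        excitation_onsets=(100.0, 600.0), inhibition_onsets=(300.0, 1400.0),
        dt=dt, electrical_coupling=electrical_coupling,
        record_conductances=True)
    return {"sweep": sweep, "sweep_table": sweep.to_dataframe(),
            "canonical_recording": canonical, "canonical_g": canonical_g}


# ---------------------------------------------------------------------------
# Output writing.
# ---------------------------------------------------------------------------

def write_outputs(name: str, results: dict, outdir, seed: int,
                  config: dict | None = None, plot: bool = False):
    """Write the experiment's tables (CSV), recordings (CSV + JSON spikes),
    manifest (JSON) and optional PNG overview plot to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, val in results.items():
        if isinstance(val, pd.DataFrame):
            path = outdir / f"{key}.csv"
            val.to_csv(path, index=False)
            written.append(path.name)
        elif isinstance(val, Recording):
            val.to_csv(outdir / f"{key}_voltage.csv")
            val.spikes_to_json(outdir / f"{key}_spikes.json")
            written.extend([f"{key}_voltage.csv", f"{key}_spikes.json"])
        elif isinstance(val, SweepResult):
            continue  # covered by its table
    config = config or {}
    manifest = {
        "experiment": name,
        "seed": seed,
        "version": _version,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "written": written,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    if plot:
        _overview_plot(name, results, outdir / f"{name}.png")
    return manifest


def _overview_plot(name: str, results: dict, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    if name == "perfusion":
        df = results["firing"]
        for mg, grp in df.groupby("mg"):
            ax.plot(grp.g_nS, grp.freq_Hz, "o-",
                    label="with Mg block" if mg else "no Mg")
        ax.axvspan(*results["physiological_band_nS"], alpha=0.2,
                   color="tab:blue")
        ax.set_xlabel("NMDAR conductance (nS)")
        ax.set_ylabel("firing frequency (Hz)")
    elif name == "summation":
        df = results["summation"]
        ax.plot(df.freq_Hz, df.max_over_single_peak, "o-")
        ax.set_xlabel("train frequency (Hz)")
        ax.set_ylabel("max conductance / single-event peak")
    elif name in ("start", "generic"):
        df = results["sweep_table"]
        ax.plot(df.g_peak_nS, df.mean_freq_Hz, "o-")
        ax.set_xlabel("feedback NMDA g_peak per synapse (nS)")
        ax.set_ylabel("mean sustained frequency (Hz)")
    elif name == "stop":
        df = results["stop_table"]
        ax.plot(df.duration_ms, df.stop_fraction, "o")
        ax.set_xlabel("inhibition duration (ms)")
        ax.set_ylabel("stop fraction")
    ax.legend() if ax.get_legend_handles_labels()[0] else None
    ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
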