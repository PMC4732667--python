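"""Time integration of the coupled compartment/synapse system.

Fixed-step integration (default dt = 0.025 ms).  Per step:

* gate variables advance by exponential (analytic) update using tabulated
  steady states and time constants;
* ohmic channel and synaptic conductances are treated implicitly in the
  compartment voltage; GHK calcium current and gap-junction neighbour
  voltages are treated explicitly (junction conductance is still lumped
  into the diagonal, which keeps the coupled system tridiagonal under a
  per-neuron compartment ordering and solvable by the Thomas algorithm);
* synaptic (A, B) states decay analytically and queued deliveries step
  them up by 1;
* upward 0 mV soma crossings are detected with hysteresis (re-armed below
  -10 mV) and schedule feedback deliveries one synaptic delay later,
  snapped to the step grid.

The integration loop is compiled with numba.  Integration aborts with a
diagnostic if any voltage leaves (-200, 200) mV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .channels import FARADAY, GAS_CONSTANT
from .network import NetworkGraph
from .stimuli import StimulusProtocol

__all__ = ["SimulationConfig", "Recording", "simulate", "detect_spikes"]

_TAB_VMIN = -120.0
_TAB_VMAX = 80.0
_TAB_DV = 0.05

SPIKE_THRESHOLD = 0.0
SPIKE_RESET = -10.0

# theta-method voltage update (1/2 = Crank-Nicolson)
_THETA = 0.5
_THETA_C = 1.0 - _THETA


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level settings."""

    duration: float               # ms
    dt: float = 0.025             # ms
    seed: int = 0                 # feedback-transmission randomness
    record_dt: float = 0.1        # ms between recorded samples
    record_conductances: bool = False
    record_all_compartments: bool = False  # record every compartment, not somata
    v_init: float | None = None   # None: leak reversal per compartment

    def __post_init__(self):
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")
        if self.record_dt < self.dt:
            raise ValueError("record_dt must be >= dt")


@dataclass
class Recording:
    """Recorded traces and detected spikes of one simulation."""

    t: np.ndarray                       # ms
    v: np.ndarray                       # (n_neurons, nt) soma voltages, mV
    spikes: list[np.ndarray]            # per-neuron spike times, ms
    syn_g: dict[str, np.ndarray] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.v.shape[0]

    def spike_table(self):
        import pandas as pd
        rows = [(n, t) for n, ts in enumerate(self.spikes) for t in ts]
        return pd.DataFrame(rows, columns=["neuron", "t_ms"])

    def to_csv(self, path):
        """Long-format voltage traces: neuron, t_ms, v_mV."""
        import pandas as pd
        n, nt = self.v.shape
        df = pd.DataFrame({
            "neuron": np.repeat(np.arange(n), nt),
            "t_ms": np.tile(self.t, n),
            "v_mV": self.v.ravel(),
        })
        df.to_csv(path, index=False)

    def spikes_to_json(self, path=None):
        doc = {"config": self.config,
               "spikes_ms": [list(map(float, s)) for s in self.spikes]}
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def detect_spikes(t, v, threshold: float = SPIKE_THRESHOLD,
                  reset: float = SPIKE_RESET) -> np.ndarray:
    """Upward threshold crossings of a uniformly sampled trace, with
    hysteresis (no re-detection until the trace falls below ``reset``) and
    linear interpolation of the crossing time."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    out = []
    armed = v[0] < reset
    for i in range(1, len(v)):
        if armed and v[i - 1] < threshold <= v[i]:
            frac = (threshold - v[i - 1]) / (v[i] - v[i - 1])
            out.append(t[i - 1] + frac * (t[i] - t[i - 1]))
            armed = False
        elif not armed and v[i] < reset:
            armed = True
    return np.array(out)


# ---------------------------------------------------------------------------
# Numba kernel.
# ---------------------------------------------------------------------------

@njit(cache=True)
def _kernel(n_steps, dt, rec_every,
            v, v_prev, cap_over_dt, ax_low, ax_up, ax_diag,
            # channels (CSR over compartments per channel type)
            chan_ptr, chan_comp, chan_g,
            chan_erev, chan_is_ghk, chan_ucoef, chan_zf, chan_ci, chan_co,
            chan_gate_ptr,
            # gates
            gate_exp, xoff, xs, xinf_tab, efac_tab,
            # synapses
            sy_post, sy_g, sy_e, sy_do, sy_dc, sy_inorm, sy_mgk, sy_gamma,
            sy_delay_steps, sy_p, sy_rec, sy_a, sy_b,
            fb_ptr, fb_syn,
            ext_step, ext_syn,
            pend_step, pend_syn, urand,
            # gap junctions / perfusion / currents
            gj_a, gj_b, gj_g,
            perf_comp, perf_g, perf_on, perf_ramp, perf_e, perf_mgk,
            perf_gamma, perf_rec,
            ic_comp, ic_amp, ic_on, ic_off,
            # detection + recording
            soma_comp, rec_comp, armed, vout, grec, spk_t, spk_n,
            diag, rhs, cp, dp, vn, garr):
    n = v.shape[0]
    nchan = chan_ptr.shape[0] - 1
    nsyn = sy_a.shape[0]
    ngj = gj_a.shape[0]
    nperf = perf_comp.shape[0]
    nic = ic_comp.shape[0]
    nnrn = soma_comp.shape[0]
    nrec_chan = garr.shape[0]
    ntab = xinf_tab.shape[1]
    dv_inv = 1.0 / _TAB_DV
    pcap = pend_step.shape[0]
    spk_cap = spk_t.shape[0]
    nu = urand.shape[0]

    npend = 0
    nspk = 0
    iext = 0
    iu = 0
    status = 0
    n_done = n_steps

    for step in range(n_steps):
        t = step * dt

        # -- gate update (exponential Euler via tables) -------------------
        for c in range(nchan):
            c0, c1 = chan_ptr[c], chan_ptr[c + 1]
            for gi in range(chan_gate_ptr[c], chan_gate_ptr[c + 1]):
                off = xoff[gi]
                for j in range(c0, c1):
                    vv = v[chan_comp[j]]
                    pos = (vv - _TAB_VMIN) * dv_inv
                    if pos < 0.0:
                        pos = 0.0
                    elif pos > ntab - 1.001:
                        pos = ntab - 1.001
                    k = int(pos)
                    fr = pos - k
                    xinf = xinf_tab[gi, k] * (1.0 - fr) + xinf_tab[gi, k + 1] * fr
                    ef = efac_tab[gi, k] * (1.0 - fr) + efac_tab[gi, k + 1] * fr
                    idx = off + (j - c0)
                    xs[idx] += (xinf - xs[idx]) * ef

        # -- assemble linear system ---------------------------------------
        for i in range(n):
            diag[i] = cap_over_dt[i] + ax_diag[i]
            rhs[i] = cap_over_dt[i] * v[i]
        for r in range(nrec_chan):
            garr[r] = 0.0

        for c in range(nchan):
            c0, c1 = chan_ptr[c], chan_ptr[c + 1]
            g0, g1 = chan_gate_ptr[c], chan_gate_ptr[c + 1]
            if chan_is_ghk[c]:
                for j in range(c0, c1):
                    comp = chan_comp[j]
                    open_f = 1.0
                    for gi in range(g0, g1):
                        x = xs[xoff[gi] + (j - c0)]
                        for _ in range(gate_exp[gi]):
                            open_f *= x
                    u = chan_ucoef[c] * v[comp]
                    if u > 500.0:
                        u = 500.0
                    elif u < -500.0:
                        u = -500.0
                    if abs(u) < 1e-8:
                        f = (chan_ci[c] - chan_co[c]) \
                            + u * (chan_ci[c] + chan_co[c]) * 0.5
                    else:
                        f = u * (chan_ci[c] - chan_co[c] * math.exp(-u)) \
                            / (1.0 - math.exp(-u))
                    rhs[comp] -= chan_g[j] * open_f * chan_zf[c] * f
            else:
                for j in range(c0, c1):
                    comp = chan_comp[j]
                    open_f = 1.0
                    for gi in range(g0, g1):
                        x = xs[xoff[gi] + (j - c0)]
                        for _ in range(gate_exp[gi]):
                            open_f *= x
                    g = chan_g[j] * open_f
                    diag[comp] += g
                    rhs[comp] += g * chan_erev[c]

        # -- synapses: decay, deliver, conduct ----------------------------
        for s in range(nsyn):
            sy_a[s] *= sy_do[s]
            sy_b[s] *= sy_dc[s]
        while iext < ext_step.shape[0] and ext_step[iext] == step:
            s = ext_syn[iext]
            sy_a[s] += 1.0
            sy_b[s] += 1.0
            iext += 1
        k = 0
        while k < npend:
            if pend_step[k] == step:
                s = pend_syn[k]
                sy_a[s] += 1.0
                sy_b[s] += 1.0
                npend -= 1
                pend_step[k] = pend_step[npend]
                pend_syn[k] = pend_syn[npend]
            else:
                k += 1
        for s in range(nsyn):
            d = sy_b[s] - sy_a[s]
            if d > 1e-14 or d < -1e-14:
                gs = sy_g[s] * d * sy_inorm[s]
                comp = sy_post[s]
                w = 1.0
                if sy_mgk[s] > 0.0:
                    w = 1.0 / (1.0 + sy_mgk[s] * math.exp(-sy_gamma[s]
                                                          * v[comp]))
                ge = gs * w
                diag[comp] += ge
                rhs[comp] += ge * sy_e[s]
                if sy_rec[s] >= 0:
                    garr[sy_rec[s]] += gs

        # -- perfusion ----------------------------------------------------
        for p in range(nperf):
            if t >= perf_on[p]:
                if perf_ramp[p] > 0.0 and t < perf_on[p] + perf_ramp[p]:
                    gp = perf_g[p] * (t - perf_on[p]) / perf_ramp[p]
                else:
                    gp = perf_g[p]
                if gp > 0.0:
                    comp = perf_comp[p]
                    w = 1.0
                    if perf_mgk[p] > 0.0:
                        w = 1.0 / (1.0 + perf_mgk[p]
                                   * math.exp(-perf_gamma[p] * v[comp]))
                    ge = gp * w
                    diag[comp] += ge
                    rhs[comp] += ge * perf_e[p]
                    if perf_rec[p] >= 0:
                        garr[perf_rec[p]] += gp

        # -- gap junctions (semi-implicit) --------------------------------
        for q in range(ngj):
            a, b, g = gj_a[q], gj_b[q], gj_g[q]
            diag[a] += g
            rhs[a] += g * v[b]
            diag[b] += g
            rhs[b] += g * v[a]

        # -- injected currents -------------------------------------------
        for q in range(nic):
            if ic_on[q] <= step < ic_off[q]:
                rhs[ic_comp[q]] += ic_amp[q]

        # -- Crank-Nicolson transform -------------------------------------
        # assembled so far: diag = C/dt + G_i, rhs = C/dt*v + b0 with
        # G_i the total linear conductance on i; take a theta=1/2 step.
        for i in range(n):
            gtot = diag[i] - cap_over_dt[i]
            resid = gtot * v[i]
            if i > 0:
                resid -= ax_low[i] * v[i - 1]
            if i < n - 1:
                resid -= ax_up[i] * v[i + 1]
            rhs[i] -= _THETA_C * resid
            diag[i] = cap_over_dt[i] + _THETA * gtot

        # -- tridiagonal solve (Thomas) -----------------------------------
        cp[0] = -_THETA * ax_up[0] / diag[0]
        dp[0] = rhs[0] / diag[0]
        for i in range(1, n):
            m = diag[i] + _THETA * ax_low[i] * cp[i - 1]
            cp[i] = -_THETA * ax_up[i] / m
            dp[i] = (rhs[i] + _THETA * ax_low[i] * dp[i - 1]) / m
        vn[n - 1] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            vn[i] = dp[i] - cp[i] * vn[i + 1]

        # -- spike detection + feedback scheduling ------------------------
        for nr in range(nnrn):
            sc = soma_comp[nr]
            vold = v[sc]
            vnew = vn[sc]
            if armed[nr]:
                if vold < SPIKE_THRESHOLD <= vnew:
                    frac = (SPIKE_THRESHOLD - vold) / (vnew - vold)
                    if nspk < spk_cap:
                        spk_t[nspk] = t + dt * frac
                        spk_n[nspk] = nr
                        nspk += 1
                    else:
                        status = 3
                    armed[nr] = False
                    for q in range(fb_ptr[nr], fb_ptr[nr + 1]):
                        s = fb_syn[q]
                        ok = True
                        if sy_p[s] < 1.0:
                            ok = urand[iu] < sy_p[s]
                            iu += 1
                            if iu >= nu:
                                iu = 0
                        if ok:
                            if npend < pcap:
                                # delivery snapped to the step nearest the
                                # interpolated crossing time + delay
                                ds = sy_delay_steps[s]
                                if frac >= 0.5:
                                    ds += 1
                                if ds < 1:
                                    ds = 1
                                pend_step[npend] = step + ds
                                pend_syn[npend] = s
                                npend += 1
                            else:
                                status = 2
            elif vnew < SPIKE_RESET:
                armed[nr] = True

        # -- commit, abort check, record ----------------------------------
        bad = False
        for i in range(n):
            v_prev[i] = v[i]
            v[i] = vn[i]
            if not (-200.0 < v[i] < 200.0):
                bad = True
        if bad:
            status = 1
            n_done = step + 1
            break
        if (step + 1) % rec_every == 0:
            col = (step + 1) // rec_every
            for rr in range(rec_comp.shape[0]):
                vout[rr, col] = v[rec_comp[rr]]
            for r in range(nrec_chan):
                grec[r, col] = garr[r]

    return status, nspk, n_done


# ---------------------------------------------------------------------------
# Compiler: NetworkGraph + StimulusProtocol -> flat arrays.
# ---------------------------------------------------------------------------

def _density_to_uS(density_mS_cm2: float, area_cm2: float) -> float:
    return density_mS_cm2 * area_cm2 * 1e3


class _Compiled:
    """Flattened arrays for one (network, protocol, config) triple."""

    def __init__(self, net: NetworkGraph, protocol: StimulusProtocol,
                 cfg: SimulationConfig):
        self.net, self.protocol, self.cfg = net, protocol, cfg
        dt = cfg.dt
        ss = np.random.SeedSequence(cfg.seed)
        ss_ext, ss_kernel = ss.spawn(2)
        rng_ext = np.random.default_rng(ss_ext)
        rng_kernel = np.random.default_rng(ss_kernel)

        # ---- compartments ------------------------------------------------
        offsets, comps = [], []
        for nm in net.neurons:
            offsets.append(len(comps))
            comps.extend(nm.compartments)
        self.comp_offset = np.array(offsets, dtype=np.int64)
        n = len(comps)
        self.n_comp = n
        cap = np.array([c.capacitance_nF for c in comps])
        self.cap_over_dt = cap / dt
        ax_low = np.zeros(n)
        ax_up = np.zeros(n)
        for nm, off in zip(net.neurons, offsets):
            g = nm.axial_couplings_uS()
            for i, gg in enumerate(g):
                ax_up[off + i] = gg
                ax_low[off + i + 1] = gg
        self.ax_low, self.ax_up = ax_low, ax_up
        self.ax_diag = ax_low + ax_up

        v0 = np.empty(n)
        for idx, c in enumerate(comps):
            if cfg.v_init is not None:
                v0[idx] = cfg.v_init
            else:
                leaks = [sp.reversal_potential for sp in c.channels.values()
                         if (not sp.is_ghk) and not sp.gates]
                v0[idx] = leaks[0] if leaks else -65.0
        self.v = v0

        # ---- channels, grouped by name ----------------------------------
        groups: dict[str, dict] = {}
        for idx, c in enumerate(comps):
            for name, spec in c.channels.items():
                grp = groups.setdefault(name, {"spec": spec, "comp": [],
                                               "g": []})
                grp["comp"].append(idx)
                if spec.is_ghk:
                    grp["g"].append(spec.ghk.permeability * c.area_cm2 * 1e3)
                else:
                    grp["g"].append(_density_to_uS(spec.conductance_density,
                                                   c.area_cm2))
        names = sorted(groups)
        nchan = len(names)
        chan_ptr = np.zeros(nchan + 1, dtype=np.int64)
        chan_gate_ptr = np.zeros(nchan + 1, dtype=np.int64)
        chan_comp, chan_g = [], []
        chan_erev = np.zeros(nchan)
        chan_is_ghk = np.zeros(nchan, dtype=np.bool_)
        chan_ucoef = np.zeros(nchan)
        chan_zf = np.zeros(nchan)
        chan_ci = np.zeros(nchan)
        chan_co = np.zeros(nchan)
        gate_kin, gate_exp, xoff, xs_parts = [], [], [], []
        xlen = 0
        for ci, name in enumerate(names):
            grp = groups[name]
            spec = grp["spec"]
            chan_comp.extend(grp["comp"])
            chan_g.extend(grp["g"])
            chan_ptr[ci + 1] = len(chan_comp)
            ncomp_c = len(grp["comp"])
            if spec.is_ghk:
                p = spec.ghk
                chan_is_ghk[ci] = True
                z = float(p.valence)
                chan_ucoef[ci] = z * FARADAY * 1e-3 \
                    / (GAS_CONSTANT * p.temperature)
                chan_zf[ci] = z * FARADAY * 1e6  # -> uA/cm^2, then *area*1e3
                chan_ci[ci] = p.ca_in * 1e-6
                chan_co[ci] = p.ca_out * 1e-6
            else:
                chan_erev[ci] = spec.reversal_potential
            for kin in spec.gates:
                gate_kin.append(kin)
                gate_exp.append(kin.exponent)
                xoff.append(xlen)
                vcomp = v0[np.array(grp["comp"], dtype=np.int64)]
                xs_parts.append(np.asarray(kin.steady_state(vcomp),
                                           dtype=float))
                xlen += ncomp_c
            chan_gate_ptr[ci + 1] = len(gate_kin)
        self.chan_ptr = chan_ptr
        self.chan_comp = np.array(chan_comp, dtype=np.int64)
        self.chan_g = np.array(chan_g, dtype=float)
        self.chan_erev, self.chan_is_ghk = chan_erev, chan_is_ghk
        self.chan_ucoef, self.chan_zf = chan_ucoef, chan_zf
        self.chan_ci, self.chan_co = chan_ci, chan_co
        self.chan_gate_ptr = chan_gate_ptr
        self.gate_exp = np.array(gate_exp, dtype=np.int64)
        self.xoff = np.array(xoff, dtype=np.int64)
        self.xs = (np.concatenate(xs_parts) if xs_parts
                   else np.zeros(0))
        self._gate_kin = gate_kin
        self._gate_comp_groups = [
            np.array(groups[name]["comp"], dtype=np.int64) for name in names]

        # rate tables (dt-dependent exponential-Euler factor)
        vgrid = np.arange(_TAB_VMIN, _TAB_VMAX + _TAB_DV / 2, _TAB_DV)
        ntab = len(vgrid)
        ngate = len(gate_kin)
        xinf_tab = np.zeros((max(ngate, 1), ntab))
        efac_tab = np.zeros((max(ngate, 1), ntab))
        for gi, kin in enumerate(gate_kin):
            a, b = kin.rates(vgrid)
            tot = np.maximum(np.asarray(a) + np.asarray(b), 1e-12)
            xinf_tab[gi] = np.asarray(a) / tot
            efac_tab[gi] = 1.0 - np.exp(-dt * tot)
        self.xinf_tab, self.efac_tab = xinf_tab, efac_tab

        # ---- synapses ----------------------------------------------------
        soma_comp = np.array(
            [off + nm.soma_index for nm, off in zip(net.neurons, offsets)],
            dtype=np.int64)
        self.soma_comp = soma_comp
        n_neurons = net.n_neurons

        rec_labels: list[str] = []

        def rec_idx(label: str, post: int) -> int:
            if not cfg.record_conductances:
                return -1
            if label not in rec_labels:
                rec_labels.append(label)
            return rec_labels.index(label) * n_neurons + post

        syns = []          # (post_comp, kin, rec, fb_pre or -1)
        ext_events = []    # (step, syn_index)
        for s in net.synapses:
            syns.append((soma_comp[s.post], s.kinetics,
                         rec_idx(s.kinetics.label or "syn", s.post), s.pre))
        for drive in protocol.drives:
            targets = (range(n_neurons) if drive.targets is None
                       else drive.targets)
            kin = drive.kinetics
            for tgt in targets:
                si = len(syns)
                syns.append((soma_comp[tgt], kin,
                             rec_idx(kin.label or "ext", tgt), -1))
                for ts in drive.spike_times:
                    if kin.transmission_p < 1.0 \
                            and rng_ext.random() >= kin.transmission_p:
                        continue
                    ext_events.append((int(round((ts + kin.delay) / dt)), si))

        nsyn = len(syns)
        self.sy_post = np.array([s[0] for s in syns], dtype=np.int64)
        self.sy_g = np.array([s[1].g_peak * 1e-3 for s in syns])  # nS->uS
        self.sy_e = np.array([s[1].e_rev for s in syns])
        self.sy_do = np.array([math.exp(-dt / s[1].tau_open) for s in syns])
        self.sy_dc = np.array([math.exp(-dt / s[1].tau_close) for s in syns])
        self.sy_inorm = np.array([1.0 / s[1].norm for s in syns])
        self.sy_mgk = np.array(
            [s[1].mg_block.eta * s[1].mg_block.mg_out
             if s[1].mg_block is not None else 0.0 for s in syns])
        self.sy_gamma = np.array(
            [s[1].mg_block.gamma if s[1].mg_block is not None else 0.0
             for s in syns])
        self.sy_delay_steps = np.array(
            [max(0, int(round(s[1].delay / dt))) for s in syns],
            dtype=np.int64)
        self.sy_p = np.array([s[1].transmission_p for s in syns])
        self.sy_rec = np.array([s[2] for s in syns], dtype=np.int64)
        self.sy_a = np.zeros(nsyn)
        self.sy_b = np.zeros(nsyn)

        fb_lists: list[list[int]] = [[] for _ in range(n_neurons)]
        for si, s in enumerate(syns):
            if s[3] >= 0:
                fb_lists[s[3]].append(si)
        fb_ptr = np.zeros(n_neurons + 1, dtype=np.int64)
        fb_syn = []
        for nr, lst in enumerate(fb_lists):
            fb_syn.extend(lst)
            fb_ptr[nr + 1] = len(fb_syn)
        self.fb_ptr = fb_ptr
        self.fb_syn = np.array(fb_syn, dtype=np.int64)

        ext_events.sort()
        self.ext_step = np.array([e[0] for e in ext_events], dtype=np.int64)
        self.ext_syn = np.array([e[1] for e in ext_events], dtype=np.int64)

        # ---- perfusion ---------------------------------------------------
        perf = protocol.perfusion
        if perf is not None and perf.target_g > 0:
            from .synapses import DEFAULT_MG_BLOCK
            mgk = (DEFAULT_MG_BLOCK.eta * DEFAULT_MG_BLOCK.mg_out
                   if perf.mg else 0.0)
            gamma = DEFAULT_MG_BLOCK.gamma if perf.mg else 0.0
            self.perf_comp = soma_comp.copy()
            self.perf_g = np.full(n_neurons, perf.target_g * 1e-3)
            self.perf_on = np.full(n_neurons, perf.onset)
            self.perf_ramp = np.full(n_neurons, perf.ramp_duration)
            self.perf_e = np.full(n_neurons, perf.e_rev)
            self.perf_mgk = np.full(n_neurons, mgk)
            self.perf_gamma = np.full(n_neurons, gamma)
            self.perf_rec = np.array(
                [rec_idx("perfusion", nr) for nr in range(n_neurons)],
                dtype=np.int64)
        else:
            self.perf_comp = np.zeros(0, dtype=np.int64)
            self.perf_g = self.perf_on = self.perf_ramp = np.zeros(0)
            self.perf_e = self.perf_mgk = self.perf_gamma = np.zeros(0)
            self.perf_rec = np.zeros(0, dtype=np.int64)

        # ---- gap junctions ----------------------------------------------
        ngj = len(net.gap_junctions)
        self.gj_a = np.array(
            [self.comp_offset[g.neuron_a] + g.comp_a
             for g in net.gap_junctions], dtype=np.int64)
        self.gj_b = np.array(
            [self.comp_offset[g.neuron_b] + g.comp_b
             for g in net.gap_junctions], dtype=np.int64)
        self.gj_g = np.array([g.conductance_uS for g in net.gap_junctions])

        # ---- step currents ----------------------------------------------
        ics = protocol.step_currents
        self.ic_comp = np.array(
            [self.comp_offset[c.neuron] + c.compartment for c in ics],
            dtype=np.int64)
        self.ic_amp = np.array([c.amplitude for c in ics])
        self.ic_on = np.array([int(round(c.t_on / dt)) for c in ics],
                              dtype=np.int64)
        self.ic_off = np.array([int(round(c.t_off / dt)) for c in ics],
                               dtype=np.int64)

        self.rec_labels = rec_labels
        self.urand = rng_kernel.random(
            max(1024, 64 * nsyn)) if nsyn else np.zeros(1)

    def run(self) -> Recording:
        cfg = self.cfg
        dt = cfg.dt
        n_steps = int(round(cfg.duration / dt))
        rec_every = max(1, int(round(cfg.record_dt / dt)))
        n_neurons = self.net.n_neurons
        nt = n_steps // rec_every + 1
        rec_comp = (np.arange(self.n_comp, dtype=np.int64)
                    if cfg.record_all_compartments else self.soma_comp)
        vout = np.zeros((len(rec_comp), nt))
        nrec_chan = len(self.rec_labels) * n_neurons
        grec = np.zeros((max(nrec_chan, 1), nt))
        vout[:, 0] = self.v[rec_comp]
        armed = self.v[self.soma_comp] < SPIKE_RESET
        spk_cap = 500_000
        spk_t = np.zeros(spk_cap)
        spk_n = np.zeros(spk_cap, dtype=np.int64)
        pend_cap = 200_000
        pend_step = np.zeros(pend_cap, dtype=np.int64)
        pend_syn = np.zeros(pend_cap, dtype=np.int64)
        n = self.n_comp
        work = [np.zeros(n) for _ in range(5)]
        garr = np.zeros(max(nrec_chan, 1))

        v_prev = self.v.copy()
        status, nspk, n_done = _kernel(
            n_steps, dt, rec_every,
            self.v, v_prev, self.cap_over_dt, self.ax_low, self.ax_up, self.ax_diag,
            self.chan_ptr, self.chan_comp, self.chan_g,
            self.chan_erev, self.chan_is_ghk, self.chan_ucoef, self.chan_zf,
            self.chan_ci, self.chan_co, self.chan_gate_ptr,
            self.gate_exp, self.xoff, self.xs, self.xinf_tab, self.efac_tab,
            self.sy_post, self.sy_g, self.sy_e, self.sy_do, self.sy_dc,
            self.sy_inorm, self.sy_mgk, self.sy_gamma, self.sy_delay_steps,
            self.sy_p, self.sy_rec, self.sy_a, self.sy_b,
            self.fb_ptr, self.fb_syn, self.ext_step, self.ext_syn,
            pend_step, pend_syn, self.urand,
            self.gj_a, self.gj_b, self.gj_g,
            self.perf_comp, self.perf_g, self.perf_on, self.perf_ramp,
            self.perf_e, self.perf_mgk, self.perf_gamma, self.perf_rec,
            self.ic_comp, self.ic_amp, self.ic_on, self.ic_off,
            self.soma_comp, rec_comp, armed, vout, grec, spk_t, spk_n,
            work[0], work[1], work[2], work[3], work[4], garr)

        if status == 1:
            raise RuntimeError(
                f"numerical blow-up: |V| > 200 mV at t = {n_done * dt:.3f} ms"
                " - reduce dt or check parameters")
        if status in (2, 3):
            raise RuntimeError("event buffer overflow during simulation")

        t = np.arange(nt) * rec_every * dt
        spikes = [spk_t[:nspk][spk_n[:nspk] == nr].copy()
                  for nr in range(n_neurons)]
        syn_g = {}
        for li, label in enumerate(self.rec_labels):
            rows = grec[li * n_neurons:(li + 1) * n_neurons, :]
            syn_g[label] = rows * 1e3  # uS -> nS
        config = dict(asdict(cfg))
        config["network_seed"] = self.net.seed
        return Recording(t, vout, spikes, syn_g, config)


def simulate(net: NetworkGraph, protocol: StimulusProtocol | None,
             cfg: SimulationConfig) -> Recording:
    """Integrate the network under the given stimulus protocol."""
    if protocol is None:
        protocol = StimulusProtocol()
    return _Compiled(net, protocol, cfg).run()
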