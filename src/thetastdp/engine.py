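"""Compiled single-trial simulation engine.

One fused step loop (numba) advances membrane potentials, synaptic
currents, oscillators and plasticity at a fixed timestep.  All randomness
(connectivity, background event counts, initial conditions, per-trial
noise) is drawn outside the loop from seeded numpy Generators, so the
loop itself is deterministic given its input arrays.

Synaptic currents: each directed synapse carries one alpha-function
EPSP current whose clock (``delta_t = t - t_fire``) is restarted by every
delivered presynaptic spike event, so a synapse's instantaneous
contribution is bounded by ``W_max * rho`` and the total afferent drive
saturates with presynaptic rate.  (The architecture has no inhibitory
population; accumulating every historic event without bound would make
the recurrent excitation divergent at the published weights.)  Events
are delivered after the synaptic delay, and the kernel amplitude is read
at delivery time — efficacy ``rho`` and, for NC->hippocampus pairs, the
entorhinal gate.  Kernels are evaluated from a lookup table truncated
beyond 10 tau_s, where the contribution is < 0.5 % of peak.  Background
events, which carry no presynaptic identity, enter as single-step
current pulses of height ``W_max``.

The engine also accepts a *forced*-spike schedule (per-step boolean): a
forced neuron spikes that millisecond unless refractory.  This models
suprathreshold stimulation whose spike pattern, not waveform, is the
experimental condition, and gives tests precise control over pairings.

Plasticity traces are maintained incrementally per neuron (decay each
step, increment at spikes) and used strictly before the same-millisecond
increments, so simultaneous spikes never see each other's contribution —
the batch update is order-stable and all deltas at one step are computed
from pre-update efficacies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .network import Architecture, gated_pairs
from .params import ModelConfig
from .plasticity import SynapseMatrix

__all__ = ["TrialResult", "run_trial_arrays"]

_E = float(np.e)


@njit(cache=True)
def _step_loop(n_steps, dt, n, hip_mask,
               v, refr_until, last_spike,
               e_l, v_th, g_m, c_arr, refr_ms, delay_steps,
               exists, w_max, rho, plastic, gated,
               kern_table,
               a_adp, tau_adp, ahp_arr, ahp_decay,
               i_dc, i_ac, i_bg, forced,
               gate_series, ltp_w, ltd_w,
               a_plus, a_minus, gamma_p, gamma_d, ltd_sign,
               eps_ltp, eps_ltd,
               trace_decay, use_window, window_steps,
               rec_src, rec_dst, rho_rec,
               spike_t, spike_n):
    buf_len = delay_steps + 1
    ring_cnt = np.zeros(buf_len, np.int64)
    ring_spk = np.empty((buf_len, n), np.int64)
    kern_len = kern_table.shape[0]
    last_deliv = np.full((n, n), -kern_len - 1, np.int64)
    amp = np.zeros((n, n))
    i_syn = np.zeros(n)
    i_ahp = np.zeros(n)
    trace_p = np.zeros(n)
    trace_d = np.zeros(n)
    wlen = window_steps if use_window else 1
    win_p = np.zeros((wlen, n))
    win_d = np.zeros((wlen, n))
    prev_spike = np.full(n, -1.0e18)
    spiked = np.empty(n, np.int64)
    cap_d = 4 * n * n
    d_src = np.empty(cap_d, np.int64)
    d_dst = np.empty(cap_d, np.int64)
    d_val = np.empty(cap_d)
    n_spk = 0
    min_isi = 1.0e18
    rho_min = 1.0
    rho_max = 0.0
    cap = spike_t.shape[0]
    n_rec = rec_src.shape[0]
    for t in range(n_steps):
        tt = t * dt
        # deliver spike events due now: restart the synapse kernels with
        # amplitude read at delivery time (rho, and EC gate if NC->hip)
        slot = t % buf_len
        g_now = gate_series[t]
        for k in range(ring_cnt[slot]):
            s = ring_spk[slot, k]
            for m in range(n):
                if exists[s, m]:
                    a = w_max[s, m] * rho[s, m]
                    if gated[s, m]:
                        a *= g_now
                    amp[s, m] = a
                    last_deliv[s, m] = t
        ring_cnt[slot] = 0
        # synaptic current: one retriggered alpha kernel per synapse
        for m in range(n):
            i_syn[m] = 0.0
        for s in range(n):
            for m in range(n):
                age = t - last_deliv[s, m]
                if age < kern_len:
                    i_syn[m] += amp[s, m] * kern_table[age]
        # plasticity traces forward to t (strictly pre-spike values)
        if use_window:
            wslot = t % window_steps
            for i in range(n):
                trace_p[i] -= win_p[wslot, i]
                trace_d[i] -= win_d[wslot, i]
                win_p[wslot, i] = 0.0
                win_d[wslot, i] = 0.0
        else:
            for i in range(n):
                trace_p[i] *= trace_decay
                trace_d[i] *= trace_decay
        # membrane update, forced spikes and threshold crossing
        n_sp = 0
        for i in range(n):
            i_ahp[i] *= ahp_decay
            if tt < refr_until[i]:
                v[i] = e_l
                continue
            i_adp = 0.0
            if hip_mask[i]:
                dta = tt - last_spike[i]
                i_adp = a_adp * (dta / tau_adp) * np.exp(1.0 - dta / tau_adp)
            total = (g_m * (e_l - v[i]) + i_syn[i] + i_bg[t, i]
                     + i_ac[t, i] + i_dc[t, i] + i_adp - i_ahp[i])
            v[i] += (dt / c_arr[i]) * total
            if not np.isfinite(v[i]):
                return -1, i, tt, n_spk, min_isi, rho_min, rho_max
            if v[i] >= v_th or forced[t, i]:
                spiked[n_sp] = i
                n_sp += 1
                v[i] = e_l
                i_ahp[i] += ahp_arr[i]
                refr_until[i] = tt + refr_ms
                if prev_spike[i] > -1.0e17:
                    isi = tt - prev_spike[i]
                    if isi < min_isi:
                        min_isi = isi
                prev_spike[i] = tt
                last_spike[i] = tt
                if n_spk < cap:
                    spike_t[n_spk] = t
                    spike_n[n_spk] = i
                n_spk += 1
        # plasticity: deltas from pre-update rho, then batch apply + clip.
        # Full/stdp_only: STDP form — incoming synapses potentiate by the
        # presynaptic partner's LTP trace, outgoing depress by the
        # postsynaptic partner's LTD trace.  theta_only (window mode):
        # phase-only form — the spiking neuron's own phase-weighted burst
        # sums update all its plastic synapses bidirectionally and
        # nonspecifically: strengthened for inhibitory-phase firing,
        # weakened for excitatory-phase firing.
        nd = 0
        for k in range(n_sp):
            s = spiked[k]
            if use_window:
                ex_p = trace_p[s] - eps_ltp
                ex_d = trace_d[s] - eps_ltd
                if ex_p > 0.0 or ex_d > 0.0:
                    for i in range(n):
                        if plastic[i, s]:
                            d_src[nd] = i
                            d_dst[nd] = s
                            d_val[nd] = (gamma_p * (1.0 - rho[i, s])
                                         * max(0.0, ex_p)
                                         - gamma_d * rho[i, s]
                                         * max(0.0, ex_d))
                            nd += 1
                        if plastic[s, i]:
                            d_src[nd] = s
                            d_dst[nd] = i
                            d_val[nd] = (gamma_p * (1.0 - rho[s, i])
                                         * max(0.0, ex_p)
                                         - gamma_d * rho[s, i]
                                         * max(0.0, ex_d))
                            nd += 1
                continue
            for i in range(n):
                if plastic[i, s]:
                    ex = trace_p[i] - eps_ltp
                    if ex > 0.0:
                        d_src[nd] = i
                        d_dst[nd] = s
                        d_val[nd] = gamma_p * (1.0 - rho[i, s]) * ex
                        nd += 1
            for j in range(n):
                if plastic[s, j]:
                    ex = trace_d[j] - eps_ltd
                    if ex > 0.0:
                        d_src[nd] = s
                        d_dst[nd] = j
                        d_val[nd] = ltd_sign * gamma_d * rho[s, j] * ex
                        nd += 1
        for k in range(nd):
            r = rho[d_src[k], d_dst[k]] + d_val[k]
            if r < 0.0:
                r = 0.0
            elif r > 1.0:
                r = 1.0
            rho[d_src[k], d_dst[k]] = r
        # trace increments for this step's spikes (visible from t+1 on)
        lw = ltp_w[t]
        dw = ltd_w[t]
        for k in range(n_sp):
            s = spiked[k]
            pinc = a_plus * lw
            dinc = a_minus * dw
            trace_p[s] += pinc
            trace_d[s] += dinc
            if use_window:
                wslot = t % window_steps
                win_p[wslot, s] += pinc
                win_d[wslot, s] += dinc
        # schedule EPSP deliveries after the synaptic delay
        dslot = (t + delay_steps) % buf_len
        for k in range(n_sp):
            ring_spk[dslot, ring_cnt[dslot]] = spiked[k]
            ring_cnt[dslot] += 1
        # record requested efficacies; track plastic-efficacy bounds
        for p in range(n_rec):
            rho_rec[t, p] = rho[rec_src[p], rec_dst[p]]
        for i in range(n):
            for j in range(n):
                if plastic[i, j]:
                    r = rho[i, j]
                    if r < rho_min:
                        rho_min = r
                    if r > rho_max:
                        rho_max = r
    return 0, -1, 0.0, n_spk, min_isi, rho_min, rho_max


@dataclass
class TrialResult:
    """Everything one simulated trial produced."""

    arch: Architecture
    synapses: SynapseMatrix          # final state (rho mutated in place)
    spike_times_ms: np.ndarray       # (n_spikes,)
    spike_neurons: np.ndarray        # (n_spikes,)
    rec_src: np.ndarray              # recorded pair sources
    rec_dst: np.ndarray
    rho_trajectory: np.ndarray       # (n_steps, n_recorded)
    dt_ms: float
    onset_ms: float                  # stimulus onset within the trial
    min_isi_ms: float                # smallest per-neuron inter-spike interval
    rho_bounds: Tuple[float, float]  # (min, max) plastic efficacy seen

    @property
    def n_steps(self) -> int:
        return self.rho_trajectory.shape[0]

    def mean_rho_series(self, pre: str, post: str) -> np.ndarray:
        """Mean efficacy over recorded plastic pairs from hippocampal
        subgroup ``pre`` to subgroup ``post`` ('visual'/'auditory'),
        one value per timestep.  Zero (with a warning) if the draw
        produced no such pair."""
        pre_idx = self.arch.subgroup("hip", pre)
        post_idx = self.arch.subgroup("hip", post)
        sel = (np.isin(self.rec_src, pre_idx) & np.isin(self.rec_dst, post_idx))
        if not np.any(sel):
            import warnings
            warnings.warn(f"no plastic {pre}->{post} pair in this network draw;"
                          " mean efficacy reported as 0")
            return np.zeros(self.n_steps)
        return self.rho_trajectory[:, sel].mean(axis=1)

    def spikes_dataframe(self, trial: int = 0):
        import pandas as pd
        labels = self.arch.labels()
        return pd.DataFrame({
            "trial": trial,
            "time_ms": self.spike_times_ms,
            "region": [labels[i][0] for i in self.spike_neurons],
            "subgroup": [labels[i][1] for i in self.spike_neurons],
            "neuron_id": self.spike_neurons,
        })


def run_trial_arrays(config: ModelConfig, arch: Architecture,
                     synapses: SynapseMatrix,
                     i_dc: np.ndarray, i_ac: np.ndarray, i_bg: np.ndarray,
                     gate_series: np.ndarray,
                     ltp_w: np.ndarray, ltd_w: np.ndarray,
                     v0: np.ndarray, onset_ms: float,
                     forced: Optional[np.ndarray] = None,
                     rec_pairs: Optional[np.ndarray] = None) -> TrialResult:
    """Run the compiled step loop on fully assembled input arrays.

    ``i_dc``, ``i_ac``, ``i_bg``: (n_steps, n) currents (``i_bg`` holds
    the background event pulses, W_max per counted event); ``gate_series``:
    per-step entorhinal gain for NC->hip deliveries; ``ltp_w``/``ltd_w``:
    per-step phase weights entering the trace increments; ``forced``:
    optional (n_steps, n) boolean spike schedule.  ``rec_pairs`` defaults
    to every plastic pair.  Raises on a non-finite membrane potential and
    asserts the efficacy-bounds invariant on exit.
    """
    n_steps, n = i_dc.shape
    p = config.plasticity
    nrn = config.neuron
    dt = config.sim.dt_ms
    if rec_pairs is None:
        rec_pairs = np.argwhere(synapses.plastic)
    rec_src = np.ascontiguousarray(rec_pairs[:, 0], dtype=np.int64)
    rec_dst = np.ascontiguousarray(rec_pairs[:, 1], dtype=np.int64)
    rho_rec = np.zeros((n_steps, rec_src.size))
    cap = n_steps * n // 2 + n
    spike_t = np.empty(cap, np.int64)
    spike_n = np.empty(cap, np.int64)
    use_window = p.variant == "theta_only"
    window_steps = max(1, round(p.trace_window_ms / dt))
    ltd_sign = 1.0 if p.variant == "theta_only" else -1.0
    v = v0.astype(np.float64).copy()
    refr_until = np.full(n, -1.0e18)
    last_spike = np.zeros(n)
    if forced is None:
        forced = np.zeros((n_steps, n), dtype=bool)
    # alpha kernel lookup, truncated where < 0.5 % of peak
    ages = np.arange(int(np.ceil(10.0 * nrn.tau_s / dt)) + 1) * dt
    kern_table = _E * (ages / nrn.tau_s) * np.exp(-ages / nrn.tau_s)

    status, bad, bad_t, n_spk, min_isi, rho_min, rho_max = _step_loop(
        n_steps, float(dt), n, arch.hip_mask,
        v, refr_until, last_spike,
        nrn.e_l, nrn.v_th, nrn.g_m,
        np.where(arch.hip_mask, nrn.c_m, nrn.c_m_nc).astype(np.float64),
        nrn.refractory_ms,
        int(round(nrn.delay_ms / dt)),
        synapses.exists, synapses.w_max, synapses.rho, synapses.plastic,
        gated_pairs(arch),
        kern_table,
        nrn.a_adp, nrn.tau_adp,
        np.where(arch.hip_mask, nrn.ahp_amp, nrn.ahp_amp_nc).astype(np.float64),
        float(np.exp(-dt / nrn.ahp_tau)),
        np.ascontiguousarray(i_dc), np.ascontiguousarray(i_ac),
        np.ascontiguousarray(i_bg), np.ascontiguousarray(forced),
        np.ascontiguousarray(gate_series),
        np.ascontiguousarray(ltp_w), np.ascontiguousarray(ltd_w),
        p.a_plus, p.a_minus, p.gamma_p, p.gamma_d, ltd_sign,
        p.eps_ltp, p.eps_ltd,
        float(np.exp(-dt / p.tau_s)), use_window, window_steps,
        rec_src, rec_dst, rho_rec,
        spike_t, spike_n)

    if status != 0:
        raise FloatingPointError(
            f"non-finite membrane potential for neuron {bad} at t={bad_t} ms")
    if n_spk > cap:
        raise RuntimeError(f"spike buffer overflow ({n_spk} > {cap})")
    if not (0.0 <= rho_min and rho_max <= 1.0) and n_spk > 0:
        raise AssertionError("plastic efficacy escaped [0, 1] during the trial")
    synapses.check()
    return TrialResult(
        arch=arch, synapses=synapses,
        spike_times_ms=spike_t[:n_spk] * dt,
        spike_neurons=spike_n[:n_spk],
        rec_src=rec_src, rec_dst=rec_dst,
        rho_trajectory=rho_rec, dt_ms=dt, onset_ms=onset_ms,
        min_isi_ms=(min_isi if min_isi < 1.0e17 else np.inf),
        rho_bounds=(rho_min, rho_max))
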