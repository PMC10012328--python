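"""Experimental protocols: entrainment trials and theta-phase bursts.

Two paradigms are generated here.

* The multisensory entrainment memory paradigm: after a 2 s interstimulus
  interval, cosine-modulated direct currents drive the NC visual and
  auditory subgroups for 3 s (1.5 s unmodulated in the no-flicker
  control), with the auditory stream phase-shifted by the condition's
  offset.  Hippocampal theta is reset at stimulus onset 180 deg from the
  visual modulation, aligning every visual peak with the LTP-permissive
  theta trough.  Stimulus amplitude follows the frequency-scaling rules
  (exponential below beta, logarithmic above).

* The theta-phase burst replication: a single burst of 1-4 suprathreshold
  current pulses at 100 Hz into one hippocampal subgroup, centred on the
  theta trough (LTP) or peak (LTD), with synaptic change reported as the
  percentage difference from a pre-burst baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .engine import TrialResult, run_trial_arrays
from .kernels import ec_gate, poisson_background, theta_normalized
from .network import Architecture, build_network
from .params import (EXPONENTIAL_BANDS, FREQUENCIES, BurstProtocolSpec,
                     ModelConfig, NoiseSpec, StimulusSpec)
from .seeding import derive_trial_seed, spawn_streams

__all__ = [
    "input_strength_for_frequency", "make_modulated_input",
    "make_no_flicker_input", "run_trial", "run_burst_protocol",
    "run_condition", "ConditionResult", "BurstResult", "frequency_for",
]


def frequency_for(band: str) -> Optional[float]:
    """Modulation frequency (Hz) for a named band; None for 'none'."""
    if band == "none":
        return None
    try:
        return FREQUENCIES[band]
    except KeyError:
        raise ValueError(f"unknown frequency band '{band}'") from None


def input_strength_for_frequency(f: float, rule: Optional[str] = None) -> float:
    """Stimulus amplitude as a function of modulation frequency.

    ``exponential_low``: 1.75 * exp((f/20)^3) — used for the delta, theta
    and alpha bands.  ``logarithmic_high``: 2.2 * log10(f) — used for beta
    and gamma.  With ``rule=None`` the band is inferred from ``f`` (the
    exponential rule up to and including alpha, logarithmic above).
    """
    if f <= 0:
        raise ValueError("input_strength_for_frequency: f must be > 0")
    if rule is None:
        cutoff = max(FREQUENCIES[b] for b in EXPONENTIAL_BANDS)
        rule = "exponential_low" if f <= cutoff else "logarithmic_high"
    if rule == "exponential_low":
        return 1.75 * math.exp((f / 20.0) ** 3)
    if rule == "logarithmic_high":
        return 2.2 * math.log10(f)
    raise ValueError(f"unknown scaling rule '{rule}'")


def make_modulated_input(spec: StimulusSpec, noise: NoiseSpec,
                         rng: np.random.Generator, dt_ms: float = 1.0
                         ) -> Tuple[np.ndarray, np.ndarray, Dict[str, float]]:
    """Visual and auditory drive time-series for one trial.

    Unipolar modulation: ``A (1 - cos(2 pi f (t - onset) + phi)) / 2`` —
    zero at onset (trough), range [0, A].  Bipolar maps the same cosine
    onto [-A, A].  The auditory phase lags the visual one by the
    condition's offset; per-trial noise perturbs frequencies and phases.
    Returns (visual, auditory) series over the whole trial (zero during
    the interstimulus interval and after stimulus end) plus the drawn
    trial parameters.
    """
    spec.validate()
    if spec.modulation_hz is None:
        raise ValueError("make_modulated_input: use make_no_flicker_input "
                         "for the unmodulated condition")
    n_steps = int(round((spec.isi_ms + spec.duration_ms) / dt_ms))
    onset = int(round(spec.isi_ms / dt_ms))
    amp = (spec.amplitude if spec.amplitude is not None
           else input_strength_for_frequency(spec.modulation_hz))
    f_vis = f_aud = spec.modulation_hz
    if noise.input_freq_sd_frac > 0:
        sd = noise.input_freq_sd_frac * spec.modulation_hz
        f_vis = float(rng.normal(spec.modulation_hz, sd))
        f_aud = float(rng.normal(spec.modulation_hz, sd))
    phi_vis = 0.0
    phi_aud = -math.radians(spec.phase_offset_deg)
    if noise.input_phase_sd_deg > 0:
        jit = math.radians(noise.input_phase_sd_deg)
        phi_vis = float(rng.normal(0.0, jit))
        phi_aud = -float(rng.normal(math.radians(spec.phase_offset_deg), jit))
    t_rel = (np.arange(n_steps) - onset) * dt_ms / 1000.0
    active = t_rel >= 0.0

    def series(f, phi):
        c = np.cos(2.0 * np.pi * f * t_rel + phi)
        s = amp * (-c if spec.bipolar else 0.5 * (1.0 - c))
        return np.where(active, s, 0.0)

    meta = {"amplitude": amp, "f_visual": f_vis, "f_auditory": f_aud,
            "phi_visual": phi_vis, "phi_auditory": phi_aud,
            "onset_step": onset}
    return series(f_vis, phi_vis), series(f_aud, phi_aud), meta


def make_no_flicker_input(amplitude: float = 1.75, duration_ms: float = 1500.0,
                          isi_ms: float = 2000.0, dt_ms: float = 1.0,
                          total_ms: Optional[float] = None
                          ) -> Tuple[np.ndarray, np.ndarray, Dict[str, float]]:
    """Constant (unmodulated) drive to both subgroups for ``duration_ms``
    (half the flicker duration), zero during the interstimulus interval
    and after stimulus end."""
    total = total_ms if total_ms is not None else isi_ms + duration_ms
    n_steps = int(round(total / dt_ms))
    onset = int(round(isi_ms / dt_ms))
    end = onset + int(round(duration_ms / dt_ms))
    s = np.zeros(n_steps)
    s[onset:end] = amplitude
    meta = {"amplitude": amplitude, "onset_step": onset}
    return s, s.copy(), meta


def _hip_phase_series(n_steps: int, dt_ms: float, f_hip: float,
                      phi0: float, reset: bool, onset: int,
                      phi_vis: float) -> np.ndarray:
    """Hippocampal theta phase per step: free-running before onset; if
    reset, re-pinned at onset 180 deg from the visual modulation (phase
    equal to the visual drive's phase offset, so theta = 0 at each visual
    peak when the frequencies match)."""
    t_ms = np.arange(n_steps) * dt_ms
    w = 2.0 * np.pi * f_hip / 1000.0
    phase = phi0 + w * t_ms
    if reset:
        post = np.arange(n_steps) >= onset
        phase = np.where(post, phi_vis + w * (t_ms - onset * dt_ms), phase)
    return phase


@dataclass
class TrialInputs:
    """Fully assembled per-trial arrays (for inspection and replay)."""

    i_dc: np.ndarray
    i_ac: np.ndarray
    i_bg: np.ndarray
    gate_series: np.ndarray
    ltp_w: np.ndarray
    ltd_w: np.ndarray
    v0: np.ndarray
    theta_hip: np.ndarray
    meta: Dict[str, float] = field(default_factory=dict)


def _phase_weights(theta: np.ndarray, variant: str
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-step theta weighting of the LTP/LTD trace increments."""
    if variant == "stdp_only":
        ones = np.ones_like(theta)
        return ones, ones.copy()
    if variant == "theta_only":
        th2 = 2.0 * theta - 1.0
        return 1.0 - th2, th2
    return 1.0 - theta, theta.copy()


def assemble_trial(config: ModelConfig, arch: Architecture,
                   stimulus: StimulusSpec, streams: Dict[str, np.random.Generator],
                   total_ms: Optional[float] = None) -> TrialInputs:
    """Build all input arrays for one entrainment trial."""
    dt = config.sim.dt_ms
    conn = config.connectivity
    noise = config.noise
    variant = config.plasticity.variant
    n = arch.n

    if stimulus.modulation_hz is None:
        vis, aud, meta = make_no_flicker_input(
            amplitude=stimulus.amplitude if stimulus.amplitude is not None else 1.75,
            duration_ms=stimulus.duration_ms, isi_ms=stimulus.isi_ms, dt_ms=dt,
            total_ms=total_ms)
    else:
        vis, aud, meta = make_modulated_input(stimulus, noise,
                                              streams["noise"], dt_ms=dt)
        if total_ms is not None:
            want = int(round(total_ms / dt))
            vis = np.pad(vis, (0, max(0, want - vis.size)))[:want]
            aud = np.pad(aud, (0, max(0, want - aud.size)))[:want]
    n_steps = vis.size
    onset = int(meta["onset_step"])

    i_dc = np.zeros((n_steps, n))
    i_dc[:, arch.nc_visual] = vis[:, None]
    i_dc[:, arch.nc_auditory] = aud[:, None]

    # oscillators: free-running NC alpha; hippocampal theta with reset
    phases = streams["phases"]
    phi_nc = float(phases.uniform(0.0, 2.0 * np.pi))
    phi_hip0 = float(phases.uniform(0.0, 2.0 * np.pi))
    f_hip = conn.hip_theta_hz
    if noise.hip_freq_sd > 0:
        f_hip = float(streams["noise"].normal(conn.hip_theta_hz,
                                              noise.hip_freq_sd))
    reset = stimulus.theta_reset and variant != "stdp_only"
    phase_hip = _hip_phase_series(n_steps, dt, f_hip, phi_hip0, reset, onset,
                                  float(meta.get("phi_visual", 0.0)))
    theta_hip = theta_normalized(phase_hip)

    t_ms = np.arange(n_steps) * dt
    i_ac = np.zeros((n_steps, n))
    i_ac[:, arch.nc] = (conn.nc_alpha_amp
                        * np.cos(phi_nc + 2.0 * np.pi * conn.nc_alpha_hz
                                 * t_ms / 1000.0))[:, None]
    hip_amp = 0.0 if variant == "stdp_only" else conn.hip_theta_amp
    i_ac[:, arch.hip] = (hip_amp * np.cos(phase_hip))[:, None]

    # entorhinal gate at delivery time; offset noise shifts the phase at
    # which the gate reads theta (nominal 180 deg = exact phase reversal)
    if variant == "stdp_only":
        gate = np.ones(n_steps)
    else:
        shift = 0.0
        if noise.ec_offset_sd_deg > 0:
            delta = float(streams["noise"].normal(180.0, noise.ec_offset_sd_deg))
            shift = math.radians(delta - 180.0)
        theta_gate = theta_normalized(phase_hip - shift)
        gate = np.asarray(ec_gate(theta_gate, conn.w_ec))

    ltp_w, ltd_w = _phase_weights(np.asarray(theta_hip), variant)

    # background shot noise: W_max current pulse per counted event
    i_bg = np.zeros((n_steps, n))
    bg = streams["background"]
    i_bg[:, arch.nc] = conn.nc_bg_wmax * poisson_background(
        conn.nc_bg_rate, dt, n_steps, arch.nc.size, bg)
    i_bg[:, arch.hip] = conn.hip_bg_wmax * poisson_background(
        conn.hip_bg_rate, dt, n_steps, arch.hip.size, bg)

    v0 = streams["init"].uniform(config.neuron.e_l, config.neuron.v_th, n)
    meta.update({"f_hip": f_hip, "phi_nc": phi_nc, "phi_hip0": phi_hip0})
    return TrialInputs(i_dc=i_dc, i_ac=i_ac, i_bg=i_bg, gate_series=gate,
                       ltp_w=ltp_w, ltd_w=ltd_w, v0=v0,
                       theta_hip=np.asarray(theta_hip), meta=meta)


def run_trial(config: ModelConfig, stimulus: StimulusSpec,
              seed_or_streams, total_ms: Optional[float] = None
              ) -> TrialResult:
    """Simulate one entrainment trial: a fresh network draw, fresh
    background spike trains and random initial oscillator phases, then the
    interstimulus interval followed by the stimulus at dt resolution.

    ``seed_or_streams`` is either a SeedSequence/int (expanded into the
    per-consumer streams) or an already-spawned stream dict.
    """
    config.validate()
    streams = (seed_or_streams if isinstance(seed_or_streams, dict)
               else spawn_streams(seed_or_streams))
    arch, synapses = build_network(config.connectivity,
                                   streams["connectivity"])
    inputs = assemble_trial(config, arch, stimulus, streams, total_ms)
    onset_ms = float(inputs.meta["onset_step"]) * config.sim.dt_ms
    return run_trial_arrays(config, arch, synapses,
                            inputs.i_dc, inputs.i_ac, inputs.i_bg,
                            inputs.gate_series, inputs.ltp_w, inputs.ltd_w,
                            inputs.v0, onset_ms)


@dataclass
class ConditionResult:
    """Across-trial summary of one condition cell."""

    label: str
    per_trial_mean_rho: np.ndarray    # read-out window mean, aud->vis
    per_trial_mean_rho_v2a: np.ndarray
    per_trial_baseline_rho: np.ndarray
    min_isi_ms: float
    rho_bounds: Tuple[float, float]

    @property
    def mean(self) -> float:
        return float(self.per_trial_mean_rho.mean())

    @property
    def sem(self) -> float:
        x = self.per_trial_mean_rho
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def run_condition(config: ModelConfig, stimulus: StimulusSpec,
                  n_trials: int, master_seed: int, label: str,
                  window_ms: Tuple[float, float] = (2750.0, 3000.0),
                  baseline_ms: Tuple[float, float] = (-1750.0, 0.0),
                  ) -> ConditionResult:
    """Run ``n_trials`` independent trials of one condition and collect
    read-out-window mean efficacies (auditory->visual and the reverse)
    plus prestimulus baselines and invariant diagnostics."""
    from .analysis import mean_weight_window
    means, means_v2a, bases = [], [], []
    min_isi = np.inf
    lo, hi = 1.0, 0.0
    # run every condition to the same horizon so the read-out window is
    # covered even when the stimulus itself is shorter (no-flicker)
    total_ms = stimulus.isi_ms + max(stimulus.duration_ms, window_ms[1])
    for k in range(n_trials):
        res = run_trial(config, stimulus, derive_trial_seed(master_seed, label, k),
                        total_ms=total_ms)
        means.append(mean_weight_window(res, window_ms, "auditory", "visual"))
        means_v2a.append(mean_weight_window(res, window_ms, "visual", "auditory"))
        bases.append(mean_weight_window(res, baseline_ms, "auditory", "visual"))
        min_isi = min(min_isi, res.min_isi_ms)
        lo = min(lo, res.rho_bounds[0])
        hi = max(hi, res.rho_bounds[1])
    return ConditionResult(label, np.asarray(means), np.asarray(means_v2a),
                           np.asarray(bases), min_isi, (lo, hi))


# ---------------------------------------------------------------------------
# theta-phase burst protocol
# ---------------------------------------------------------------------------

@dataclass
class BurstResult:
    """Per-trial percentage synaptic change for one burst condition."""

    spec: BurstProtocolSpec
    percent_change: np.ndarray
    min_isi_ms: float
    rho_bounds: Tuple[float, float]

    @property
    def mean(self) -> float:
        return float(self.percent_change.mean())


def _burst_trial(config: ModelConfig, spec: BurstProtocolSpec,
                 streams: Dict[str, np.random.Generator]) -> float:
    """One burst trial; returns the % change of mean plastic efficacy on
    synapses touching the stimulated subgroup, post vs baseline."""
    from .analysis import percent_baseline_change
    dt = config.sim.dt_ms
    conn = config.connectivity
    arch, synapses = build_network(conn, streams["connectivity"])
    # mid-range initial efficacies: both LTP and LTD expressible
    synapses.rho[synapses.plastic] = spec.initial_rho

    phases = streams["phases"]
    phi0 = float(phases.uniform(0.0, 2.0 * np.pi))
    w = 2.0 * np.pi * conn.hip_theta_hz / 1000.0
    # first theta extreme (trough: phase pi; peak: phase 0) after t_min,
    # chosen so a full baseline window precedes the burst
    target = np.pi if spec.target_phase == "trough" else 0.0
    t_min = spec.baseline_window_ms + 600.0
    k = math.ceil((w * t_min + phi0 - target) / (2.0 * np.pi))
    t_center = (target - phi0 + 2.0 * np.pi * k) / w

    # suprathreshold pulse train: each pulse (amplitude 3, ~6 ms) drives
    # one spike per stimulated neuron; spike latencies scatter by a few
    # ms across neurons (initial conditions, background), which is what
    # makes pre/post pairings within the burst non-simultaneous
    n_pulses = spec.n_spikes_per_burst
    period = spec.inter_pulse_ms
    first_spike = t_center - (n_pulses - 1) * period / 2.0
    spike_times = [first_spike + i * period for i in range(n_pulses)]
    pulse_starts = [st - spec.pulse_width_ms for st in spike_times]
    last_spike_est = spike_times[-1] + 4.0
    post_start = last_spike_est + spec.post_gap_ms
    total_ms = post_start + spec.post_window_ms + 50.0
    n_steps = int(round(total_ms / dt))

    n = arch.n
    stim_idx = arch.subgroup("hip", spec.stimulated_subgroup)
    i_dc = np.zeros((n_steps, n))
    for ps in pulse_starts:
        a = int(round(ps / dt))
        b = int(round((ps + spec.pulse_width_ms) / dt))
        i_dc[a:b, stim_idx] = spec.pulse_amplitude

    t_ms = np.arange(n_steps) * dt
    phase_hip = phi0 + w * t_ms
    theta_hip = np.asarray(theta_normalized(phase_hip))
    i_ac = np.zeros((n_steps, n))
    phi_nc = float(phases.uniform(0.0, 2.0 * np.pi))
    i_ac[:, arch.nc] = (conn.nc_alpha_amp
                        * np.cos(phi_nc + 2.0 * np.pi * conn.nc_alpha_hz
                                 * t_ms / 1000.0))[:, None]
    i_ac[:, arch.hip] = (conn.hip_theta_amp * np.cos(phase_hip))[:, None]
    gate = np.asarray(ec_gate(theta_hip, conn.w_ec))
    ltp_w, ltd_w = _phase_weights(theta_hip, config.plasticity.variant)

    i_bg = np.zeros((n_steps, n))
    bg = streams["background"]
    i_bg[:, arch.nc] = conn.nc_bg_wmax * poisson_background(
        conn.nc_bg_rate, dt, n_steps, arch.nc.size, bg)
    i_bg[:, arch.hip] = conn.hip_bg_wmax * poisson_background(
        conn.hip_bg_rate, dt, n_steps, arch.hip.size, bg)
    v0 = streams["init"].uniform(config.neuron.e_l, config.neuron.v_th, n)

    res = run_trial_arrays(config, arch, synapses, i_dc, i_ac, i_bg,
                           gate, ltp_w, ltd_w, v0, onset_ms=pulse_starts[0])
    touched = (np.isin(res.rec_src, stim_idx) | np.isin(res.rec_dst, stim_idx))
    traj = res.rho_trajectory[:, touched].mean(axis=1)
    b0 = int(round((pulse_starts[0] - spec.baseline_window_ms) / dt))
    b1 = int(round(pulse_starts[0] / dt))
    p0 = int(round(post_start / dt))
    p1 = int(round((post_start + spec.post_window_ms) / dt))
    return (percent_baseline_change(traj[b0:b1].mean(), traj[p0:p1].mean()),
            res.min_isi_ms, res.rho_bounds)


def run_burst_protocol(config: ModelConfig, spec: BurstProtocolSpec,
                       master_seed: int) -> BurstResult:
    """Run the burst condition for ``spec.n_trials`` independent trials."""
    config.validate()
    spec.validate()
    label = f"burst_{spec.n_spikes_per_burst}_{spec.target_phase}"
    changes = []
    min_isi = np.inf
    lo, hi = 1.0, 0.0
    for k in range(spec.n_trials):
        streams = spawn_streams(derive_trial_seed(master_seed, label, k))
        pc, isi, (rlo, rhi) = _burst_trial(config, spec, streams)
        changes.append(pc)
        min_isi = min(min_isi, isi)
        lo, hi = min(lo, rlo), max(hi, rhi)
    return BurstResult(spec, np.asarray(changes), min_isi, (lo, hi))
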