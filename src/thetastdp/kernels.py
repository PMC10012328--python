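"""Single-timestep neuron and current primitives.

Closed-form pieces of the model: the leaky integrate-and-fire membrane
update, the alpha-function EPSP kernel, the afterdepolarization ramp, the
cosine oscillators with their normalized theta value, Poisson background
events, and the entorhinal gate applied to neocortex->hippocampus
transmission.  These are the reference (vectorized numpy) forms; the trial
engine fuses the same arithmetic into a compiled step loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .params import NeuronParams

__all__ = [
    "NeuronState", "CurrentBundle", "OscillatorState",
    "theta_normalized", "epsp_kernel", "adp_current", "ec_gate",
    "poisson_background", "lif_step", "lif_fixed_point",
]


def theta_normalized(phase: np.ndarray | float) -> np.ndarray | float:
    """Normalized oscillation value theta = (1 + cos(phase)) / 2 in [0, 1].

    theta = 1 at the depolarizing (excitatory, LTD-permissive) extreme of
    the cosine and 0 at the hyperpolarizing (inhibitory, LTP-permissive)
    extreme; the AC current itself is amplitude * cos(phase).
    """
    return 0.5 * (1.0 + np.cos(phase))


def epsp_kernel(delta_t, rho, w_max, tau_s: float = 20.0):
    """Alpha-function EPSP current at ``delta_t`` ms after event delivery.

    ``W_max * rho * (e * dt / tau_s) * exp(-dt / tau_s)`` — zero at the
    origin, maximal (= ``W_max * rho``) at ``delta_t = tau_s``.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise ValueError("epsp_kernel: delta_t must be >= 0")
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("epsp_kernel: rho must lie in [0, 1]")
    out = w_max * rho * (np.e * delta_t / tau_s) * np.exp(-delta_t / tau_s)
    return out if out.ndim else float(out)


def adp_current(delta_t_since_spike, a_adp: float = 0.2,
                tau_adp: float = 250.0):
    """Afterdepolarization ramp ``A * (dt/tau) * exp(1 - dt/tau)``.

    Reset to zero by each spike (the caller tracks the last-spike time);
    peaks at exactly ``a_adp`` when ``delta_t = tau_adp``.
    """
    dt = np.asarray(delta_t_since_spike, dtype=float)
    if np.any(dt < 0):
        raise ValueError("adp_current: delta_t_since_spike must be >= 0")
    out = a_adp * (dt / tau_adp) * np.exp(1.0 - dt / tau_adp)
    return out if out.ndim else float(out)


def ec_gate(theta_hip, w_ec: float = 0.3):
    """Entorhinal gain on neocortex->hippocampus EPSP amplitudes.

    ``((1 - theta_hip) + (1 - W_EC)) / (1 + (1 - W_EC))`` — a strictly
    decreasing affine function of hippocampal theta, equal to 1 at the
    theta trough (maximal transmission) for any gate weight.  Models the
    entorhinal pathway whose theta is phase-reversed relative to the
    hippocampus.
    """
    th = np.asarray(theta_hip, dtype=float)
    if np.any(th < 0) or np.any(th > 1):
        raise ValueError("ec_gate: theta_hip must lie in [0, 1]")
    if not 0.0 <= w_ec <= 1.0:
        raise ValueError("ec_gate: w_ec must lie in [0, 1]")
    out = ((1.0 - th) + (1.0 - w_ec)) / (1.0 + (1.0 - w_ec))
    return out if out.ndim else float(out)


def poisson_background(rate_hz: float, dt_ms: float, n_steps: int,
                       n_neurons: int, rng: np.random.Generator) -> np.ndarray:
    """Background spike-event counts, Poisson with mean rate*dt per step.

    Returns an ``(n_steps, n_neurons)`` integer array.  Each counted event
    is delivered as a brief background current pulse of the background
    ``W_max`` (these events carry no presynaptic identity and take no part
    in plasticity).
    """
    if rate_hz < 0:
        raise ValueError("poisson_background: rate must be >= 0")
    if rng is None:
        raise ValueError("poisson_background: a seeded Generator is required")
    lam = rate_hz * dt_ms / 1000.0
    return rng.poisson(lam, size=(n_steps, n_neurons))


@dataclass
class OscillatorState:
    """A region-wide cosine oscillator; one phase variable serves both the
    AC current (amplitude * cos(phase)) and the normalized theta value."""

    frequency: float
    phase: float
    amplitude: float

    @property
    def theta(self) -> float:
        return float(theta_normalized(self.phase))

    @property
    def current(self) -> float:
        return self.amplitude * float(np.cos(self.phase))

    def advanced(self, dt_ms: float) -> "OscillatorState":
        phase = (self.phase + 2.0 * np.pi * self.frequency * dt_ms / 1000.0)
        return OscillatorState(self.frequency, phase % (2.0 * np.pi),
                               self.amplitude)


@dataclass
class CurrentBundle:
    """Per-neuron input currents; the membrane integrates their sum plus
    the leak term."""

    i_syn: np.ndarray
    i_ac: np.ndarray
    i_dc: np.ndarray
    i_adp: np.ndarray

    def total(self) -> np.ndarray:
        return self.i_syn + self.i_ac + self.i_dc + self.i_adp


@dataclass
class NeuronState:
    """Membrane potentials and per-neuron clocks.

    ``pending_events`` holds scheduled deliveries (deliver_time_ms, source,
    target); delivery times always equal creation time + synaptic delay.
    """

    v: np.ndarray
    refractory_until: np.ndarray
    last_spike: np.ndarray
    pending_events: List[Tuple[float, int, int]] = field(default_factory=list)

    @classmethod
    def at_rest(cls, n: int, params: NeuronParams) -> "NeuronState":
        return cls(v=np.full(n, params.e_l),
                   refractory_until=np.full(n, -np.inf),
                   last_spike=np.zeros(n))


def lif_step(state: NeuronState, params: NeuronParams,
             currents: CurrentBundle, t: float, dt: float
             ) -> Tuple[NeuronState, np.ndarray]:
    """One forward-Euler step of the integrate-and-fire membrane.

    Non-refractory neurons integrate ``dv = (dt/C_m) [g_m (E_L - v) + sum I]``;
    neurons crossing threshold are reported spiked, reset to rest and
    clamped for the refractory period.  Returns the mutated state and the
    index array of spiking neurons.
    """
    if dt <= 0:
        raise ValueError("lif_step: dt must be > 0")
    v = state.v
    free = t >= state.refractory_until
    total = params.g_m * (params.e_l - v) + currents.total()
    v[free] += (dt / params.c_m) * total[free]
    v[~free] = params.e_l
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise FloatingPointError(
            f"non-finite membrane potential for neuron {bad} at t={t} ms")
    spiked = np.flatnonzero(free & (v >= params.v_th))
    if spiked.size:
        v[spiked] = params.e_l
        state.refractory_until[spiked] = t + params.refractory_ms
        state.last_spike[spiked] = t
    return state, spiked


def lif_fixed_point(i_dc: float, params: NeuronParams | None = None) -> float:
    """Steady-state membrane potential ``E_L + I_DC / g_m`` under constant
    current with all other inputs silent (the closed-form Euler limit)."""
    p = params or NeuronParams()
    return p.e_l + i_dc / p.g_m
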