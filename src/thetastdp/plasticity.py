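"""Theta phase-gated spike timing-dependent plasticity.

Potential plasticity is accumulated in two exponential traces per neuron:
an LTP trace weighted by the *inverse* of theta at each historic spike
(so spikes at the inhibitory theta extreme, theta = 0, count fully) and an
LTD trace weighted by theta itself.  When a neuron spikes, each of its
plastic synapses changes only if the partner's trace exceeds a threshold
(nullifying singlet and doublet pairings), by an amount graded by the
excess and soft-bounded by the current efficacy:

    LTP:  d_rho_i = gamma_p * (1 - rho_i) * max(0, F_LTP(i) - eps_LTP)
    LTD:  d_rho_j = -gamma_d * rho_j      * max(0, F_LTD(j) - eps_LTD)

Two lesioned variants are supported.  ``theta_only`` removes the STDP
component: the exponential kernel is dropped (a finite history window
bounds the sums), theta is re-ranged to [-1, 1], and each spike updates
all of the spiking neuron's plastic synapses bidirectionally and
nonspecifically from its *own* phase-weighted spike sums — strengthened
for inhibitory-phase firing, weakened for excitatory-phase firing.
``stdp_only`` removes the theta component: both phase-weighting factors
become 1 and the entorhinal gate, theta drive and theta reset are
disabled by the protocol layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .params import PlasticityParams

__all__ = [
    "SynapseMatrix", "SpikeHistorySet", "TracePair",
    "potential_ltp", "potential_ltd",
    "apply_plasticity_at_spike", "record_spike",
]


@dataclass
class SynapseMatrix:
    """Directed synapses: existence, maximal weight, efficacy, plasticity mask.

    ``rho`` is the plastic efficacy in [0, 1]; it changes only where
    ``plastic`` is set, and non-existing pairs contribute nothing.
    """

    exists: np.ndarray   # (n, n) bool
    w_max: np.ndarray    # (n, n) float
    rho: np.ndarray      # (n, n) float in [0, 1]
    plastic: np.ndarray  # (n, n) bool

    def __post_init__(self) -> None:
        self.check()

    @property
    def n(self) -> int:
        return self.exists.shape[0]

    def check(self) -> None:
        if np.any(self.rho < 0) or np.any(self.rho > 1):
            raise AssertionError("synaptic efficacy rho escaped [0, 1]")
        if np.any(self.plastic & ~self.exists):
            raise AssertionError("plasticity enabled on a non-existing pair")
        if np.any(np.diag(self.exists)):
            raise AssertionError("self-connection present")

    def copy(self) -> "SynapseMatrix":
        return SynapseMatrix(self.exists.copy(), self.w_max.copy(),
                             self.rho.copy(), self.plastic.copy())


def _summands(entries: Sequence[Tuple[float, float]], t: float,
              params: PlasticityParams, ltp: bool) -> float:
    """Sum one potential-plasticity trace over a spike history.

    ``entries`` are (spike_time_ms, theta_at_spike) pairs, all < t.
    """
    if any(ts >= t for ts, _ in entries):
        raise ValueError("potential plasticity: history times must be < t")
    a = params.a_plus if ltp else params.a_minus
    total = 0.0
    if params.variant == "theta_only":
        # no exponential kernel; bounded by the finite history window
        for ts, th in entries:
            if t - ts > params.trace_window_ms:
                continue
            th2 = 2.0 * th - 1.0
            total += a * ((1.0 - th2) if ltp else th2)
        return total
    for ts, th in entries:
        if params.variant == "stdp_only":
            w = 1.0
        else:
            w = (1.0 - th) if ltp else th
        total += a * w * np.exp((ts - t) / params.tau_s)
    return total


def potential_ltp(t: float, presyn_history: Sequence[Tuple[float, float]],
                  params: PlasticityParams) -> float:
    """Potential LTP trace at a spike event at time ``t``.

    Sum over the presynaptic partner's historic spikes of
    ``A+ * [1 - theta(t_i)] * exp((t_i - t) / tau_s)``.
    """
    return _summands(presyn_history, t, params, ltp=True)


def potential_ltd(t: float, postsyn_history: Sequence[Tuple[float, float]],
                  params: PlasticityParams) -> float:
    """Potential LTD trace: ``sum A- * theta(t_j) * exp((t_j - t)/tau_s)``."""
    return _summands(postsyn_history, t, params, ltp=False)


@dataclass
class SpikeHistorySet:
    """Per-neuron ordered spike histories with the theta value cached at
    each spike time; entries older than the trace window may be pruned."""

    trace_window_ms: float = 200.0
    _hist: Dict[int, List[Tuple[float, float]]] = field(default_factory=dict)

    def entries(self, neuron: int) -> List[Tuple[float, float]]:
        return self._hist.get(neuron, [])

    def record(self, neuron: int, t: float, theta_now: float) -> None:
        if not 0.0 <= theta_now <= 1.0:
            raise ValueError("theta at spike time must lie in [0, 1]")
        h = self._hist.setdefault(neuron, [])
        if h and t < h[-1][0]:
            raise ValueError(
                f"spike time regression for neuron {neuron}: {t} < {h[-1][0]}")
        h.append((t, theta_now))
        cutoff = t - self.trace_window_ms
        while h and h[0][0] < cutoff:
            h.pop(0)


def record_spike(neuron: int, t: float, theta_now: float,
                 histories: SpikeHistorySet) -> SpikeHistorySet:
    """Append a (time, theta) entry and prune entries older than the
    trace window; mutates and returns ``histories``."""
    histories.record(neuron, t, theta_now)
    return histories


def apply_plasticity_at_spike(spiking_neuron: int, t: float,
                              synapses: SynapseMatrix,
                              histories: SpikeHistorySet,
                              params: PlasticityParams) -> SynapseMatrix:
    """Weight updates triggered by one spike event, applied in a single
    use at the millisecond of spike occurrence.

    Full and stdp_only variants (the STDP form): incoming plastic synapses
    (i -> spiker) potentiate by the thresholded LTP excess of i's history;
    outgoing plastic synapses (spiker -> j) depress by the thresholded LTD
    excess of j's history.  The theta_only variant (the phase-only form):
    the spiking neuron's *own* kernel-free windowed phase sums update all
    its plastic synapses bidirectionally and nonspecifically — potentiated
    by the inhibitory-phase sum, depressed by the excitatory-phase sum.
    All deltas are computed from the pre-update efficacies, then clipped
    into [0, 1].
    """
    out = synapses.copy()
    n = spiking_neuron
    deltas: List[Tuple[int, int, float]] = []
    if params.variant == "theta_only":
        own = histories.entries(n)
        ex_p = max(0.0, potential_ltp(t, own, params) - params.eps_ltp)
        ex_d = max(0.0, potential_ltd(t, own, params) - params.eps_ltd)
        if ex_p > 0.0 or ex_d > 0.0:
            for i in range(out.n):
                for pre, post in ((i, n), (n, i)):
                    if out.plastic[pre, post]:
                        r = out.rho[pre, post]
                        deltas.append((pre, post,
                                       params.gamma_p * (1.0 - r) * ex_p
                                       - params.gamma_d * r * ex_d))
    else:
        for i in range(out.n):
            if out.plastic[i, n]:
                excess = (potential_ltp(t, histories.entries(i), params)
                          - params.eps_ltp)
                if excess > 0.0:
                    deltas.append((i, n, params.gamma_p
                                   * (1.0 - out.rho[i, n]) * excess))
        for j in range(out.n):
            if out.plastic[n, j]:
                excess = (potential_ltd(t, histories.entries(j), params)
                          - params.eps_ltd)
                if excess > 0.0:
                    deltas.append((n, j, -params.gamma_d
                                   * out.rho[n, j] * excess))
    for i, j, d in deltas:
        out.rho[i, j] = float(np.clip(out.rho[i, j] + d, 0.0, 1.0))
    out.check()
    return out


class TracePair:
    """Incremental per-neuron potential-plasticity traces.

    Maintains the same running sums the compiled engine uses: decay every
    step by ``exp(-dt/tau_s)`` (or expire entries beyond the window in the
    kernel-free ``theta_only`` mode), then add ``A * weight(theta)`` at each
    spike.  Equivalent, at spike-resolution, to re-summing the full history
    through :func:`potential_ltp` / :func:`potential_ltd`.
    """

    def __init__(self, params: PlasticityParams, dt_ms: float = 1.0):
        self.p = params
        self.dt = dt_ms
        self.ltp = 0.0
        self.ltd = 0.0
        self._decay = np.exp(-dt_ms / params.tau_s)
        self._window: List[Tuple[float, float, float]] = []  # (t, pinc, dinc)
        self._t = 0.0

    def advance(self, t: float) -> None:
        """Move the traces forward to time ``t`` (>= current time)."""
        if t < self._t:
            raise ValueError("traces cannot run backwards")
        if self.p.variant == "theta_only":
            cutoff = t - self.p.trace_window_ms
            while self._window and self._window[0][0] < cutoff:
                _, pinc, dinc = self._window.pop(0)
                self.ltp -= pinc
                self.ltd -= dinc
        else:
            steps = round((t - self._t) / self.dt)
            f = self._decay ** steps
            self.ltp *= f
            self.ltd *= f
        self._t = t

    def on_spike(self, t: float, theta: float) -> None:
        """Record this neuron's spike at ``t`` (after any updates using the
        pre-spike trace values have been taken)."""
        self.advance(t)
        if self.p.variant == "theta_only":
            th2 = 2.0 * theta - 1.0
            pinc = self.p.a_plus * (1.0 - th2)
            dinc = self.p.a_minus * th2
            self._window.append((t, pinc, dinc))
        elif self.p.variant == "stdp_only":
            pinc = self.p.a_plus
            dinc = self.p.a_minus
        else:
            pinc = self.p.a_plus * (1.0 - theta)
            dinc = self.p.a_minus * theta
        self.ltp += pinc
        self.ltd += dinc
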