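"""Parameter containers for the theta-gated STDP network model.

Every default below is the model's published operating point: a two-region
leaky integrate-and-fire network (neocortex -> hippocampus) in which
hippocampal synapses obey spike timing-dependent plasticity whose LTP and
LTD components are gated by opposing phases of a 4 Hz theta oscillation.
Current amplitudes are expressed in a single dimensionless model-current
unit; voltages in mV; times in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

#: Canonical stimulus modulation frequencies (Hz) for the entrainment paradigm.
FREQUENCIES = {
    "delta": 1.652,
    "theta": 4.0,
    "alpha": 10.472,
    "beta": 18.335,
    "lowgamma": 41.236,
    "highgamma": 71.771,
}

#: Frequencies whose stimulus strength follows the exponential rule; the
#: remaining (beta and gamma) bands use the logarithmic rule.
EXPONENTIAL_BANDS = ("delta", "theta", "alpha")

VARIANTS = ("full", "theta_only", "stdp_only")


class ConfigError(ValueError):
    """A configuration value violates a model constraint."""


def _require(cond: bool, key: str, constraint: str) -> None:
    if not cond:
        raise ConfigError(f"config key '{key}' violates constraint: {constraint}")


@dataclass
class NeuronParams:
    """Membrane, refractory, EPSP-kernel and afterdepolarization constants.

    The membrane follows ``C_m dV/dt = g_m (E_L - V) + I`` with a hard
    threshold, reset to rest and an absolute refractory clamp.  ``C_m`` is
    not separately constrained by the published parameter set (only
    current-to-capacitance ratios are), so it is the free parameter that
    sets each region's firing regime.  Neocortical neurons are slow
    integrators (``c_m_nc = 8``): they accumulate drive over tens of
    milliseconds and fire one short volley per modulation cycle near the
    stimulus peak, giving sharp phase-locking.  Hippocampal neurons are
    fast (``c_m = 1``, the burst-capable regime of pyramidal cells): a
    convergent afferent volley drives a brief >= 100 Hz burst — the spike
    multiplicity the plasticity thresholds require — and a 3-unit current
    pulse depolarizes the 15 mV gap within ~6 ms, as the burst-
    stimulation replication assumes.
    """

    e_l: float = -70.0          # resting potential, mV
    v_th: float = -55.0         # spike threshold, mV
    g_m: float = 0.03           # leak conductance, model units
    c_m: float = 1.0            # hippocampal capacitance, model units
    c_m_nc: float = 8.0         # neocortical capacitance, model units
    refractory_ms: float = 2.0
    delay_ms: float = 2.0       # synaptic delivery delay for every spike event
    tau_s: float = 20.0         # EPSP alpha-kernel time constant, ms
    a_adp: float = 0.2          # afterdepolarization peak current
    tau_adp: float = 250.0      # afterdepolarization ramp time constant, ms
    ahp_amp: float = 0.6        # hippocampal after-hyperpolarization per spike
    ahp_amp_nc: float = 0.2     # neocortical adaptation increment per spike
    ahp_tau: float = 80.0       # AHP decay time constant, ms

    def validate(self) -> "NeuronParams":
        _require(self.v_th > self.e_l, "neuron.v_th", "V_th > E_L")
        for key in ("refractory_ms", "delay_ms", "tau_s", "tau_adp",
                    "ahp_tau"):
            _require(getattr(self, key) > 0, f"neuron.{key}", "> 0")
        _require(self.c_m > 0, "neuron.c_m", "> 0")
        _require(self.c_m_nc > 0, "neuron.c_m_nc", "> 0")
        _require(self.g_m > 0, "neuron.g_m", "> 0")
        _require(self.ahp_amp >= 0, "neuron.ahp_amp", ">= 0")
        _require(self.ahp_amp_nc >= 0, "neuron.ahp_amp_nc", ">= 0")
        return self


@dataclass
class PlasticityParams:
    """Constants of the phase-gated STDP rule and its lesioned variants.

    ``a_plus``/``a_minus`` weight each historic spike's contribution to the
    potential-LTP/LTD traces; ``gamma_p``/``gamma_d`` are the potentiation
    and depression rates (potentiation runs at twice the depression rate);
    ``eps_ltp``/``eps_ltd`` are the burst thresholds that nullify singlet
    and doublet spike pairings.
    """

    a_plus: float = 0.65
    a_minus: float = 0.65
    tau_s: float = 20.0
    gamma_p: float = 1.5
    gamma_d: float = 0.75
    eps_ltp: float = 1.0
    eps_ltd: float = 1.0
    variant: str = "full"
    trace_window_ms: float = 200.0
    heterosynaptic_enabled: bool = False

    def validate(self) -> "PlasticityParams":
        _require(self.variant in VARIANTS, "plasticity.variant",
                 f"one of {VARIANTS}")
        _require(self.tau_s > 0, "plasticity.tau_s", "> 0")
        _require(self.trace_window_ms > 0, "plasticity.trace_window_ms", "> 0")
        for key in ("a_plus", "a_minus", "gamma_p", "gamma_d"):
            _require(getattr(self, key) >= 0, f"plasticity.{key}", ">= 0")
        if self.heterosynaptic_enabled:
            raise ConfigError(
                "config key 'plasticity.heterosynaptic_enabled': heterosynaptic "
                "LTD is not part of the supported model surface")
        return self


@dataclass
class ConnectivitySpec:
    """Architecture-level wiring probabilities, weights and drive.

    Neocortex (NC): two subgroups of 10 (visual, auditory); sparse fixed
    recurrence inside each subgroup, none across.  Hippocampus: two
    subgroups of 5; all-to-all candidate wiring drawn at 50 %, plastic.
    NC->hippocampus and hippocampus->NC projections are full within
    modality and fixed.
    """

    nc_intra_p: float = 0.25
    nc_intra_wmax: float = 0.3
    nc_to_hip_wmax: float = 0.35
    hip_to_nc_wmax: float = 0.08
    hip_p: float = 0.5
    hip_wmax: float = 0.65
    nc_bg_rate: float = 4000.0   # Poisson background, spikes/s per NC neuron
    nc_bg_wmax: float = 0.023
    hip_bg_rate: float = 1500.0  # spikes/s per hippocampal neuron
    hip_bg_wmax: float = 0.015
    nc_alpha_hz: float = 10.0
    nc_alpha_amp: float = 0.1
    hip_theta_hz: float = 4.0
    hip_theta_amp: float = 0.25
    w_ec: float = 0.3            # entorhinal gate weight

    def validate(self) -> "ConnectivitySpec":
        for key in ("nc_intra_p", "hip_p"):
            _require(0.0 <= getattr(self, key) <= 1.0,
                     f"connectivity.{key}", "probability in [0, 1]")
        for key in ("nc_intra_wmax", "nc_to_hip_wmax", "hip_to_nc_wmax",
                    "hip_wmax", "nc_bg_wmax", "hip_bg_wmax"):
            _require(getattr(self, key) >= 0, f"connectivity.{key}", ">= 0")
        _require(self.nc_bg_rate >= 0, "connectivity.nc_bg_rate", ">= 0")
        _require(self.hip_bg_rate >= 0, "connectivity.hip_bg_rate", ">= 0")
        _require(0.0 <= self.w_ec <= 1.0, "connectivity.w_ec", "in [0, 1]")
        return self


@dataclass
class NoiseSpec:
    """Per-trial noise draws, each independently enabled by a nonzero SD.

    All draws come from normal distributions centred on the nominal values:
    stimulus-modulation frequency (SD as a fraction of the frequency),
    hippocampal theta frequency (SD in Hz), entorhinal phase offset
    relative to theta (SD in degrees, nominal 180) and stimulus phases
    (SD in degrees around the nominal offsets).
    """

    input_freq_sd_frac: float = 0.0
    hip_freq_sd: float = 0.0
    ec_offset_sd_deg: float = 0.0
    input_phase_sd_deg: float = 0.0

    def validate(self) -> "NoiseSpec":
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f"noise.{f.name}", ">= 0")
        return self

    @classmethod
    def preset(cls, name: str) -> "NoiseSpec":
        """Named noise models: none, input_freq, hip_dynamics, input_phase."""
        presets = {
            "none": cls(),
            "input_freq": cls(input_freq_sd_frac=0.015),
            "hip_dynamics": cls(hip_freq_sd=0.02, ec_offset_sd_deg=0.167),
            "input_phase": cls(input_phase_sd_deg=5.0),
        }
        try:
            return presets[name]
        except KeyError:
            raise ConfigError(f"unknown noise preset '{name}'; "
                              f"one of {sorted(presets)}") from None


@dataclass
class StimulusSpec:
    """One trial of the multisensory entrainment paradigm.

    Two cosine-modulated direct currents drive the NC visual and auditory
    subgroups; the auditory stream is phase-shifted by ``phase_offset_deg``.
    ``modulation_hz = None`` selects the unmodulated ("no-flicker") control,
    which runs at half duration.  ``bipolar`` maps the modulation from the
    unipolar [0, A] range onto [-A, A] (used by the stdp_only variant).
    """

    modulation_hz: Optional[float] = 4.0
    phase_offset_deg: float = 0.0
    amplitude: Optional[float] = None   # None -> frequency-scaling rule
    bipolar: bool = False
    duration_ms: float = 3000.0
    isi_ms: float = 2000.0
    theta_reset: bool = True

    def validate(self) -> "StimulusSpec":
        if self.modulation_hz is not None:
            _require(self.modulation_hz > 0, "stimulus.modulation_hz", "> 0")
        _require(self.duration_ms > 0, "stimulus.duration_ms", "> 0")
        _require(self.isi_ms >= 0, "stimulus.isi_ms", ">= 0")
        return self

    @classmethod
    def no_flicker(cls, amplitude: float = 1.75, *,
                   theta_reset: bool = True, isi_ms: float = 2000.0
                   ) -> "StimulusSpec":
        """Constant-input control at half the flicker duration (1.5 s)."""
        return cls(modulation_hz=None, amplitude=amplitude,
                   duration_ms=1500.0, isi_ms=isi_ms, theta_reset=theta_reset)


@dataclass
class BurstProtocolSpec:
    """Theta-phase burst stimulation of one hippocampal subgroup.

    A single burst of 1-4 suprathreshold current pulses at 100 Hz
    (amplitude 3) is injected into every neuron of one hippocampal
    subgroup, centred either on the theta trough (the LTP-permissive
    phase, theta = 0) or the peak (LTD-permissive, theta = 1).  Each pulse
    is ``pulse_width_ms`` long, sized so one pulse elicits exactly one
    spike per 10-ms pulse cycle at the 3-unit amplitude.  Plastic synapses start at ``initial_rho`` so both potentiation
    and depression are expressible against the baseline.
    """

    n_spikes_per_burst: int = 4
    intra_burst_hz: float = 100.0
    pulse_amplitude: float = 3.0
    pulse_width_ms: float = 9.0
    target_phase: str = "trough"
    n_trials: int = 25
    baseline_window_ms: float = 500.0
    post_gap_ms: float = 250.0
    post_window_ms: float = 500.0
    initial_rho: float = 0.5
    stimulated_subgroup: str = "visual"

    def validate(self) -> "BurstProtocolSpec":
        _require(1 <= self.n_spikes_per_burst <= 4,
                 "burst.n_spikes_per_burst", "in 1..4")
        _require(self.target_phase in ("peak", "trough"),
                 "burst.target_phase", "peak or trough")
        _require(self.intra_burst_hz > 0, "burst.intra_burst_hz", "> 0")
        _require(0.0 <= self.initial_rho <= 1.0, "burst.initial_rho", "in [0, 1]")
        return self

    @property
    def inter_pulse_ms(self) -> float:
        return 1000.0 / self.intra_burst_hz


@dataclass
class SimParams:
    """Discretization and seeding."""

    dt_ms: float = 1.0
    seed: int = 0

    def validate(self) -> "SimParams":
        _require(self.dt_ms > 0, "sim.dt_ms", "> 0")
        _require(0 <= int(self.seed) < 2**31, "sim.seed", "in [0, 2^31)")
        return self


@dataclass
class ModelConfig:
    """The fully resolved model configuration (all sections)."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    connectivity: ConnectivitySpec = field(default_factory=ConnectivitySpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    sim: SimParams = field(default_factory=SimParams)

    def validate(self) -> "ModelConfig":
        for f in fields(self):
            getattr(self, f.name).validate()
        return self

    def with_variant(self, variant: str) -> "ModelConfig":
        return replace(self, plasticity=replace(self.plasticity, variant=variant))
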