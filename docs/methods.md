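# Methods

## Model overview

`thetastdp` simulates a two-region spiking network: a neocortex (NC) of
20 leaky integrate-and-fire neurons in two modality subgroups (visual,
auditory) and a hippocampus of 10 neurons in two matching subgroups.
Within each NC subgroup, directed pairs connect sparsely (p = 0.25,
fixed W_max = 0.3); there are no synapses across NC subgroups.  Each NC
subgroup projects fully onto its hippocampal counterpart
(W_max = 0.35) and back (W_max = 0.08).  Hippocampal directed pairs are
drawn independently at p = 0.5 (W_max = 0.65) and are the only plastic
synapses: intra-subgroup efficacies start at 1, inter-subgroup at 0, and
the growth of the inter-subgroup efficacies is the memory read-out.
Connection draws are independent per directed pair, so bidirectional
pairs arise at p².

Oscillatory drive: one 10 Hz cosine (amplitude 0.1) to all NC neurons
and one 4 Hz theta cosine (amplitude 0.25) to all hippocampal neurons,
each with a random initial phase per trial.  The normalized theta
θ = (1 + cos φ)/2 shares the AC phase variable: θ = 1 at the
depolarizing (excitatory, LTD-permissive) extreme, θ = 0 at the
hyperpolarizing (inhibitory, LTP-permissive) extreme.  The entorhinal
pathway is modelled as a multiplicative gate on NC→hippocampus EPSP
amplitudes, `((1−θ)+(1−W_EC))/(1+(1−W_EC))` with W_EC = 0.3, evaluated
at event delivery time: phase-reversed relative to hippocampal theta,
it passes most input at the theta trough.

Background activity: each neuron receives an independent Poisson event
train (NC 4000 events/s with weight 0.023; hippocampus 1500 events/s
with weight 0.015), delivered as single-timestep current pulses.  These
events carry no presynaptic identity and take no part in plasticity.
(Summing a full 20-ms synaptic kernel per event at these rates would
put the mean background drive an order of magnitude above rheobase,
saturating every neuron; the pulse form keeps the printed rates and
weights while acting as the intended jitter source.)

## Synaptic events

Every spike is delivered to all existing postsynaptic targets after a
2 ms delay.  Each directed synapse carries one alpha-function EPSP
current, `W_max ρ (e Δt/τ_s) e^(−Δt/τ_s)` with τ_s = 20 ms, whose clock
Δt = t − t_fire restarts at each delivery; the amplitude (efficacy ρ,
and the entorhinal gate for NC→hippocampus pairs) is read at delivery
time.  The retriggered-kernel form bounds each synapse's instantaneous
contribution by W_max·ρ, which matters because the architecture has no
inhibitory population: letting historic events accumulate without bound
makes the excitatory recurrence divergent at these weights.  Kernels
are evaluated from a lookup table and truncated beyond 10 τ_s, where
the contribution is below 0.5 % of peak.

## Neuron physiology and excitability regimes

The membrane follows `C_m dV/dt = g_m(E_L − V) + ΣI` with E_L = −70 mV,
V_th = −55 mV, g_m = 0.03, an absolute 2 ms refractory clamp to rest,
and forward-Euler integration at dt = 1 ms (dt is a config field, so
finer steps can be checked).  Only current-to-capacitance ratios are
constrained by the published parameter set, so capacitance is the free
parameter that fixes each region's firing regime, chosen once:

* **Neocortex, C_m = 8** (slow integrator, τ_m ≈ 270 ms): the membrane
  effectively integrates the unipolar cosine drive, so threshold
  crossings cluster at the stimulus peak — one narrow volley per
  modulation cycle.  With faster membranes NC fires throughout the ~60 %
  of the cycle where the drive exceeds rheobase, and the late stragglers
  arrive at the hippocampus through the wide-open trough gate, erasing
  the phase-offset conditions.
* **Hippocampus, C_m = 1** (fast, burst-capable): a convergent afferent
  volley (10 NC kernels) drives a brief burst at ≥100 Hz — the spike
  multiplicity the plasticity thresholds demand — and a 3-unit current
  pulse crosses the 15 mV threshold gap within one 10 ms pulse cycle,
  as the burst-stimulation protocol requires.

Hippocampal neurons receive the afterdepolarization ramp
`A_ADP (Δt/τ_ADP) e^(1−Δt/τ_ADP)` (A_ADP = 0.2, τ_ADP = 250 ms), reset
by each spike: together with the theta AC it biases them toward one
spike per theta cycle near the excitatory phase when otherwise unstimulated.

**After-hyperpolarization.** Each spike also increments an adaptation
current (hippocampus 0.6, NC 0.2 per spike; exponential decay,
τ = 80 ms).  This is this package's own completion of the model: with
intra-subgroup hippocampal synapses at full efficacy, the recurrent
drive alone (~0.6–1.0 units) exceeds rheobase (0.45) at every theta
phase, so a single ignition would otherwise keep the hippocampus firing
continuously and no phase-offset condition could differ.  The AHP is the
minimal standard episode terminator; its constants were set once so that
hippocampal firing is confined to afferent volleys (bursts of ~3–5
spikes) and recovers within one theta cycle.  All burst-threshold
plasticity behaviour is then carried by the published trace rules.

## Plasticity

At each spike of neuron n at time t, incoming plastic synapses i→n
potentiate by `γ_p (1−ρ) max(0, F_LTP(i) − ε_LTP)` and outgoing plastic
synapses n→j depress by `γ_d ρ max(0, F_LTD(j) − ε_LTD)`, where the
traces sum the partner's spike history with exponential decay (τ_s =
20 ms) weighted by [1−θ] (LTP) or θ (LTD) at each historic spike
(A₊ = A₋ = 0.65; γ_p = 1.5; γ_d = 0.75; ε = 1).  Updates happen once,
at the millisecond of the spike; the (1−ρ)/ρ factors soft-bound ρ to
[0, 1] and the result is clipped (the engine asserts the bounds every
step).  Simultaneous (same-millisecond) spikes are excluded from each
other's traces and all deltas at one step are computed from pre-update
efficacies, so the batch update is order-stable.  The engine maintains
the traces incrementally (decay each step, increment at spikes), which
is exactly equivalent to re-summing the full history; the test suite
verifies this to 1e−9 against a brute-force oracle and replays forced
spike trains through the pure-Python reference implementation to 1e−12.

With ε = 1 and A = 0.65, one historic spike contributes at most 0.65
and a 100 Hz doublet at most 0.65(e^{−1/20}+e^{−11/20}) ≈ 0.99, so
singlet and doublet pairings never change weights; 3–4 spike bursts
cross the threshold with an excess that grows with spike count.

### Lesioned variants

* **theta_only** (no STDP): the exponential kernel is dropped; θ is
  re-ranged to θ′ = 2θ−1 ∈ [−1, 1]; spike sums run over a finite 200 ms
  window (without the kernel they would otherwise grow without bound).
  Each spike updates *all* of the spiking neuron's plastic synapses
  bidirectionally and nonspecifically from its own windowed sums:
  potentiated by `γ_p (1−ρ) max(0, ΣA₊(1−θ′) − ε)` and depressed by
  `γ_d ρ max(0, ΣA₋θ′ − ε)` — strengthened when the neuron fires in the
  inhibitory phase, weakened in the excitatory phase.  A partner-history
  form was evaluated first and rejected: it inherits STDP's
  directionality (which this variant is defined to remove) and produces
  a spurious lead/lag asymmetry between the ±90° conditions.  The
  default thresholds are retained.
* **stdp_only** (no theta): both phase-weighting factors are 1, the
  entorhinal gate is fixed at 1, the hippocampal theta current is
  removed, and theta does not reset at stimulus onset.  Learning then
  depends on spike timing alone.  Its standard protocol here drives the
  network with the same unipolar cosine as the full model: under the
  slow cortical integrator this input already produces narrow spiking
  windows per cycle, so the offset conditions dissociate (0°≈90° >
  180°≈270°) without re-ranging the drive.  A bipolar option
  (`StimulusSpec(bipolar=True)`, range −A..A) is available, but a
  zero-mean 4 Hz drive is low-pass filtered by the slow NC membrane to
  under the threshold gap and elicits no spikes in this physiology.

## Protocols

**Entrainment paradigm.**  After a 2 s interstimulus interval, the
visual and auditory NC subgroups receive cosine-modulated direct
currents, `A(1 − cos 2πf(t−t_on))/2`, for 3 s; the auditory stream lags
the visual one by the condition's phase offset (offset/360 × period).
The visual drive starts at its trough, avoiding an onset discontinuity.
Amplitude follows the frequency-scaling rules (exponential
1.75·exp((f/20)³) for delta 1.652 Hz, theta 4 Hz and alpha 10.472 Hz;
logarithmic 2.2·log₁₀ f for beta 18.335 Hz and the gammas 41.236 and
71.771 Hz).  At onset, hippocampal theta is reset 180° from the visual
modulation, so θ = 0 (LTP-permissive) at every visual peak; the reset
also applies in the unmodulated control (it is a property of stimulus
onset), and never in stdp_only.  The no-flicker control injects a
constant 1.75 for 1.5 s (half duration, equating total stimulus
exposure).  The read-out is the mean auditory→visual plastic efficacy
over 2.75–3 s after onset (one theta cycle); a per-trial
recalled/forgotten call thresholds that value at the 10th percentile of
the distribution pooled across the theta, delta, alpha and no-flicker
conditions (linear-interpolation percentile by default; nearest-rank
selectable).

**Noise models.**  Per-trial draws from normal distributions: stimulus
modulation frequency (SD 0.015·f, drawn independently per stream),
hippocampal theta frequency (SD 0.02 Hz), entorhinal phase offset
relative to theta (nominal 180°, SD 0.167° as printed — exposed as
config since the magnitude is conspicuously small), and stimulus phases
(SD 5° around the nominal offsets).  Each consumer owns an independent
RNG stream, so enabling one noise source never perturbs the others'
draws.

**Burst replication.**  A single burst of 1–4 current pulses (amplitude
3, 9 ms wide, 10 ms spacing) is injected into every neuron of one
hippocampal subgroup, with the spike train centred on the theta trough
or peak.  The 9 ms width makes each pulse elicit exactly one spike per
pulse cycle given the 6–9 ms crossing latencies (AC- and AHP-dependent);
per-neuron latency scatter from initial conditions and connectivity
provides the non-simultaneous pre/post pairings plasticity needs.
Plastic efficacies start at 0.5 so both potentiation and depression are
expressible (the depression condition conceptually follows prior
potentiation).  The outcome per trial is the percentage change of the
mean efficacy over all plastic synapses touching stimulated neurons,
post window (500 ms starting 250 ms after the last spike) versus
baseline (500 ms before the first pulse).

**Reproducibility.**  A master seed expands to per-trial seeds via
`SeedSequence(entropy=master, spawn_key=(crc32(condition_id), trial))`;
any trial can be re-run in isolation and reproduces its in-grid result
bit for bit.  Runs write RFC-4180 CSVs (spikes; weight trajectories;
per-trial summaries) and a manifest JSON carrying the resolved config,
seed scheme and file checksums.

## Model comparison statistics

Each model's four condition means are fit to a 4-row behavioural
accuracy table by ordinary least squares (accuracy = a·sim + b); the
fitted a, b absorb affine rescalings of the simulated weights.  A
variant is compared with the full model through
`F = (RSS_variant − RSS_full)/(RSS_full/3)` with df (1, 3) — reported as
the conventional summary even though the two fits are not strictly
nested — and `BIC = n ln(RSS/n) + k ln n` with n = 4 and k = 2.
Accuracies can be centred by subtracting the 4-condition mean to compare
across studies.

## Synthetic data and problem sizes

All inputs are generated: no external data are required, and the
behavioural accuracy table consumed by the comparison statistics is
user-supplied (the bundled example is synthetic).  The generator's
defaults are the study conditions described above; trial counts are the
one scaled-down quantity.  The acceptance tests run 32 trials per
condition for the entrainment grids and 25 for the burst protocol
(the full study design uses 384 and the extended grid 48); at these
sizes the no-noise effects are strongly separated (Welch p < 1e−10 for
the headline contrasts), so the reduction costs statistical resolution
only for near-tied conditions.  What passing these tests shows is that
the implemented mechanisms produce the qualitative experimental
patterns under the model's idealized inputs — perfectly periodic
stimuli, exact theta reset, homogeneous neurons; they do not show that
the model fits any particular behavioural dataset, nor calibrate its
effect sizes against real recordings, where entrainment variability,
theta discontinuity and population heterogeneity would all shrink the
condition differences (adding the provided noise models moves in that
direction).

## Numerical choices and degenerate inputs

Fixed-step Euler at dt = 1 ms (all delays and refractory periods are
whole milliseconds; plasticity applies at the millisecond of the
spike).  Kernel lookup truncation at 10 τ_s (< 0.5 % of peak).  Ties:
simultaneous spikes are processed in ascending neuron index with
batch-applied deltas, making the result order-independent.  A network
draw with no plastic pair in a requested direction reports a mean
efficacy of 0 with a warning.  A percentile pool smaller than 10 trials,
a read-out window outside the recorded trajectory, non-finite membrane
potentials, and efficacies escaping [0, 1] are hard errors.  The
degenerate all-equal percentile pool recalls nothing (strict >).

## Known limitations

* No inhibitory interneurons, conductance-based synapses or
  multi-compartment structure; the AHP stands in for every
  burst-terminating process.
* The entorhinal cortex is a gate function, not a population.
* Heterosynaptic LTD is out of scope (`heterosynaptic_enabled` exists
  but only rejects activation).
* Capacitances and AHP constants are identified from qualitative firing
  regimes, not fit to recordings; other (C_m, AHP) pairs producing
  peak-locked NC volleys and confined hippocampal bursts would serve
  equally.
* With 5-neuron subgroups, single connectivity draws are coarse; means
  over ≥25 trials are the intended unit of analysis.
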