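"""Lesioned model variants: why both mechanisms are needed.

theta_only removes spike-timing dependence: each spike strengthens or
weakens all of the neuron's plastic synapses according to the theta phase
it fired at.  stdp_only removes every theta element (phase weighting,
entorhinal gate, theta drive and reset): weight changes depend on spike
timing alone.  Neither variant reproduces the full model's pattern, where
0 deg stands clearly above three mutually similar out-of-phase conditions.
"""

from thetastdp import ModelConfig, StimulusSpec, run_condition

config = ModelConfig()
for variant in ("full", "theta_only", "stdp_only"):
    vconf = config.with_variant(variant)
    means = []
    for offset in (0, 90, 180, 270):
        stim = StimulusSpec(modulation_hz=4.0, phase_offset_deg=offset)
        cond = run_condition(vconf, stim, n_trials=6, master_seed=2,
                             label=f"demo_{variant}_{offset}")
        means.append(cond.mean)
    row = " ".join(f"{off}°:{m:.3f}" for off, m in
                   zip((0, 90, 180, 270), means))
    print(f"{variant:>10}: {row}")
print("\ntheta_only grades conditions by overlap with the LTP phase"
      "\n(90/270 sit between 0 and 180); stdp_only rewards any tight"
      "\nspike-timing overlap (0 and 90 both high) - only the full model"
      "\nseparates 0 deg from all three out-of-phase conditions.")
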