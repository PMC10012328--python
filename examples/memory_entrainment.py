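"""The multisensory theta-entrainment associative-memory paradigm.

Visual and auditory direct currents, cosine-modulated at 4 Hz, drive the
two neocortical subgroups with a phase offset between the streams.
Hippocampal theta is reset at stimulus onset so every visual peak lands
on the LTP-permissive phase.  The memory read-out is the mean plastic
efficacy from the hippocampal auditory to the visual subgroup over the
last theta cycle of the 3 s stimulus (recall was cued with the sound).
"""

from thetastdp import ModelConfig, StimulusSpec, run_condition

config = ModelConfig()
print(f"{'offset':>7} {'aud->vis rho':>13} {'SEM':>7}")
for offset in (0, 90, 180, 270):
    stim = StimulusSpec(modulation_hz=4.0, phase_offset_deg=offset)
    cond = run_condition(config, stim, n_trials=8, master_seed=1,
                         label=f"demo_theta_{offset}")
    print(f"{offset:>6}° {cond.mean:>13.3f} {cond.sem:>7.3f}")

nf = run_condition(config, StimulusSpec.no_flicker(), n_trials=8,
                   master_seed=1, label="demo_noflicker")
print(f"{'none':>7} {nf.mean:>13.3f} {nf.sem:>7.3f}   (unmodulated control)")
print("\nOnly the in-phase (0 deg) condition places both inputs on the"
      "\nLTP-permissive theta phase, so only there do the inter-subgroup"
      "\nweights grow substantially; the constant input learns a little"
      "\n(the entorhinal gate still favours the trough), out-of-phase"
      "\nstimulation learns essentially nothing.")
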