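"""Theta-phase burst stimulation of hippocampal synapses.

A single burst of 1-4 suprathreshold current pulses at 100 Hz is injected
into one hippocampal subgroup, centred on the theta trough (the
LTP-permissive phase) or the peak (LTD-permissive).  Synaptic change is
the percentage difference of mean plastic efficacy between a 500 ms
post-burst window and a 500 ms pre-burst baseline, averaged over trials.
Bursting acts as a gateway: single spikes and doublets leave the weights
untouched, while 3-4 spike bursts potentiate at the trough and depress at
the peak, increasingly with spike count.
"""

from thetastdp import BurstProtocolSpec, ModelConfig, run_burst_protocol

config = ModelConfig()
print(f"{'phase':>7} {'spikes':>6} {'mean change':>12}")
for phase in ("trough", "peak"):
    for k in (1, 2, 3, 4):
        spec = BurstProtocolSpec(n_spikes_per_burst=k, target_phase=phase,
                                 n_trials=10)
        result = run_burst_protocol(config, spec, master_seed=7)
        print(f"{phase:>7} {k:>6} {result.mean:>+11.2f}%")
print("\nPositive values at the trough and negative values at the peak for"
      "\n3-4 spike bursts reproduce phase-gated LTP/LTD; ~0 for 1-2 spikes"
      "\nshows the burst threshold nullifying singlet/doublet pairings.")
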