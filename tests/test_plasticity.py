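"""Phase-gated STDP: traces, thresholded updates, variants, oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetastdp.params import PlasticityParams
from thetastdp.plasticity import (SpikeHistorySet, SynapseMatrix, TracePair,
                                  apply_plasticity_at_spike, potential_ltd,
                                  potential_ltp, record_spike)


def two_neuron_synapses(rho0=0.0):
    exists = np.array([[False, True], [True, False]])
    return SynapseMatrix(exists=exists, w_max=np.where(exists, 0.65, 0.0),
                         rho=np.where(exists, rho0, 0.0),
                         plastic=exists.copy())


class TestPotentialTraces:
    def test_single_spike_at_optimal_phase_stays_subthreshold(self, plast):
        # one presynaptic spike can never trigger plasticity (A+ < eps)
        val = potential_ltp(0.0, [(-0.0 - 1e-9, 0.0)], plast)
        assert val == pytest.approx(0.65, abs=1e-9)
        assert val < plast.eps_ltp

    def test_ltp_nullified_at_excitatory_phase(self, plast):
        hist = [(t, 1.0) for t in (-30.0, -20.0, -10.0)]
        assert potential_ltp(0.0, hist, plast) == 0.0

    def test_ltd_nullified_at_inhibitory_phase(self, plast):
        hist = [(t, 0.0) for t in (-30.0, -20.0, -10.0)]
        assert potential_ltd(0.0, hist, plast) == 0.0

    def test_two_spike_ltp_sum(self, plast):
        # spikes at delta-t 0 and 10 ms, theta = 0 throughout
        hist = [(-10.0, 0.0), (-1e-12, 0.0)]
        expected = 0.65 * (1.0 + np.exp(-0.5))
        assert potential_ltp(0.0, hist, plast) == pytest.approx(expected,
                                                                rel=1e-9)
        assert expected > plast.eps_ltp

    def test_three_spike_ltd_sum(self, plast):
        hist = [(-20.0, 1.0), (-10.0, 1.0), (-1e-12, 1.0)]
        expected = 0.65 * (1.0 + np.exp(-0.5) + np.exp(-1.0))
        assert potential_ltd(0.0, hist, plast) == pytest.approx(expected,
                                                                rel=1e-9)

    def test_single_ltd_spike_subthreshold(self, plast):
        assert potential_ltd(0.0, [(-1e-12, 1.0)], plast) < plast.eps_ltd

    def test_future_history_rejected(self, plast):
        with pytest.raises(ValueError):
            potential_ltp(0.0, [(1.0, 0.5)], plast)

    @given(st.lists(st.tuples(st.floats(-100.0, -0.001),
                              st.floats(0.0, 1.0)), max_size=12))
    @settings(deadline=None, max_examples=100)
    def test_phase_antisymmetry(self, hist):
        """Exchanging theta <-> 1-theta maps the LTP trace into LTD."""
        p = PlasticityParams()
        flipped = [(t, 1.0 - th) for t, th in hist]
        assert potential_ltp(0.0, hist, p) == pytest.approx(
            potential_ltd(0.0, flipped, p), rel=1e-12, abs=1e-12)


class TestApplyPlasticity:
    def test_excess_exactly_zero_changes_nothing(self):
        # a trace exactly at threshold yields zero update
        p = PlasticityParams(a_plus=1.0, a_minus=1.0)
        syn = two_neuron_synapses(rho0=0.5)
        hist = SpikeHistorySet()
        hist.record(0, 100.0, 0.0)      # F_LTP = 1.0 = eps at dt=0+
        out = apply_plasticity_at_spike(1, 100.0 + 1e-9, syn, hist, p)
        assert np.allclose(out.rho, syn.rho)

    def test_graded_ltp_update(self):
        # F_LTP = 1.5 on a rho=0 synapse: d_rho = 1.5 * 1 * 0.5 = 0.75
        p = PlasticityParams(a_plus=1.5)
        syn = two_neuron_synapses(rho0=0.0)
        hist = SpikeHistorySet()
        hist.record(0, 100.0, 0.0)
        out = apply_plasticity_at_spike(1, 100.0 + 1e-9, syn, hist, p)
        assert out.rho[0, 1] == pytest.approx(0.75, rel=1e-9)

    def test_graded_ltd_update(self):
        # F_LTD = 1.5 on a rho=1 synapse: d_rho = -0.75 * 1 * 0.5 = -0.375
        p = PlasticityParams(a_minus=1.5)
        syn = two_neuron_synapses(rho0=1.0)
        hist = SpikeHistorySet()
        hist.record(1, 100.0, 1.0)      # postsynaptic partner of 0->1
        out = apply_plasticity_at_spike(0, 100.0 + 1e-9, syn, hist, p)
        assert out.rho[0, 1] == pytest.approx(1.0 - 0.375, rel=1e-9)

    @pytest.mark.parametrize("k, prev_k_change", [(1, None), (2, None),
                                                  (3, None), (4, 3)])
    def test_burst_grading(self, plast, k, prev_k_change):
        """100 Hz presynaptic bursts at the inhibitory phase: no change for
        1-2 spikes, strictly increasing potentiation from 3 spikes up."""
        def drho(n_spikes):
            syn = two_neuron_synapses(rho0=0.0)
            hist = SpikeHistorySet()
            for i in range(n_spikes):
                hist.record(0, 1000.0 + 10.0 * i, 0.0)
            t = 1000.0 + 10.0 * (n_spikes - 1) + 1.0
            out = apply_plasticity_at_spike(1, t, syn, hist, plast)
            return out.rho[0, 1]

        change = drho(k)
        if k <= 2:
            assert change == 0.0
        else:
            assert change > 0.0
            if prev_k_change:
                assert change > drho(prev_k_change)

    @given(st.lists(st.tuples(st.integers(0, 500), st.floats(0.0, 1.0)),
                    min_size=1, max_size=40),
           st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=60)
    def test_rho_stays_bounded_for_arbitrary_trains(self, events, rho0):
        p = PlasticityParams()
        syn = two_neuron_synapses(rho0=rho0)
        hist = SpikeHistorySet()
        t_sorted = sorted(set(t for t, _ in events))
        thetas = dict(events)
        for t in t_sorted:
            spiker = int(t) % 2
            syn = apply_plasticity_at_spike(spiker, float(t) + 0.5, syn,
                                            hist, p)
            hist.record(spiker, float(t) + 0.5, thetas[t])
            assert np.all((syn.rho >= 0.0) & (syn.rho <= 1.0))

    def test_theta_only_updates_are_bidirectional_and_phase_signed(self):
        p = PlasticityParams(variant="theta_only")
        hist = SpikeHistorySet()
        # own burst at the inhibitory extreme: theta' = -1, summand 2*A
        for t in (100.0, 110.0):
            hist.record(0, t, 0.0)
        syn = two_neuron_synapses(rho0=0.2)
        out = apply_plasticity_at_spike(0, 111.0, syn, hist, p)
        assert out.rho[0, 1] > 0.2 and out.rho[1, 0] > 0.2
        assert out.rho[0, 1] == pytest.approx(out.rho[1, 0])
        # own burst at the excitatory extreme depresses instead
        hist2 = SpikeHistorySet()
        for t in (100.0, 110.0):
            hist2.record(0, t, 1.0)
        out2 = apply_plasticity_at_spike(0, 111.0, syn, hist2, p)
        assert out2.rho[0, 1] < 0.2 and out2.rho[1, 0] < 0.2


class TestSpikeHistory:
    def test_record_and_prune(self, plast):
        hist = SpikeHistorySet(trace_window_ms=200.0)
        record_spike(3, 100.0, 0.2, hist)
        assert hist.entries(3) == [(100.0, 0.2)]
        record_spike(3, 300.0 + 1e-6, 0.5, hist)
        assert all(t >= 100.0 + 1e-7 for t, _ in hist.entries(3))

    def test_time_regression_rejected(self):
        hist = SpikeHistorySet()
        hist.record(0, 50.0, 0.5)
        with pytest.raises(ValueError):
            hist.record(0, 40.0, 0.5)

    def test_pruning_error_bounded_by_geometric_tail(self, plast):
        """Dropping entries older than the window changes the trace by at
        most n * A+ * exp(-window/tau)."""
        window = plast.trace_window_ms
        old = [(-window - 1.0 - i, 0.0) for i in range(5)]
        recent = [(-15.0, 0.0), (-5.0, 0.0)]
        full = potential_ltp(0.0, old + recent, plast)
        pruned = potential_ltp(0.0, recent, plast)
        bound = len(old) * plast.a_plus * np.exp(-window / plast.tau_s)
        assert abs(full - pruned) <= bound


class TestIncrementalTraceOracle:
    @pytest.mark.parametrize("variant", ["full", "stdp_only"])
    def test_incremental_matches_brute_force(self, variant, rng):
        """Incremental (decay + increment) traces agree with re-summing
        the whole spike history to 1e-9 on random spike trains."""
        p = PlasticityParams(variant=variant)
        for _ in range(100):
            n_spk = rng.integers(1, 30)
            times = np.sort(rng.choice(np.arange(1, 2000), size=n_spk,
                                       replace=False)).astype(float)
            thetas = rng.random(n_spk)
            inc = TracePair(p)
            hist = []
            for t, th in zip(times, thetas):
                inc.on_spike(t, th)
                hist.append((t, th))
            t_eval = float(times[-1] + rng.integers(1, 50))
            inc.advance(t_eval)
            assert inc.ltp == pytest.approx(
                potential_ltp(t_eval, hist, p), rel=1e-9, abs=1e-9)
            assert inc.ltd == pytest.approx(
                potential_ltd(t_eval, hist, p), rel=1e-9, abs=1e-9)


class TestParams:
    def test_heterosynaptic_flag_rejected(self):
        p = dataclasses.replace(PlasticityParams(),
                                heterosynaptic_enabled=True)
        with pytest.raises(Exception):
            p.validate()

    def test_default_rate_ratio(self, plast):
        assert plast.gamma_p == pytest.approx(2.0 * plast.gamma_d)
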