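"""Read-outs and model-comparison statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetastdp.analysis import (ComparisonResult, compare_models,
                                mean_weight_window, memory_decision_index,
                                normalize_accuracy, percent_baseline_change)
from thetastdp.engine import TrialResult
from thetastdp.network import Architecture
from thetastdp.plasticity import SynapseMatrix


def make_result(series_a2v, onset_ms=2000.0):
    """A minimal TrialResult with one auditory->visual plastic pair."""
    arch = Architecture()
    n = arch.n
    n_steps = len(series_a2v)
    exists = np.zeros((n, n), dtype=bool)
    src, dst = arch.hip_auditory[0], arch.hip_visual[0]
    exists[src, dst] = True
    syn = SynapseMatrix(exists, np.where(exists, 0.65, 0.0),
                        np.zeros((n, n)), exists.copy())
    traj = np.asarray(series_a2v, dtype=float)[:, None]
    return TrialResult(arch=arch, synapses=syn,
                       spike_times_ms=np.array([]),
                       spike_neurons=np.array([], dtype=int),
                       rec_src=np.array([src]), rec_dst=np.array([dst]),
                       rho_trajectory=traj, dt_ms=1.0, onset_ms=onset_ms,
                       min_isi_ms=np.inf, rho_bounds=(0.0, 1.0))


class TestMeanWeightWindow:
    def test_constant_trajectory(self):
        res = make_result(np.full(5000, 0.4))
        assert mean_weight_window(res) == pytest.approx(0.4)

    def test_linear_ramp_averages_to_midpoint(self):
        series = np.zeros(5000)
        series[4750:] = np.linspace(0.0, 1.0, 250)
        res = make_result(series)
        assert mean_weight_window(res) == pytest.approx(0.5, abs=0.01)

    def test_window_outside_trajectory_fails(self):
        res = make_result(np.zeros(3000))
        with pytest.raises(ValueError):
            mean_weight_window(res, (2750.0, 3000.0))

    def test_missing_direction_reports_zero_with_warning(self):
        res = make_result(np.full(5000, 0.7))
        with pytest.warns(UserWarning):
            assert mean_weight_window(res, pre="visual",
                                      post="auditory") == 0.0


class TestMemoryDecisionIndex:
    def test_against_sort_and_count_oracle(self):
        vals = np.arange(0.05, 0.55, 0.05)
        recalled = memory_decision_index(vals)
        thr = np.percentile(vals, 10.0)       # independent oracle
        expected = np.array([v > thr for v in vals])
        assert np.array_equal(recalled, expected)
        assert recalled.sum() == (vals > thr).sum()

    def test_degenerate_pool_recalls_nothing(self):
        assert memory_decision_index(np.full(20, 0.3)).sum() == 0

    def test_small_pool_rejected(self):
        with pytest.raises(ValueError):
            memory_decision_index(np.arange(5))

    def test_nearest_rank_method(self):
        vals = np.arange(1.0, 11.0)
        out = memory_decision_index(vals, method="nearest_rank")
        assert out.sum() == 9          # threshold at the 1st order statistic

    @given(st.lists(st.floats(0.0, 1.0), min_size=12, max_size=40),
           st.integers(0, 39), st.floats(0.01, 0.5))
    @settings(deadline=None, max_examples=60)
    def test_raising_one_trial_never_unrecalls_another(self, vals, idx, bump):
        vals = np.asarray(vals)
        idx = idx % len(vals)
        before = memory_decision_index(vals)
        raised = vals.copy()
        raised[idx] += bump
        after = memory_decision_index(raised)
        others = np.arange(len(vals)) != idx
        # monotone: no other trial flips from recalled to forgotten
        # unless the pooled threshold rose past it; threshold moves by at
        # most the single-value perturbation at the 10th percentile, and
        # recalled trials strictly above the old threshold stay recalled
        # whenever the threshold is unchanged
        thr_before = np.percentile(vals, 10.0)
        thr_after = np.percentile(raised, 10.0)
        if thr_after == thr_before:
            assert not np.any(before[others] & ~after[others])

    def test_threshold_invariant_to_order_and_duplication(self):
        vals = np.array([0.1, 0.9, 0.4, 0.2, 0.8, 0.3, 0.7, 0.5, 0.6, 0.05])
        a = memory_decision_index(vals)
        perm = np.random.default_rng(0).permutation(len(vals))
        b = memory_decision_index(vals[perm])
        assert np.array_equal(a[perm], b)
        doubled = memory_decision_index(np.concatenate([vals, vals]))
        assert np.array_equal(doubled[:len(vals)], a)


class TestPercentChange:
    @pytest.mark.parametrize("base, post, expected", [
        (0.5, 0.5, 0.0), (0.5, 0.75, 50.0), (0.5, 0.25, -50.0),
    ])
    def test_arithmetic(self, base, post, expected):
        assert percent_baseline_change(base, post) == pytest.approx(expected)

    def test_zero_baseline_is_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(percent_baseline_change(0.0, 0.5))


class TestNormalizeAccuracy:
    def test_constant_input_centres_to_zero(self):
        assert np.allclose(normalize_accuracy([3.0] * 4), 0.0)

    def test_example(self):
        out = normalize_accuracy([4.0, 2.0, 2.0, 2.0])
        assert np.allclose(out, [1.5, -0.5, -0.5, -0.5])

    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=4))
    @settings(deadline=None)
    def test_output_sums_to_zero(self, vals):
        assert normalize_accuracy(vals).sum() == pytest.approx(0.0, abs=1e-9)

    def test_wrong_condition_count_rejected(self):
        with pytest.raises(ValueError):
            normalize_accuracy([1.0, 2.0, 3.0])


class TestCompareModels:
    OFFSETS = [0.0, 90.0, 180.0, 270.0]

    def _table(self, vals):
        return dict(zip(self.OFFSETS, vals))

    def test_perfect_fit_beats_imperfect_competitor(self):
        emp = self._table([0.8, 0.5, 0.45, 0.5])
        sim = {"full": self._table([0.40, 0.25, 0.225, 0.25]),  # proportional
               "variant": self._table([0.5, 0.5, 0.2, 0.4])}
        res = compare_models(sim, emp)
        assert res.rss["full"] == pytest.approx(0.0, abs=1e-12)
        assert res.f_statistic["variant"] > 100 or \
            res.f_statistic["variant"] == np.inf
        assert res.bic["full"] < res.bic["variant"]

    def test_identical_models_give_f_zero(self):
        emp = self._table([0.8, 0.5, 0.45, 0.5])
        same = self._table([0.3, 0.1, 0.05, 0.12])
        res = compare_models({"full": same, "variant": dict(same)}, emp)
        assert res.f_statistic["variant"] == pytest.approx(0.0, abs=1e-9)

    def test_against_normal_equations_oracle(self, rng):
        emp_v = rng.random(4)
        sim_v = rng.random(4)
        res = compare_models({"full": self._table(sim_v)},
                             self._table(emp_v))
        # closed-form normal equations for a 2-parameter fit
        x, y = sim_v, emp_v
        a = ((x * y).mean() - x.mean() * y.mean()) / ((x ** 2).mean()
                                                      - x.mean() ** 2)
        b = y.mean() - a * x.mean()
        rss = float(np.sum((y - a * x - b) ** 2))
        assert res.scale["full"] == pytest.approx(a, rel=1e-9)
        assert res.intercept["full"] == pytest.approx(b, rel=1e-9)
        assert res.rss["full"] == pytest.approx(rss, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        emp = self._table(rng.random(4))
        sim_v = rng.random(4)
        r1 = compare_models({"full": self._table(sim_v)}, emp)
        r2 = compare_models({"full": self._table(3.7 * sim_v + 0.2)}, emp)
        assert r1.rss["full"] == pytest.approx(r2.rss["full"], abs=1e-10)

    def test_mismatched_conditions_rejected(self):
        emp = self._table([1, 2, 3, 4])
        with pytest.raises(ValueError):
            compare_models({"full": {0.0: 1.0, 45.0: 2.0, 180.0: 3.0,
                                     270.0: 4.0}}, emp)
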