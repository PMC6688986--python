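import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikelearn.inputs import InputGenParams, generate_dendritic_example
from spikelearn.plasticity import (
    AdaptationSource,
    STDPParams,
    adapt_dendritic,
    adapt_synaptic,
    stdp_delta,
    stimulation_ranks,
)

from conftest import make_example, make_trace

EXP = STDPParams(amplitude=0.003, kernel="exp")
STEP = STDPParams(amplitude=0.003, kernel="step")


class TestStdpDelta:
    def test_exp_kernel_one_tau(self):
        assert stdp_delta(15.0, EXP) == pytest.approx(0.003 * math.exp(-1.0), abs=1e-12)
        assert stdp_delta(15.0, EXP) == pytest.approx(0.0011036, abs=5e-8)

    def test_step_kernel_sign(self):
        assert stdp_delta(-10.0, STEP) == -0.003
        assert stdp_delta(10.0, STEP) == 0.003

    def test_cutoff_window(self):
        for params in (EXP, STEP):
            assert stdp_delta(60.0, params) == 0.0
            assert stdp_delta(-60.0, params) == 0.0
            assert stdp_delta(50.0, params) != 0.0

    def test_zero_lag_is_noop(self):
        assert stdp_delta(0.0, EXP) == 0.0
        assert stdp_delta(0.0, STEP) == 0.0

    def test_antisymmetric(self):
        for lag in (1.0, 7.5, 30.0):
            assert stdp_delta(-lag, EXP) == -stdp_delta(lag, EXP)


class TestAdaptSynaptic:
    def bounds(self):
        return (1e-4, 1.5)

    def test_strengthen_after_spike(self):
        # sub-threshold stimulation 10 ms after a spike, step kernel
        ex = make_example(units=[0, 1], times=[0.0, 10.0], n_units=4)
        trace = make_trace([1, 0], ex.time_ms)
        w = np.array([0.5, 0.5, 0.5, 0.5])
        out = adapt_synaptic(w, ex, trace, AdaptationSource(trace), STEP, self.bounds())
        assert out[1] == pytest.approx(0.5 * 1.003, abs=1e-15)

    def test_spiking_event_weight_untouched(self):
        ex = make_example(units=[0, 1], times=[0.0, 10.0], n_units=4)
        trace = make_trace([1, 0], ex.time_ms)
        w = np.full(4, 0.5)
        out = adapt_synaptic(w, ex, trace, AdaptationSource(trace), STEP, self.bounds())
        assert out[0] == 0.5

    def test_clip_at_upper_bound(self):
        ex = make_example(units=[0, 1], times=[0.0, 10.0], n_units=2)
        trace = make_trace([1, 0], ex.time_ms)
        w = np.array([0.5, 1.4999])
        out = adapt_synaptic(w, ex, trace, AdaptationSource(trace), STEP, self.bounds())
        assert out[1] == 1.5

    def test_weaken_before_spike(self):
        ex = make_example(units=[0, 1], times=[0.0, 10.0], n_units=2)
        trace = make_trace([0, 1], ex.time_ms)
        w = np.array([0.5, 0.5])
        out = adapt_synaptic(w, ex, trace, AdaptationSource(trace), STEP, self.bounds())
        assert out[0] == pytest.approx(0.5 * 0.997, abs=1e-15)
        assert out[1] == 0.5

    def test_nearest_spike_pairing_tie_goes_earlier(self):
        # spikes at 0 and 20; sub event at 10 is equidistant -> pairs with
        # the earlier spike -> positive lag -> strengthened
        ex = make_example(units=[0, 1, 2], times=[0.0, 10.0, 20.0], n_units=4)
        trace = make_trace([1, 0, 1], ex.time_ms)
        w = np.full(4, 0.5)
        out = adapt_synaptic(w, ex, trace, AdaptationSource(trace), STEP, self.bounds())
        assert out[1] == pytest.approx(0.5 * 1.003, abs=1e-15)

    def test_nearest_spike_pairing_prefers_closer(self):
        ex = make_example(units=[0, 1, 2], times=[0.0, 14.0, 20.0], n_units=4)
        trace = make_trace([1, 0, 1], ex.time_ms)
        w = np.full(4, 0.5)
        out = adapt_synaptic(w, ex, trace, AdaptationSource(trace), EXP, self.bounds())
        # closer spike is at 20 (lag -6) -> weakened with exp kernel
        assert out[1] == pytest.approx(0.5 * (1 - 0.003 * math.exp(-6 / 15)), abs=1e-15)

    def test_outside_cutoff_no_change(self):
        ex = make_example(units=[0, 1], times=[0.0, 60.0], n_units=2)
        trace = make_trace([1, 0], ex.time_ms)
        out = adapt_synaptic(
            np.array([0.5, 0.5]), ex, trace, AdaptationSource(trace), STEP, self.bounds()
        )
        assert out[1] == 0.5

    def test_pair_all_spikes_option(self):
        params = STDPParams(amplitude=0.003, kernel="step", pair_all_spikes=True)
        ex = make_example(units=[0, 1, 2], times=[0.0, 10.0, 15.0], n_units=4)
        trace = make_trace([1, 0, 1], ex.time_ms)
        out = adapt_synaptic(
            np.full(4, 0.5), ex, trace, AdaptationSource(trace), params, self.bounds()
        )
        assert out[1] == pytest.approx(0.5 * 1.003 * 0.997, abs=1e-15)

    def test_bounds_violation_on_input_rejected(self):
        ex = make_example(units=[0], times=[0.0], n_units=2)
        trace = make_trace([0], ex.time_ms)
        with pytest.raises(ValueError):
            adapt_synaptic(
                np.array([2.0, 0.5]), ex, trace, AdaptationSource(trace), STEP, self.bounds()
            )

    def test_teacher_reference_applies_to_student_weights(self):
        # same factors, different base values: ratio is preserved
        ex = make_example(units=[0, 1], times=[0.0, 10.0], n_units=2)
        trace = make_trace([1, 0], ex.time_ms)
        src = AdaptationSource(trace, "teacher")
        w_t = adapt_synaptic(np.array([0.5, 0.8]), ex, trace, src, STEP, self.bounds())
        w_s = adapt_synaptic(np.array([0.5, 0.4]), ex, trace, src, STEP, self.bounds())
        assert w_s[1] / w_t[1] == pytest.approx(0.5, abs=1e-12)


def _dendritic_example_two_blocks():
    # dendrites 0 and 1 stimulated as ordered blocks (N=20, K=4)
    units = [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
    times = [0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0, 36.0]
    return make_example(
        units=units,
        times=times,
        n_units=20,
        scenario="dendritic",
        dendrite_order=np.array([0, 1]),
    )


class TestAdaptDendritic:
    def test_single_pairing_with_prior_dendrite(self):
        ex = _dendritic_example_two_blocks()
        # dendrite 0 spikes at t=8; dendrite 1 events all sub-threshold
        bits = [0, 0, 1, 0, 0, 0, 0, 0, 0, 0]
        trace = make_trace(bits, ex.time_ms)
        params = STDPParams(amplitude=0.003, kernel="step", mode="rank_window")
        out = adapt_dendritic(
            np.ones(4), ex, trace, AdaptationSource(trace), params, (0.1, 2.0)
        )
        # each of dendrite 1's five sub events pairs once with the spike
        assert out[1] == pytest.approx(1.003**5, abs=1e-12)
        # dendrite 0's own sub events ignore its own spike
        assert out[0] == 1.0

    def test_no_spikes_in_window_no_change(self):
        ex = _dendritic_example_two_blocks()
        trace = make_trace([0] * 10, ex.time_ms)
        params = STDPParams(mode="rank_window")
        out = adapt_dendritic(
            np.ones(4), ex, trace, AdaptationSource(trace), params, (0.1, 2.0)
        )
        np.testing.assert_array_equal(out, np.ones(4))

    def test_clip_at_upper_bound(self):
        ex = _dendritic_example_two_blocks()
        bits = [0, 1, 0, 1, 0, 0, 0, 0, 0, 0]
        # dendrite 1: first two events sub -> no, all dendrite-1 events sub;
        # two spikes from dendrite 0 -> two strengthening factors per event
        trace = make_trace(bits, ex.time_ms)
        params = STDPParams(amplitude=0.003, kernel="step", mode="rank_window")
        strengths = np.array([1.0, 1.999, 1.0, 1.0])
        out = adapt_dendritic(
            strengths, ex, trace, AdaptationSource(trace), params, (0.1, 2.0)
        )
        assert out[1] == 2.0  # 1.999 * 1.003^10 clipped

    def test_rank_window_excludes_far_dendrites(self):
        # N=40, K=8: blocks 0..3 stimulated, spike only in dendrite 0;
        # dendrite 3 is outside the +/-2 rank window of dendrite 0
        units = list(range(20))
        times = [float(4 * k) for k in range(20)]
        ex = make_example(
            units=units,
            times=times,
            n_units=40,
            scenario="dendritic",
            dendrite_order=np.array([0, 1, 2, 3]),
        )
        bits = [1] + [0] * 19
        trace = make_trace(bits, ex.time_ms)
        params = STDPParams(amplitude=0.003, kernel="step", mode="rank_window", rank_window=2)
        out = adapt_dendritic(
            np.ones(8), ex, trace, AdaptationSource(trace), params, (0.1, 2.0)
        )
        assert out[1] == pytest.approx(1.003**5, abs=1e-12)
        assert out[2] == pytest.approx(1.003**5, abs=1e-12)
        assert out[3] == 1.0  # rank distance 3 > 2

    def test_time_window_mode_nearest_other_dendrite(self):
        ex = _dendritic_example_two_blocks()
        bits = [0, 0, 1, 0, 0, 0, 0, 0, 0, 0]
        trace = make_trace(bits, ex.time_ms)
        params = STDPParams(amplitude=0.003, kernel="step", mode="time_window", cutoff_ms=50.0)
        out = adapt_dendritic(
            np.ones(4), ex, trace, AdaptationSource(trace), params, (0.1, 2.0)
        )
        assert out[1] == pytest.approx(1.003**5, abs=1e-12)
        assert out[0] == 1.0  # own spike is not a partner; no other spikes

    def test_stimulation_ranks_interleaves_weak_dendrites(self, rng):
        params = InputGenParams(weak_fill_amplitude=0.01)
        ex = generate_dendritic_example(100, params=params, rng=rng)
        ranks = stimulation_ranks(ex, 20)
        assert np.all(ranks >= 0)  # weak fill activates every dendrite
        chosen_ranks = ranks[ex.dendrite_order]
        assert np.all(np.diff(chosen_ranks) > 0)  # block order preserved


class TestInvariantProperties:
    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**32 - 1))
    def test_positivity_and_bounds_after_adaptation(self, seed):
        rng = np.random.default_rng(seed)
        ex = generate_dendritic_example(
            50, params=InputGenParams(weak_fill_amplitude=0.01), rng=rng
        )
        bits = rng.integers(0, 2, ex.n_events).astype(np.int8)
        trace = make_trace(bits, ex.time_ms)
        params = STDPParams(amplitude=0.05, kernel="step", mode="rank_window")
        strengths = rng.uniform(0.1, 2.0, 10)
        out = adapt_dendritic(
            strengths, ex, trace, AdaptationSource(trace), params, (0.1, 2.0)
        )
        assert np.all(out >= 0.1) and np.all(out <= 2.0)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**32 - 1))
    def test_ratio_preserved_until_clip(self, seed):
        rng = np.random.default_rng(seed)
        ex = generate_dendritic_example(50, params=InputGenParams(), rng=rng)
        bits = rng.integers(0, 2, ex.n_events).astype(np.int8)
        trace = make_trace(bits, ex.time_ms)
        params = STDPParams(amplitude=0.01, kernel="step", mode="rank_window")
        src = AdaptationSource(trace, "teacher")
        j_t = rng.uniform(0.5, 1.5, 10)
        j_s = j_t * rng.uniform(0.9, 1.1, 10)
        wide = (1e-6, 1e6)  # no clipping possible
        out_t = adapt_dendritic(j_t, ex, trace, src, params, wide)
        out_s = adapt_dendritic(j_s, ex, trace, src, params, wide)
        np.testing.assert_allclose(out_s / out_t, j_s / j_t, rtol=1e-12)

    def test_clip_strictly_reduces_gap(self):
        # both above the bound -> both clipped to it -> gap collapses
        ex = _dendritic_example_two_blocks()
        bits = [0, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        trace = make_trace(bits, ex.time_ms)
        params = STDPParams(amplitude=0.05, kernel="step", mode="rank_window")
        src = AdaptationSource(trace, "teacher")
        j_t = np.array([1.0, 1.95, 1.0, 1.0])
        j_s = np.array([1.0, 1.99, 1.0, 1.0])
        out_t = adapt_dendritic(j_t, ex, trace, src, params, (0.1, 2.0))
        out_s = adapt_dendritic(j_s, ex, trace, src, params, (0.1, 2.0))
        assert out_t[1] == out_s[1] == 2.0

    def test_equal_vectors_stay_equal(self, rng):
        ex = generate_dendritic_example(50, params=InputGenParams(), rng=rng)
        bits = rng.integers(0, 2, ex.n_events).astype(np.int8)
        trace = make_trace(bits, ex.time_ms)
        params = STDPParams(amplitude=0.003, kernel="step", mode="rank_window")
        src = AdaptationSource(trace, "teacher")
        j = rng.uniform(0.5, 1.5, 10)
        out_t = adapt_dendritic(j.copy(), ex, trace, src, params, (0.1, 2.0))
        out_s = adapt_dendritic(j.copy(), ex, trace, src, params, (0.1, 2.0))
        np.testing.assert_array_equal(out_t, out_s)
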