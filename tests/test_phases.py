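import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcnatrace.phases import (
    CallerConfig,
    NoSDetected,
    call_phases,
    call_s_boundaries,
    flag_mitosis_candidates,
    segment_s_subphases,
    smooth,
)
from pcnatrace.io import mitosis_from_timelines
from pcnatrace.traces import get_trace


def synthetic_sobel_trace(n=64, dt=15.0, s0_f=21, em_f=29, ml_f=43, s1_f=49,
                          base=300.0, noise=0.0, seed=0):
    """Idealized Sobel trace: jump at S entry, early plateau, mid rise,
    late fall; returns (times, values, frame indices of the boundaries)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    v = np.full(n, base)
    v[s0_f:em_f] = 4 * base                       # early-S plateau after the jump
    v[em_f:ml_f] = np.linspace(4 * base, 7 * base, ml_f - em_f)  # mid-S rise
    v[ml_f:s1_f] = np.linspace(6 * base, base, s1_f - ml_f)      # late-S fall
    return t, v + rng.normal(0, noise, n), (s0_f, em_f, ml_f, s1_f)


class TestSmooth:
    def test_window_one_is_identity(self):
        v = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert np.array_equal(smooth(v, 1), v)

    def test_constant_trace_unchanged(self):
        v = np.full(9, 2.5)
        assert np.allclose(smooth(v, 3), v)

    def test_hand_computed_example(self):
        assert np.allclose(smooth([0, 0, 3, 0, 0], 3), [0, 1, 1, 1, 0])

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth([1.0, 2.0], 5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_preserves_length_and_mean_range(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=21)
        out = smooth(v, 5)
        assert out.shape == v.shape
        assert out.min() >= v.min() - 1e-12 and out.max() <= v.max() + 1e-12


class TestCallSBoundaries:
    def test_recovers_the_constructed_boundaries(self):
        t, v, (s0, _, _, s1) = synthetic_sobel_trace()
        a, b = call_s_boundaries(t, v, m_start_min=60 * 15.0)
        assert abs(a - t[s0]) <= 15.0
        # the ramp reaches baseline at frame s1 - 1, which is the true end
        # of the decline in this construction
        assert abs(b - t[s1 - 1]) <= 15.0

    def test_flat_trace_raises_no_s_detected(self):
        t = np.arange(50) * 15.0
        with pytest.raises(NoSDetected):
            call_s_boundaries(t, np.full(50, 200.0), m_start_min=700.0)

    def test_deterministic(self):
        t, v, _ = synthetic_sobel_trace(noise=5.0, seed=4)
        assert call_s_boundaries(t, v, 900.0) == call_s_boundaries(t, v, 900.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_raising_k_never_widens_the_called_s_phase(self, seed):
        t, v, _ = synthetic_sobel_trace(noise=8.0, seed=seed)
        results = []
        for k in (2.0, 3.0, 5.0):
            try:
                results.append(call_s_boundaries(t, v, 900.0, CallerConfig(k=k)))
            except NoSDetected:
                results.append(None)
        prev = None
        for res in results:
            if prev is not None and res is not None:
                assert res[0] >= prev[0]  # S start never moves earlier
                assert res[1] <= prev[1]  # S end never moves later
            prev = res if res is not None else prev

    def test_noise_free_rendered_cell_recovered_within_two_frames(
            self, single_cell_scene, single_cell_traces):
        tl = single_cell_scene.timelines[0]
        t, v = get_trace(single_cell_traces, 1, "red", "sobel_mean")
        s0, s1 = call_s_boundaries(t, v, tl.m_start)
        assert abs(s0 - tl.s_start) <= 30.0
        assert abs(s1 - tl.s_end) <= 30.0


class TestSegmentSubphases:
    def test_recovers_constructed_subphase_boundaries(self):
        t, v, (s0, em, ml, s1) = synthetic_sobel_trace()
        a, b, methods = segment_s_subphases(t, v, (t[s0], t[s1]))
        assert methods == {"early_mid": "changepoint", "mid_late": "changepoint"}
        assert abs(a - t[em]) <= 30.0
        assert abs(b - t[ml]) <= 30.0

    def test_monotone_rise_falls_back_to_fixed_fractions(self):
        t = np.arange(40) * 15.0
        v = np.linspace(100, 4000, 40)  # no plateau, no interior maximum
        s0, s1 = t[5], t[35]
        a, b, methods = segment_s_subphases(t, v, (s0, s1))
        assert methods["early_mid"] == "fallback"
        assert a == pytest.approx(s0 + (2 / 7) * (s1 - s0))
        assert b == pytest.approx(s0 + (5.5 / 7) * (s1 - s0))

    def test_inverted_bounds_rejected(self):
        t, v, _ = synthetic_sobel_trace()
        with pytest.raises(ValueError):
            segment_s_subphases(t, v, (500.0, 400.0))

    def test_rendered_cell_subphases_within_two_frames(
            self, single_cell_scene, single_cell_traces):
        tl = single_cell_scene.timelines[0]
        t, v = get_trace(single_cell_traces, 1, "red", "sobel_mean")
        s0, s1 = call_s_boundaries(t, v, tl.m_start)
        em, ml, methods = segment_s_subphases(t, v, (s0, s1))
        assert methods == {"early_mid": "changepoint", "mid_late": "changepoint"}
        assert abs(em - tl.early_mid) <= 30.0
        assert abs(ml - tl.mid_late) <= 30.0


class TestCallPhases:
    def test_end_to_end_recovery_on_a_rendered_cell(self, single_cell_scene,
                                                    single_cell_traces):
        scene = single_cell_scene
        mit = mitosis_from_timelines(scene.timelines)
        calls, undetected = call_phases(single_cell_traces, mit)
        assert undetected == []
        tl_true = scene.timelines[0]
        tl = calls[1].timeline
        assert tl.provenance == "called"
        for name in ("s_start", "early_mid", "mid_late", "s_end"):
            assert abs(tl.boundaries()[name] - tl_true.boundaries()[name]) <= 30.0
        # G1 = cytokinesis -> S start by definition
        assert tl.g1_duration == tl.s_start

    def test_missing_red_channel_named_in_error(self, single_cell_scene,
                                                single_cell_traces):
        green_only = single_cell_traces[single_cell_traces["channel"] == "green"]
        mit = mitosis_from_timelines(single_cell_scene.timelines)
        with pytest.raises(KeyError, match="red"):
            call_phases(green_only, mit)

    def test_annotation_outside_trace_extent_names_the_cell(
            self, single_cell_traces):
        import pandas as pd
        mit = pd.DataFrame([{"cell_id": 1, "m_start_min": 9000.0,
                             "cycle_end_min": 9100.0}])
        with pytest.raises(ValueError, match="cell 1"):
            call_phases(single_cell_traces, mit)


class TestMitosisFlag:
    def test_flags_the_dilution_drop(self):
        t = np.arange(10) * 15.0
        v = np.array([100.0] * 6 + [45.0] * 4)  # 55% single-frame drop
        flagged = flag_mitosis_candidates(t, v)
        assert list(flagged) == [90.0]
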