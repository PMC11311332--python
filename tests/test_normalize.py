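import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcnatrace.cycle import PhaseTimeline
from pcnatrace.normalize import (
    align_phases,
    build_profile,
    default_grid,
    interpolate_to_grid,
    minmax_scale,
    normalize_cycle,
    phase_proportions,
    population_profile,
    population_proportions,
)

MEAN_PROPS = np.array([325.0, 420.0, 158.0, 55.0]) / 958.0


class TestNormalizeCycle:
    def test_divides_by_the_cycle_length(self):
        # the worked measurement: frame times 15, 30, 45 ... on a 940-min cycle
        unit = normalize_cycle(np.array([15.0, 30.0, 45.0]), 940.0)
        assert unit[0] == pytest.approx(15 / 940)
        assert unit[0] == pytest.approx(0.01596, abs=5e-6)

    def test_endpoint_is_exactly_one(self):
        t = np.arange(0.0, 941.0, 15.0)
        unit = normalize_cycle(t, t[-1])
        assert unit[-1] == 1.0
        # default cycle length is the last observed frame time
        assert normalize_cycle(t)[-1] == 1.0

    def test_times_only_transform(self):
        t = np.array([0.0, 15.0, 30.0])
        v = np.array([5.0, 6.0, 7.0])
        normalize_cycle(t, 30.0)
        assert np.array_equal(v, [5.0, 6.0, 7.0])

    def test_nonpositive_cycle_length_rejected(self):
        with pytest.raises(ValueError):
            normalize_cycle(np.array([0.0, 15.0]), 0.0)


class TestAlignPhases:
    def test_g1_boundary_maps_to_population_proportion(self):
        # a cell with G1 = 0.31 of its cycle; population mean G1 proportion
        # 325/958 ~ 0.339: the G1/S boundary must land exactly there
        cell = np.array([0.31, 0.44, 0.17, 0.08])
        out = align_phases(np.array([0.31]), cell, MEAN_PROPS)
        assert out[0] == pytest.approx(325.0 / 958.0)

    def test_population_matching_cell_maps_identically(self):
        u = np.linspace(0, 1, 17)
        out = align_phases(u, MEAN_PROPS, MEAN_PROPS)
        assert np.allclose(out, u, atol=1e-12)

    def test_all_cells_share_boundary_positions_after_alignment(self):
        rng = np.random.default_rng(5)
        pop = MEAN_PROPS
        boundary_images = []
        for _ in range(10):
            props = rng.dirichlet([20, 25, 10, 4])
            cum = np.concatenate([[0], np.cumsum(props)])
            boundary_images.append(align_phases(cum, props, pop))
        ref = boundary_images[0]
        for img in boundary_images[1:]:
            assert np.allclose(img, ref, atol=1e-12)

    def test_zero_length_phase_rejected_with_phase_name(self):
        with pytest.raises(ValueError, match="G2"):
            align_phases(np.array([0.5]), np.array([0.5, 0.5, 0.0, 0.0]),
                         MEAN_PROPS, cell_id=7)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_alignment_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        props = rng.dirichlet([20, 25, 10, 4])
        u = np.sort(rng.random(30))
        out = align_phases(u, props, MEAN_PROPS)
        assert np.all(np.diff(out) >= 0)


class TestInterpolateToGrid:
    def test_sample_coincident_grid_point(self):
        got = interpolate_to_grid([0.0, 0.5, 1.0], [1.0, 3.0, 2.0], [0.5])
        assert got[0] == 3.0

    def test_midpoint_of_a_line(self):
        got = interpolate_to_grid([0.2, 0.4], [10.0, 20.0], [0.3])
        assert got[0] == pytest.approx(15.0)

    def test_matches_two_point_line_oracle_exactly(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.random(12))
        t[0], t[-1] = 0.0, 1.0
        v = rng.normal(size=12)
        grid = np.linspace(0, 1, 301)
        got = interpolate_to_grid(t, v, grid)
        # brute-force evaluation of the line through the two nearest samples
        expect = np.empty_like(grid)
        for i, g in enumerate(grid):
            j = np.searchsorted(t, g)
            if j == 0:
                expect[i] = v[0]
            elif j == len(t):
                expect[i] = v[-1]
            elif t[j] == g:
                expect[i] = v[j]
            else:
                t0, t1, v0, v1 = t[j - 1], t[j], v[j - 1], v[j]
                expect[i] = v0 + (v1 - v0) * (g - t0) / (t1 - t0)
        # the two formulations of the same line differ only in last-ulp
        # rounding
        assert np.max(np.abs(got - expect)) <= 2 ** -50

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            interpolate_to_grid([0.5], [1.0], [0.5])


class TestPopulationProfile:
    def test_single_trace_mean_is_the_trace_with_zero_sd(self):
        grid = default_grid(16)
        v = np.sin(grid * 3)
        prof = population_profile(v[None, :], grid, 15.967)
        assert np.allclose(prof.mean, v)
        assert np.all(prof.sd == 0.0)
        assert np.all(prof.n == 1)

    def test_symmetric_traces_average_to_the_midline(self):
        grid = default_grid(8)
        v = np.linspace(0, 1, 8)
        c = 5.0
        prof = population_profile(np.stack([v, -v + c]), grid, 15.967)
        assert np.allclose(prof.mean, c / 2)

    def test_axis_endpoint_is_the_configured_mean_cycle_duration(self):
        grid = default_grid()
        prof = population_profile(np.ones((3, len(grid))), grid, 15.967)
        assert prof.time_h[-1] == 15.967
        assert prof.time_h[0] == 0.0

    def test_minmax_scaled_mean_attains_zero_and_one(self):
        grid = default_grid(32)
        prof = population_profile(np.sin(grid * 7)[None, :], grid, 15.967)
        mm = prof.minmax_mean
        assert mm.min() == 0.0 and mm.max() == 1.0

    def test_constant_profile_cannot_be_minmax_scaled(self):
        with pytest.raises(ValueError):
            minmax_scale(np.ones(5))


class TestFullChain:
    def make_timeline(self, g1, s, g2, m):
        return PhaseTimeline(s_start=g1, early_mid=g1 + 2 * s / 7,
                             mid_late=g1 + 5.5 * s / 7, s_end=g1 + s,
                             m_start=g1 + s + g2, cycle_end=g1 + s + g2 + m)

    def test_phase_proportion_conservation_to_machine_precision(self):
        rng = np.random.default_rng(13)
        timelines = [self.make_timeline(*(rng.uniform(0.6, 1.4, 4)
                                          * [325, 420, 158, 55]))
                     for _ in range(12)]
        props = np.array([phase_proportions(tl) for tl in timelines])
        pop = population_proportions(props)
        pop_cum = np.concatenate([[0], np.cumsum(pop)])
        for tl, p in zip(timelines, props):
            bounds = np.array([0, tl.s_start, tl.s_end, tl.m_start, tl.cycle_end])
            unit = bounds / tl.cycle_end
            aligned = align_phases(unit, p, pop)
            assert np.max(np.abs(aligned - pop_cum)) < 1e-14

    def test_mean_duration_cell_round_trips_through_the_chain(self):
        tl = self.make_timeline(325.0, 420.0, 158.0, 55.0)
        t = np.arange(0.0, 958.1, 15.0)
        t[-1] = 958.0
        props = phase_proportions(tl)
        unit = normalize_cycle(t, 958.0)
        aligned = align_phases(unit, props, props)
        rescaled = aligned * 958.0
        assert np.max(np.abs(rescaled - t)) < 1e-9

    def test_build_profile_on_the_cohort(self, cohort_traces, cohort_calls):
        prof = build_profile(cohort_traces, cohort_calls, channel="green",
                             value="mean_intensity", grid_size=64)
        assert len(prof.time_h) == 64
        assert np.all(prof.n == len(cohort_calls))
        assert np.all(prof.sd >= 0)
        # cohort mean cycle duration is close to the 15 h 58 min population mean
        assert prof.time_h[-1] == pytest.approx(15.967, rel=0.05)
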