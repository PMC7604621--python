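"""Filopodia-particle proximity analysis and its randomised control."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mrnapolar.proximity import (
    FilopodiumEvent,
    ParticleTrack,
    RoiStack,
    bin_frequencies,
    bin_positions_along_axis,
    filter_complete_events,
    nearest_particle_distance,
    proximity_analysis,
    sample_control_position,
)
from mrnapolar.synthetic import SimTimelapseSpec, disk_roi, gen_timelapse


def _event(t0, t1, base=(0.0, 0.0), eid="e"):
    return FilopodiumEvent(event_id=eid, base=base, t_emerge=t0, t_retract=t1)


class TestCompleteEvents:
    def test_interior_event_kept(self):
        assert filter_complete_events([_event(3, 10)], (0, 100)) != []

    def test_event_at_first_frame_dropped(self):
        assert filter_complete_events([_event(0, 10)], (0, 100)) == []

    def test_event_reaching_last_frame_dropped(self):
        assert filter_complete_events([_event(3, 100)], (0, 100)) == []


class TestNearestDistance:
    def test_three_four_five(self):
        track = ParticleTrack("t0", frames=[5], xy=[[0.0, 0.0]])
        assert nearest_particle_distance((3.0, 4.0), [track], 5) == pytest.approx(5.0)

    def test_picks_nearest_of_two(self):
        tracks = [
            ParticleTrack("a", frames=[2], xy=[[0.0, 0.0]]),
            ParticleTrack("b", frames=[2], xy=[[10.0, 0.0]]),
        ]
        assert nearest_particle_distance((6.0, 0.0), tracks, 2) == pytest.approx(4.0)

    def test_no_particle_at_frame_is_error(self):
        track = ParticleTrack("t0", frames=[5], xy=[[0.0, 0.0]])
        with pytest.raises(ValueError, match="no particle"):
            nearest_particle_distance((1.0, 1.0), [track], 6)

    def test_track_requires_increasing_frames(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ParticleTrack("t0", frames=[3, 3], xy=[[0, 0], [1, 1]])


class TestControlSampling:
    def test_single_pixel_roi(self):
        mask = np.zeros((4, 4), bool)
        mask[2, 1] = True
        rng = np.random.default_rng(0)
        for _ in range(5):
            x, y = sample_control_position(mask, 0.5, rng)
            assert 0.5 <= x <= 1.0 and 1.0 <= y <= 1.5

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sample_control_position(np.zeros((3, 3), bool), 0.5, np.random.default_rng(0))

    def test_same_seed_reproduces_draws(self):
        mask = np.ones((16, 16), bool)
        a = [sample_control_position(mask, 1.0, np.random.default_rng(7)) for _ in range(1)]
        b = [sample_control_position(mask, 1.0, np.random.default_rng(7)) for _ in range(1)]
        np.testing.assert_array_equal(a, b)

    def test_uniform_over_quadrants(self):
        mask = np.ones((20, 20), bool)
        rng = np.random.default_rng(11)
        counts = np.zeros(4)
        for _ in range(10_000):
            x, y = sample_control_position(mask, 1.0, rng)
            counts[int(x >= 10) + 2 * int(y >= 10)] += 1
        assert stats.chisquare(counts).pvalue > 0.001


class TestBinFrequencies:
    def test_basic_fractions(self):
        freq, edges = bin_frequencies(np.array([1, 2, 7, 12]), 5.0)
        np.testing.assert_allclose(freq, [0.5, 0.25, 0.25])
        np.testing.assert_allclose(edges, [0, 5, 10, 15])

    def test_boundary_distance_goes_to_upper_bin(self):
        freq, _ = bin_frequencies(np.array([5.0]), 5.0)
        np.testing.assert_allclose(freq, [0.0, 1.0])

    def test_single_bin(self):
        freq, _ = bin_frequencies(np.array([1.0, 2.0]), 5.0)
        np.testing.assert_allclose(freq, [1.0])

    def test_area_normalisation_upweights_near_bins(self):
        freq, _ = bin_frequencies(np.array([2.0, 7.0]), 5.0, area_normalize=True)
        assert freq.sum() == pytest.approx(1.0)
        assert freq[0] > freq[1]  # equal counts, smaller annulus wins

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_frequencies(np.array([]), 5.0)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=200.0, allow_nan=False),
            min_size=1,
            max_size=50,
        ),
        st.floats(min_value=0.5, max_value=20.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_frequencies_always_sum_to_one_and_cover_max(self, distances, width):
        freq, edges = bin_frequencies(np.array(distances), width)
        assert freq.sum() == pytest.approx(1.0)
        assert edges[-1] > max(distances)
        assert len(freq) == len(edges) - 1


class TestProximityAnalysis:
    def test_perfectly_monotone_duration_gives_spearman_minus_one(self):
        track = ParticleTrack("t0", frames=np.arange(50), xy=np.zeros((50, 2)) + 1.0)
        events = [
            FilopodiumEvent(f"e{i}", base=(1.0 + d, 1.0), t_emerge=5, t_retract=5 + 30 - i)
            for i, d in enumerate([1.0, 2.0, 4.0, 8.0, 16.0])
        ]
        roi = RoiStack(masks=np.ones((40, 40), bool), pixel_size=1.0)
        res = proximity_analysis(events, [track], roi, seed=1)
        assert res.spearman_observed[0] == pytest.approx(-1.0)

    def test_fewer_than_three_events_rejected(self):
        track = ParticleTrack("t0", frames=np.arange(10), xy=np.zeros((10, 2)))
        roi = RoiStack(masks=np.ones((10, 10), bool), pixel_size=1.0)
        with pytest.raises(ValueError, match="at least 3"):
            proximity_analysis([_event(1, 2, (1, 1))], [track], roi, seed=0)

    def test_coupled_observed_distances_are_shorter(self):
        spec = SimTimelapseSpec(n_filopodia=150, coupling_strength=1.0,
                                coupling_lambda=2.0, seed=21)
        tracks, events, roi = gen_timelapse(spec)
        kept = filter_complete_events(events, (0, spec.n_frames - 1))
        res = proximity_analysis(kept, tracks, roi, seed=21)
        assert np.median(res.observed) < np.median(res.control)
        assert res.mannwhitney_less_p < 0.01

    def test_uncoupled_distances_match_control_distribution(self):
        # with no coupling the observed distances are exchangeable with the
        # randomised control: a two-sample KS test should not reject
        spec = SimTimelapseSpec(n_filopodia=500, coupling_strength=0.0, seed=11)
        tracks, events, roi = gen_timelapse(spec)
        kept = filter_complete_events(events, (0, spec.n_frames - 1))
        res = proximity_analysis(kept, tracks, roi, seed=11)
        assert stats.ks_2samp(res.observed, res.control).pvalue > 0.01
        assert res.pearson_observed[1] > 0.01 and res.pearson_control[1] > 0.01

    def test_frequencies_sum_to_one_with_common_bins(self):
        spec = SimTimelapseSpec(n_filopodia=80, seed=2)
        tracks, events, roi = gen_timelapse(spec)
        kept = filter_complete_events(events, (0, spec.n_frames - 1))
        res = proximity_analysis(kept, tracks, roi, seed=2)
        assert res.freq_observed.sum() == pytest.approx(1.0)
        assert res.freq_control.sum() == pytest.approx(1.0)
        assert len(res.freq_observed) == len(res.freq_control)

    def test_control_draws_reproducible_from_seed(self):
        spec = SimTimelapseSpec(n_filopodia=50, seed=3)
        tracks, events, roi = gen_timelapse(spec)
        kept = filter_complete_events(events, (0, spec.n_frames - 1))
        a = proximity_analysis(kept, tracks, roi, seed=9)
        b = proximity_analysis(kept, tracks, roi, seed=9)
        np.testing.assert_array_equal(a.control, b.control)


class TestAxialBinning:
    def test_filopodium_at_tip_in_first_interval(self):
        counts = bin_positions_along_axis([(0.0, 0.0)], (0, 0), (1, 0))
        assert counts.tolist() == [1]

    def test_projections_fill_consecutive_intervals(self):
        pts = [(5.0, 0.0), (13.0, 0.0), (25.0, 0.0)]
        counts = bin_positions_along_axis(pts, (0, 0), (1, 0))
        assert counts.tolist() == [1, 1, 1]

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            bin_positions_along_axis([(1.0, 1.0)], (0, 0), (0, 0))

    def test_uniform_filopodia_spread_evenly(self):
        rng = np.random.default_rng(17)
        pts = np.column_stack([rng.uniform(0, 48, 2000), rng.uniform(-5, 5, 2000)])
        counts = bin_positions_along_axis(pts, (0, 0), (1, 0), bin_width=12.0)
        expected = 2000 / 4
        sd = np.sqrt(2000 * 0.25 * 0.75)
        assert np.all(np.abs(counts - expected) <= 3 * sd)
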