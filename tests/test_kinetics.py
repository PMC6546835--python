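import dataclasses

import numpy as np
import pytest
from scipy import stats

from cytoprof.errors import EventOrderError, SampleSizeError
from cytoprof.imaging import parse_timestamp
from cytoprof.kinetics import (
    Track,
    compare_groups,
    detect_contact,
    detect_pi_uptake,
    extract_kill_events,
    link_tracks,
    time_for_killing,
)
from cytoprof.segmentation import BinaryMask, label_components
from cytoprof.synth import generate_timelapse


def components_from(mask, pixel_size=1.0):
    return label_components(BinaryMask(np.asarray(mask, bool), pixel_size))


def square_mask(shape, r0, c0, size=2):
    m = np.zeros(shape, bool)
    m[r0 : r0 + size, c0 : c0 + size] = True
    return m


class TestLinkTracks:
    def test_stationary_cells_one_track_each(self):
        frame = square_mask((20, 20), 2, 2) | square_mask((20, 20), 10, 10)
        frames = [components_from(frame) for _ in range(5)]
        tracks = link_tracks(frames, max_step=3.0)
        assert len(tracks) == 2
        assert all(t.frames == list(range(5)) for t in tracks)

    def test_large_jump_starts_new_track(self):
        frames = [
            components_from(square_mask((30, 30), 2, 2)),
            components_from(square_mask((30, 30), 20, 20)),
        ]
        tracks = link_tracks(frames, max_step=5.0)
        assert len(tracks) == 2
        assert tracks[0].frames == [0]
        assert tracks[1].frames == [1]

    def test_slow_drift_is_followed(self):
        frames = [components_from(square_mask((30, 30), 2, 2 + i)) for i in range(6)]
        tracks = link_tracks(frames, max_step=2.0)
        assert len(tracks) == 1
        assert tracks[0].frames == list(range(6))

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        masks = [rng.random((30, 30)) < 0.1 for _ in range(4)]
        frames = [components_from(m) for m in masks]
        a = link_tracks(frames, max_step=4.0)
        b = link_tracks([components_from(m) for m in masks], max_step=4.0)
        assert [t.frames for t in a] == [t.frames for t in b]

    def test_synthetic_identity_recovery(self):
        """Non-crossing slow walks are recovered as single tracks."""
        from cytoprof.synth import TimeLapseParams

        recovered, total = 0, 0
        for seed in range(5):
            params = TimeLapseParams(
                field_size=(400.0, 400.0), n_target_cells=0, dead_fraction=0.0,
                n_effector_cells=12, infiltration_decay_length=300.0,
                n_frames=15, effector_step_sd=2.0, contact_distance=4.0,
                kill_probability_per_contact=0.0, noise_sd=30.0, seed=seed,
            )
            movie, _ = generate_timelapse(params)
            from cytoprof.segmentation import segment_channel

            frames = [
                label_components(segment_channel(img, params.pixel_size), min_area=40.0)
                for img in movie.channel_series("effector")
            ]
            tracks = link_tracks(frames, max_step=20.0)
            full = [t for t in tracks if len(t.frames) == params.n_frames]
            recovered += len(full)
            total += params.n_effector_cells
        assert recovered / total >= 0.95


class TestDetectContact:
    def _track(self, masks, first=0):
        t = Track(track_id=0)
        for i, m in enumerate(masks):
            (comp,) = components_from(m)
            t.frames.append(first + i)
            t.components.append(comp)
        return t

    def test_shared_pixel_contact(self):
        apart_a = square_mask((20, 20), 2, 2)
        apart_b = square_mask((20, 20), 2, 12)
        touch_a = square_mask((20, 20), 2, 2)
        touch_b = square_mask((20, 20), 2, 3)  # overlapping
        eff = self._track([apart_a, apart_a, apart_a, touch_a])
        tgt = self._track([apart_b, apart_b, apart_b, touch_b])
        ts = [0.0, 5.0, 10.0, 15.0]
        assert detect_contact(eff, tgt, ts, contact_dilation=1) == 15.0

    def test_always_far_apart_none(self):
        eff = self._track([square_mask((20, 20), 2, 2)] * 3)
        tgt = self._track([square_mask((20, 20), 2, 10)] * 3)
        assert detect_contact(eff, tgt, [0.0, 1.0, 2.0], contact_dilation=1) is None

    def test_dilation_reaches_adjacent_component(self):
        eff = self._track([square_mask((20, 20), 2, 2)])  # cols 2-3
        tgt = self._track([square_mask((20, 20), 2, 4)])  # cols 4-5, adjacent
        assert detect_contact(eff, tgt, [0.0], contact_dilation=0) is None
        assert detect_contact(eff, tgt, [0.0], contact_dilation=1) == 0.0

    def test_gap_needs_matching_dilation(self):
        eff = self._track([square_mask((20, 20), 2, 2)])  # cols 2-3
        tgt = self._track([square_mask((20, 20), 2, 5)])  # cols 5-6, gap col 4
        assert detect_contact(eff, tgt, [0.0], contact_dilation=1) is None
        assert detect_contact(eff, tgt, [0.0], contact_dilation=2) == 0.0


class TestDetectPiUptake:
    def _target(self, n_frames):
        t = Track(track_id=0)
        for i in range(n_frames):
            (comp,) = components_from(square_mask((10, 10), 4, 4))
            t.frames.append(i)
            t.components.append(comp)
        return t

    def _masks(self, overlaps):
        out = []
        for frac in overlaps:
            m = np.zeros((10, 10), bool)
            if frac >= 1.0:
                m[4:6, 4:6] = True
            elif frac > 0:
                m[4, 4] = True  # 1 of 4 pixels -> 0.25
            out.append(BinaryMask(m, 1.0))
        return out

    def test_no_overlap_none(self):
        tgt = self._target(5)
        masks = self._masks([0] * 5)
        assert detect_pi_uptake(tgt, masks, list(range(5))) is None

    def test_step_to_full_overlap(self):
        tgt = self._target(8)
        masks = self._masks([0, 0, 0, 0, 0, 1, 1, 1])
        ts = [float(10 * i) for i in range(8)]
        assert detect_pi_uptake(tgt, masks, ts, onset_fraction=0.3, persistence=2) == 50.0

    def test_single_frame_flicker_rejected(self):
        tgt = self._target(6)
        masks = self._masks([0, 0, 1, 0, 0, 0])
        assert detect_pi_uptake(tgt, masks, [float(i) for i in range(6)],
                                onset_fraction=0.3, persistence=2) is None

    def test_low_overlap_below_onset(self):
        tgt = self._target(4)
        masks = self._masks([0.25] * 4)  # 25% < 30% onset
        assert detect_pi_uptake(tgt, masks, [float(i) for i in range(4)]) is None


class TestTimeForKilling:
    def test_hhmm_difference(self):
        assert time_for_killing(parse_timestamp("01:00"), parse_timestamp("01:45")) == 45

    def test_equal_times_rejected(self):
        with pytest.raises(EventOrderError):
            time_for_killing(60.0, 60.0)

    def test_reversed_times_rejected(self):
        with pytest.raises(EventOrderError):
            time_for_killing(100.0, 40.0)


class TestCompareGroups:
    def test_identical_groups(self):
        result = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.t_statistic == 0.0
        assert result.p_value == 1.0

    def test_frozen_hand_value(self):
        result = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert result.t_statistic == pytest.approx(-3.6742, abs=1e-4)
        assert result.degrees_of_freedom == 4
        assert result.p_value == pytest.approx(0.0213, abs=1e-3)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(10):
            a = list(rng.normal(30, 5, size=rng.integers(3, 12)))
            b = list(rng.normal(35, 7, size=rng.integers(3, 12)))
            ours = compare_groups(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert ours.t_statistic == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_symmetry_under_swap(self, rng):
        a = list(rng.normal(30, 5, size=6))
        b = list(rng.normal(40, 5, size=8))
        fwd = compare_groups(a, b)
        rev = compare_groups(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_too_small_group_rejected(self):
        with pytest.raises(SampleSizeError):
            compare_groups([1.0], [2.0, 3.0])

    def test_power_at_three_sd_gap(self):
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            a = list(rng.normal(30.0, 5.0, size=30))
            b = list(rng.normal(45.0, 5.0, size=30))  # 3 sd gap
            if compare_groups(a, b).p_value < 0.001:
                hits += 1
        assert hits / n_runs >= 0.95


class TestEndToEndRecovery:
    def test_events_recovered_from_movie(self, small_timelapse_params):
        movie, truth_events = generate_timelapse(small_timelapse_params)
        events = extract_kill_events(movie, min_area=40.0, max_step=25.0)
        assert truth_events
        # at least 80% of truth events recovered on this small movie
        assert len(events) >= 0.8 * len(truth_events)
        # each recovered event's times are consistent
        for e in events:
            assert e.pi_time > e.contact_time

    def test_contact_times_within_one_frame_of_truth(self, small_timelapse_params):
        movie, truth_events = generate_timelapse(small_timelapse_params)
        events = extract_kill_events(movie, min_area=40.0, max_step=25.0)
        interval = small_timelapse_params.frame_interval
        matched = 0
        for te in truth_events:
            best = min(
                (abs(e.contact_time - te.contact_time) for e in events),
                default=np.inf,
            )
            if best <= interval:
                matched += 1
        assert matched / len(truth_events) >= 0.9

    def test_degenerate_delay_recovered_within_one_frame(self, small_timelapse_params):
        params = dataclasses.replace(
            small_timelapse_params, pi_delay_mean=40.0, pi_delay_sd=0.0,
            frame_interval=10.0, n_frames=30,
        )
        movie, truth_events = generate_timelapse(params)
        events = extract_kill_events(movie, min_area=40.0, max_step=30.0)
        assert events
        mean = np.mean([e.time_for_killing for e in events])
        assert abs(mean - 40.0) <= params.frame_interval
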