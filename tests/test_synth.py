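import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cytoprof.errors import ConfigError, PlacementError
from cytoprof.synth import (
    SceneParams,
    TimeLapseParams,
    generate_scene,
    generate_timelapse,
    read_events,
    read_truth_cells,
    render_cell_mask,
    write_truth,
)


class TestSceneParamsValidation:
    def test_dead_fraction_domain(self):
        with pytest.raises(ConfigError):
            SceneParams(dead_fraction=1.5)

    def test_axis_ratio_domain(self):
        with pytest.raises(ConfigError):
            SceneParams(live_axis_ratio=0.5)

    def test_field_must_be_pixel_multiple(self):
        with pytest.raises(ConfigError):
            SceneParams(field_size=(701.0, 700.0), pixel_size=2.0)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ConfigError):
            SceneParams(live_area_mean=0.0)


class TestGenerateScene:
    def test_exact_dead_count_when_integral(self):
        params = SceneParams(n_target_cells=50, dead_fraction=0.2,
                             n_effector_cells=10, seed=5)
        _, truth = generate_scene(params)
        targets = truth.targets()
        assert len(targets) == 50
        assert sum(t.state == "dead" for t in targets) == 10

    def test_no_effectors_empty_channel(self):
        params = SceneParams(n_effector_cells=0, n_target_cells=10,
                             noise_sd=0.0, seed=2)
        channels, truth = generate_scene(params)
        assert (channels["effector"].data == params.background_level).all()
        assert truth.per_bin_effector_count.sum() == 0

    def test_determinism_bit_identical(self, small_scene_params):
        ch1, tr1 = generate_scene(small_scene_params)
        ch2, tr2 = generate_scene(dataclasses.replace(small_scene_params))
        for name in ch1:
            np.testing.assert_array_equal(ch1[name].data, ch2[name].data)
        assert tr1.cells == tr2.cells

    def test_different_seeds_differ(self, small_scene_params):
        ch1, _ = generate_scene(small_scene_params)
        ch2, _ = generate_scene(dataclasses.replace(small_scene_params, seed=8))
        assert any((ch1[n].data != ch2[n].data).any() for n in ch1)

    def test_dead_stain_confined_to_dead_targets(self, small_scene_params):
        params = dataclasses.replace(small_scene_params, noise_sd=0.0)
        channels, truth = generate_scene(params)
        stained = channels["dead_stain"].data[0] > params.background_level
        footprint = np.zeros_like(stained)
        for cell in truth.targets():
            if cell.state == "dead":
                footprint |= render_cell_mask(cell, stained.shape, params.pixel_size)
        assert not (stained & ~footprint).any()
        assert (stained == footprint).all()

    def test_per_bin_counts_match_depth_recount(self, small_scene_params):
        _, truth = generate_scene(small_scene_params)
        roi = truth.roi
        recount = np.zeros(roi.n_bins, dtype=int)
        for cell in truth.effectors():
            b = roi.bin_of_depth(cell.depth)
            if b is not None:
                recount[b] += 1
        np.testing.assert_array_equal(truth.per_bin_effector_count, recount)

    def test_rendered_areas_close_to_nominal(self, small_scene_params):
        _, truth = generate_scene(small_scene_params)
        live = [c.rendered_area for c in truth.targets() if c.state == "live"]
        p = small_scene_params
        assert abs(np.mean(live) - p.live_area_mean) < 0.15 * p.live_area_mean

    def test_overcrowded_placement_fails(self):
        params = SceneParams(field_size=(100.0, 100.0), n_target_cells=100,
                             n_effector_cells=0, seed=0)
        with pytest.raises(PlacementError, match="density"):
            generate_scene(params)

    def test_true_percent_killed_bounded(self, small_scene_params):
        _, truth = generate_scene(small_scene_params)
        for v in truth.true_percent_killed:
            assert v is None or 0.0 <= v <= 100.0
        assert 0.0 <= truth.overall_percent_killed <= 100.0

    def test_decay_length_recovered_by_mle(self):
        """Truth depths follow the truncated-exponential infiltration law.

        Maximum-likelihood fit of a truncated exponential to the exported
        effector depths, averaged over 20 seeds, recovers the nominal decay
        length within 20%.
        """
        decay, depth_max = 100.0, 700.0
        fits = []
        for seed in range(20):
            params = SceneParams(n_effector_cells=500, n_target_cells=0,
                                 infiltration_decay_length=decay,
                                 allow_overlap=True, seed=seed)
            _, truth = generate_scene(params)
            depths = np.array([c.depth for c in truth.effectors()])

            def nll(L):
                return len(depths) * math.log(L * (1 - math.exp(-depth_max / L))) + depths.sum() / L

            res = minimize_scalar(nll, bounds=(10.0, 1000.0), method="bounded")
            fits.append(res.x)
        assert abs(np.mean(fits) - decay) <= 0.2 * decay

    def test_per_bin_counts_decrease_with_depth(self):
        counts = []
        for seed in range(10):
            params = SceneParams(n_effector_cells=500, n_target_cells=0,
                                 infiltration_decay_length=100.0,
                                 allow_overlap=True, seed=seed)
            _, truth = generate_scene(params)
            counts.append(truth.per_bin_effector_count)
        mean = np.mean(counts, axis=0)
        assert all(mean[i] > mean[i + 1] for i in range(1, 5))


class TestGenerateTimelapse:
    def test_no_kill_limit(self, small_timelapse_params):
        params = dataclasses.replace(small_timelapse_params,
                                     kill_probability_per_contact=0.0, noise_sd=0.0)
        movie, events = generate_timelapse(params)
        assert events == []
        for frame in movie.frames:
            assert (frame["dead_stain"].data == params.background_level).all()

    def test_degenerate_delay_gives_exact_times(self, small_timelapse_params):
        params = dataclasses.replace(small_timelapse_params,
                                     pi_delay_mean=30.0, pi_delay_sd=0.0,
                                     frame_interval=15.0)
        _, events = generate_timelapse(params)
        assert len(events) > 0
        for e in events:
            assert e.time_for_killing == 30.0
            assert e.pi_time > e.contact_time

    def test_monte_carlo_delay_mean(self):
        params = TimeLapseParams(
            field_size=(500.0, 500.0), n_target_cells=80, dead_fraction=0.0,
            n_effector_cells=100, infiltration_decay_length=400.0,
            n_frames=60, frame_interval=5.0, effector_step_sd=6.0,
            contact_distance=4.0, kill_probability_per_contact=1.0,
            pi_delay_mean=40.0, pi_delay_sd=10.0, seed=3,
        )
        _, events = generate_timelapse(params)
        assert len(events) >= 50
        times = [e.time_for_killing for e in events]
        assert abs(np.mean(times) - 40.0) <= 5.0

    def test_determinism(self, small_timelapse_params):
        m1, e1 = generate_timelapse(small_timelapse_params)
        m2, e2 = generate_timelapse(dataclasses.replace(small_timelapse_params))
        assert e1 == e2
        for f1, f2 in zip(m1.frames, m2.frames):
            for name in f1:
                np.testing.assert_array_equal(f1[name].data, f2[name].data)

    def test_contact_distance_below_pixel_rejected(self, small_timelapse_params):
        with pytest.raises(ConfigError, match="pixel"):
            dataclasses.replace(small_timelapse_params, contact_distance=1.0)

    def test_timestamps_follow_frame_interval(self, small_timelapse_params):
        movie, _ = generate_timelapse(small_timelapse_params)
        expected = [i * small_timelapse_params.frame_interval for i in range(len(movie))]
        assert movie.timestamps == expected

    def test_masks_touch_at_contact_frame(self, small_timelapse_params):
        """The pair's rendered footprints meet within one frame of contact."""
        params = dataclasses.replace(small_timelapse_params, noise_sd=0.0)
        movie, events = generate_timelapse(params)
        assert events
        interval = params.frame_interval
        for e in events:
            f = round(e.contact_time / interval)
            tgt = movie.frames[f]["target"].data[0] > params.background_level
            eff = movie.frames[f]["effector"].data[0] > params.background_level
            # dilate effector by one pixel (8-neighbourhood) and intersect
            from scipy.ndimage import binary_dilation

            assert (binary_dilation(eff, np.ones((3, 3), bool)) & tgt).any()


class TestTruthIO:
    def test_cells_round_trip(self, tmp_path, small_scene_params):
        _, truth = generate_scene(small_scene_params)
        path = write_truth(truth, tmp_path / "truth.csv")
        cells = read_truth_cells(path)
        assert cells == truth.cells
        assert len(path.read_text().strip().splitlines()) == len(truth.cells) + 1

    def test_three_cells_three_rows(self, tmp_path, small_scene_params):
        params = dataclasses.replace(small_scene_params, n_target_cells=3,
                                     n_effector_cells=0, dead_fraction=0.0)
        _, truth = generate_scene(params)
        path = write_truth(truth, tmp_path / "t.csv")
        assert len(path.read_text().strip().splitlines()) == 4  # header + 3

    def test_events_round_trip(self, tmp_path, small_timelapse_params):
        _, events = generate_timelapse(small_timelapse_params)
        path = write_truth(events, tmp_path / "events.csv")
        assert read_events(path) == events

    def test_empty_event_list(self, tmp_path):
        path = write_truth([], tmp_path / "empty.csv")
        assert read_events(path) == []
        assert path.read_text().startswith("effector_id")
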