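"""Evaluation statistics: sawtooth errors, thresholds, watershed, precision."""

import numpy as np
import pytest
from scipy import ndimage

from cellphantom import (
    GrowthTrace,
    extract_mother_trace,
    identification_error,
    mask_geometry,
    optimal_threshold,
    precision_from_stationary,
    seeded_watershed,
)
from cellphantom.pipeline import make_blob_probmap, make_clean_trace, make_error_trace


class TestExtractMotherTrace:
    def test_matches_simulator_log_within_one_superpixel(self, short_sim):
        from cellphantom import RenderIntensities, render_opl

        stacks, sim_lengths, px = [], [], None
        for frame in short_sim.frames[100:110]:
            scene = render_opl(frame, RenderIntensities(1.0, 0.0, 0.0))
            stacks.append(scene.labels)
            sim_lengths.append(frame.mother().length)
            px = scene.pixel_size
        trace = extract_mother_trace(stacks)
        err = np.abs(trace.length * px - np.array(sim_lengths)) / px
        assert err.max() <= 1.0

    def test_static_mask_gives_constant_trace(self):
        labels = np.zeros((30, 10), np.int32)
        labels[2:20, 3:7] = 1
        trace = extract_mother_trace([labels] * 5)
        assert np.all(trace.length == trace.length[0])

    def test_empty_stack_gives_empty_trace(self):
        trace = extract_mother_trace([])
        assert trace.length.size == 0

    def test_empty_frame_marked_as_gap(self):
        labels = np.zeros((30, 10), np.int32)
        labels[2:20, 3:7] = 1
        trace = extract_mother_trace([labels, np.zeros_like(labels), labels])
        assert np.isnan(trace.length[1])
        assert np.isfinite(trace.length[[0, 2]]).all()


class TestIdentificationError:
    def test_clean_simulated_sawtooth_has_zero_rate(self):
        trace = make_clean_trace(seed=5)
        assert identification_error(trace) == 0.0

    @pytest.mark.parametrize("n_errors", [1, 5, 10])
    def test_injected_one_frame_dips_counted_exactly(self, n_errors):
        trace = make_clean_trace(seed=5, n_timepoints=499)
        n = trace.length.size
        eps = n_errors / n
        err_trace = make_error_trace(eps, seed=5, n_timepoints=499)
        assert identification_error(err_trace) == pytest.approx(eps, abs=1e-12)

    def test_constant_trace_has_zero_rate(self):
        trace = GrowthTrace(0, np.arange(50), np.full(50, 3.0))
        assert identification_error(trace) == 0.0

    def test_spike_also_counted(self):
        # increase-then-decrease is as spurious as a dip
        l = np.full(100, 3.0)
        l[40] = 3.6
        rate = identification_error(GrowthTrace(0, np.arange(100), l))
        assert rate == pytest.approx(1 / 100)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            identification_error(GrowthTrace(0, np.arange(2), np.ones(2)))


class TestOptimalThreshold:
    def test_binary_truth_map_returns_lowest_argmax(self):
        truth = np.zeros((20, 20), np.int32)
        truth[5:15, 5:15] = 1
        result = optimal_threshold(truth.astype(float), truth)
        assert result.threshold == pytest.approx(0.50)
        assert result.jaccard.max() == pytest.approx(1.0)

    def test_blurred_truth_matches_fine_grid_scan(self):
        truth = np.zeros((40, 40), np.int32)
        truth[10:30, 15:25] = 1
        pmap = ndimage.gaussian_filter(truth.astype(float), 2.0)
        pmap = np.clip(pmap / pmap.max(), 0, 1)
        grid = np.arange(0.05, 0.95, 0.005)
        result = optimal_threshold(pmap, truth, grid=grid)
        # independent brute-force fine scan
        fine = np.arange(0.05, 0.95, 0.0005)
        scores = [
            np.logical_and(pmap > t, truth > 0).sum()
            / np.logical_or(pmap > t, truth > 0).sum()
            for t in fine
        ]
        best_fine = fine[int(np.argmax(scores))]
        assert abs(result.threshold - best_fine) <= 0.005

    def test_all_zero_map_rejected(self):
        truth = np.zeros((10, 10), np.int32)
        truth[2:5, 2:5] = 1
        with pytest.raises(ValueError):
            optimal_threshold(np.zeros((10, 10)), truth)

    def test_map_outside_unit_interval_rejected(self):
        truth = np.zeros((10, 10), np.int32)
        with pytest.raises(ValueError):
            optimal_threshold(np.full((10, 10), 1.5), truth)

    def test_distribution_intersection_statistic_peaks_at_truth(self):
        truth = np.zeros((40, 40), np.int32)
        truth[5:20, 10:18] = 1
        truth[25:38, 10:18] = 2
        pmap = ndimage.gaussian_filter((truth > 0).astype(float), 1.0)
        pmap = np.clip(pmap / pmap.max(), 0, 1)
        result = optimal_threshold(pmap, truth, with_distribution_statistic=True)
        assert result.distribution_intersection is not None
        best = result.grid[int(np.argmax(result.distribution_intersection))]
        assert abs(best - result.threshold) < 0.2


class TestSeededWatershed:
    def test_two_separated_blobs_two_labels(self):
        pmap = np.zeros((40, 40))
        pmap[5:15, 5:15] = 0.9999
        pmap[25:35, 25:35] = 0.9999
        labels = seeded_watershed(pmap, t_opt=0.5)
        assert len(np.unique(labels)) - 1 == 2

    def test_blobs_merged_at_topt_split_along_watershed_line(self):
        pmap = make_blob_probmap(seed=0)
        merged, n_merged = ndimage.label(pmap > 0.5)
        assert n_merged == 1  # fixture: single component at t_opt
        labels = seeded_watershed(pmap, t_opt=0.5, t_seed=0.95)
        assert len(np.unique(labels)) - 1 == 2

    def test_labels_partition_the_foreground(self):
        pmap = make_blob_probmap(seed=1)
        labels = seeded_watershed(pmap, t_opt=0.5, t_seed=0.95)
        fg = pmap > 0.5
        assert np.array_equal(labels > 0, fg)

    def test_bad_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            seeded_watershed(np.zeros((5, 5)), t_opt=0.999, t_seed=0.5)

    def test_no_seeds_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            labels = seeded_watershed(np.full((5, 5), 0.7), t_opt=0.6, t_seed=0.999)
        assert np.all(labels == 0)


class TestPrecisionFromStationary:
    def test_exact_quadratic_gives_zero(self):
        x = np.arange(50, dtype=float)
        seg = 3.0 + 0.01 * x - 1e-4 * x**2
        assert precision_from_stationary([seg]) == pytest.approx(0.0, abs=1e-10)

    def test_recovers_injected_noise_sd(self):
        rng = np.random.default_rng(4)
        x = np.arange(1000, dtype=float)
        seg = 5.0 + 1e-3 * x - 1e-6 * x**2 + rng.normal(0.0, 0.04, x.size)
        assert precision_from_stationary([seg]) == pytest.approx(0.04, rel=0.1)

    def test_short_segments_skipped_with_warning(self):
        rng = np.random.default_rng(4)
        long_seg = 5.0 + rng.normal(0, 0.02, 100)
        with pytest.warns(UserWarning):
            value = precision_from_stationary([np.ones(3), long_seg])
        assert value == pytest.approx(0.02, rel=0.3)

    def test_all_segments_short_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                precision_from_stationary([np.ones(3)])


class TestMaskGeometry:
    def test_axis_aligned_rectangle(self):
        labels = np.zeros((60, 60), np.int32)
        labels[10:50, 20:30] = 1
        length, width = mask_geometry(labels)[1]
        assert length == pytest.approx(40.0, abs=0.5)
        assert width == pytest.approx(10.0, abs=0.5)

    def test_rotation_invariant_within_one_pixel(self):
        from skimage.transform import rotate

        labels = np.zeros((80, 80), np.int32)
        labels[20:60, 35:45] = 1
        rotated = rotate(labels.astype(float), 37.0, order=0, preserve_range=True)
        rotated = (rotated > 0.5).astype(np.int32)
        l0, w0 = mask_geometry(labels)[1]
        l1, w1 = mask_geometry(rotated)[1]
        assert abs(l1 - l0) <= 1.5
        assert abs(w1 - w0) <= 1.5

    def test_rendered_cell_dimensions_recovered(self):
        from cellphantom import RenderIntensities, render_opl
        from cellphantom.growth import CellAgent, SceneFrame, TrenchGeometry

        cell = CellAgent(id=1, parent_id=None, length=4.0, width=1.0, x=3.0,
                         birth_length=4.0, division_threshold=8.0)
        scene = render_opl(SceneFrame(0, [cell], TrenchGeometry(length=10.0)),
                           RenderIntensities(1.0, 0.0, 0.0))
        length_px, width_px = mask_geometry(scene.labels)[1]
        px = scene.pixel_size
        assert length_px * px == pytest.approx(4.0, abs=2 * px * 3)
        assert width_px * px == pytest.approx(1.0, abs=px * 3)

    def test_single_pixel_label_flagged(self):
        labels = np.zeros((5, 5), np.int32)
        labels[2, 2] = 1
        with pytest.warns(UserWarning):
            assert mask_geometry(labels)[1] == (1.0, 1.0)
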