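"""Unit and property tests for nuclei tracking and the regularized watershed."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from skimage.morphology import disk

from qpi_deathwatch.synthetic_scenes import SceneConfig, generate_scene
from qpi_deathwatch.tracking import (
    GaussianComponent,
    TrackingParams,
    TrackletInfo,
    _per_label_erosion,
    em_update,
    filter_complete_tracklets,
    initialize_tracks,
    movement_regularized_watershed,
    mser_nuclei_foreground,
    segment_foreground,
    split_nuclei_masks,
    track_sequence,
)


def _gauss_spot(H, W, center, sigma=3.5, amp=1.0):
    rr, cc = np.mgrid[0:H, 0:W]
    return amp * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


class TestSegmentForeground:
    def test_all_zero_frame_gives_empty_mask(self):
        assert not segment_foreground(np.zeros((32, 32)), 0.1).any()

    def test_threshold_above_max_gives_empty_mask(self):
        frame = np.full((16, 16), 0.5)
        assert not segment_foreground(frame, 0.6).any()

    def test_blob_area_close_to_ground_truth(self):
        cfg = SceneConfig(n_cells=1, T=1, H=160, W=160, noise_sd=0.0, seed=0)
        seq, gt, _, _ = generate_scene(cfg)
        # threshold well below the blob peak: the cosine-tapered rim thins
        # the mask relative to the exact render support
        threshold = 0.003 * seq.phase[0].max()
        mask = segment_foreground(seq.phase[0], threshold)
        gt_area = (gt.labels[0] > 0).sum()
        assert abs(mask.sum() - gt_area) < 0.1 * gt_area


class TestMser:
    def test_blank_frame_gives_empty_mask(self):
        assert not mser_nuclei_foreground(np.zeros((32, 32))).any()

    def test_two_spots_detected_and_contain_centers(self):
        img = _gauss_spot(96, 96, (30, 30)) + _gauss_spot(96, 96, (70, 64))
        mask = mser_nuclei_foreground(img)
        labels, n = ndi.label(mask)
        assert n >= 2
        assert mask[30, 30] and mask[70, 64]

    def test_saturated_disk_gives_one_region_covering_it(self):
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        d = (rr - 32) ** 2 + (cc - 32) ** 2 < 10**2
        img[d] = 1.0
        mask = mser_nuclei_foreground(img)
        labels, n = ndi.label(mask)
        assert n == 1
        assert (mask & d).sum() == d.sum()


class TestInitializeTracks:
    def test_components_have_identity_covariance_and_equal_weights(self):
        comps = initialize_tracks([(10, 10), (20, 30), (40, 5)])
        assert len(comps) == 3
        for c in comps:
            np.testing.assert_array_equal(c.covariance, np.eye(2))
            assert c.weight == pytest.approx(1 / 3)

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            initialize_tracks([(10, 10), (10, 10)])

    def test_no_seeds_gives_empty_set(self):
        assert initialize_tracks([]) == []


class TestEmUpdate:
    def test_fixed_point_on_stationary_spot(self):
        img = _gauss_spot(64, 64, (32, 32))
        fg = img > 0.05
        comps = [GaussianComponent(1, np.array([32.0, 32.0]), 12 * np.eye(2), 1.0)]
        out, lost, hist = em_update(comps, img, fg, n_steps=5)
        assert not lost
        assert np.linalg.norm(out[0].mean - [32, 32]) < 0.1

    def test_recovers_3px_displacement(self):
        img = _gauss_spot(64, 64, (35, 32))
        fg = img > 0.05
        comps = [GaussianComponent(1, np.array([32.0, 32.0]), 12 * np.eye(2), 1.0)]
        out, _, _ = em_update(comps, img, fg, n_steps=5)
        assert np.linalg.norm(out[0].mean - [35, 32]) < 0.5

    def test_two_separated_spots_keep_identities(self):
        img = _gauss_spot(96, 96, (30, 30)) + _gauss_spot(96, 96, (70, 64))
        fg = img > 0.05
        comps = [
            GaussianComponent(1, np.array([28.0, 31.0]), 12 * np.eye(2), 0.5),
            GaussianComponent(2, np.array([72.0, 62.0]), 12 * np.eye(2), 0.5),
        ]
        out, _, _ = em_update(comps, img, fg, n_steps=5)
        assert np.linalg.norm(out[0].mean - [30, 30]) < np.linalg.norm(out[0].mean - [70, 64])
        assert np.linalg.norm(out[1].mean - [70, 64]) < np.linalg.norm(out[1].mean - [30, 30])

    def test_loglik_non_decreasing(self):
        img = _gauss_spot(96, 96, (30, 30)) + _gauss_spot(96, 96, (44, 40))
        fg = img > 0.03
        comps = [
            GaussianComponent(1, np.array([28.0, 28.0]), 10 * np.eye(2), 0.5),
            GaussianComponent(2, np.array([46.0, 42.0]), 10 * np.eye(2), 0.5),
        ]
        _, _, hist = em_update(comps, img, fg, n_steps=8)
        for h in hist.values():
            diffs = np.diff(h)
            assert np.all(diffs >= -1e-8 * np.abs(h[:-1]))

    def test_stranded_component_flagged_lost(self):
        img = _gauss_spot(64, 64, (32, 32))
        fg = img > 0.05
        comps = [GaussianComponent(1, np.array([5.0, 60.0]), np.eye(2), 1.0)]
        _, lost, _ = em_update(comps, img, fg, n_steps=3)
        assert lost == {1}


class TestSplitNucleiMasks:
    def test_single_component_claims_all_foreground(self):
        fg = np.zeros((32, 32), dtype=bool)
        fg[10:20, 10:20] = True
        comps = [GaussianComponent(7, np.array([15.0, 15.0]), 4 * np.eye(2), 1.0)]
        labels = split_nuclei_masks(comps, fg)
        assert set(np.unique(labels[fg])) == {7}
        assert (labels[~fg] == 0).all()

    def test_symmetric_components_split_along_bisector(self):
        fg = np.zeros((21, 41), dtype=bool)
        fg[5:16, 5:36] = True
        comps = [
            GaussianComponent(1, np.array([10.0, 12.0]), 4 * np.eye(2), 0.5),
            GaussianComponent(2, np.array([10.0, 28.0]), 4 * np.eye(2), 0.5),
        ]
        labels = split_nuclei_masks(comps, fg)
        assert (labels[fg & (np.arange(41)[None, :] < 20)] == 1).all()
        assert (labels[fg & (np.arange(41)[None, :] > 20)] == 2).all()

    def test_touching_nuclei_split_matches_ground_truth(self):
        a = _gauss_spot(64, 64, (32, 26))
        b = _gauss_spot(64, 64, (32, 40))
        img = a + b
        fg = img > 0.05
        comps = [
            GaussianComponent(1, np.array([32.0, 26.0]), 12 * np.eye(2), 0.5),
            GaussianComponent(2, np.array([32.0, 40.0]), 12 * np.eye(2), 0.5),
        ]
        comps, _, _ = em_update(comps, img, fg, n_steps=5)
        labels = split_nuclei_masks(comps, fg)
        truth = np.where(a >= b, 1, 2)
        agree = (labels[fg] == truth[fg]).mean()
        assert agree >= 0.9


class TestMovementRegularizedWatershed:
    def _two_cell_frame(self, shift=0):
        phase = np.zeros((64, 96))
        rr, cc = np.mgrid[0:64, 0:96]
        for amp, (r0, c0) in ((1.0, (32, 30 + shift)), (0.8, (32, 62 + shift))):
            d = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2) / 18
            phase += amp * np.where(d < 1, np.cos(np.pi * d / 2) ** 2, 0)
        seeds = np.zeros((64, 96), dtype=np.int64)
        seeds[32, 30 + shift] = 1
        seeds[32, 62 + shift] = 2
        return phase, phase > 0.05, seeds

    def test_static_scene_is_idempotent(self):
        phase, fg, seeds = self._two_cell_frame()
        s0, f0 = movement_regularized_watershed(phase, fg, seeds)
        s1, _ = movement_regularized_watershed(
            phase, fg, seeds, prev_labels=s0, prev_foreground=f0, r_e=3, r_d=3
        )
        np.testing.assert_array_equal(s0, s1)

    def test_prior_owner_pixels_never_switch(self):
        phase0, fg0, seeds0 = self._two_cell_frame(0)
        s0, f0 = movement_regularized_watershed(phase0, fg0, seeds0)
        phase1, fg1, seeds1 = self._two_cell_frame(4)
        s1, f1 = movement_regularized_watershed(
            phase1, fg1, seeds1, prev_labels=s0, prev_foreground=f0, r_e=3, r_d=3
        )
        s_hat = _per_label_erosion(s0, 3)
        switched = (s_hat > 0) & (s1 > 0) & (s1 != s_hat)
        assert switched.sum() == 0

    def test_growth_bounded_by_dilated_previous_foreground(self):
        phase0, fg0, seeds0 = self._two_cell_frame(0)
        s0, f0 = movement_regularized_watershed(phase0, fg0, seeds0)
        phase1, fg1, seeds1 = self._two_cell_frame(5)
        s1, _ = movement_regularized_watershed(
            phase1, fg1, seeds1, prev_labels=s0, prev_foreground=f0, r_e=3, r_d=3
        )
        f_hat = ndi.binary_dilation(f0, structure=disk(3))
        assert ((s1 > 0) & ~f_hat).sum() == 0

    def test_new_distant_blob_excluded(self):
        phase0, fg0, seeds0 = self._two_cell_frame(0)
        s0, f0 = movement_regularized_watershed(phase0, fg0, seeds0)
        phase1 = phase0.copy()
        phase1[5:12, 85:92] = 1.0  # a cell appearing far from everything
        fg1 = phase1 > 0.05
        s1, f1 = movement_regularized_watershed(
            phase1, fg1, seeds0, prev_labels=s0, prev_foreground=f0, r_e=3, r_d=3
        )
        assert (s1[5:12, 85:92] == 0).all()
        assert not f1[5:12, 85:92].any()


class TestTrackSequence:
    def test_small_scene_all_tracklets_complete(self, small_scene):
        cfg, seq, gt, centers, _ = small_scene
        trackset, masks, info = track_sequence(
            seq,
            [tuple(c) for c in centers[0]],
            TrackingParams(foreground_threshold=0.1),
        )
        kept = filter_complete_tracklets(masks, trackset, info)
        assert kept == [1, 2, 3, 4]
        # label-id bijection: every nonzero label is a live track id
        assert set(np.unique(masks.labels)) - {0} <= {1, 2, 3, 4}

    def test_empty_seed_list_gives_empty_outputs(self, small_scene):
        cfg, seq, *_ = small_scene
        trackset, masks, info = track_sequence(
            seq, [], TrackingParams(foreground_threshold=0.1)
        )
        assert masks.labels.max() == 0
        assert filter_complete_tracklets(masks, trackset, info) == []

    def test_missing_nuclei_channel_rejected(self, small_scene):
        cfg, seq, *_ = small_scene
        seq.channels.pop("nuclei")
        with pytest.raises(ValueError, match="nuclei"):
            track_sequence(seq, [(10, 10)], TrackingParams())

    def test_cell_disappearing_midway_is_excluded(self):
        cfg = SceneConfig(n_cells=3, T=20, H=220, W=220, noise_sd=0.0, seed=11)
        seq, gt, centers, _ = generate_scene(cfg)
        # erase cell 2 (phase and nuclei) from frame 10 on
        for t in range(10, cfg.T):
            gone = gt.labels[t] == 2
            seq.channels["phase"][t][gone] = 0.0
            seq.channels["nuclei"][t][gone] = 0.0
        trackset, masks, info = track_sequence(
            seq,
            [tuple(c) for c in centers[0]],
            TrackingParams(foreground_threshold=0.1),
        )
        kept = filter_complete_tracklets(masks, trackset, info)
        assert 2 not in kept
        assert {1, 3} <= set(kept)


class TestTrackletFilter:
    def test_complete_ids_exclude_lost_merged_and_empty(self):
        info = TrackletInfo(
            empty_frames={1: [], 2: [50], 3: [], 4: []},
            merged_ids={4},
            lost_ids={3},
        )
        assert info.complete_ids([1, 2, 3, 4]) == [1]
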