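"""Vision pipeline: colour mask, opening, blobs, selection, smoothing, tracking."""

import colorsys
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lasertrack import (
    Blob,
    ColorSpec,
    SceneConfig,
    TrackerParams,
    TrackState,
    color_mask,
    default_red_spec,
    extract_blobs,
    morphological_clean,
    render_frame,
    select_target,
    track_sequence,
    update_track,
)
from lasertrack.scene import iter_scene
from lasertrack.tracking import rgb_to_hsv_deg

from _oracles import flood_components, mask_oracle, opening_oracle


def random_mask(rng, shape=(32, 32), p=0.3):
    return rng.random(shape) < p


class TestColorMask:
    def test_black_frame_is_all_background(self, red_spec):
        frame = np.zeros((16, 16, 3), dtype=np.uint8)
        assert not color_mask(frame, red_spec).any()

    def test_uniform_in_bounds_color_is_all_foreground(self, red_spec):
        frame = np.full((16, 16, 3), (200, 30, 30), dtype=np.uint8)
        assert color_mask(frame, red_spec).all()

    def test_rendered_frame_matches_per_pixel_oracle(self, red_spec):
        scene = SceneConfig(
            image_width_px=48, image_height_px=48, body_axes_px=(9.0, 4.0),
            marker_radius_px=3.0, noise_sigma=4.0, n_frames=1, seed=3,
        )
        frame, _ = render_frame(scene, (0.09, 0.12), rng=np.random.default_rng(3))
        np.testing.assert_array_equal(color_mask(frame, red_spec), mask_oracle(frame, red_spec))

    def test_rgb_space_mask_matches_oracle(self, rng):
        spec = ColorSpec(space="rgb", windows=(((120, 0, 0), (255, 80, 80)),))
        frame = rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)
        np.testing.assert_array_equal(color_mask(frame, spec), mask_oracle(frame, spec))

    def test_malformed_bounds_rejected(self):
        with pytest.raises(ValueError):
            ColorSpec(space="hsv", windows=(((20.0, 0.5, 0.5), (10.0, 1.0, 1.0)),))
        with pytest.raises(ValueError):
            ColorSpec(space="hsv", windows=())
        with pytest.raises(ValueError):
            ColorSpec(space="xyz", windows=(((0, 0, 0), (1, 1, 1)),))

    def test_non_uint8_frame_rejected(self, red_spec):
        with pytest.raises(ValueError):
            color_mask(np.zeros((4, 4, 3), dtype=float), red_spec)

    def test_hsv_conversion_agrees_with_colorsys(self, rng):
        frame = rng.integers(0, 256, (12, 12, 3), dtype=np.uint8)
        hsv = rgb_to_hsv_deg(frame)
        for v in range(12):
            for u in range(12):
                r, g, b = (int(c) for c in frame[v, u])
                h0, s0, v0 = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)
                assert hsv[v, u, 0] / 360.0 == pytest.approx(h0, abs=1e-12)
                assert hsv[v, u, 1] == pytest.approx(s0, abs=1e-12)
                assert hsv[v, u, 2] == pytest.approx(v0, abs=1e-12)


class TestMorphologicalClean:
    def test_radius_zero_is_identity(self, rng):
        m = random_mask(rng)
        out = morphological_clean(m, 0)
        np.testing.assert_array_equal(out, m)
        assert out is not m

    def test_isolated_pixel_vanishes_at_radius_one(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert not morphological_clean(m, 1).any()

    def test_matches_sliding_window_oracle(self, rng):
        for _ in range(5):
            m = random_mask(rng, shape=(24, 24), p=0.45)
            np.testing.assert_array_equal(morphological_clean(m, 2), opening_oracle(m, 2))

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            morphological_clean(np.zeros((4, 4), dtype=bool), -1)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), radius=st.integers(0, 3))
    def test_opening_is_anti_extensive_and_idempotent(self, seed, radius):
        m = random_mask(np.random.default_rng(seed), shape=(20, 20), p=0.5)
        opened = morphological_clean(m, radius)
        assert not (opened & ~m).any()  # output subset of input
        np.testing.assert_array_equal(morphological_clean(opened, radius), opened)


class TestExtractBlobs:
    def test_empty_mask_gives_no_blobs(self):
        assert extract_blobs(np.zeros((8, 8), dtype=bool)) == []

    def test_single_pixel_blob(self):
        m = np.zeros((32, 32), dtype=bool)
        m[20, 10] = True  # v=20, u=10
        (b,) = extract_blobs(m)
        assert (b.pixel_count, b.centroid_u, b.centroid_v) == (1, 10.0, 20.0)

    def test_filled_rectangle_centroid(self):
        m = np.zeros((16, 16), dtype=bool)
        m[3:10, 2:7] = True  # u in [2,6], v in [3,9]
        (b,) = extract_blobs(m)
        assert (b.centroid_u, b.centroid_v) == (4.0, 6.0)
        assert b.bbox == (2, 3, 6, 9)

    def test_sorted_by_size_then_position(self):
        m = np.zeros((20, 20), dtype=bool)
        m[1:3, 1:3] = True     # 4 px, upper left
        m[10:14, 10:14] = True  # 16 px
        m[16:18, 2:4] = True   # 4 px, lower left
        blobs = extract_blobs(m)
        assert [b.pixel_count for b in blobs] == [16, 4, 4]
        assert blobs[1].centroid_v < blobs[2].centroid_v

    def test_centroids_match_flood_fill_oracle(self, rng):
        for _ in range(5):
            m = random_mask(rng, shape=(30, 30), p=0.25)
            blobs = extract_blobs(m)
            comps = flood_components(m)
            assert len(blobs) == len(comps)
            expected = sorted(
                (
                    (
                        -len(c),
                        float(np.mean([v for v, _ in c])),
                        float(np.mean([u for _, u in c])),
                    )
                    for c in comps
                ),
            )
            for b, (negn, cv, cu) in zip(blobs, expected):
                assert b.pixel_count == -negn
                assert abs(b.centroid_u - cu) < 1e-9
                assert abs(b.centroid_v - cv) < 1e-9


def _blob(n, u, v):
    return Blob(pixel_count=n, centroid_u=u, centroid_v=v, bbox=(0, 0, 1, 1))


class TestSelectTarget:
    def test_no_blobs_gives_none(self):
        assert select_target([], None, TrackerParams()) is None

    def test_largest_wins_without_history(self):
        blobs = [_blob(50, 5, 5), _blob(200, 30, 30)]
        sel = select_target(blobs, None, TrackerParams())
        assert sel.pixel_count == 200

    def test_nearest_wins_with_history(self):
        prev = TrackState(0, (10.0, 10.0), (10.0, 10.0), found=True)
        near = _blob(100, 13, 14)   # 5 px away
        far = _blob(100, 40, 50)    # 50 px away
        sel = select_target([far, near], prev, TrackerParams(max_jump_px=30.0))
        assert sel is near

    def test_small_blobs_discarded(self):
        assert select_target([_blob(3, 5, 5)], None, TrackerParams(min_blob_px=20)) is None

    def test_falls_back_to_largest_when_all_far(self):
        prev = TrackState(0, (0.0, 0.0), (0.0, 0.0), found=True)
        blobs = [_blob(100, 200, 200), _blob(300, 150, 150)]
        sel = select_target(blobs, prev, TrackerParams(max_jump_px=30.0))
        assert sel.pixel_count == 300


class TestUpdateTrack:
    def test_alpha_one_means_no_smoothing(self):
        params = TrackerParams(ema_alpha=1.0)
        s = update_track(None, _blob(10, 4, 6), params)
        s = update_track(s, _blob(10, 8, 2), params)
        assert s.smoothed_centroid == s.raw_centroid == (8.0, 2.0)

    def test_ema_arithmetic(self):
        params = TrackerParams(ema_alpha=0.5)
        prev = TrackState(0, (0.0, 0.0), (0.0, 0.0), found=True)
        s = update_track(prev, _blob(10, 10, 10), params)
        assert s.smoothed_centroid == (5.0, 5.0)
        assert s.found and s.hold_counter == 0

    def test_hold_then_drop(self):
        params = TrackerParams(hold_frames=3)
        s = update_track(None, _blob(10, 7, 7), params)
        for k in range(3):
            s = update_track(s, None, params)
            assert s.smoothed_centroid == (7.0, 7.0)
            assert not s.found and s.hold_counter == k + 1
        s = update_track(s, None, params)
        assert s.smoothed_centroid is None
        assert s.hold_counter == 4

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        alpha=st.floats(0.01, 1.0),
        prev_u=st.floats(-100, 100),
        raw_u=st.floats(-100, 100),
    )
    def test_smoothed_lies_between_previous_and_raw(self, alpha, prev_u, raw_u):
        params = TrackerParams(ema_alpha=alpha)
        prev = TrackState(0, (prev_u, 0.0), (prev_u, 0.0), found=True)
        s = update_track(prev, _blob(10, raw_u, 0.0), params)
        lo, hi = min(prev_u, raw_u), max(prev_u, raw_u)
        assert lo - 1e-9 <= s.smoothed_centroid[0] <= hi + 1e-9


class TestTrackSequence:
    def test_noise_free_sequence_tracks_ground_truth(self, small_scene, motion, red_spec, small_tracker):
        pairs = list(iter_scene(small_scene, motion))
        states = track_sequence([f for f, _ in pairs], red_spec, small_tracker)
        assert len(states) == small_scene.n_frames
        for s, (_, gt) in zip(states, pairs):
            assert s.found
            err = math.hypot(
                s.raw_centroid[0] - gt.marker_u_px, s.raw_centroid[1] - gt.marker_v_px
            )
            assert err <= 0.5

    def test_all_black_sequence_never_finds_target(self, red_spec, small_tracker):
        frames = [np.zeros((32, 32, 3), dtype=np.uint8)] * 5
        states = track_sequence(frames, red_spec, small_tracker)
        assert all(not s.found for s in states)

    def test_occlusion_shorter_than_hold_keeps_smoothed(self, small_scene, motion, red_spec):
        scene = SceneConfig(**{**vars(small_scene), "occlusion_intervals": ((10, 18),)})
        params = TrackerParams(opening_radius_px=1, min_blob_px=5, hold_frames=15)
        states = track_sequence((f for f, _ in iter_scene(scene, motion)), red_spec, params)
        assert all(s.smoothed_centroid is not None for s in states)
        assert not any(s.found for s in states[10:18])

    def test_empty_source_rejected(self, red_spec, small_tracker):
        with pytest.raises(ValueError):
            track_sequence([], red_spec, small_tracker)

    def test_directory_source(self, tmp_path, small_scene, motion, red_spec, small_tracker):
        from lasertrack import generate_dataset

        scene = SceneConfig(**{**vars(small_scene), "n_frames": 5})
        generate_dataset(scene, motion, tmp_path)
        states = track_sequence(tmp_path, red_spec, small_tracker)
        assert len(states) == 5
        assert all(s.found for s in states)

    def test_translation_equivariance(self, small_scene, red_spec, small_tracker):
        frame, _ = render_frame(small_scene, (0.07, 0.09))
        du, dv = 11, -6
        shifted = np.roll(frame, (dv, du), axis=(0, 1))
        (s0,) = track_sequence([frame], red_spec, small_tracker)
        (s1,) = track_sequence([shifted], red_spec, small_tracker)
        assert s1.raw_centroid[0] - s0.raw_centroid[0] == pytest.approx(du, abs=1e-9)
        assert s1.raw_centroid[1] - s0.raw_centroid[1] == pytest.approx(dv, abs=1e-9)
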