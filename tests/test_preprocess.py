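"""Splitting, augmentation geometry, and label-transform consistency."""

import numpy as np
import pytest

from flowpose.labels import KeypointAnnotation, generate_heatmap
from flowpose.metrics import argmax_location
from flowpose.preprocess import (
    AugmentSpec,
    SplitSpec,
    flip_with_labels,
    make_training_target,
    random_augment,
    resize_area_with_labels,
    rotate_with_labels,
    split_dataset,
    video_of,
)


def _blob_frame(x, y, size=64, sigma=2.0):
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)))


def _centroid(frame):
    total = frame.sum()
    yy, xx = np.mgrid[0 : frame.shape[0], 0 : frame.shape[1]]
    return (xx * frame).sum() / total, (yy * frame).sum() / total


class TestSplit:
    def test_three_one_one_sizing(self):
        ids = [f"v0_{i}" for i in range(500)]
        train, val, test = split_dataset(ids, SplitSpec(seed=3))
        assert (len(train), len(val), len(test)) == (300, 100, 100)
        assert set(train) | set(val) | set(test) == set(ids)
        assert not (set(train) & set(val)) and not (set(val) & set(test))

    def test_deterministic_for_fixed_seed(self):
        ids = [f"f{i}" for i in range(101)]
        a = split_dataset(ids, SplitSpec(seed=7))
        b = split_dataset(ids, SplitSpec(seed=7))
        assert a == b
        c = split_dataset(ids, SplitSpec(seed=8))
        assert a != c

    def test_video_grouping_keeps_videos_whole(self):
        ids = [f"vid{v}/frame{i:03d}" for v in range(5) for i in range(100)]
        train, val, test = split_dataset(
            ids, SplitSpec(group_by="video_id", seed=0)
        )
        for part in (train, val, test):
            videos = {video_of(f) for f in part}
            for other in (train, val, test):
                if other is part:
                    continue
                assert not (videos & {video_of(f) for f in other})
        assert len(train) + len(val) + len(test) == 500

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="group"):
            split_dataset(
                ["v0/a", "v0/b", "v1/a"], SplitSpec(group_by="video_id")
            )


class TestRotation:
    def test_zero_angle_is_identity(self):
        frame = np.arange(64, dtype=float).reshape(8, 8)
        anns = [KeypointAnnotation("f", "kp", 3.0, 5.0, 3, 3)]
        out, out_anns = rotate_with_labels(frame, anns, 0.0)
        np.testing.assert_array_equal(out, frame)
        assert out_anns[0].x == 3.0 and out_anns[0].y == 5.0

    def test_quarter_turn_on_square_maps_coordinates(self):
        size = 21
        frame = np.zeros((size, size))
        anns = [KeypointAnnotation("f", "kp", 4.0, 15.0, 3, 3)]
        _, out_anns = rotate_with_labels(frame, anns, 90.0)
        # (x, y) -> (W-1-y, x) for a quarter turn on a square canvas
        assert out_anns[0].x == pytest.approx(size - 1 - 15.0, abs=1e-9)
        assert out_anns[0].y == pytest.approx(4.0, abs=1e-9)

    def test_blob_centroid_follows_label_map(self):
        frame = _blob_frame(24.0, 40.0)
        anns = [KeypointAnnotation("f", "kp", 24.0, 40.0, 9, 9)]
        out, out_anns = rotate_with_labels(frame, anns, 7.3)
        cx, cy = _centroid(out)
        assert abs(cx - out_anns[0].x) < 1.0
        assert abs(cy - out_anns[0].y) < 1.0

    def test_canvas_expands_without_cropping(self):
        frame = np.ones((20, 40))
        out, _ = rotate_with_labels(frame, [], 45.0)
        assert out.shape[0] > 20 and out.shape[1] > 40
        # all original mass retained (padding is black)
        assert out.sum() == pytest.approx(frame.sum(), rel=0.02)


class TestFlip:
    def test_double_flip_is_identity(self, rng):
        frame = rng.random((12, 10))
        anns = [KeypointAnnotation("f", "kp", 3.0, 5.0, 3, 3)]
        once = flip_with_labels(frame, anns, "y")
        twice = flip_with_labels(*once[:2], "y")
        np.testing.assert_array_equal(twice[0], frame)
        assert twice[1] == anns

    def test_mirror_formula(self):
        frame = np.zeros((12, 10))
        anns = [KeypointAnnotation("f", "kp", 3.0, 5.0, 3, 3)]
        _, out = flip_with_labels(frame, anns, "y")
        assert (out[0].x, out[0].y) == (6.0, 5.0)
        _, out = flip_with_labels(frame, anns, "x")
        assert (out[0].x, out[0].y) == (3.0, 6.0)
        _, out = flip_with_labels(frame, anns, "xy")
        assert (out[0].x, out[0].y) == (6.0, 6.0)

    def test_swap_map_exchanges_names(self):
        frame = np.zeros((10, 10))
        anns = [
            KeypointAnnotation("f", "L", 2.0, 4.0, 3, 3),
            KeypointAnnotation("f", "R", 7.0, 4.0, 3, 3),
        ]
        _, out = flip_with_labels(frame, anns, "y", swap_map={"L": "R"})
        assert [a.keypoint for a in out] == ["R", "L"]
        assert out[0].x == 7.0 and out[1].x == 2.0

    def test_non_bijective_swap_rejected(self):
        with pytest.raises(ValueError, match="bijection"):
            flip_with_labels(
                np.zeros((4, 4)), [], "y", swap_map={"a": "b", "b": "c"}
            )


class TestResize:
    def test_linear_coordinate_scaling(self):
        frame = np.zeros((100, 200))
        anns = [KeypointAnnotation("f", "kp", 60.0, 30.0, 8, 8)]
        out, out_anns = resize_area_with_labels(frame, anns, 100, 50)
        assert out.shape == (50, 100)
        assert (out_anns[0].x, out_anns[0].y) == (30.0, 15.0)
        assert out_anns[0].box_w == 4 and out_anns[0].box_h == 4

    def test_constant_image_preserved(self):
        frame = np.full((40, 40), 0.37)
        out, _ = resize_area_with_labels(frame, [], 13, 13)
        np.testing.assert_allclose(out, 0.37, atol=1e-12)

    def test_checkerboard_area_mean(self):
        frame = np.array([[0.0, 1.0], [1.0, 0.0]])
        out, _ = resize_area_with_labels(frame, [], 1, 1)
        assert out[0, 0] == pytest.approx(0.5)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            resize_area_with_labels(np.zeros((4, 4)), [], 0, 4)


class TestTrainingTarget:
    def test_peak_scaling_and_stage_copies(self):
        from flowpose.labels import stack_labels

        anns = [KeypointAnnotation("f", "kp", 8.0, 8.0, 7, 7)]
        stack = stack_labels(anns, ["kp"], 16, 16)
        targets = make_training_target(stack, peak=16.0, stages=2)
        assert len(targets) == 2
        for t in targets:
            assert t.data.max() == pytest.approx(16.0)
        np.testing.assert_array_equal(targets[0].data, targets[1].data)
        # identity at peak 1
        same = make_training_target(stack, peak=1.0, stages=1)[0]
        np.testing.assert_array_equal(same.data, stack.data)


class TestAugmentationLabelConsistency:
    def test_transforms_commute_with_label_generation(self, rng):
        """Heatmap from transformed annotation peaks where the
        transformed coordinates say it should (within a pixel)."""
        spec = AugmentSpec(rotation_range=(-25, 25), flip_mode="all_axes", seed=0)
        for _ in range(25):
            x, y = rng.uniform(20, 44, size=2)
            frame = _blob_frame(x, y)
            anns = [KeypointAnnotation("f", "kp", float(x), float(y), 9, 9)]
            out, out_anns, _ = random_augment(frame, anns, spec, rng=rng)
            a = out_anns[0]
            grid = generate_heatmap(
                a, out.shape[1], out.shape[0]
            ).grid
            gx, gy = argmax_location(grid)
            assert abs(gx - a.x) <= 1.0 and abs(gy - a.y) <= 1.0
            # and the rendered blob agrees with the mapped annotation
            cx, cy = _centroid(out)
            assert abs(cx - a.x) < 1.0 and abs(cy - a.y) < 1.0
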