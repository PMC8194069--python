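"""Window indexing, dense flow, heatmap morphing, and weight fitting."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from flowpose.base_model import MockPredictorConfig, MockSequencePredictor
from flowpose.flow import (
    AggregatorWeights,
    FitConfig,
    FlowField,
    FlowParams,
    FrameWindowSpec,
    aggregate,
    aggregate_mse,
    build_window,
    dense_flow,
    fit_weights,
    morph_window,
    predict_target,
    run_temporal,
    warp_heatmap,
)
from flowpose.labels import HeatmapStack
from flowpose.metrics import apck_error_table, argmax_location
from flowpose.synthetic import SceneSpec, simulate_sequence, truth_stacks


class TestBuildWindow:
    def test_skip_ratio_indexing_rule(self):
        assert build_window(10, FrameWindowSpec(2, 3), 100) == [
            4, 6, 8, 10, 12, 14, 16,
        ]

    def test_zero_range_degenerates_to_target(self):
        assert build_window(7, FrameWindowSpec(3, 0), 50) == [7]

    def test_edges_clamp_to_sequence_bounds(self):
        assert build_window(1, FrameWindowSpec(1, 4), 100) == [
            0, 0, 0, 0, 1, 2, 3, 4, 5,
        ]
        assert build_window(99, FrameWindowSpec(1, 2), 100) == [97, 98, 99, 99, 99]

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            build_window(100, FrameWindowSpec(1, 1), 100)


class TestDenseFlow:
    def test_null_motion_flow_is_tiny(self, textured_frame):
        flow = dense_flow(textured_frame, textured_frame)
        assert np.percentile(flow.magnitude, 95) < 0.5

    def test_known_shift_recovered(self, rng):
        big = gaussian_filter(rng.normal(0.2, 0.1, (80, 96)), 1.5)
        ref = big[8:72, 8:88]
        src = big[8:72, 3:83]  # ref content sits 5 px to the right in src
        flow = dense_flow(ref, src)
        inner = np.s_[10:-10, 10:-10]
        assert abs(np.median(flow.u[inner]) - 5) < 1.0
        assert abs(np.median(flow.v[inner])) < 1.0

    def test_blank_frames_give_finite_flow(self):
        blank = np.zeros((32, 32), dtype=np.float32)
        flow = dense_flow(blank, blank)
        assert np.isfinite(flow.u).all() and np.isfinite(flow.v).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            dense_flow(np.zeros((16, 16)), np.zeros((16, 18)))


def _random_stack(rng, n_kp=2, size=12):
    data = gaussian_filter(rng.random((n_kp, size, size)), (0, 1.0, 1.0))
    return HeatmapStack(data=data, keypoint_order=tuple(f"k{i}" for i in range(n_kp)))


class TestWarpHeatmap:
    def test_zero_flow_is_bit_identical(self, rng):
        stack = _random_stack(rng)
        zero = FlowField(u=np.zeros((12, 12)), v=np.zeros((12, 12)))
        out = warp_heatmap(stack, zero)
        assert np.array_equal(out.data, stack.data)

    def test_integer_flow_matches_shift_oracle(self, rng):
        stack = _random_stack(rng)
        flow = FlowField(u=np.full((12, 12), 3.0), v=np.zeros((12, 12)))
        out = warp_heatmap(stack, flow)
        oracle = np.zeros_like(stack.data)
        oracle[:, :, :-3] = stack.data[:, :, 3:]  # h(p + u): shift left
        np.testing.assert_allclose(out.data, oracle, atol=1e-6)

    def test_all_out_of_bounds_flow_gives_zero_stack(self, rng):
        stack = _random_stack(rng)
        flow = FlowField(u=np.full((12, 12), 100.0), v=np.zeros((12, 12)))
        assert not warp_heatmap(stack, flow).data.any()


class TestMorphWindow:
    def test_identical_frames_preserve_argmax(self, rng, textured_frame):
        frames = [textured_frame] * 5
        stacks = [_random_stack(rng, n_kp=2, size=64) for _ in range(5)]
        morphed = morph_window(frames, stacks, t_pos=2)
        for src, out in zip(stacks, morphed):
            for p in range(2):
                assert argmax_location(out.data[p]) == argmax_location(src.data[p])

    def test_centre_member_is_returned_unchanged(self, rng, textured_frame):
        frames = [textured_frame + 0.01 * i for i in range(3)]
        stacks = [_random_stack(rng, size=64) for _ in range(3)]
        morphed = morph_window(frames, stacks, t_pos=1)
        assert np.array_equal(morphed[1].data, stacks[1].data)
        assert len(morphed) == 3

    def test_misaligned_lists_rejected(self, textured_frame):
        with pytest.raises(ValueError):
            morph_window([textured_frame], [], t_pos=0)


class TestAggregate:
    def test_one_hot_centre_weights_return_target(self, rng):
        stacks = [_random_stack(rng) for _ in range(5)]
        w = np.zeros((2, 5))
        w[:, 2] = 1.0
        out = aggregate(stacks, AggregatorWeights(w=w, keypoint_order=("k0", "k1")))
        np.testing.assert_allclose(out.data, stacks[2].data, atol=1e-12)

    def test_uniform_weights_over_identical_stacks(self, rng):
        stack = _random_stack(rng)
        out = aggregate(
            [stack] * 5, AggregatorWeights.uniform(("k0", "k1"), 5)
        )
        np.testing.assert_allclose(out.data, stack.data, atol=1e-12)

    def test_linearity_before_clipping(self, rng):
        sa = [_random_stack(rng) for _ in range(3)]
        sb = [_random_stack(rng) for _ in range(3)]
        w = AggregatorWeights(w=rng.normal(size=(2, 3)), keypoint_order=("k0", "k1"))
        mix = [
            HeatmapStack(data=2.0 * a.data + 3.0 * b.data,
                         keypoint_order=a.keypoint_order)
            for a, b in zip(sa, sb)
        ]
        lhs = aggregate(mix, w).data
        rhs = 2.0 * aggregate(sa, w).data + 3.0 * aggregate(sb, w).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_length_mismatch_rejected(self, rng):
        w = AggregatorWeights.uniform(("k0", "k1"), 5)
        with pytest.raises(ValueError, match="window length"):
            aggregate([_random_stack(rng)] * 3, w)


def _mixing_windows(rng, w_star, n_windows=30, noise=0.0):
    """Windows whose labels are an exact (or noisy) known mix."""
    windows = []
    k_len = len(w_star)
    for _ in range(n_windows):
        morphs = np.stack(
            [gaussian_filter(rng.random((2, 12, 12)), (0, 1, 1)) for _ in range(k_len)]
        )
        label = np.einsum("k,kphw->phw", w_star, morphs)
        if noise:
            label = label + rng.normal(0, noise, label.shape)
        windows.append((morphs, label))
    return windows


class TestFitWeights:
    def test_least_squares_recovers_known_mix(self, rng):
        w_star = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        windows = _mixing_windows(rng, w_star)
        fitted = fit_weights(windows)
        np.testing.assert_allclose(fitted.w, np.tile(w_star, (2, 1)), atol=1e-6)

    def test_centre_labels_give_one_hot_weights(self, rng):
        windows = []
        for _ in range(20):
            morphs = np.stack(
                [gaussian_filter(rng.random((1, 10, 10)), (0, 1, 1)) for _ in range(3)]
            )
            windows.append((morphs, morphs[1].copy()))
        fitted = fit_weights(windows)
        np.testing.assert_allclose(fitted.w[0], [0.0, 1.0, 0.0], atol=1e-8)

    def test_gradient_descent_approaches_least_squares(self, rng):
        w_star = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        windows = _mixing_windows(rng, w_star, n_windows=150, noise=0.05)
        ls = fit_weights(windows, FitConfig(method="lstsq"))
        gd = fit_weights(windows, FitConfig(method="adam", seed=0))
        assert aggregate_mse(windows, gd) <= 1.05 * aggregate_mse(windows, ls)

    def test_rank_deficient_system_warns_and_falls_back(self, rng):
        morphs = np.repeat(
            gaussian_filter(rng.random((1, 1, 8, 8)), (0, 0, 1, 1)), 3, axis=0
        )
        with pytest.warns(UserWarning, match="rank-deficient"):
            fitted = fit_weights([(morphs, morphs[0])])
        assert np.isfinite(fitted.w).all()

    def test_scalar_regression_closed_form(self):
        # single window, single keypoint, 1x1 grids: y = w * o
        morphs = np.array([[[[2.0]]]])
        label = np.array([[[3.0]]])
        fitted = fit_weights([(morphs, label)])
        assert fitted.w[0, 0] == pytest.approx(1.5)


class TestPredictTarget:
    def _scene(self, n_frames=20):
        spec = SceneSpec(
            width=64, height=64, n_keypoints=2, n_frames=n_frames,
            amplitude=6.0, period=16.0, seed=2,
        )
        frames, tracks, _ = simulate_sequence(spec)
        return spec, frames, tracks

    def _mock(self, spec, tracks, **cfg_kw):
        cfg = MockPredictorConfig(loc_noise_sigma=0.0, seed=3, **cfg_kw)
        return MockSequencePredictor(
            locations=tracks.locations, occluded=tracks.occluded,
            order=tracks.keypoint_order,
            image_shape=(spec.height, spec.width), cfg=cfg,
        )

    def test_zero_range_equals_base_decode(self):
        spec, frames, tracks = self._scene()
        mock = self._mock(spec, tracks)
        weights = AggregatorWeights.uniform(tracks.keypoint_order, 1)
        _, locs = predict_target(
            list(frames), mock, FrameWindowSpec(1, 0), weights, t=10
        )
        base = mock.predict_index(10)
        for p in range(2):
            assert tuple(locs[p]) == argmax_location(base.data[p])

    def test_clean_window_decodes_truth(self):
        spec, frames, tracks = self._scene()
        mock = self._mock(spec, tracks)
        weights = AggregatorWeights.uniform(tracks.keypoint_order, 5)
        _, locs = predict_target(
            list(frames), mock, FrameWindowSpec(1, 2), weights, t=10
        )
        for p in range(2):
            tx, ty = tracks.locations[10, p]
            assert np.hypot(locs[p, 0] - tx, locs[p, 1] - ty) < 1.5

    def test_sequence_aggregation_corrects_isolated_errors(self):
        spec, frames, tracks = self._scene(n_frames=40)
        mock = self._mock(spec, tracks, error_prob=0.15,
                          error_displacement=30.0)
        stacks = [mock.predict_index(t) for t in range(spec.n_frames)]
        gts = truth_stacks(tracks, spec)
        res = run_temporal(
            frames, stacks, FrameWindowSpec(1, 2), FlowParams(), labels=gts
        )
        base_err = apck_error_table(res.base_locations, gts).mean_error
        agg_err = apck_error_table(res.locations, gts).mean_error
        assert mock.error_frames.any() and base_err > 0
        assert agg_err < base_err
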