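"""End-to-end scenario runners on the synthetic benchmark scenes.

These helpers wire the simulator, the mock base predictor, the temporal
aggregator, and the evaluation together for the named standard
scenarios, so that scripts and tests exercise one shared code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base_model import MockSequencePredictor
from .flow import FitConfig, FlowParams, run_temporal
from .labels import HeatmapStack
from .metrics import EvalReport, apck_error_table, argmax_location
from .multiview import ViewPairing, correct_keypoints
from .preprocess import make_training_target
from .synthetic import get_scenario, simulate_sequence, simulate_two_views, truth_stacks

__all__ = [
    "TemporalScenarioResult",
    "MultiviewScenarioResult",
    "run_temporal_scenario",
    "run_multiview_scenario",
]

#: peak value applied to label heatmaps when fitting the aggregator,
#: matching the training-target scaling used for base-model regression
TRAIN_PEAK = 16.0


@dataclass
class TemporalScenarioResult:
    """Base-model vs temporally aggregated evaluation on one scenario."""

    base_report: EvalReport
    aggregated_report: EvalReport
    weights: np.ndarray
    error_frames: np.ndarray  # (n_frames, P) mock failure schedule
    keypoint_order: tuple[str, ...]


def run_temporal_scenario(
    name: str,
    seed: int = 0,
    flow_params: FlowParams = FlowParams(),
) -> TemporalScenarioResult:
    """Simulate a named scenario, run the mock base predictor and the
    temporal aggregator over it, and evaluate both with aPCK.

    The aggregation weights are fitted on the scenario's own sequence by
    per-keypoint least squares against the peak-scaled label heatmaps.
    """
    scen = get_scenario(name, seed=seed)
    frames, tracks, _ = simulate_sequence(scen.scene)
    gts = truth_stacks(tracks, scen.scene)
    shape = (scen.scene.height, scen.scene.width)
    mock = MockSequencePredictor(
        locations=tracks.locations,
        occluded=tracks.occluded,
        order=tracks.keypoint_order,
        image_shape=shape,
        cfg=scen.mock,
    )
    stacks = [mock.predict_index(t) for t in range(scen.scene.n_frames)]
    scaled = [make_training_target(g, peak=TRAIN_PEAK, stages=1)[0] for g in gts]
    result = run_temporal(
        frames,
        stacks,
        scen.window,
        flow_params,
        labels=scaled,
        fit_cfg=FitConfig(method="lstsq", seed=seed),
    )
    return TemporalScenarioResult(
        base_report=apck_error_table(result.base_locations, gts),
        aggregated_report=apck_error_table(result.locations, gts),
        weights=result.weights.w,
        error_frames=mock.error_frames,
        keypoint_order=tracks.keypoint_order,
    )


@dataclass
class MultiviewScenarioResult:
    """Side-view evaluation before/after bottom-view x correction."""

    before_report: EvalReport
    after_report: EvalReport
    injected: np.ndarray  # (n_frames, P) bool, side-view failure frames
    dx_before: np.ndarray  # (n_frames, P) |x_side - x_ref| pre-correction
    dx_after: np.ndarray  # (n_frames, P) post-correction
    locations_before: np.ndarray  # (n_frames, P, 2)
    locations_after: np.ndarray  # (n_frames, P, 2)
    truth: list[HeatmapStack]
    keypoint_order: tuple[str, ...]


def run_multiview_scenario(seed: int = 0) -> MultiviewScenarioResult:
    """Simulate the paired-view scenario and correct the side view's
    argmax locations against the bottom view's x-coordinates."""
    scen = get_scenario("two-view-swap", seed=seed)
    side, bottom = simulate_two_views(scen.scene)
    _, side_tracks, _ = side
    _, bottom_tracks, _ = bottom
    shape = (scen.scene.height, scen.scene.width)
    order = side_tracks.keypoint_order
    side_mock = MockSequencePredictor(
        locations=side_tracks.locations,
        occluded=side_tracks.occluded,
        order=order,
        image_shape=shape,
        cfg=scen.mock,
    )
    bottom_mock = MockSequencePredictor(
        locations=bottom_tracks.locations,
        occluded=bottom_tracks.occluded,
        order=order,
        image_shape=shape,
        cfg=scen.reference_mock,
    )
    pairing = ViewPairing(pairs=tuple((k, k) for k in order))
    n_frames = scen.scene.n_frames
    n_kp = len(order)
    before = np.empty((n_frames, n_kp, 2))
    after = np.empty((n_frames, n_kp, 2))
    dx_before = np.empty((n_frames, n_kp))
    dx_after = np.empty((n_frames, n_kp))
    for t in range(n_frames):
        side_stack: HeatmapStack = side_mock.predict_index(t)
        bottom_stack = bottom_mock.predict_index(t)
        side_locs = {k: argmax_location(side_stack.grid(k)) for k in order}
        bottom_locs = {k: argmax_location(bottom_stack.grid(k)) for k in order}
        corrected, _ = correct_keypoints(
            side_stack, side_locs, bottom_locs, pairing
        )
        for p, k in enumerate(order):
            before[t, p] = side_locs[k]
            after[t, p] = corrected[k]
            ref_x = bottom_locs[k][0]
            dx_before[t, p] = abs(side_locs[k][0] - ref_x)
            dx_after[t, p] = abs(corrected[k][0] - ref_x)
    gts = truth_stacks(side_tracks, scen.scene)
    return MultiviewScenarioResult(
        before_report=apck_error_table(before, gts),
        after_report=apck_error_table(after, gts),
        injected=side_mock.error_frames,
        dx_before=dx_before,
        dx_after=dx_after,
        locations_before=before,
        locations_after=after,
        truth=gts,
        keypoint_order=order,
    )
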