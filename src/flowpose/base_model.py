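"""Base-predictor contract and a deterministic mock predictor.

Any single-frame model that maps an image to one confidence heatmap per
keypoint can serve as the base predictor of the temporal pipeline.  The
contract is deliberately minimal so that deep-learning backends (e.g. a
ResNet-backed heatmap regressor, whose structural hyperparameters are
parsed here as configuration) can be slotted in without this package
depending on a deep-learning stack.

The mock predictor emulates the failure mode the temporal module exists
to fix: it renders a near-perfect Gaussian peak at the true keypoint
location on clean frames, and a peak displaced by a fixed distance in a
random direction on error frames (always when the keypoint is occluded).
Error episodes have a configurable run length; runs are separated by at
least one clean frame, so run length 1 yields strictly isolated
single-frame errors.
"""

from __future__ import annotations

import zlib
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .labels import HeatmapStack

__all__ = [
    "BasePredictor",
    "MockPredictorConfig",
    "MockSequencePredictor",
    "ResNetHeatmapConfig",
    "mock_predict",
    "validate_stack",
]


class BasePredictor(ABC):
    """Contract for single-frame heatmap predictors.

    ``predict`` must return a :class:`HeatmapStack` whose grids match the
    input frame dimensions, with finite non-negative values, in a fixed
    keypoint order.
    """

    #: number of model outputs (intermediate supervision stages); the
    #: final output is the one consumed downstream.
    n_outputs: int = 1

    @property
    @abstractmethod
    def keypoint_order(self) -> tuple[str, ...]: ...

    @abstractmethod
    def predict(self, frame: np.ndarray, frame_id: str = "0") -> HeatmapStack: ...


def validate_stack(stack: HeatmapStack, image_shape: tuple[int, int]) -> None:
    """Check a predictor's output against the contract before it enters
    the temporal module."""
    if stack.image_shape != tuple(image_shape):
        raise ValueError(
            f"predictor output {stack.image_shape} does not match frame "
            f"{tuple(image_shape)}"
        )
    if not np.isfinite(stack.data).all():
        raise ValueError("predictor output contains non-finite values")
    if (stack.data < 0).any():
        raise ValueError("predictor output contains negative values")


@dataclass(frozen=True)
class ResNetHeatmapConfig:
    """Structural hyperparameters of a ResNet-backed heatmap regressor,
    parsed and validated as configuration only.

    A user with a deep-learning stack can instantiate such a model behind
    :class:`BasePredictor`; this package does not train it.  The final
    output layer always carries one filter per keypoint; the three
    transposed-convolution layers use 13x13 kernels.
    """

    n_keypoints: int
    backbone_cut: str = "Conv4"
    deconv_filters: tuple[int, int, int] = (64, 64, 0)  # 0 => 2 * n_keypoints
    intermediate_supervision_after: str | None = "Conv3"
    deconv_kernel: int = 13
    # training defaults for external implementers
    epochs: int = 50
    batch_size: int = 10
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    loss: str = "mse"

    def __post_init__(self) -> None:
        valid_cuts = {f"Conv{i}" for i in range(1, 6)}
        if self.backbone_cut not in valid_cuts:
            raise ValueError(f"backbone_cut must be one of {sorted(valid_cuts)}")
        if self.intermediate_supervision_after is not None and (
            self.intermediate_supervision_after not in valid_cuts
        ):
            raise ValueError(
                "intermediate_supervision_after must be a Conv block or None"
            )
        if len(self.deconv_filters) != 3:
            raise ValueError("deconv_filters must list 3 integers")
        if self.n_keypoints < 1:
            raise ValueError("n_keypoints must be >= 1")

    @property
    def final_filters(self) -> int:
        """The output layer filter count equals the keypoint count."""
        return self.n_keypoints

    @classmethod
    def from_dict(cls, cfg: dict) -> "ResNetHeatmapConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown base-model config keys: {sorted(unknown)}")
        if "deconv_filters" in cfg:
            cfg = {**cfg, "deconv_filters": tuple(cfg["deconv_filters"])}
        return cls(**cfg)


@dataclass(frozen=True)
class MockPredictorConfig:
    """Parameters of the deterministic mock predictor.

    ``loc_noise_sigma`` jitters the rendered peak around the truth on
    clean frames (pixels).  With probability ``error_prob`` -- and always
    when a keypoint is occluded -- the peak is displaced by
    ``error_displacement`` pixels in a seeded random direction
    (restricted to the x-axis when ``error_axis="x"``) for
    ``error_run_length`` consecutive frames.  ``truth_peak_frac`` > 0
    additionally renders a secondary peak of that relative height at the
    true location on error frames, emulating a predictor that retains a
    weaker truthful mode.
    """

    loc_noise_sigma: float = 0.5
    error_prob: float = 0.0
    error_displacement: float = 30.0
    error_run_length: int = 1
    error_axis: str | None = None  # None (any direction) or "x"
    truth_peak_frac: float = 0.0
    render_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_prob <= 1.0:
            raise ValueError(f"error_prob must be in [0, 1], got {self.error_prob}")
        if self.error_run_length < 1:
            raise ValueError("error_run_length must be >= 1")
        if self.error_axis not in (None, "x"):
            raise ValueError(f"error_axis must be None or 'x', got {self.error_axis!r}")


def _rng_for(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic generator keyed on (seed, string tokens)."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF] + [zlib.crc32(t.encode()) for t in tokens]
    )


def render_peak(
    shape: tuple[int, int], x: float, y: float, sigma: float, amplitude: float = 1.0
) -> np.ndarray:
    """A full-image Gaussian confidence peak at (x, y)."""
    height, width = shape
    cols = np.arange(width, dtype=np.float64)
    rows = np.arange(height, dtype=np.float64)
    gx = np.exp(-((cols - x) ** 2) / (2.0 * sigma * sigma))
    gy = np.exp(-((rows - y) ** 2) / (2.0 * sigma * sigma))
    return amplitude * gy[:, None] * gx[None, :]


def _error_direction(rng: np.random.Generator, axis: str | None) -> np.ndarray:
    if axis == "x":
        return np.array([rng.choice([-1.0, 1.0]), 0.0])
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(theta), np.sin(theta)])


def _clip_loc(x: float, y: float, shape: tuple[int, int]) -> tuple[float, float]:
    height, width = shape
    return float(np.clip(x, 0, width - 1)), float(np.clip(y, 0, height - 1))


def mock_predict(
    truth: HeatmapStack,
    occluded: Sequence[bool],
    cfg: MockPredictorConfig,
    frame_id: str = "0",
) -> HeatmapStack:
    """Emulate a single-frame base prediction from a ground-truth stack.

    Per keypoint, a Gaussian peak is re-rendered at the truth argmax
    jittered by ``loc_noise_sigma``; on error frames (occlusion, or a
    ``error_prob`` draw) the peak moves ``error_displacement`` pixels
    away.  Reproducible per (seed, frame_id, keypoint).
    """
    shape = truth.image_shape
    out = np.zeros_like(truth.data, dtype=np.float64)
    for p, name in enumerate(truth.keypoint_order):
        grid = truth.data[p]
        if not grid.any():
            continue  # absent keypoint: all-zero prediction
        r, c = np.unravel_index(int(np.argmax(grid)), shape)
        rng = _rng_for(cfg.seed, frame_id, name)
        x = c + rng.normal(0.0, cfg.loc_noise_sigma) if cfg.loc_noise_sigma else float(c)
        y = r + rng.normal(0.0, cfg.loc_noise_sigma) if cfg.loc_noise_sigma else float(r)
        x, y = _clip_loc(x, y, shape)
        is_error = bool(occluded[p]) or (
            cfg.error_prob > 0 and rng.random() < cfg.error_prob
        )
        if is_error:
            direction = _error_direction(rng, cfg.error_axis)
            ex, ey = _clip_loc(
                x + cfg.error_displacement * direction[0],
                y + cfg.error_displacement * direction[1],
                shape,
            )
            out[p] = render_peak(shape, ex, ey, cfg.render_sigma)
            if cfg.truth_peak_frac > 0:
                out[p] += render_peak(
                    shape, x, y, cfg.render_sigma, amplitude=cfg.truth_peak_frac
                )
        else:
            out[p] = render_peak(shape, x, y, cfg.render_sigma)
    return HeatmapStack(
        data=out, keypoint_order=truth.keypoint_order, missing=truth.missing
    )


@dataclass
class MockSequencePredictor(BasePredictor):
    """Mock base predictor over a whole simulated sequence.

    Holds the true tracks of a synthetic video and a precomputed error
    schedule: per keypoint, error runs of ``cfg.error_run_length`` frames
    start with probability ``cfg.error_prob / run_length`` at each
    eligible frame, and consecutive runs are separated by at least one
    clean frame.  The displacement direction is drawn once per run, so a
    run mimics a persistent confusion with one wrong location.  Occluded
    frames (from the scene's occlusion annotations) always count as
    errors.
    """

    locations: np.ndarray  # (n_frames, P, 2) true (x, y)
    occluded: np.ndarray  # (n_frames, P) bool
    order: tuple[str, ...]
    image_shape: tuple[int, int]
    cfg: MockPredictorConfig
    error_frames: np.ndarray = field(init=False)  # (n_frames, P) bool
    _directions: np.ndarray = field(init=False)  # (n_frames, P, 2)

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=np.float64)
        self.occluded = np.asarray(self.occluded, dtype=bool)
        n_frames, n_kp = self.occluded.shape
        self.order = tuple(self.order)
        errors = np.zeros((n_frames, n_kp), dtype=bool)
        directions = np.zeros((n_frames, n_kp, 2), dtype=np.float64)
        run_len = self.cfg.error_run_length
        start_prob = self.cfg.error_prob / run_len
        for p, name in enumerate(self.order):
            rng = _rng_for(self.cfg.seed, "schedule", name)
            t = 0
            while t < n_frames:
                if start_prob > 0 and rng.random() < start_prob:
                    end = min(t + run_len, n_frames)
                    direction = _error_direction(rng, self.cfg.error_axis)
                    errors[t:end, p] = True
                    directions[t:end, p] = direction
                    t = end + 1  # at least one clean frame between runs
                else:
                    t += 1
        # occlusions force errors too (direction drawn per episode)
        for p, name in enumerate(self.order):
            rng = _rng_for(self.cfg.seed, "occlusion", name)
            in_episode = False
            for t in range(n_frames):
                if self.occluded[t, p] and not errors[t, p]:
                    if not in_episode:
                        direction = _error_direction(rng, self.cfg.error_axis)
                        in_episode = True
                    errors[t, p] = True
                    directions[t, p] = direction
                elif not self.occluded[t, p]:
                    in_episode = False
        self.error_frames = errors
        self._directions = directions

    @property
    def keypoint_order(self) -> tuple[str, ...]:
        return self.order

    @property
    def n_frames(self) -> int:
        return self.locations.shape[0]

    def predict_index(self, t: int) -> HeatmapStack:
        """Prediction stack for frame index ``t``."""
        if not 0 <= t < self.n_frames:
            raise IndexError(f"frame index {t} out of range [0, {self.n_frames})")
        cfg = self.cfg
        n_kp = len(self.order)
        out = np.zeros((n_kp,) + tuple(self.image_shape), dtype=np.float64)
        for p, name in enumerate(self.order):
            rng = _rng_for(cfg.seed, f"frame{t}", name)
            tx, ty = self.locations[t, p]
            x = tx + (rng.normal(0.0, cfg.loc_noise_sigma) if cfg.loc_noise_sigma else 0.0)
            y = ty + (rng.normal(0.0, cfg.loc_noise_sigma) if cfg.loc_noise_sigma else 0.0)
            x, y = _clip_loc(x, y, self.image_shape)
            if self.error_frames[t, p]:
                dx, dy = self._directions[t, p]
                ex, ey = _clip_loc(
                    x + cfg.error_displacement * dx,
                    y + cfg.error_displacement * dy,
                    self.image_shape,
                )
                out[p] = render_peak(self.image_shape, ex, ey, cfg.render_sigma)
                if cfg.truth_peak_frac > 0:
                    out[p] += render_peak(
                        self.image_shape, x, y, cfg.render_sigma,
                        amplitude=cfg.truth_peak_frac,
                    )
            else:
                out[p] = render_peak(self.image_shape, x, y, cfg.render_sigma)
        return HeatmapStack(data=out, keypoint_order=self.order)

    def predict(self, frame: np.ndarray, frame_id: str = "0") -> HeatmapStack:
        return self.predict_index(int(frame_id))
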