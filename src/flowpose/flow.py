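"""Optical-flow temporal aggregation of per-frame keypoint heatmaps.

The temporal module turns a single-frame heatmap predictor into a
multi-frame one.  For a target frame ``t`` it gathers the window of
2f+1 frames at indices ``t + k*s`` (skip ratio ``s``, frame range ``f``,
k = -f..f, clamped at the sequence edges), computes dense optical flow
from the target to each neighbour, warps ("morphs") each neighbour's
predicted heatmaps onto the target frame's coordinates by backward
bilinear sampling, and combines the 2f+1 morphed stacks with a learned
per-keypoint weight vector -- a 1x1 convolution over the window axis,
i.e. a weighted sum.  The final location of each keypoint is the global
maximum of its aggregated heatmap.

Because morphed neighbour heatmaps carry the keypoint's position as seen
a few frames away, the weighted sum overrides isolated single-frame
prediction failures (e.g. during temporary occlusion) while leaving
correct predictions untouched.  Runs of consecutive errors spanning the
whole window cannot be corrected -- the window then contains no truthful
evidence.

Dense flow is estimated with the iterative Lucas-Kanade solver from
scikit-image.  Flow is computed with the *target* as the reference image
so that warping is backward sampling (no holes); samples falling outside
the grid contribute zero confidence mass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.registration import optical_flow_ilk

from .base_model import BasePredictor, validate_stack
from .labels import HeatmapStack

__all__ = [
    "FrameWindowSpec",
    "FlowParams",
    "FlowField",
    "AggregatorWeights",
    "FitConfig",
    "build_window",
    "dense_flow",
    "warp_heatmap",
    "morph_window",
    "aggregate",
    "fit_weights",
    "aggregate_mse",
    "predict_target",
    "run_temporal",
    "TemporalResult",
]


@dataclass(frozen=True)
class FrameWindowSpec:
    """Temporal window: stride ``skip_ratio`` (s) and half-width
    ``frame_range`` (f); the window holds 2f+1 frames."""

    skip_ratio: int = 1
    frame_range: int = 4

    def __post_init__(self) -> None:
        if self.skip_ratio < 1:
            raise ValueError(f"skip_ratio must be >= 1, got {self.skip_ratio}")
        if self.frame_range < 0:
            raise ValueError(f"frame_range must be >= 0, got {self.frame_range}")

    @property
    def length(self) -> int:
        return 2 * self.frame_range + 1


@dataclass(frozen=True)
class FlowParams:
    """Dense-flow estimator parameters.

    ``window_size`` is the side of the local integration window in pixels
    (27 px default, i.e. a solver radius of 13); ``num_warp`` the number
    of iterative warp refinements; ``gaussian`` selects a Gaussian rather
    than uniform window.  Defaults are sized for inter-frame
    displacements up to roughly half the window radius: on the
    known-shift oracle, refinement beyond two warps does not improve the
    recovered displacement in that regime.
    """

    window_size: int = 27
    num_warp: int = 2
    gaussian: bool = True
    prefilter: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 3:
            raise ValueError(f"window_size must be >= 3, got {self.window_size}")
        if self.num_warp < 1:
            raise ValueError(f"num_warp must be >= 1, got {self.num_warp}")

    @property
    def radius(self) -> int:
        return self.window_size // 2


@dataclass
class FlowField:
    """Per-pixel displacement mapping target-frame coordinates into a
    source frame: source sampled at (r + v, c + u) aligns with the
    target at (r, c)."""

    u: np.ndarray  # displacement along x (columns)
    v: np.ndarray  # displacement along y (rows)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u)
        self.v = np.asarray(self.v)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share a shape")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


def build_window(t: int, spec: FrameWindowSpec, n_frames: int) -> list[int]:
    """Window indices ``t + k*s`` for k = -f..f, clamped into
    [0, n_frames-1]; the centre element is always ``t``."""
    if not 0 <= t < n_frames:
        raise ValueError(f"target index {t} out of range [0, {n_frames})")
    s, f = spec.skip_ratio, spec.frame_range
    return [min(max(t + k * s, 0), n_frames - 1) for k in range(-f, f + 1)]


def to_intensity(frame: np.ndarray) -> np.ndarray:
    """Reduce a frame to single-channel float32 (Rec.601 luminance for
    3-channel input)."""
    frame = np.asarray(frame)
    if frame.ndim == 3 and frame.shape[-1] == 3:
        frame = frame @ np.array([0.299, 0.587, 0.114], dtype=np.float64)
    elif frame.ndim != 2:
        raise ValueError(f"expected 2D or HxWx3 frame, got shape {frame.shape}")
    return np.ascontiguousarray(frame, dtype=np.float32)


def dense_flow(
    ref: np.ndarray, src: np.ndarray, params: FlowParams = FlowParams()
) -> FlowField:
    """Estimate dense flow such that ``src`` sampled at p + (u, v)
    corresponds to ``ref`` at p (backward flow with ``ref`` as target)."""
    ref_i = to_intensity(ref)
    src_i = to_intensity(src)
    if ref_i.shape != src_i.shape:
        raise ValueError(
            f"frame dimensions differ: {ref_i.shape} vs {src_i.shape}"
        )
    v, u = optical_flow_ilk(
        ref_i,
        src_i,
        radius=params.radius,
        num_warp=params.num_warp,
        gaussian=params.gaussian,
        prefilter=params.prefilter,
        dtype=np.float32,
    )
    return FlowField(u=u, v=v)


def warp_heatmap(stack: HeatmapStack, flow: FlowField) -> HeatmapStack:
    """Morph a heatmap stack by backward bilinear sampling through a flow
    field; out-of-bounds samples contribute 0."""
    height, width = stack.image_shape
    if flow.u.shape != (height, width):
        raise ValueError(
            f"flow shape {flow.u.shape} does not match heatmaps {(height, width)}"
        )
    if not flow.u.any() and not flow.v.any():
        return HeatmapStack(
            data=stack.data.copy(),
            keypoint_order=stack.keypoint_order,
            missing=stack.missing,
        )
    rows, cols = np.mgrid[0:height, 0:width]
    coords = np.stack([rows + flow.v, cols + flow.u])
    out = np.empty(stack.data.shape, dtype=np.result_type(stack.data, np.float32))
    for p in range(stack.n_keypoints):
        out[p] = map_coordinates(
            np.ascontiguousarray(stack.data[p], dtype=out.dtype),
            coords, order=1, mode="constant", cval=0.0,
        )
    return HeatmapStack(
        data=out, keypoint_order=stack.keypoint_order, missing=stack.missing
    )


def morph_window(
    frames: list[np.ndarray],
    stacks: list[HeatmapStack],
    t_pos: int,
    params: FlowParams = FlowParams(),
) -> list[HeatmapStack]:
    """Morph every window member's heatmaps onto the centre frame.

    ``frames`` and ``stacks`` must be aligned with a ``build_window``
    output and ``t_pos`` indexes the centre (target) member, which is
    returned unmodified (morphing a frame onto itself is the identity).
    """
    if len(frames) != len(stacks):
        raise ValueError(
            f"{len(frames)} frames but {len(stacks)} heatmap stacks"
        )
    if not 0 <= t_pos < len(frames):
        raise ValueError(f"t_pos {t_pos} out of range")
    out = []
    for k, (frame, stack) in enumerate(zip(frames, stacks)):
        if k == t_pos:
            out.append(
                HeatmapStack(
                    data=stack.data.copy(),
                    keypoint_order=stack.keypoint_order,
                    missing=stack.missing,
                )
            )
        else:
            out.append(warp_heatmap(stack, dense_flow(frames[t_pos], frame, params)))
    return out


@dataclass
class AggregatorWeights:
    """Per-keypoint weight vector over the 2f+1 window offsets (the 1x1
    convolution parameters): shape (P, 2f+1)."""

    w: np.ndarray
    keypoint_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        self.keypoint_order = tuple(self.keypoint_order)
        if self.w.ndim != 2 or self.w.shape[0] != len(self.keypoint_order):
            raise ValueError(
                f"weights shape {self.w.shape} does not match "
                f"{len(self.keypoint_order)} keypoints"
            )
        if not np.isfinite(self.w).all():
            raise ValueError("weights must be finite")

    @classmethod
    def uniform(
        cls, keypoint_order: tuple[str, ...], window_length: int
    ) -> "AggregatorWeights":
        n_kp = len(keypoint_order)
        return cls(
            w=np.full((n_kp, window_length), 1.0 / window_length),
            keypoint_order=keypoint_order,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "keypoint_order": list(self.keypoint_order),
                    "weights": self.w.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "AggregatorWeights":
        obj = json.loads(Path(path).read_text())
        return cls(
            w=np.array(obj["weights"]), keypoint_order=tuple(obj["keypoint_order"])
        )


def _as_morph_array(morphed) -> np.ndarray:
    """(K, P, H, W) float array from a list of HeatmapStack or an array."""
    if isinstance(morphed, np.ndarray):
        if morphed.ndim != 4:
            raise ValueError(f"morphed array must be (K, P, H, W), got {morphed.shape}")
        return morphed
    return np.stack([st.data for st in morphed])


def aggregate(morphed, weights: AggregatorWeights) -> HeatmapStack:
    """Pixelwise weighted sum of the morphed window stacks:
    y_p = sum_k w[p, k] * o^k_p.  No bias, no nonlinearity; raw values
    are returned (negatives are clipped only at decode time)."""
    arr = _as_morph_array(morphed)
    if arr.shape[0] != weights.w.shape[1]:
        raise ValueError(
            f"window length {arr.shape[0]} does not match weight columns "
            f"{weights.w.shape[1]}"
        )
    data = np.einsum("kphw,pk->phw", arr.astype(np.float64), weights.w)
    return HeatmapStack(data=data, keypoint_order=weights.keypoint_order)


def decode_stack(stack: HeatmapStack) -> np.ndarray:
    """Per-keypoint (x, y) of the global maximum after clipping negative
    aggregate values to zero; ties break at the smallest row-major index."""
    from .metrics import argmax_location

    clipped = np.maximum(stack.data, 0.0)
    return np.array([argmax_location(g) for g in clipped], dtype=np.int64)


@dataclass(frozen=True)
class FitConfig:
    """Aggregator-weight fitting configuration.

    ``method="lstsq"`` solves the per-keypoint linear least-squares
    problem exactly; ``"adam"`` minimises the same MSE by minibatch Adam
    (lr 1e-4, betas 0.9/0.999, 30 epochs by default) starting from
    uniform weights 1/(2f+1).  Adam's effective travel per weight is
    bounded by lr times the step count, so the small default batch keeps
    enough steps per epoch to reach the optimum at this learning rate.
    """

    method: str = "lstsq"
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 64
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("lstsq", "adam"):
            raise ValueError(f"unknown fit method {self.method!r}")


def _normalize_windows(windows):
    """Yield (morph_array (K,P,H,W), label_array (P,H,W)) pairs."""
    if not windows:
        raise ValueError("at least one training window is required")
    out = []
    for morphed, label in windows:
        arr = _as_morph_array(morphed)
        lab = label.data if isinstance(label, HeatmapStack) else np.asarray(label)
        if lab.shape != arr.shape[1:]:
            raise ValueError(
                f"label shape {lab.shape} does not match morphs {arr.shape[1:]}"
            )
        out.append((arr, lab))
    return out


def _keypoint_order_of(windows) -> tuple[str, ...] | None:
    for morphed, _ in windows:
        if not isinstance(morphed, np.ndarray):
            return tuple(morphed[0].keypoint_order)
        if isinstance(_, HeatmapStack):
            return tuple(_.keypoint_order)
    return None


def fit_weights(
    windows, cfg: FitConfig = FitConfig(), keypoint_order=None
) -> AggregatorWeights:
    """Fit the per-keypoint aggregation weights by minimising the mean
    squared error between the weighted sum of morphed stacks and the
    label heatmaps.

    ``windows`` is a sequence of (morphed, label) pairs, where ``morphed``
    is a (2f+1)-long list of stacks (or a (K, P, H, W) array) and
    ``label`` the target heatmap stack for the centre frame, scaled like
    the training targets.  A rank-deficient system falls back to the
    minimum-norm solution with a warning.
    """
    order = keypoint_order or _keypoint_order_of(windows)
    pairs = _normalize_windows(windows)
    n_kp = pairs[0][0].shape[1]
    k_len = pairs[0][0].shape[0]
    if order is None:
        order = tuple(f"kp{p}" for p in range(n_kp))
    if cfg.method == "lstsq":
        w = np.empty((n_kp, k_len))
        for p in range(n_kp):
            gram = np.zeros((k_len, k_len))
            rhs = np.zeros(k_len)
            for arr, lab in pairs:
                design = arr[:, p].reshape(k_len, -1).astype(np.float64)
                gram += design @ design.T
                rhs += design @ lab[p].ravel().astype(np.float64)
            if np.linalg.matrix_rank(gram, hermitian=True) < k_len:
                warnings.warn(
                    f"rank-deficient aggregation system for keypoint {order[p]!r}; "
                    "using the minimum-norm solution",
                    stacklevel=2,
                )
                w[p] = np.linalg.pinv(gram, hermitian=True) @ rhs
            else:
                w[p] = np.linalg.solve(gram, rhs)
        return AggregatorWeights(w=w, keypoint_order=tuple(order))
    # minibatch Adam on the identical objective
    rng = np.random.default_rng(cfg.seed)
    w = np.full((n_kp, k_len), 1.0 / k_len)
    designs = []  # per keypoint: (n_samples, K), (n_samples,)
    for p in range(n_kp):
        xs = np.concatenate(
            [arr[:, p].reshape(k_len, -1).T for arr, _ in pairs]
        ).astype(np.float64)
        ys = np.concatenate([lab[p].ravel() for _, lab in pairs]).astype(np.float64)
        designs.append((xs, ys))
    for p in range(n_kp):
        xs, ys = designs[p]
        n_samples = xs.shape[0]
        wp = w[p].copy()
        m = np.zeros(k_len)
        v = np.zeros(k_len)
        step = 0
        for _ in range(cfg.epochs):
            perm = rng.permutation(n_samples)
            for lo in range(0, n_samples, cfg.batch_size):
                idx = perm[lo : lo + cfg.batch_size]
                xb, yb = xs[idx], ys[idx]
                grad = 2.0 * xb.T @ (xb @ wp - yb) / len(idx)
                step += 1
                m = cfg.adam_beta1 * m + (1 - cfg.adam_beta1) * grad
                v = cfg.adam_beta2 * v + (1 - cfg.adam_beta2) * grad**2
                m_hat = m / (1 - cfg.adam_beta1**step)
                v_hat = v / (1 - cfg.adam_beta2**step)
                wp -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + 1e-8)
        w[p] = wp
    return AggregatorWeights(w=w, keypoint_order=tuple(order))


def aggregate_mse(windows, weights: AggregatorWeights) -> float:
    """Mean squared error of the weighted sum against the labels over a
    set of training windows (all keypoints and pixels pooled)."""
    pairs = _normalize_windows(windows)
    total = 0.0
    count = 0
    for arr, lab in pairs:
        pred = np.einsum("kphw,pk->phw", arr.astype(np.float64), weights.w)
        total += float(((pred - lab) ** 2).sum())
        count += lab.size
    return total / count


def predict_target(
    frames: list[np.ndarray],
    base: BasePredictor,
    spec: FrameWindowSpec,
    weights: AggregatorWeights,
    params: FlowParams = FlowParams(),
    t: int | None = None,
) -> tuple[HeatmapStack, np.ndarray]:
    """Full temporal prediction for one target frame.

    Runs the base predictor on every window frame, morphs the neighbour
    stacks onto the target, aggregates with the fitted weights, and
    decodes the per-keypoint argmax.  ``t`` defaults to the sequence
    midpoint.  Returns the aggregated stack and an (P, 2) array of
    decoded (x, y) locations.
    """
    n_frames = len(frames)
    t = n_frames // 2 if t is None else t
    indices = build_window(t, spec, n_frames)
    stacks = []
    for idx in indices:
        stack = base.predict(frames[idx], frame_id=str(idx))
        validate_stack(stack, frames[idx].shape[:2])
        stacks.append(stack)
    morphed = morph_window(
        [frames[i] for i in indices], stacks, t_pos=spec.frame_range, params=params
    )
    agg = aggregate(morphed, weights)
    return agg, decode_stack(agg)


@dataclass
class TemporalResult:
    """Output of a sequence-level temporal run."""

    weights: AggregatorWeights
    locations: np.ndarray  # (n_frames, P, 2) aggregated (x, y)
    base_locations: np.ndarray  # (n_frames, P, 2) centre-frame decode


def run_temporal(
    frames,
    base_stacks: list[HeatmapStack],
    spec: FrameWindowSpec = FrameWindowSpec(),
    params: FlowParams = FlowParams(),
    labels: list[HeatmapStack] | None = None,
    weights: AggregatorWeights | None = None,
    fit_cfg: FitConfig = FitConfig(),
    cache_dtype=np.float16,
) -> TemporalResult:
    """Temporal aggregation over a whole sequence.

    Morphs every frame's window once (cached at ``cache_dtype`` to bound
    memory; fitting accumulates in float64 from the full-precision
    morphs), fits the aggregation weights against ``labels`` unless
    ``weights`` is given, then aggregates and decodes every frame.
    """
    n_frames = len(base_stacks)
    if len(frames) != n_frames:
        raise ValueError(f"{len(frames)} frames but {n_frames} base stacks")
    order = base_stacks[0].keypoint_order
    n_kp = len(order)
    height, width = base_stacks[0].image_shape
    k_len = spec.length
    fit = weights is None
    if fit and labels is None:
        raise ValueError("either labels (to fit) or weights must be provided")
    cache = np.empty((n_frames, k_len, n_kp, height, width), dtype=cache_dtype)
    if fit:
        grams = np.zeros((n_kp, k_len, k_len))
        rhss = np.zeros((n_kp, k_len))
    base_locs = np.empty((n_frames, n_kp, 2), dtype=np.int64)
    for t in range(n_frames):
        indices = build_window(t, spec, n_frames)
        morphed = np.empty((k_len, n_kp, height, width))
        flows: dict[int, FlowField] = {}
        for pos, idx in enumerate(indices):
            if idx == t:
                morphed[pos] = base_stacks[idx].data
                continue
            if idx not in flows:  # clamped windows repeat edge indices
                flows[idx] = dense_flow(frames[t], frames[idx], params)
            morphed[pos] = warp_heatmap(base_stacks[idx], flows[idx]).data
        cache[t] = morphed
        base_locs[t] = decode_stack(base_stacks[t])
        if fit:
            lab = labels[t].data
            for p in range(n_kp):
                design = morphed[:, p].reshape(k_len, -1)
                grams[p] += design @ design.T
                rhss[p] += design @ lab[p].ravel()
    if fit:
        w = np.empty((n_kp, k_len))
        for p in range(n_kp):
            if np.linalg.matrix_rank(grams[p], hermitian=True) < k_len:
                warnings.warn(
                    f"rank-deficient aggregation system for keypoint {order[p]!r}; "
                    "using the minimum-norm solution",
                    stacklevel=2,
                )
                w[p] = np.linalg.pinv(grams[p], hermitian=True) @ rhss[p]
            else:
                w[p] = np.linalg.solve(grams[p], rhss[p])
        weights = AggregatorWeights(w=w, keypoint_order=order)
    locations = np.empty((n_frames, n_kp, 2), dtype=np.int64)
    for t in range(n_frames):
        agg = np.einsum(
            "kphw,pk->phw", cache[t].astype(np.float64), weights.w
        )
        locations[t] = decode_stack(HeatmapStack(data=agg, keypoint_order=order))
    return TemporalResult(
        weights=weights, locations=locations, base_locations=base_locs
    )
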