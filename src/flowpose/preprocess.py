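"""Dataset splitting, augmentation, and training-target construction.

All geometric augmentations transform the annotation coordinates with the
exact affine map applied to the image, so heatmap labels generated after
augmentation stay aligned with the augmented frames.  Rotation keeps the
whole image (the canvas expands and is padded with black) so no
information is cropped away; a subsequent resize restores uniform
dimensions across the dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage import transform as sktransform

from .labels import KeypointAnnotation

__all__ = [
    "SplitSpec",
    "AugmentSpec",
    "split_dataset",
    "rotate_with_labels",
    "flip_with_labels",
    "resize_area_with_labels",
    "make_training_target",
    "random_augment",
    "video_of",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partition parameters (default 3:1:1)."""

    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    group_by: str | None = None  # None (frame-level) or "video_id"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios):
            raise ValueError(f"ratios must be 3 non-negative reals, got {self.ratios}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(self.ratios)}")
        if self.group_by not in (None, "video_id"):
            raise ValueError(f"unknown group_by {self.group_by!r}")


@dataclass(frozen=True)
class AugmentSpec:
    """Random rotation range (degrees) and flip mode, all seeded."""

    rotation_range: tuple[float, float] = (-10.0, 10.0)
    flip_mode: str = "none"  # none | y_axis | all_axes
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range
        if lo > hi:
            raise ValueError(f"rotation_range must be ordered, got {self.rotation_range}")
        if self.flip_mode not in ("none", "y_axis", "all_axes"):
            raise ValueError(f"unknown flip_mode {self.flip_mode!r}")


def video_of(frame_id: str) -> str:
    """Video grouping key for a frame id: the part before the first '/'
    for path-like ids, otherwise the part before the last '_'."""
    if "/" in frame_id:
        return frame_id.split("/", 1)[0]
    if "_" in frame_id:
        return frame_id.rsplit("_", 1)[0]
    return frame_id


def _target_sizes(n: int, ratios: tuple[float, float, float]) -> list[int]:
    # Largest-remainder apportionment: sizes within one of n * ratio.
    raw = [n * r for r in ratios]
    sizes = [int(math.floor(v)) for v in raw]
    rem = n - sum(sizes)
    order = sorted(range(3), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def split_dataset(
    frame_ids: list[str], spec: SplitSpec
) -> tuple[list[str], list[str], list[str]]:
    """Partition frame ids into train/validation/test lists.

    The partition is disjoint, exhaustive, deterministic for a fixed
    seed, and sized within one element of the exact ratios.  With
    ``group_by="video_id"`` whole videos are assigned to a single split
    (greedy fill of the most under-target split), so no video leaks
    across splits.
    """
    if not frame_ids:
        raise ValueError("frame id list is empty")
    rng = np.random.default_rng(spec.seed)
    if spec.group_by is None:
        perm = rng.permutation(len(frame_ids))
        shuffled = [frame_ids[i] for i in perm]
        n_train, n_val, _ = _target_sizes(len(frame_ids), spec.ratios)
        return (
            shuffled[:n_train],
            shuffled[n_train : n_train + n_val],
            shuffled[n_train + n_val :],
        )
    groups: dict[str, list[str]] = {}
    for fid in frame_ids:
        groups.setdefault(video_of(fid), []).append(fid)
    n_nonzero = sum(1 for r in spec.ratios if r > 0)
    if len(groups) < n_nonzero:
        raise ValueError(
            f"{len(groups)} video group(s) but {n_nonzero} nonzero splits; "
            "cannot keep videos whole"
        )
    names = sorted(groups)
    perm = rng.permutation(len(names))
    targets = [len(frame_ids) * r for r in spec.ratios]
    assigned: list[list[str]] = [[], [], []]
    counts = [0.0, 0.0, 0.0]
    for gi in perm:
        members = groups[names[gi]]
        # most under-target split; skip zero-ratio splits
        deficits = [
            (targets[s] - counts[s]) if spec.ratios[s] > 0 else -np.inf
            for s in range(3)
        ]
        s = int(np.argmax(deficits))
        assigned[s].extend(members)
        counts[s] += len(members)
    return assigned[0], assigned[1], assigned[2]


# ---------------------------------------------------------------------------
# Geometric augmentations


def _rotation_transform(
    width: int, height: int, angle_deg: float
) -> tuple[np.ndarray, int, int]:
    """3x3 homogeneous matrix mapping input (x, y) to output coordinates
    for a rotation about the image centre with an expanded canvas, plus
    the output canvas size."""
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    # In display coordinates (y down) this matrix rotates the image
    # content counterclockwise on screen for positive angles.
    rot = np.array([[c, -s], [s, c]])
    centre = np.array([(width - 1) / 2.0, (height - 1) / 2.0])
    corners = np.array(
        [[0, 0], [width - 1, 0], [0, height - 1], [width - 1, height - 1]],
        dtype=float,
    )
    moved = (corners - centre) @ rot.T + centre
    mins = moved.min(axis=0)
    maxs = moved.max(axis=0)
    out_w = int(math.ceil(maxs[0] - mins[0] - 1e-9)) + 1
    out_h = int(math.ceil(maxs[1] - mins[1] - 1e-9)) + 1
    shift = -mins
    matrix = np.eye(3)
    matrix[:2, :2] = rot
    matrix[:2, 2] = centre - rot @ centre + shift
    return matrix, out_w, out_h


def map_points(matrix: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Apply a 3x3 homogeneous transform to an (N, 2) array of (x, y)."""
    xy = np.asarray(xy, dtype=float)
    homo = np.c_[xy, np.ones(len(xy))]
    out = homo @ matrix.T
    return out[:, :2]


def _warp(frame: np.ndarray, matrix: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    tf = sktransform.AffineTransform(matrix=np.linalg.inv(matrix))
    if frame.ndim == 2:
        return sktransform.warp(
            frame, tf, output_shape=out_shape, order=1, cval=0.0,
            preserve_range=True,
        ).astype(frame.dtype, copy=False)
    channels = [
        sktransform.warp(
            frame[..., ch], tf, output_shape=out_shape, order=1, cval=0.0,
            preserve_range=True,
        )
        for ch in range(frame.shape[-1])
    ]
    return np.stack(channels, axis=-1).astype(frame.dtype, copy=False)


def rotate_with_labels(
    frame: np.ndarray, anns: list[KeypointAnnotation], angle: float
) -> tuple[np.ndarray, list[KeypointAnnotation]]:
    """Rotate a frame about its centre on an expanded, black-padded canvas
    and map annotation coordinates through the identical affine map.
    Box dimensions are unchanged."""
    height, width = frame.shape[:2]
    matrix, out_w, out_h = _rotation_transform(width, height, angle)
    if angle % 360 == 0:
        return frame.copy(), list(anns)
    out = _warp(frame, matrix, (out_h, out_w))
    xy = map_points(matrix, [[a.x, a.y] for a in anns]) if anns else np.empty((0, 2))
    new_anns = [
        replace(a, x=float(p[0]), y=float(p[1])) for a, p in zip(anns, xy)
    ]
    return out, new_anns


def flip_with_labels(
    frame: np.ndarray,
    anns: list[KeypointAnnotation],
    axis: str,
    swap_map: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[KeypointAnnotation]]:
    """Mirror a frame about the x-, y-, or both axes and mirror the
    annotation coordinates accordingly.

    ``axis="y"`` mirrors horizontally (x -> W-1-x), ``"x"`` vertically
    (y -> H-1-y), ``"xy"`` both.  ``swap_map`` optionally exchanges
    bilaterally symmetric keypoint names (e.g. left/right paws); it must
    be an involutive bijection.
    """
    if axis not in ("x", "y", "xy"):
        raise ValueError(f"axis must be 'x', 'y' or 'xy', got {axis!r}")
    full_swap: dict[str, str] = {}
    if swap_map:
        for a, b in swap_map.items():
            for k, v in ((a, b), (b, a)):
                if full_swap.get(k, v) != v:
                    raise ValueError(f"swap map is not a bijection at {k!r}")
                full_swap[k] = v
    height, width = frame.shape[:2]
    out = frame
    if "y" in axis:
        out = out[:, ::-1]
    if "x" in axis:
        out = out[::-1, :]
    new_anns = []
    for a in anns:
        x = (width - 1) - a.x if "y" in axis else a.x
        y = (height - 1) - a.y if "x" in axis else a.y
        new_anns.append(
            replace(a, x=x, y=y, keypoint=full_swap.get(a.keypoint, a.keypoint))
        )
    return out.copy(), new_anns


def resize_area_with_labels(
    frame: np.ndarray,
    anns: list[KeypointAnnotation],
    out_w: int,
    out_h: int,
) -> tuple[np.ndarray, list[KeypointAnnotation]]:
    """Resize a frame (area-average when shrinking, bilinear when
    enlarging) and scale annotation coordinates and box sizes by the same
    factors."""
    if out_w < 1 or out_h < 1:
        raise ValueError(f"target dimensions must be >= 1, got {out_w}x{out_h}")
    height, width = frame.shape[:2]
    out_shape = (out_h, out_w) + frame.shape[2:]
    if out_w <= width and out_h <= height:
        out = sktransform.resize_local_mean(frame, out_shape, preserve_range=True)
    else:
        out = sktransform.resize(
            frame, out_shape, order=1, preserve_range=True, anti_aliasing=False
        )
    out = out.astype(frame.dtype, copy=False)
    sx = out_w / width
    sy = out_h / height
    new_anns = [
        replace(
            a,
            x=a.x * sx,
            y=a.y * sy,
            box_w=max(1, int(round(a.box_w * sx))),
            box_h=max(1, int(round(a.box_h * sy))),
        )
        for a in anns
    ]
    return out, new_anns


def random_augment(
    frame: np.ndarray,
    anns: list[KeypointAnnotation],
    spec: AugmentSpec,
    rng: np.random.Generator | None = None,
    swap_map: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[KeypointAnnotation], dict]:
    """Apply one random rotation plus seeded flips per ``spec``.

    Returns the augmented frame, mapped annotations, and a record of the
    parameters applied (for reproducibility logs).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    angle = float(rng.uniform(*spec.rotation_range))
    frame, anns = rotate_with_labels(frame, anns, angle)
    applied = {"angle": angle, "flips": []}
    axes: list[str] = []
    if spec.flip_mode == "y_axis":
        axes = ["y"]
    elif spec.flip_mode == "all_axes":
        axes = ["x", "y"]
    for ax in axes:
        if rng.random() < 0.5:
            frame, anns = flip_with_labels(frame, anns, ax, swap_map=swap_map)
            applied["flips"].append(ax)
    return frame, anns, applied


def make_training_target(stack, peak: float = 16.0, stages: int = 1):
    """Scale a label stack by the training peak value, one copy per
    supervision stage.

    Multiplying the unit-peak labels by a large peak (default 16)
    increases the contrast between the label region and the rest of the
    image during regression training; evaluation-side labels are never
    scaled.  Returns ``stages`` independent scaled copies.
    """
    from .labels import HeatmapStack

    if peak <= 0:
        raise ValueError(f"peak must be > 0, got {peak}")
    if stages < 1:
        raise ValueError(f"stages must be >= 1, got {stages}")
    return [
        HeatmapStack(
            data=stack.data * peak,
            keypoint_order=stack.keypoint_order,
            missing=stack.missing,
        )
        for _ in range(stages)
    ]
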