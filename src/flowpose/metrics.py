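"""Evaluation of predicted keypoint locations: aPCK and RMSE.

aPCK (adjusted percentage of correct key points) counts a prediction as
correct when its decoded location lands inside the nonzero support of
the human-defined ground-truth heatmap label -- the acceptance region
the labeller drew, whatever its size per keypoint.  The reported "error
rate" is 1 - aPCK.  Unlike a fixed-radius PCK or RMSE, the metric
adapts to keypoints of very different physical sizes, which is the
normal situation across animal body plans.

Frames whose label grid is all-zero for a keypoint (the keypoint was
absent/unlabelled there) are excluded from that keypoint's denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .labels import HeatmapLabel, HeatmapStack

__all__ = [
    "EvalReport",
    "argmax_location",
    "is_correct_apck",
    "apck_error_table",
    "rmse_table",
    "paired_error_ttest",
    "read_locations",
    "write_locations",
]


def argmax_location(grid: np.ndarray) -> tuple[int, int]:
    """(x, y) of the global maximum of a heatmap grid; ties break at the
    smallest row-major index.  NaNs are ignored; an all-NaN grid is an
    error."""
    grid = np.asarray(grid)
    if np.isnan(grid).all():
        raise ValueError("cannot decode an all-NaN heatmap")
    flat = np.nanargmax(grid)
    r, c = np.unravel_index(int(flat), grid.shape)
    return int(c), int(r)


def _nearest_pixel(x: float, y: float) -> tuple[int, int]:
    # round-half-up, consistent with the label box placement
    return int(np.floor(x + 0.5)), int(np.floor(y + 0.5))


def is_correct_apck(
    pred: tuple[float, float], gt: HeatmapLabel | np.ndarray
) -> bool:
    """True iff the prediction's nearest pixel has a strictly positive
    ground-truth label value (i.e. lies in the acceptance region).
    Predictions outside the image count as incorrect."""
    grid = gt.grid if isinstance(gt, HeatmapLabel) else np.asarray(gt)
    c, r = _nearest_pixel(float(pred[0]), float(pred[1]))
    height, width = grid.shape
    if not (0 <= c < width and 0 <= r < height):
        return False
    return bool(grid[r, c] > 0)


@dataclass
class EvalReport:
    """Per-keypoint evaluation table plus summary statistics.

    ``table`` is indexed by keypoint with columns ``n_eval``,
    ``n_correct`` (aPCK only), ``apck_error`` and/or ``rmse``.  The mean
    and SD are taken across keypoints (each keypoint weighted equally,
    matching per-keypoint reporting).
    """

    table: pd.DataFrame

    @property
    def mean_error(self) -> float:
        return float(self.table["apck_error"].mean())

    @property
    def sd_error(self) -> float:
        return float(self.table["apck_error"].std(ddof=1))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="keypoint")

    def __str__(self) -> str:
        lines = [self.table.to_string()]
        if "apck_error" in self.table:
            lines.append(
                f"MEAN apck_error = {self.mean_error:.6f}  "
                f"SD = {self.sd_error:.6f}"
            )
        return "\n".join(lines)


def _locs_array(preds, n_frames: int, n_kp: int) -> np.ndarray:
    arr = np.asarray(preds, dtype=np.float64)
    if arr.shape != (n_frames, n_kp, 2):
        raise ValueError(
            f"predictions must be (n_frames, P, 2) = ({n_frames}, {n_kp}, 2), "
            f"got {arr.shape}"
        )
    return arr


def apck_error_table(preds, gts: list[HeatmapStack]) -> EvalReport:
    """Per-keypoint aPCK error rates for a sequence.

    ``preds`` is an (n_frames, P, 2) array of (x, y) locations aligned
    with the keypoint order of the ground-truth stacks ``gts``.  A
    keypoint with zero evaluable frames gets a NaN (missing) rate.
    """
    if not gts:
        raise ValueError("no ground-truth stacks supplied")
    order = gts[0].keypoint_order
    n_kp = len(order)
    arr = _locs_array(preds, len(gts), n_kp)
    n_eval = np.zeros(n_kp, dtype=np.int64)
    n_correct = np.zeros(n_kp, dtype=np.int64)
    for t, stack in enumerate(gts):
        if stack.keypoint_order != order:
            raise ValueError(f"keypoint order differs at frame {t}")
        for p in range(n_kp):
            grid = stack.data[p]
            if not grid.any():
                continue  # absent keypoint: excluded from the denominator
            n_eval[p] += 1
            if is_correct_apck(arr[t, p], grid):
                n_correct[p] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        err = np.where(n_eval > 0, 1.0 - n_correct / np.maximum(n_eval, 1), np.nan)
    table = pd.DataFrame(
        {"n_eval": n_eval, "n_correct": n_correct, "apck_error": err},
        index=pd.Index(order, name="keypoint"),
    )
    return EvalReport(table=table)


def rmse_table(preds, gt_points, keypoint_order, valid=None) -> EvalReport:
    """Per-keypoint RMSE (pixels) of predicted against true point
    coordinates; ``valid`` optionally masks out (frame, keypoint) pairs
    excluded from evaluation."""
    order = tuple(keypoint_order)
    gt = np.asarray(gt_points, dtype=np.float64)
    arr = _locs_array(preds, gt.shape[0], gt.shape[1])
    if valid is None:
        valid = np.ones(gt.shape[:2], dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    sq = ((arr - gt) ** 2).sum(axis=2)
    n_eval = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmse = np.sqrt(np.where(valid, sq, 0.0).sum(axis=0) / np.maximum(n_eval, 1))
    rmse = np.where(n_eval > 0, rmse, np.nan)
    table = pd.DataFrame(
        {"n_eval": n_eval, "rmse": rmse}, index=pd.Index(order, name="keypoint")
    )
    return EvalReport(table=table)


def paired_error_ttest(a: EvalReport, b: EvalReport):
    """Paired t-test (paired by keypoint) between two models'
    per-keypoint aPCK error rates.  Returns the scipy result object."""
    if list(a.table.index) != list(b.table.index):
        raise ValueError("reports cover different keypoints")
    return stats.ttest_rel(a.table["apck_error"], b.table["apck_error"])


# ---------------------------------------------------------------------------
# Location-table serialization (frame_id, keypoint, x, y)


def write_locations(
    locations: np.ndarray,
    keypoint_order,
    path: str | Path,
    frame_ids=None,
) -> None:
    locations = np.asarray(locations)
    n_frames, n_kp = locations.shape[:2]
    if frame_ids is None:
        frame_ids = [f"{t:05d}" for t in range(n_frames)]
    rows = [
        {
            "frame_id": frame_ids[t],
            "keypoint": keypoint_order[p],
            "x": float(locations[t, p, 0]),
            "y": float(locations[t, p, 1]),
        }
        for t in range(n_frames)
        for p in range(n_kp)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_locations(path: str | Path, keypoint_order=None):
    """Read a location table; returns ((n_frames, P, 2) array, frame ids,
    keypoint order).  Frames are ordered by first appearance."""
    df = pd.read_csv(path, dtype={"frame_id": str})
    for col in ("frame_id", "keypoint", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    frame_ids = list(dict.fromkeys(df["frame_id"]))
    order = (
        tuple(keypoint_order)
        if keypoint_order is not None
        else tuple(dict.fromkeys(df["keypoint"]))
    )
    arr = np.full((len(frame_ids), len(order), 2), np.nan)
    f_idx = {f: i for i, f in enumerate(frame_ids)}
    k_idx = {k: i for i, k in enumerate(order)}
    for row in df.itertuples(index=False):
        arr[f_idx[row.frame_id], k_idx[row.keypoint]] = (row.x, row.y)
    return arr, frame_ids, order
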