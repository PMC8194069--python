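"""Keypoint annotations and their heatmap-label encoding.

A keypoint annotation is a point location plus a per-keypoint acceptance
box chosen by the human labeller.  Labels are encoded as truncated 2D
Gaussian heatmaps: the probability density is evaluated only inside the
box, rescaled so the maximum is exactly 1.0, and every value below 0.1 is
zeroed.  The nonzero support of the resulting grid is the region a
prediction must land in to count as correct under aPCK (see
:mod:`flowpose.metrics`).

Coordinate convention (used package-wide): 0-based, ``x`` = column,
``y`` = row, origin at the top-left; grids are indexed ``[row, column]``.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "KeypointAnnotation",
    "HeatmapLabel",
    "HeatmapStack",
    "generate_heatmap",
    "support_mask",
    "stack_labels",
    "read_annotations",
    "write_annotations",
    "save_stack",
    "load_stack",
]

#: Default Gaussian scale as a fraction of the box dimension per axis.
#: 0.25 places the box edges near +/-2 sigma, so the truncated tail is
#: small while most of the box stays above the 0.1 cut.
DEFAULT_SIGMA_FRAC = 0.25

#: Heatmap values strictly below this are zeroed after peak normalization.
SUPPORT_THRESHOLD = 0.1


@dataclass(frozen=True)
class KeypointAnnotation:
    """A single human-labelled keypoint with its acceptance box.

    ``x``/``y`` are continuous pixel coordinates (column/row); ``box_w``
    and ``box_h`` are the integer dimensions of the rectangular region the
    labeller considers "correct" for this keypoint.
    """

    frame_id: str
    keypoint: str
    x: float
    y: float
    box_w: int
    box_h: int

    def __post_init__(self) -> None:
        if self.box_w < 1 or self.box_h < 1:
            raise ValueError(
                f"annotation {self.frame_id}/{self.keypoint}: box dimensions "
                f"must be >= 1, got {self.box_w}x{self.box_h}"
            )


@dataclass
class HeatmapLabel:
    """A single-keypoint label grid (H x W, values in [0, 1])."""

    grid: np.ndarray
    keypoint: str


@dataclass
class HeatmapStack:
    """An ordered set of per-keypoint heatmaps sharing one image size.

    ``data`` has shape (P, H, W) in the order given by ``keypoint_order``.
    ``missing`` flags keypoints whose grid is all-zero because no
    annotation was available for them in this frame.
    """

    data: np.ndarray
    keypoint_order: tuple[str, ...]
    missing: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.keypoint_order = tuple(self.keypoint_order)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be (P, H, W), got {self.data.shape}")
        if self.data.shape[0] != len(self.keypoint_order):
            raise ValueError(
                f"{self.data.shape[0]} grids but {len(self.keypoint_order)} "
                "keypoint names"
            )

    @property
    def n_keypoints(self) -> int:
        return self.data.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def grid(self, keypoint: str) -> np.ndarray:
        return self.data[self.keypoint_order.index(keypoint)]


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def box_bounds(
    ann: KeypointAnnotation, width: int, height: int
) -> tuple[int, int, int, int]:
    """Integer pixel window (c0, c1, r0, r1), end-exclusive, clipped to the
    image, of the annotation's acceptance box centred on the nearest
    in-image pixel (so a visible annotation always has support)."""
    cc = min(max(_round_half_up(ann.x), 0), width - 1)
    cr = min(max(_round_half_up(ann.y), 0), height - 1)
    c0 = cc - (ann.box_w - 1) // 2
    r0 = cr - (ann.box_h - 1) // 2
    c1 = c0 + ann.box_w
    r1 = r0 + ann.box_h
    return max(c0, 0), min(c1, width), max(r0, 0), min(r1, height)


def generate_heatmap(
    ann: KeypointAnnotation,
    width: int,
    height: int,
    sigma_frac: float = DEFAULT_SIGMA_FRAC,
) -> HeatmapLabel:
    """Render a truncated-Gaussian heatmap label for one annotation.

    The Gaussian PDF (sigma_x = box_w * sigma_frac, sigma_y = box_h *
    sigma_frac) is evaluated at pixel centres inside the acceptance box
    only, zero outside, rescaled so the maximum equals 1.0, and values
    strictly below 0.1 are set to zero.

    Raises ``ValueError`` if the annotation lies outside the image.  If
    the box is entirely clipped away a zero grid is returned with a
    warning.
    """
    if sigma_frac <= 0:
        raise ValueError(f"sigma_frac must be > 0, got {sigma_frac}")
    if not (0 <= ann.x < width and 0 <= ann.y < height):
        raise ValueError(
            f"annotation {ann.frame_id}/{ann.keypoint} at ({ann.x}, {ann.y}) "
            f"lies outside the {width}x{height} image"
        )
    grid = np.zeros((height, width), dtype=np.float64)
    c0, c1, r0, r1 = box_bounds(ann, width, height)
    if c0 >= c1 or r0 >= r1:
        warnings.warn(
            f"acceptance box of {ann.frame_id}/{ann.keypoint} is entirely "
            "outside the image; emitting an all-zero label",
            stacklevel=2,
        )
        return HeatmapLabel(grid=grid, keypoint=ann.keypoint)
    sx = ann.box_w * sigma_frac
    sy = ann.box_h * sigma_frac
    cols = np.arange(c0, c1, dtype=np.float64)
    rows = np.arange(r0, r1, dtype=np.float64)
    gx = np.exp(-((cols - ann.x) ** 2) / (2.0 * sx * sx))
    gy = np.exp(-((rows - ann.y) ** 2) / (2.0 * sy * sy))
    patch = gy[:, None] * gx[None, :]
    patch /= patch.max()
    patch[patch < SUPPORT_THRESHOLD] = 0.0
    grid[r0:r1, c0:c1] = patch
    return HeatmapLabel(grid=grid, keypoint=ann.keypoint)


def support_mask(label: HeatmapLabel | np.ndarray) -> np.ndarray:
    """Boolean grid marking the aPCK "correct" region: True where > 0."""
    grid = label.grid if isinstance(label, HeatmapLabel) else np.asarray(label)
    return grid > 0


def stack_labels(
    anns: list[KeypointAnnotation],
    keypoint_order: list[str] | tuple[str, ...],
    width: int,
    height: int,
    sigma_frac: float = DEFAULT_SIGMA_FRAC,
) -> HeatmapStack:
    """Assemble one frame's annotations into a P-grid heatmap stack.

    Keypoints absent from ``anns`` yield all-zero grids and are recorded
    in ``missing``.  A duplicated keypoint raises ``ValueError``.
    """
    order = tuple(keypoint_order)
    by_name: dict[str, KeypointAnnotation] = {}
    for ann in anns:
        if ann.keypoint in by_name:
            raise ValueError(
                f"frame {ann.frame_id}: duplicate annotation for keypoint "
                f"{ann.keypoint!r}"
            )
        by_name[ann.keypoint] = ann
    unknown = set(by_name) - set(order)
    if unknown:
        raise ValueError(f"annotations for keypoints not in order: {sorted(unknown)}")
    data = np.zeros((len(order), height, width), dtype=np.float64)
    missing = []
    for p, name in enumerate(order):
        if name in by_name:
            data[p] = generate_heatmap(by_name[name], width, height, sigma_frac).grid
        else:
            missing.append(name)
    return HeatmapStack(data=data, keypoint_order=order, missing=frozenset(missing))


# ---------------------------------------------------------------------------
# Annotation serialization (CSV / JSON)

_CSV_FIELDS = ("frame_id", "keypoint", "x", "y", "box_w", "box_h")


def _record_from_row(row: dict, where: str) -> KeypointAnnotation:
    missing = [k for k in _CSV_FIELDS if k not in row or row[k] in (None, "")]
    if missing:
        raise ValueError(f"{where}: missing fields {missing}")
    try:
        x = float(row["x"])
        y = float(row["y"])
        box_w = int(row["box_w"])
        box_h = int(row["box_h"])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: non-numeric coordinate or box size ({exc})")
    if box_w < 1 or box_h < 1:
        raise ValueError(f"{where}: box dimensions must be >= 1, got {box_w}x{box_h}")
    return KeypointAnnotation(
        frame_id=str(row["frame_id"]),
        keypoint=str(row["keypoint"]),
        x=x,
        y=y,
        box_w=box_w,
        box_h=box_h,
    )


def read_annotations(path: str | Path) -> list[KeypointAnnotation]:
    """Read annotations from CSV (header ``frame_id,keypoint,x,y,box_w,box_h``)
    or a JSON array of equivalent records; format chosen by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValueError(f"{path}: expected a JSON array of records")
        return [
            _record_from_row(rec, f"{path.name} record {i}")
            for i, rec in enumerate(records)
        ]
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing = set(_CSV_FIELDS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        return [
            _record_from_row(row, f"{path.name} row {i}")
            for i, row in enumerate(reader, start=2)  # header is line 1
        ]


def write_annotations(anns: list[KeypointAnnotation], path: str | Path) -> None:
    """Write annotations as CSV or JSON (by extension); coordinates are
    kept to 6 decimals so a write/read round trip is lossless at that
    precision."""
    path = Path(path)
    rows = [
        {
            "frame_id": a.frame_id,
            "keypoint": a.keypoint,
            "x": f"{a.x:.6f}",
            "y": f"{a.y:.6f}",
            "box_w": a.box_w,
            "box_h": a.box_h,
        }
        for a in anns
    ]
    if path.suffix.lower() == ".json":
        records = [
            {**row, "x": float(row["x"]), "y": float(row["y"])} for row in rows
        ]
        path.write_text(json.dumps(records, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# Heatmap-stack persistence (NPZ or multi-page TIFF)


def save_stack(stack: HeatmapStack, path: str | Path) -> None:
    """Persist a heatmap stack as compressed NPZ (``.npz``) or multi-page
    TIFF (``.tif``/``.tiff``, keypoint names in the image description)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        np.savez_compressed(
            path,
            data=stack.data,
            keypoint_order=np.array(stack.keypoint_order),
            missing=np.array(sorted(stack.missing)),
        )
    elif suffix in (".tif", ".tiff"):
        meta = {
            "keypoint_order": list(stack.keypoint_order),
            "missing": sorted(stack.missing),
        }
        tifffile.imwrite(
            path,
            stack.data.astype(np.float32),
            photometric="minisblack",
            description=json.dumps(meta),
        )
    else:
        raise ValueError(f"unsupported stack format {suffix!r} (use .npz or .tif)")


def load_stack(path: str | Path) -> HeatmapStack:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            return HeatmapStack(
                data=npz["data"],
                keypoint_order=tuple(str(k) for k in npz["keypoint_order"]),
                missing=frozenset(str(k) for k in npz["missing"]),
            )
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = json.loads(tif.pages[0].description)
        return HeatmapStack(
            data=np.asarray(data, dtype=np.float64),
            keypoint_order=tuple(meta["keypoint_order"]),
            missing=frozenset(meta["missing"]),
        )
    raise ValueError(f"unsupported stack format {suffix!r} (use .npz or .tif)")
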