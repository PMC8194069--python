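"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from flowpose.labels import KeypointAnnotation


def brute_force_heatmap(
    ann: KeypointAnnotation, width: int, height: int, sigma_frac: float
) -> np.ndarray:
    """Independent per-pixel reference for the heatmap label: plain
    Python loops evaluating the Gaussian PDF inside the box, then
    normalize to max 1 and zero everything below 0.1."""
    cc = min(max(math.floor(ann.x + 0.5), 0), width - 1)
    cr = min(max(math.floor(ann.y + 0.5), 0), height - 1)
    c0 = cc - (ann.box_w - 1) // 2
    r0 = cr - (ann.box_h - 1) // 2
    sx = ann.box_w * sigma_frac
    sy = ann.box_h * sigma_frac
    grid = [[0.0] * width for _ in range(height)]
    peak = 0.0
    for r in range(height):
        for c in range(width):
            if c0 <= c < c0 + ann.box_w and r0 <= r < r0 + ann.box_h:
                v = math.exp(
                    -((c - ann.x) ** 2) / (2 * sx * sx)
                    - ((r - ann.y) ** 2) / (2 * sy * sy)
                )
                grid[r][c] = v
                peak = max(peak, v)
    for r in range(height):
        for c in range(width):
            v = grid[r][c] / peak if peak > 0 else 0.0
            grid[r][c] = v if v >= 0.1 else 0.0
    return np.array(grid)


def random_annotation(
    rng: np.random.Generator, width: int, height: int, frame_id: str = "f0",
    keypoint: str = "kp",
) -> KeypointAnnotation:
    return KeypointAnnotation(
        frame_id=frame_id,
        keypoint=keypoint,
        x=float(rng.uniform(0, width - 1e-6)),
        y=float(rng.uniform(0, height - 1e-6)),
        box_w=int(rng.integers(1, 15)),
        box_h=int(rng.integers(1, 15)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def textured_frame(rng) -> np.ndarray:
    """A 64x64 frame with smooth texture and one bright blob, giving
    optical flow something to lock onto."""
    from scipy.ndimage import gaussian_filter

    base = 0.2 + gaussian_filter(rng.normal(0, 0.08, (64, 64)), 1.5)
    yy, xx = np.mgrid[0:64, 0:64]
    base = base + 0.6 * np.exp(-(((xx - 30) ** 2 + (yy - 34) ** 2) / 8.0))
    return base.astype(np.float32)
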