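"""Multi-view keypoint correction across two views sharing the x-axis.

With a side and a bottom view of the same scene (e.g. a corridor with a
bottom mirror), a keypoint's x-coordinate is common to both views.  When
one view predicts a keypoint reliably (the reference view), its
x-coordinate can arbitrate between alternative peaks in the other view's
confidence heatmap: the corrected location is the candidate local
maximum whose x-value differs least from the reference x.  This fixes
failures where the true location survives in the heatmap as a secondary
peak while the global maximum jumped elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter

from .labels import HeatmapStack

__all__ = [
    "ViewPairing",
    "CandidatePeak",
    "local_maxima",
    "correct_keypoints",
]

DEFAULT_SMOOTH_SIGMA = 3.0
DEFAULT_MIN_REL = 0.1


@dataclass(frozen=True)
class CandidatePeak:
    """An alternative prediction location: a local maximum of the
    (smoothed) confidence heatmap."""

    x: int
    y: int
    score: float


@dataclass(frozen=True)
class ViewPairing:
    """Pairs of (side keypoint, bottom keypoint) names linked across the
    two views, plus which view serves as the x reference."""

    pairs: tuple[tuple[str, str], ...]
    reference_view: str = "bottom"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", tuple((str(a), str(b)) for a, b in self.pairs)
        )
        sides = [a for a, _ in self.pairs]
        bottoms = [b for _, b in self.pairs]
        if len(set(sides)) != len(sides) or len(set(bottoms)) != len(bottoms):
            raise ValueError("pairing must be injective on each side")


def local_maxima(
    grid: np.ndarray,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    min_rel: float = DEFAULT_MIN_REL,
) -> list[CandidatePeak]:
    """Candidate peaks of a heatmap after Gaussian smoothing.

    Returns pixels strictly greater than all 8 neighbours with score at
    least ``min_rel`` times the global maximum, sorted by descending
    score (ties: smaller row-major index).  The global maximum is always
    included.  An all-zero (or non-positive) grid yields no candidates.
    """
    if smooth_sigma < 0:
        raise ValueError(f"smooth_sigma must be >= 0, got {smooth_sigma}")
    if not 0 < min_rel <= 1:
        raise ValueError(f"min_rel must be in (0, 1], got {min_rel}")
    grid = np.asarray(grid, dtype=np.float64)
    sm = gaussian_filter(grid, smooth_sigma) if smooth_sigma > 0 else grid
    gmax = sm.max()
    if gmax <= 0:
        return []
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbour_max = maximum_filter(
        sm, footprint=footprint, mode="constant", cval=-np.inf
    )
    peaks = (sm > neighbour_max) & (sm >= min_rel * gmax)
    gr, gc = np.unravel_index(int(np.argmax(sm)), sm.shape)
    peaks[gr, gc] = True  # a plateau global max is still a candidate
    rows, cols = np.nonzero(peaks)
    order = sorted(
        range(len(rows)),
        key=lambda i: (-sm[rows[i], cols[i]], rows[i] * sm.shape[1] + cols[i]),
    )
    return [
        CandidatePeak(x=int(cols[i]), y=int(rows[i]), score=float(sm[rows[i], cols[i]]))
        for i in order
    ]


def correct_keypoints(
    side_stack: HeatmapStack,
    side_locs: dict[str, tuple[float, float]],
    bottom_locs: dict[str, tuple[float, float]],
    pairing: ViewPairing,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    min_rel: float = DEFAULT_MIN_REL,
) -> tuple[dict[str, tuple[float, float]], set[str]]:
    """Correct side-view keypoint locations against bottom-view x-values.

    For every paired side keypoint, candidate peaks are gathered from its
    side-view heatmap and the location is replaced by the candidate with
    the least |x - x_reference| (ties: higher score, then smaller
    row-major index).  The original location is kept whenever it already
    matches the reference at least as well, so the correction never
    increases |x_side - x_reference|.  Unpaired keypoints are untouched.

    Returns the corrected location map and the set of keypoints flagged
    because no candidate peak existed.
    """
    corrected = dict(side_locs)
    flagged: set[str] = set()
    for side_kp, bottom_kp in pairing.pairs:
        if side_kp not in side_locs or bottom_kp not in bottom_locs:
            raise KeyError(
                f"pairing ({side_kp!r}, {bottom_kp!r}) not present in the "
                "supplied locations"
            )
        ref_x = float(bottom_locs[bottom_kp][0])
        candidates = local_maxima(
            side_stack.grid(side_kp), smooth_sigma=smooth_sigma, min_rel=min_rel
        )
        if not candidates:
            flagged.add(side_kp)
            continue
        width = side_stack.image_shape[1]
        best = min(
            candidates,
            key=lambda c: (abs(c.x - ref_x), -c.score, c.y * width + c.x),
        )
        cur = side_locs[side_kp]
        if abs(best.x - ref_x) <= abs(float(cur[0]) - ref_x):
            corrected[side_kp] = (float(best.x), float(best.y))
    return corrected, flagged
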