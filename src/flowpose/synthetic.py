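"""Seeded synthetic articulated-animal videos with ground-truth tracks.

The simulator renders P Gaussian blobs ("body parts") moving along
smooth sinusoidal trajectories over a lightly textured static background
-- a stand-in for a behaving animal filmed on a uniform arena.  The
texture gives dense optical flow gradients to lock onto (perfectly flat
backgrounds make flow ill-posed); per-frame sensor noise is added on
top.  Temporary occlusion episodes cover a keypoint's blob with a moving
rectangle, mimicking e.g. overlapping paws during gait, while the true
track continues underneath.

Every random choice derives from the single scene seed, so a fixed spec
reproduces frames bit-for-bit.  A paired orthogonal view can be
generated that shares the x-coordinate of every keypoint with the first
view (side/bottom mirror geometry), with independent y-trajectories and
independent occlusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .base_model import MockPredictorConfig
from .flow import FrameWindowSpec
from .labels import DEFAULT_SIGMA_FRAC, HeatmapStack, KeypointAnnotation, stack_labels

__all__ = [
    "OcclusionSpec",
    "SceneSpec",
    "TrackSet",
    "Scenario",
    "simulate_sequence",
    "simulate_two_views",
    "truth_stacks",
    "standard_scenarios",
]


@dataclass(frozen=True)
class OcclusionSpec:
    """Occlusion episode process per keypoint.

    ``rate_per_100`` is the expected number of episode starts per 100
    frames; episode length is fixed at ``run_length`` frames, or drawn
    geometrically with that mean when ``geometric`` is true.
    """

    rate_per_100: float = 0.0
    run_length: int = 1
    geometric: bool = False

    def __post_init__(self) -> None:
        if self.rate_per_100 < 0:
            raise ValueError("rate_per_100 must be >= 0")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Keypoint p follows
    ``x_p(t) = x0_p + A sin(2 pi t / T + phi_p) + drift_x t`` with a
    smaller independent sinusoid in y (amplitude ``y_amplitude_frac * A``),
    so different keypoints move out of phase like alternating limbs.
    Trajectories must stay at least 3 blob sigma away from the borders.
    """

    width: int = 96
    height: int = 96
    n_keypoints: int = 4
    n_frames: int = 500
    amplitude: float = 12.0  # px, x sinusoid
    period: float = 60.0  # frames
    y_amplitude_frac: float = 0.4
    drift: tuple[float, float] = (0.0, 0.0)  # px/frame
    blob_sigma: float = 2.0
    blob_amplitude: float = 0.6
    background: float = 0.2
    texture_amp: float = 0.08
    texture_smooth: float = 1.5
    noise_sigma: float = 0.01
    occlusion: OcclusionSpec = field(default_factory=OcclusionSpec)
    box_scale: float = 4.0  # annotation box side = box_scale * blob_sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_keypoints < 1:
            raise ValueError("n_keypoints must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def keypoint_order(self) -> tuple[str, ...]:
        return tuple(f"kp{p}" for p in range(self.n_keypoints))

    @property
    def box_size(self) -> int:
        return max(1, int(round(self.box_scale * self.blob_sigma)))


@dataclass
class TrackSet:
    """Ground truth for a simulated sequence: per-frame, per-keypoint
    true (x, y) locations, visibility flags, and occlusion flags
    (occluded keypoints are invisible but keep a valid true location)."""

    locations: np.ndarray  # (n_frames, P, 2)
    occluded: np.ndarray  # (n_frames, P) bool
    keypoint_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=np.float64)
        self.occluded = np.asarray(self.occluded, dtype=bool)
        self.keypoint_order = tuple(self.keypoint_order)

    @property
    def visible(self) -> np.ndarray:
        return ~self.occluded

    @property
    def n_frames(self) -> int:
        return self.locations.shape[0]


def _margin(spec: SceneSpec) -> float:
    return 3.0 * spec.blob_sigma


def _base_positions(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Rest positions spread over the image with room for the motion."""
    amp_x = abs(spec.amplitude)
    amp_y = abs(spec.amplitude) * spec.y_amplitude_frac
    lo_x = _margin(spec) + amp_x
    hi_x = spec.width - 1 - _margin(spec) - amp_x
    lo_y = _margin(spec) + amp_y
    hi_y = spec.height - 1 - _margin(spec) - amp_y
    if lo_x >= hi_x or lo_y >= hi_y:
        raise ValueError(
            "scene too small for the requested amplitude and blob size"
        )
    n = spec.n_keypoints
    xs = np.linspace(lo_x, hi_x, n + 2)[1:-1]
    ys = np.linspace(lo_y, hi_y, n + 2)[1:-1]
    # stagger y so keypoints do not share rows; small seeded offset
    ys = ys[rng.permutation(n)]
    jitter = rng.uniform(-1.0, 1.0, size=(n, 2))
    return np.c_[xs, ys] + jitter


def _trajectories(
    spec: SceneSpec,
    base: np.ndarray,
    phases: np.ndarray,
    y_rng: np.random.Generator | None = None,
    y_base: np.ndarray | None = None,
    y_phases: np.ndarray | None = None,
) -> np.ndarray:
    t = np.arange(spec.n_frames, dtype=np.float64)[:, None]
    omega_x = 2.0 * np.pi / spec.period
    omega_y = 2.0 * np.pi / (0.7 * spec.period)
    yb = base[:, 1] if y_base is None else y_base
    yp = phases + 1.0 if y_phases is None else y_phases
    x = base[None, :, 0] + spec.amplitude * np.sin(omega_x * t + phases[None, :])
    y = yb[None, :] + spec.amplitude * spec.y_amplitude_frac * np.sin(
        omega_y * t + yp[None, :]
    )
    x = x + spec.drift[0] * t
    y = y + spec.drift[1] * t
    locs = np.stack([x, y], axis=2)
    m = _margin(spec)
    if (
        locs[..., 0].min() < m
        or locs[..., 0].max() > spec.width - 1 - m
        or locs[..., 1].min() < m
        or locs[..., 1].max() > spec.height - 1 - m
    ):
        raise ValueError(
            "trajectories escape the 3-sigma border margin; reduce amplitude "
            "or drift"
        )
    return locs


def _occlusion_schedule(
    spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    occ = np.zeros((spec.n_frames, spec.n_keypoints), dtype=bool)
    o = spec.occlusion
    if o.rate_per_100 <= 0:
        return occ
    start_prob = o.rate_per_100 / 100.0
    for p in range(spec.n_keypoints):
        t = 0
        while t < spec.n_frames:
            if rng.random() < start_prob:
                length = (
                    int(rng.geometric(1.0 / o.run_length))
                    if o.geometric
                    else o.run_length
                )
                occ[t : t + length, p] = True
                t += length + 1  # at least one clear frame between episodes
            else:
                t += 1
    return occ


def _render_frame(
    spec: SceneSpec,
    texture: np.ndarray,
    locs: np.ndarray,
    occluded: np.ndarray,
    noise_rng: np.random.Generator,
) -> np.ndarray:
    frame = texture.copy()
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    two_s2 = 2.0 * spec.blob_sigma**2
    for p in range(spec.n_keypoints):
        x, y = locs[p]
        frame += spec.blob_amplitude * np.exp(
            -(((xx - x) ** 2 + (yy - y) ** 2) / two_s2)
        )
    half = int(round(3 * spec.blob_sigma)) + 1
    for p in range(spec.n_keypoints):
        if occluded[p]:
            x, y = locs[p]
            r0 = max(int(round(y)) - half, 0)
            r1 = min(int(round(y)) + half + 1, spec.height)
            c0 = max(int(round(x)) - half, 0)
            c1 = min(int(round(x)) + half + 1, spec.width)
            frame[r0:r1, c0:c1] = spec.background + 0.25  # occluder panel
    if spec.noise_sigma > 0:
        frame = frame + noise_rng.normal(0.0, spec.noise_sigma, frame.shape)
    return frame.astype(np.float32)


def _texture(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, spec.texture_amp, (spec.height, spec.width))
    return spec.background + gaussian_filter(noise, spec.texture_smooth)


def _annotations(spec: SceneSpec, tracks: TrackSet) -> list[KeypointAnnotation]:
    box = spec.box_size
    return [
        KeypointAnnotation(
            frame_id=f"{t:05d}",
            keypoint=tracks.keypoint_order[p],
            x=float(tracks.locations[t, p, 0]),
            y=float(tracks.locations[t, p, 1]),
            box_w=box,
            box_h=box,
        )
        for t in range(tracks.n_frames)
        for p in range(len(tracks.keypoint_order))
    ]


def simulate_sequence(
    spec: SceneSpec,
) -> tuple[np.ndarray, TrackSet, list[KeypointAnnotation]]:
    """Render a seeded synthetic sequence.

    Returns the (n_frames, H, W) float32 frame array, the ground-truth
    :class:`TrackSet`, and the per-frame keypoint annotations (fixed
    square acceptance boxes of side ``box_scale * blob_sigma``).
    """
    root = np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 0x51C3])
    pos_rng, tex_rng, occ_rng, noise_rng = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    base = _base_positions(spec, pos_rng)
    phases = 2.0 * np.pi * np.arange(spec.n_keypoints) / max(spec.n_keypoints, 1)
    locs = _trajectories(spec, base, phases)
    occ = _occlusion_schedule(spec, occ_rng)
    tracks = TrackSet(
        locations=locs, occluded=occ, keypoint_order=spec.keypoint_order
    )
    texture = _texture(spec, tex_rng)
    frames = np.stack(
        [
            _render_frame(spec, texture, locs[t], occ[t], noise_rng)
            for t in range(spec.n_frames)
        ]
    )
    return frames, tracks, _annotations(spec, tracks)


def simulate_two_views(
    spec: SceneSpec,
) -> tuple[
    tuple[np.ndarray, TrackSet, list[KeypointAnnotation]],
    tuple[np.ndarray, TrackSet, list[KeypointAnnotation]],
]:
    """Render paired side/bottom views sharing per-keypoint x(t) exactly.

    The y-trajectories of the two views are independent (each view sees
    an independent vertical component), as are occlusion episodes and
    sensor noise.
    """
    root = np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 0x2B1E])
    (pos_rng, y2_rng, tex1_rng, tex2_rng, occ1_rng, occ2_rng,
     noise1_rng, noise2_rng) = (np.random.default_rng(s) for s in root.spawn(8))
    base = _base_positions(spec, pos_rng)
    phases = 2.0 * np.pi * np.arange(spec.n_keypoints) / max(spec.n_keypoints, 1)
    # second view: same x, independent y rest positions and phases
    amp_y = abs(spec.amplitude) * spec.y_amplitude_frac
    lo_y = _margin(spec) + amp_y
    hi_y = spec.height - 1 - _margin(spec) - amp_y
    y2_base = y2_rng.uniform(lo_y, hi_y, size=spec.n_keypoints)
    y2_phases = y2_rng.uniform(0.0, 2.0 * np.pi, size=spec.n_keypoints)
    locs1 = _trajectories(spec, base, phases)
    locs2 = _trajectories(spec, base, phases, y_base=y2_base, y_phases=y2_phases)
    assert np.array_equal(locs1[..., 0], locs2[..., 0])
    views = []
    for locs, tex_rng, occ_rng, noise_rng in (
        (locs1, tex1_rng, occ1_rng, noise1_rng),
        (locs2, tex2_rng, occ2_rng, noise2_rng),
    ):
        occ = _occlusion_schedule(spec, occ_rng)
        tracks = TrackSet(
            locations=locs, occluded=occ, keypoint_order=spec.keypoint_order
        )
        texture = _texture(spec, tex_rng)
        frames = np.stack(
            [
                _render_frame(spec, texture, locs[t], occ[t], noise_rng)
                for t in range(spec.n_frames)
            ]
        )
        views.append((frames, tracks, _annotations(spec, tracks)))
    return views[0], views[1]


def truth_stacks(
    tracks: TrackSet, spec: SceneSpec, sigma_frac: float = DEFAULT_SIGMA_FRAC
) -> list[HeatmapStack]:
    """Ground-truth heatmap labels for every frame of a simulated
    sequence (occluded keypoints keep their labels: the truth is known
    even when the blob is covered)."""
    box = spec.box_size
    stacks = []
    for t in range(tracks.n_frames):
        anns = [
            KeypointAnnotation(
                frame_id=f"{t:05d}",
                keypoint=tracks.keypoint_order[p],
                x=float(tracks.locations[t, p, 0]),
                y=float(tracks.locations[t, p, 1]),
                box_w=box,
                box_h=box,
            )
            for p in range(len(tracks.keypoint_order))
        ]
        stacks.append(
            stack_labels(anns, tracks.keypoint_order, spec.width, spec.height,
                         sigma_frac)
        )
    return stacks


@dataclass(frozen=True)
class Scenario:
    """A named study condition: a scene plus the mock-predictor and
    window configuration exercised on it."""

    name: str
    scene: SceneSpec
    mock: MockPredictorConfig
    window: FrameWindowSpec = field(default_factory=FrameWindowSpec)
    reference_mock: MockPredictorConfig | None = None  # bottom view, if any
    description: str = ""


def standard_scenarios(seed: int = 0) -> dict[str, Scenario]:
    """The named presets used throughout the test suite.

    ``static``: zero-motion scene, clean mock -- temporal aggregation
    must change nothing.  ``gait``: out-of-phase sinusoidal limb motion,
    clean mock.  ``isolated-errors``: the gait scene with strictly
    isolated single-frame mock failures (error probability 0.15,
    displacement 40 px) -- the condition temporal aggregation corrects.
    ``error-runs``: same, but failures persist for 9 consecutive frames,
    spanning the whole default window -- the documented limitation.
    ``two-view-swap``: paired views; side-view failures are x-displaced
    but retain a truthful secondary peak, the bottom view is reliable --
    the condition multi-view correction fixes.
    """
    gait_scene = SceneSpec(seed=seed)
    scenarios = {
        "static": Scenario(
            name="static",
            scene=SceneSpec(amplitude=0.0, n_frames=120, seed=seed),
            mock=MockPredictorConfig(loc_noise_sigma=0.0, error_prob=0.0, seed=seed),
            description="zero motion, clean predictions",
        ),
        "gait": Scenario(
            name="gait",
            scene=gait_scene,
            mock=MockPredictorConfig(loc_noise_sigma=0.5, error_prob=0.0, seed=seed),
            description="sinusoidal limb-like motion, clean predictions",
        ),
        "isolated-errors": Scenario(
            name="isolated-errors",
            scene=gait_scene,
            mock=MockPredictorConfig(
                loc_noise_sigma=0.5,
                error_prob=0.15,
                error_displacement=40.0,
                error_run_length=1,
                seed=seed,
            ),
            description="isolated single-frame failures (the correctable case)",
        ),
        "error-runs": Scenario(
            name="error-runs",
            scene=gait_scene,
            mock=MockPredictorConfig(
                loc_noise_sigma=0.5,
                error_prob=0.15,
                error_displacement=40.0,
                error_run_length=9,
                seed=seed,
            ),
            description="9-frame failure runs spanning the window (uncorrectable)",
        ),
        "two-view-swap": Scenario(
            name="two-view-swap",
            scene=gait_scene,
            mock=MockPredictorConfig(
                loc_noise_sigma=0.5,
                error_prob=0.15,
                error_displacement=40.0,
                error_axis="x",
                truth_peak_frac=0.6,
                seed=seed,
            ),
            reference_mock=MockPredictorConfig(
                loc_noise_sigma=0.5, error_prob=0.0, seed=seed + 1
            ),
            description="side-view x-swaps with truthful secondary peaks; "
            "clean bottom reference",
        ),
    }
    return scenarios


def get_scenario(name: str, seed: int = 0) -> Scenario:
    scenarios = standard_scenarios(seed)
    if name not in scenarios:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(scenarios)}"
        )
    return scenarios[name]
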