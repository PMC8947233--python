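"""Synthetic plate-video generator with per-frame ground truth.

Emulates recordings of crawling *C. elegans* on an agar plate: dark,
elongated, undulating bodies (~1 mm) on a light background, imaged from
below at a few frames per second on a megapixel grayscale sensor.  Every
simulated worm carries a behavioral state machine (forward runs, abrupt
reversals, stationary coiled episodes) so that the downstream segmentation,
tracking and metric stages can be validated against exact ground truth.

The worm body is a discretized midline whose tangent angle varies
sinusoidally along the arc length (one undulation wavelength per body
length); this is the minimal shape model that supports centroid, topological
hole and mid-body-curvature readouts.  A coiled worm bends its midline into
a closed circle of circumference equal to the body length, which guarantees
an enclosed background hole at the default body width.

All randomness flows through a single :class:`numpy.random.Generator`
passed explicitly; identical (config, seed) pairs give bit-identical
frames and ground-truth tables.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

MODE_RUN = "RUN"
MODE_REVERSAL = "REVERSAL"
MODE_COIL = "COIL"

GROUND_TRUTH_COLUMNS = [
    "frame",
    "worm_id",
    "x_um",
    "y_um",
    "mode",
    "speed_um_s",
    "cum_reversals",
    "cum_bends",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic plate recording.

    Geometry and acquisition defaults mirror a 35 mm dish imaged on a
    1280 x 1024 grayscale sensor at 3 frames/s for 10 min.  Behavioral
    rates are per-worm Poisson intensities in events/min; episode
    durations are exponential with the stated means.
    """

    arena_size: tuple[int, int] = (1024, 1280)  # (rows, cols) in px
    um_per_px: float = 15.0
    fps: float = 3.0
    duration: float = 600.0  # s
    n_worms: int = 20
    body_length: float = 1000.0  # um
    body_width: float = 80.0  # um
    speed_mean: float = 50.0  # um/s, across worms
    speed_sd: float = 10.0  # um/s
    undulation_freq: float = 0.5  # Hz
    undulation_amp: float = 150.0  # um, lateral half-amplitude
    reversal_rate: float = 3.0  # events/min while running
    reversal_duration_mean: float = 2.0  # s
    coil_rate: float = 0.5  # events/min while running
    coil_duration_mean: float = 10.0  # s
    noise_sd: float = 5.0  # grayscale units (8-bit scale)
    seed: int = 0
    # rendering
    background_level: float = 200.0
    worm_level: float = 30.0
    n_midline_points: int = 21
    # boundary handling: smooth steering away from walls; a worm that
    # nevertheless reaches the inner margin is specularly reflected.
    boundary: str = "steer"  # "steer" | "reflect"
    steer_margin: float = 2000.0  # um, distance from wall where steering starts
    steer_rate: float = 35.0  # deg/s maximum steering turn rate

    def __post_init__(self) -> None:
        pos_fields = [
            "um_per_px", "fps", "duration", "body_length", "body_width",
            "speed_mean", "undulation_freq", "reversal_duration_mean",
            "coil_duration_mean", "background_level",
        ]
        for name in pos_fields:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ["speed_sd", "reversal_rate", "coil_rate", "noise_sd",
                     "undulation_amp", "worm_level"]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_worms < 0:
            raise ValueError("n_worms must be >= 0")
        if len(self.arena_size) != 2 or min(self.arena_size) < 8:
            raise ValueError("arena_size must be (rows, cols) with both >= 8")
        if self.n_midline_points < 11:
            raise ValueError("n_midline_points must be >= 11")
        if self.boundary not in ("steer", "reflect"):
            raise ValueError("boundary must be 'steer' or 'reflect'")
        if self.body_length / self.um_per_px >= min(self.arena_size):
            raise ValueError("arena too small to contain a worm")

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))

    @property
    def arena_um(self) -> tuple[float, float]:
        return (self.arena_size[0] * self.um_per_px,
                self.arena_size[1] * self.um_per_px)

    def worm_area_px(self) -> float:
        """Nominal rendered worm area in px^2 (length x width)."""
        return (self.body_length / self.um_per_px) * (
            self.body_width / self.um_per_px)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arena_size"] = list(self.arena_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "arena_size" in d:
            d["arena_size"] = tuple(d["arena_size"])
        return cls(**d)


@dataclass
class WormState:
    """Instantaneous state of one simulated worm.

    ``centroid`` is the body centroid in um, stored as (y, x) to match
    image (row, col) order.  ``phase`` is the undulation phase in radians;
    the mid-body curvature is extremal whenever the phase crosses a
    multiple of pi, which is how ground-truth body bends are counted.
    """

    centroid: np.ndarray  # (2,) um, (y, x)
    heading: float  # radians
    speed: float  # um/s forward speed while moving
    mode: str = MODE_RUN
    phase: float = 0.0
    mode_time_left: float = 0.0
    cum_reversals: int = 0
    cum_bends: int = 0

    def copy(self) -> "WormState":
        return WormState(
            centroid=self.centroid.copy(),
            heading=self.heading,
            speed=self.speed,
            mode=self.mode,
            phase=self.phase,
            mode_time_left=self.mode_time_left,
            cum_reversals=self.cum_reversals,
            cum_bends=self.cum_bends,
        )

    @property
    def instantaneous_speed(self) -> float:
        return 0.0 if self.mode == MODE_COIL else self.speed


@dataclass
class GroundTruth:
    """Per-(frame, worm) ground-truth table of a simulated cohort."""

    table: pd.DataFrame
    config: SimulationConfig

    def __post_init__(self) -> None:
        missing = set(GROUND_TRUTH_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"ground truth missing columns: {sorted(missing)}")

    def per_worm(self) -> "pd.api.typing.DataFrameGroupBy":
        return self.table.groupby("worm_id", sort=True)

    def mean_speed(self) -> float:
        return float(self.table["speed_um_s"].mean())

    def total_reversals(self) -> int:
        return int(self.per_worm()["cum_reversals"].max().sum())

    def total_bends(self) -> int:
        return int(self.per_worm()["cum_bends"].max().sum())

    def coil_fraction(self) -> float:
        return float((self.table["mode"] == MODE_COIL).mean())

    def reversals_per_min(self) -> float:
        worm_minutes = self.config.n_worms * self.config.duration / 60.0
        return self.total_reversals() / worm_minutes

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: SimulationConfig) -> "GroundTruth":
        return cls(pd.read_csv(path), config)


@dataclass
class ImageStack:
    """Ordered grayscale frames with pixel-size and frame-rate metadata."""

    frames: np.ndarray  # (T, H, W) uint8
    um_per_px: float
    fps: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


# ---------------------------------------------------------------------------
# worm shape
# ---------------------------------------------------------------------------

def midline_points(state: WormState, config: SimulationConfig,
                   n_points: int | None = None) -> np.ndarray:
    """Midline of a worm as ``(n, 2)`` (y, x) points in um.

    The tangent angle along arc length s is
    ``heading + alpha * sin(phase + 2*pi*s/L)`` for a running worm
    (alpha chosen so the lateral half-amplitude equals ``undulation_amp``)
    and ``heading + 2*pi*s/L`` for a coiled worm (a closed circle).
    Points are obtained by stepping equal arc-length increments along the
    tangent evaluated at segment midpoints, so consecutive points are
    exactly equidistant and the arc length is exactly ``body_length``.
    The polyline is translated so its mean equals the state centroid.
    """
    n = n_points if n_points is not None else config.n_midline_points
    L = config.body_length
    ds = L / (n - 1)
    s_mid = (np.arange(n - 1) + 0.5) * ds
    if state.mode == MODE_COIL:
        theta = state.heading + 2.0 * np.pi * s_mid / L
    else:
        alpha = 2.0 * np.pi * config.undulation_amp / L
        theta = state.heading + alpha * np.sin(
            state.phase + 2.0 * np.pi * s_mid / L)
    steps = np.stack([np.sin(theta), np.cos(theta)], axis=1) * ds  # (y, x)
    pts = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    pts -= pts.mean(axis=0)
    pts += state.centroid
    return pts


# ---------------------------------------------------------------------------
# behavior state machine
# ---------------------------------------------------------------------------

def _init_worm(rng: np.random.Generator, config: SimulationConfig) -> WormState:
    h_um, w_um = config.arena_um
    margin = min(config.steer_margin, 0.35 * min(h_um, w_um))
    margin = max(margin, 0.55 * config.body_length)
    y = rng.uniform(margin, h_um - margin)
    x = rng.uniform(margin, w_um - margin)
    heading = rng.uniform(0.0, 2.0 * np.pi)
    speed = rng.normal(config.speed_mean, config.speed_sd)
    speed = max(speed, 0.05 * config.speed_mean)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return WormState(centroid=np.array([y, x]), heading=heading,
                     speed=speed, phase=phase)


def _steer_from_walls(state: WormState, dt: float,
                      config: SimulationConfig) -> None:
    """Rotate the heading toward the arena center at a bounded turn rate
    whenever the worm is inside the wall margin and pointed outward.

    The turn rate is kept below the reversal detector's angle threshold per
    measurement window so wall avoidance never mimics a reversal.
    """
    h_um, w_um = config.arena_um
    margin = min(config.steer_margin, 0.35 * min(h_um, w_um))
    y, x = state.centroid
    d_wall = min(y, h_um - y, x, w_um - x)
    if d_wall >= margin:
        return
    target = math.atan2(h_um / 2.0 - y, w_um / 2.0 - x)
    diff = (target - state.heading + np.pi) % (2.0 * np.pi) - np.pi
    # only steer when heading has an outward component
    vy, vx = math.sin(state.heading), math.cos(state.heading)
    outward = (
        (y < margin and vy < 0) or (h_um - y < margin and vy > 0)
        or (x < margin and vx < 0) or (w_um - x < margin and vx > 0)
    )
    if not outward:
        return
    max_turn = math.radians(config.steer_rate) * dt
    state.heading += float(np.clip(diff, -max_turn, max_turn))


def _reflect(state: WormState, config: SimulationConfig) -> None:
    """Specular reflection at the inner hard margin (half a body length)."""
    h_um, w_um = config.arena_um
    lim = 0.55 * config.body_length
    y, x = state.centroid
    vy, vx = math.sin(state.heading), math.cos(state.heading)
    if y < lim:
        y = 2 * lim - y
        vy = abs(vy)
    elif y > h_um - lim:
        y = 2 * (h_um - lim) - y
        vy = -abs(vy)
    if x < lim:
        x = 2 * lim - x
        vx = abs(vx)
    elif x > w_um - lim:
        x = 2 * (w_um - lim) - x
        vx = -abs(vx)
    state.centroid[:] = (y, x)
    state.heading = math.atan2(vy, vx)


def step_behavior(state: WormState, dt: float, rng: np.random.Generator,
                  config: SimulationConfig) -> WormState:
    """Advance one worm by ``dt`` seconds and return the new state.

    Mode transitions: from RUN, reversals and coils start as independent
    Poisson processes at the configured per-minute rates; episode lengths
    are exponential.  Entering a reversal flips the heading by an angle
    drawn uniformly in [120 deg, 180 deg] (random side) and increments the
    cumulative reversal count.  A coiled worm is stationary with frozen
    undulation phase.  Ground-truth body bends are counted whenever the
    undulation phase crosses a multiple of pi while the worm is moving
    (the mid-body curvature extrema).
    """
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    s = state.copy()

    if s.mode == MODE_RUN:
        p_rev = -math.expm1(-(config.reversal_rate / 60.0) * dt)
        p_coil = -math.expm1(-(config.coil_rate / 60.0) * dt)
        u = rng.random()
        if u < p_rev:
            flip = math.radians(rng.uniform(120.0, 180.0))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            s.heading = (s.heading + sign * flip) % (2.0 * np.pi)
            s.mode = MODE_REVERSAL
            s.mode_time_left = rng.exponential(config.reversal_duration_mean)
            s.cum_reversals += 1
        elif u < p_rev + p_coil:
            s.mode = MODE_COIL
            s.mode_time_left = rng.exponential(config.coil_duration_mean)
    else:
        s.mode_time_left -= dt
        if s.mode_time_left <= 0:
            s.mode = MODE_RUN
            s.mode_time_left = 0.0

    if s.mode != MODE_COIL:
        if config.boundary == "steer":
            _steer_from_walls(s, dt, config)
        old_phase = s.phase
        s.phase = old_phase + 2.0 * np.pi * config.undulation_freq * dt
        s.cum_bends += int(math.floor(s.phase / np.pi)
                           - math.floor(old_phase / np.pi))
        step = s.speed * dt
        s.centroid = s.centroid + step * np.array(
            [math.sin(s.heading), math.cos(s.heading)])
        _reflect(s, config)
    return s


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _disk_offsets(radius: float) -> np.ndarray:
    """Integer offset grid guaranteed to cover a disk of ``radius`` around
    any sub-pixel center."""
    r = int(math.ceil(radius)) + 1
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    return np.stack([dy.ravel(), dx.ravel()], axis=1)


def _rasterize_coverage(pts_px: np.ndarray, radius: float,
                        offsets: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Coverage raster of a disk-swept polyline on a local grid.

    Returns ``(coverage, row0, col0)`` where coverage in [0, 1] ramps
    linearly across one pixel around the body boundary (anti-aliasing).
    """
    base = np.floor(pts_px).astype(np.int64)
    frac = pts_px - base
    d2 = np.sum((offsets[None, :, :] - frac[:, None, :]) ** 2, axis=2)
    pix = (base[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    d = np.sqrt(d2).ravel()
    r0 = int(pix[:, 0].min())
    c0 = int(pix[:, 1].min())
    h = int(pix[:, 0].max()) - r0 + 1
    w = int(pix[:, 1].max()) - c0 + 1
    local = np.full(h * w, np.inf, dtype=np.float32)
    np.minimum.at(local, (pix[:, 0] - r0) * w + (pix[:, 1] - c0), d)
    coverage = np.clip(radius + 0.5 - local.reshape(h, w), 0.0, 1.0)
    return coverage, r0, c0


def render_frame(worms: Sequence[WormState], config: SimulationConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one 8-bit grayscale frame: dark worms on a light background.

    Each body is the union of disks of radius ``body_width/2`` swept along
    a densely resampled midline.  Edges are anti-aliased: a pixel's value
    interpolates between worm and background according to its sub-pixel
    distance to the body boundary, emulating the partial-coverage gray
    edges a real camera produces (optics blur plus area integration).
    Without this, binary thresholding downstream would inherit strong
    pixel-quantization jitter in the object centroids, which real
    recordings do not show.  Additive Gaussian noise with ``noise_sd`` is
    applied when an ``rng`` is given.
    """
    H, W = config.arena_size
    img = np.full((H, W), config.background_level, dtype=np.float32)
    radius = max(0.5 * config.body_width / config.um_per_px, 0.75)
    offsets = _disk_offsets(radius)
    # dense midline sampling: <= 0.4 px spacing so the stroke has no gaps
    n_dense = max(int(config.body_length / config.um_per_px / 0.4) + 1,
                  config.n_midline_points)
    for state in worms:
        pts_px = midline_points(state, config, n_points=n_dense) / config.um_per_px
        # align the body's area centroid with the ground-truth centroid:
        # the swept-disk body is asymmetric around the midline mean as the
        # wave passes, so rasterize once to measure the coverage-weighted
        # centroid and shift the body by the residual before drawing
        target = state.centroid / config.um_per_px
        cov, r0, c0 = _rasterize_coverage(pts_px, radius, offsets)
        area = cov.sum()
        if area > 0:
            yy, xx = np.nonzero(cov > 0)
            wsum = cov[yy, xx]
            cy = (yy * wsum).sum() / area + r0
            cx = (xx * wsum).sum() / area + c0
            pts_px = pts_px + (target - np.array([cy, cx]))
            cov, r0, c0 = _rasterize_coverage(pts_px, radius, offsets)
        h, w = cov.shape
        ys = slice(max(r0, 0), min(r0 + h, H))
        xs = slice(max(c0, 0), min(c0 + w, W))
        lys = slice(ys.start - r0, ys.stop - r0)
        lxs = slice(xs.start - c0, xs.stop - c0)
        img[ys, xs] += (config.worm_level - config.background_level
                        ) * cov[lys, lxs]
    np.clip(img, min(config.worm_level, config.background_level),
            config.background_level, out=img)
    if rng is not None and config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape).astype(np.float32)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _check_crowding(config: SimulationConfig) -> None:
    total_area = config.n_worms * config.worm_area_px()
    arena_area = config.arena_size[0] * config.arena_size[1]
    if total_area > 0.30 * arena_area:
        raise ValueError(
            f"overcrowded arena: {config.n_worms} worms cover "
            f"{100 * total_area / arena_area:.1f}% of the arena (limit 30%)")


def init_cohort(config: SimulationConfig,
                rng: np.random.Generator) -> list[WormState]:
    _check_crowding(config)
    return [_init_worm(rng, config) for _ in range(config.n_worms)]


def _gt_records(t: int, worms: Sequence[WormState]) -> list[tuple]:
    return [
        (t, i, float(w.centroid[1]), float(w.centroid[0]), w.mode,
         float(w.instantaneous_speed), w.cum_reversals, w.cum_bends)
        for i, w in enumerate(worms)
    ]


def simulate_frames(config: SimulationConfig,
                    render: bool = True) -> Iterator[tuple[int, np.ndarray | None,
                                                           list[tuple]]]:
    """Stream ``(frame_index, frame_or_None, ground_truth_records)``.

    Streaming keeps long paper-scale recordings (1800 megapixel frames)
    out of memory; ``render=False`` runs the behavior model alone, which
    is the fast path for trajectory-level tests.
    """
    rng = np.random.default_rng(config.seed)
    worms = init_cohort(config, rng)
    dt = config.dt
    for t in range(config.n_frames):
        if t > 0:
            worms = [step_behavior(w, dt, rng, config) for w in worms]
        frame = render_frame(worms, config, rng) if render else None
        yield t, frame, _gt_records(t, worms)


def _gt_dataframe(records: list[tuple], config: SimulationConfig) -> GroundTruth:
    table = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    return GroundTruth(table, config)


def simulate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Behavior-only simulation (no rendering); exact per-frame ground truth."""
    records: list[tuple] = []
    for _, _, recs in simulate_frames(config, render=False):
        records.extend(recs)
    return _gt_dataframe(records, config)


def tracks_from_ground_truth(gt: GroundTruth) -> list:
    """Perfect-observation tracks built directly from ground truth.

    One :class:`wormtrack.track.Track` per worm, with the true centroids
    and with hole counts derived from the behavioral mode (a coiled worm
    encloses a hole).  This is the fast trajectory-level path for
    validating the metric stage independently of imaging.
    """
    from .track import Track

    tracks = []
    for worm_id, g in gt.table.groupby("worm_id", sort=True):
        g = g.sort_values("frame")
        centroids = np.stack([g["y_um"].to_numpy(), g["x_um"].to_numpy()],
                             axis=1)
        holes = (g["mode"] == MODE_COIL).to_numpy().astype(int)
        areas = np.full(len(g), gt.config.worm_area_px())
        tracks.append(Track(
            track_id=int(worm_id),
            frames=g["frame"].to_numpy(),
            centroids_um=centroids,
            areas_px=areas,
            n_holes=holes,
            midlines_um=None,
            um_per_px=gt.config.um_per_px,
        ))
    return tracks


def simulate_cohort(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Materialize a full synthetic recording and its ground truth.

    Intended for short/small recordings; use :func:`simulate_frames` to
    stream paper-scale ones.
    """
    frames = np.empty((config.n_frames, *config.arena_size), dtype=np.uint8)
    records: list[tuple] = []
    for t, frame, recs in simulate_frames(config, render=True):
        frames[t] = frame
        records.extend(recs)
    stack = ImageStack(frames, um_per_px=config.um_per_px, fps=config.fps)
    return stack, _gt_dataframe(records, config)
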