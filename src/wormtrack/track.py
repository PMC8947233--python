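"""Centroid-proximity trajectory linking with automated quality gates.

Objects detected in consecutive frames are linked into per-worm tracks by
minimum-total-cost bipartite assignment of centroid displacements, gated by
a maximum displacement ``d_max`` and an optional frame-gap tolerance.  The
original workflow validated trajectories visually; here that step is an
explicit, logged quality gate on implied speed and frame coverage, so every
rejection carries a machine-readable reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segment import DetectedObject

_INFEASIBLE = 1e12


@dataclass
class Track:
    """One worm's time-ordered trajectory.

    Parallel arrays: ``frames`` (strictly increasing), ``centroids_um``
    ((n, 2) as (y, x) um), per-frame ``areas_px`` and ``n_holes``, and
    optional per-frame midlines in um (None where unavailable).
    """

    track_id: int
    frames: np.ndarray
    centroids_um: np.ndarray
    areas_px: np.ndarray
    n_holes: np.ndarray
    midlines_um: list[np.ndarray | None] | None = None
    objects: list[DetectedObject] | None = None
    um_per_px: float = 1.0
    quality_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.centroids_um = np.asarray(self.centroids_um, dtype=float)
        if len(self.frames) != len(self.centroids_um):
            raise ValueError("frames and centroids must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames_spanned(self) -> int:
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def coverage(self) -> float:
        return len(self) / self.n_frames_spanned

    def step_speeds(self, fps: float) -> np.ndarray:
        """Speed per linked step, um/s: displacement / elapsed time."""
        disp = np.linalg.norm(np.diff(self.centroids_um, axis=0), axis=1)
        dt = np.diff(self.frames) / fps
        return disp / dt


@dataclass
class LinkResult:
    """Outcome of trajectory linking: accepted tracks plus orphan objects
    (never linked, or members of tracks shorter than the minimum length)."""

    tracks: list[Track]
    orphans: list[DetectedObject]


def _track_from_members(track_id: int, members: list[DetectedObject],
                        um_per_px: float) -> Track:
    frames = np.array([o.frame_index for o in members])
    centroids = np.array([o.centroid_um for o in members])
    areas = np.array([o.area_px for o in members])
    holes = np.array([o.n_holes for o in members])
    midlines = [o.midline_um(um_per_px) for o in members]
    return Track(track_id=track_id, frames=frames, centroids_um=centroids,
                 areas_px=areas, n_holes=holes, midlines_um=midlines,
                 objects=members, um_per_px=um_per_px)


def match_frame_pair(prev_centroids: np.ndarray, next_centroids: np.ndarray,
                     d_max: float) -> list[tuple[int, int]]:
    """Minimum-total-cost assignment between two centroid sets.

    Pairs farther apart than ``d_max`` are infeasible.  Among matchings
    restricted to feasible pairs, the assignment maximizes cardinality and,
    within that, minimizes total displacement (rectangular Hungarian
    assignment with a large constant on infeasible pairs).
    """
    if len(prev_centroids) == 0 or len(next_centroids) == 0:
        return []
    cost = np.linalg.norm(
        prev_centroids[:, None, :] - next_centroids[None, :, :], axis=2)
    feasible = cost <= d_max
    cost = np.where(feasible, cost, _INFEASIBLE)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if feasible[r, c]]


def link_tracks(objects_by_frame: dict[int, list[DetectedObject]],
                d_max: float, gap: int = 0, min_track_len: int = 30,
                um_per_px: float | None = None) -> LinkResult:
    """Link per-frame detections into tracks by centroid proximity.

    Links are allowed between frames at most ``gap + 1`` apart with
    centroid displacement at most ``d_max`` um; each frame pair is solved
    as a minimum-cost assignment.  Tracks with fewer than
    ``min_track_len`` detections are dissolved into the orphan list, so
    every input object ends up in exactly one track or among the orphans.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if um_per_px is None:
        for objs in objects_by_frame.values():
            if objs:
                um = objs[0].centroid_um
                px = objs[0].centroid_px
                um_per_px = float(um[0] / px[0]) if px[0] != 0 else 1.0
                break
        else:
            um_per_px = 1.0

    frames = sorted(objects_by_frame)
    open_tracks: list[dict] = []  # {"members": [...], "last_frame": int}
    closed: list[list[DetectedObject]] = []

    for f in frames:
        objs = sorted(objects_by_frame[f], key=lambda o: o.obj_id)
        # retire tracks that can no longer be extended
        still_open = []
        for tr in open_tracks:
            if f - tr["last_frame"] > gap + 1:
                closed.append(tr["members"])
            else:
                still_open.append(tr)
        open_tracks = still_open

        if open_tracks and objs:
            prev = np.array([tr["members"][-1].centroid_um
                             for tr in open_tracks])
            nxt = np.array([o.centroid_um for o in objs])
            pairs = match_frame_pair(prev, nxt, d_max)
        else:
            pairs = []
        matched_objs = set()
        for r, c in pairs:
            open_tracks[r]["members"].append(objs[c])
            open_tracks[r]["last_frame"] = f
            matched_objs.add(c)
        for c, obj in enumerate(objs):
            if c not in matched_objs:
                open_tracks.append({"members": [obj], "last_frame": f})

    closed.extend(tr["members"] for tr in open_tracks)

    tracks: list[Track] = []
    orphans: list[DetectedObject] = []
    for members in closed:
        if len(members) >= max(min_track_len, 2):
            tracks.append(_track_from_members(len(tracks), members, um_per_px))
        else:
            orphans.extend(members)
    return LinkResult(tracks=tracks, orphans=orphans)


REASON_SPEED = "speed"
REASON_COVERAGE = "coverage"


@dataclass
class RejectedTrack:
    track: Track
    reason: str


def validate_tracks(tracks: list[Track], fps: float,
                    max_speed: float = 500.0, min_coverage: float = 0.9
                    ) -> tuple[list[Track], list[RejectedTrack]]:
    """Quality gates replacing manual visual validation.

    Rejects tracks with any implied speed above ``max_speed`` um/s (linking
    artifacts, e.g. identity teleports) or frame coverage below
    ``min_coverage``; accepted + rejected exactly partition the input.
    """
    accepted: list[Track] = []
    rejected: list[RejectedTrack] = []
    for tr in tracks:
        speeds = tr.step_speeds(fps)
        if len(speeds) and float(np.max(speeds)) > max_speed:
            tr.quality_flags.append(REASON_SPEED)
            rejected.append(RejectedTrack(tr, REASON_SPEED))
        elif tr.coverage < min_coverage:
            tr.quality_flags.append(REASON_COVERAGE)
            rejected.append(RejectedTrack(tr, REASON_COVERAGE))
        else:
            accepted.append(tr)
    return accepted, rejected
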