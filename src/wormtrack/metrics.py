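"""Per-track behavioral readouts: speed, reversals, body bends, coiling.

Definitions follow the standard plate-tracking conventions for nematode
locomotion:

* speed — centroid displacement between consecutive linked frames times
  the frame rate;
* reversal — a trajectory bend whose angle exceeds a threshold (50 deg by
  default), measured between displacement vectors averaged over a short
  window before and after each point, with one event per contiguous
  supra-threshold excursion;
* coiled frame — the segmented object encloses at least one background
  hole AND the centroid speed is below a cutoff;
* body bend — the mid-body point reaches a curvature extremum of sign
  opposite to the previously counted bend, scored only while moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .track import Track


@dataclass
class ReversalEvent:
    track_id: int
    frame: int
    turn_angle: float  # degrees


@dataclass
class BehaviorSummary:
    """Per-track behavioral summary (rates per minute, speeds in um/s)."""

    track_id: int
    mean_speed: float
    speed_series: np.ndarray
    reversals_per_min: float
    body_bends_per_min: float
    coil_fraction: float
    observed_time: float  # s
    flags: list[str] = field(default_factory=list)


def compute_speed(track: Track, fps: float) -> tuple[np.ndarray, float]:
    """Per-step speed series and its mean, from consecutive centroids.

    Step speed i is ``|centroid_{i+1} - centroid_i| * fps`` (gap steps use
    the actual elapsed time).
    """
    if len(track) < 2:
        raise ValueError("compute_speed requires a track of length >= 2")
    series = track.step_speeds(fps)
    return series, float(series.mean())


def frame_speeds(track: Track, fps: float) -> np.ndarray:
    """Per-frame speed by centered differencing (one-sided at the ends).

    Centered differences halve the contribution of frame-to-frame centroid
    jitter, which matters when gating nearly stationary (coiled) frames.
    """
    c = track.centroids_um
    t = track.frames / fps
    n = len(c)
    if n < 2:
        raise ValueError("frame_speeds requires a track of length >= 2")
    v = np.empty(n)
    v[0] = np.linalg.norm(c[1] - c[0]) / (t[1] - t[0])
    v[-1] = np.linalg.norm(c[-1] - c[-2]) / (t[-1] - t[-2])
    if n > 2:
        v[1:-1] = np.linalg.norm(c[2:] - c[:-2], axis=1) / (t[2:] - t[:-2])
    return v


def observed_time(track: Track, fps: float) -> float:
    """Total linked time in seconds: number of linked steps / fps."""
    return float((track.frames[-1] - track.frames[0]) / fps)


def detect_reversals(track: Track, fps: float, angle_threshold: float = 50.0,
                     smooth_window: int = 3, min_step: float | None = None
                     ) -> tuple[list[ReversalEvent], float]:
    """Reversal events: trajectory bends with angle above the threshold.

    At each interior point i the pre- and post-direction vectors are the
    displacements over ``smooth_window`` frames before and after i; points
    where either displacement is shorter than ``min_step`` (default 0.2 px
    in physical units — sub-pixel jitter) carry no angle.  One event is
    scored per contiguous excursion above ``angle_threshold`` at the frame
    of maximum angle, preventing multiple counts of a single turn.  The
    rate is events per minute of total observed track time.
    """
    w = int(smooth_window)
    if w < 1:
        raise ValueError("smooth_window must be >= 1")
    n = len(track)
    if n < 2 * w + 1:
        raise ValueError("track too short for the requested smooth window")
    if min_step is None:
        min_step = 0.2 * track.um_per_px
    c = track.centroids_um
    pre = c[w:n - w] - c[:n - 2 * w]
    post = c[2 * w:] - c[w:n - w]
    norm_pre = np.linalg.norm(pre, axis=1)
    norm_post = np.linalg.norm(post, axis=1)
    valid = (norm_pre >= min_step) & (norm_post >= min_step)
    cosang = np.full(len(pre), 1.0)
    np.divide(np.sum(pre * post, axis=1), norm_pre * norm_post,
              out=cosang, where=valid)
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    above = valid & (angles > angle_threshold)

    events: list[ReversalEvent] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            k = i + int(np.argmax(angles[i:j + 1]))
            events.append(ReversalEvent(track_id=track.track_id,
                                        frame=int(track.frames[k + w]),
                                        turn_angle=float(angles[k])))
            i = j + 1
        else:
            i += 1
    t = observed_time(track, fps)
    rate = len(events) / t * 60.0 if t > 0 else 0.0
    return events, rate


def coil_fraction(track: Track, fps: float, v_coil: float) -> float:
    """Fraction of frames spent coiled: object has >= 1 hole AND the
    centroid speed is at or below ``v_coil`` um/s."""
    holes = np.asarray(track.n_holes)
    if len(track) < 2:
        return 0.0
    speeds = frame_speeds(track, fps)
    coiled = (holes >= 1) & (speeds <= v_coil)
    return float(coiled.mean())


def _resample_midline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an ordered polyline to ``n`` points equally spaced in arc
    length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(points[:1], n, axis=0)
    si = np.linspace(0.0, s[-1], n)
    return np.stack([np.interp(si, s, points[:, k]) for k in range(2)], axis=1)


def midline_curvature_mid(points: np.ndarray, n_resample: int = 51,
                          half_span: int = 5) -> float:
    """Signed discrete curvature at the midline midpoint (1/um).

    The midline is resampled to ``n_resample`` equal-arc-length points and
    a three-point circumscribed-circle curvature is evaluated on the
    points ``half_span`` samples either side of the middle (a span of
    ~20% of body length by default, which is robust to pixel-level
    skeleton jitter).  Sign is the orientation of the point triple.
    """
    pts = _resample_midline(np.asarray(points, dtype=float), n_resample)
    m = n_resample // 2
    p1, p2, p3 = pts[m - half_span], pts[m], pts[m + half_span]
    a, b = p2 - p1, p3 - p2
    cross = a[0] * b[1] - a[1] * b[0]
    la, lb, lc = (np.linalg.norm(a), np.linalg.norm(b),
                  np.linalg.norm(p3 - p1))
    if la == 0 or lb == 0 or lc == 0:
        return 0.0
    return float(2.0 * cross / (la * lb * lc))


def count_body_bends(track: Track, fps: float, v_move: float,
                     min_curvature: float = 5e-4,
                     min_midline_coverage: float = 0.8
                     ) -> tuple[int, float]:
    """Body bends per minute of moving time.

    The signed mid-body curvature series is scanned for local extrema; an
    extremum is counted as a bend when its sign is opposite to the
    previously counted bend, its magnitude exceeds ``min_curvature``
    (1/um; suppresses numerically flat postures), and the worm is moving
    (frame speed >= ``v_move``).  Returns (count, bends_per_min), the rate
    normalized by time spent moving.  Requires midlines in at least
    ``min_midline_coverage`` of frames.
    """
    if track.midlines_um is None:
        raise ValueError("track has no midlines")
    have = [m is not None and len(m) >= 3 for m in track.midlines_um]
    if np.mean(have) < min_midline_coverage:
        raise ValueError(
            f"midlines available in {100 * np.mean(have):.0f}% of frames "
            f"(need >= {100 * min_midline_coverage:.0f}%)")
    kappa = np.array([
        midline_curvature_mid(m) if ok else np.nan
        for m, ok in zip(track.midlines_um, have)
    ])
    speeds = frame_speeds(track, fps)
    moving = speeds >= v_move

    count = 0
    last_sign = 0
    for i in range(1, len(kappa) - 1):
        k0, k1, k2 = kappa[i - 1], kappa[i], kappa[i + 1]
        if np.isnan(k0) or np.isnan(k1) or np.isnan(k2):
            continue
        is_max = k1 >= k0 and k1 > k2
        is_min = k1 <= k0 and k1 < k2
        if not (is_max or is_min):
            continue
        if abs(k1) < min_curvature:
            continue
        sign = 1 if is_max else -1
        if sign == last_sign:
            continue
        if not moving[i]:
            continue
        count += 1
        last_sign = sign
    moving_time = float(moving.sum()) / fps
    rate = count / moving_time * 60.0 if moving_time > 0 else 0.0
    return count, rate


def default_speed_cutoffs(tracks: list[Track], fps: float
                          ) -> tuple[float, float]:
    """(v_coil, v_move) as 10% and 20% of the cohort median track speed."""
    if not tracks:
        raise ValueError("no tracks")
    medians = [float(np.median(tr.step_speeds(fps))) for tr in tracks
               if len(tr) >= 2]
    cohort_median = float(np.median(medians))
    return 0.1 * cohort_median, 0.2 * cohort_median


def summarize_track(track: Track, fps: float, v_coil: float, v_move: float,
                    angle_threshold: float = 50.0, smooth_window: int = 3,
                    min_step: float | None = None) -> BehaviorSummary:
    """All four behavioral readouts for one track."""
    series, mean_speed = compute_speed(track, fps)
    flags: list[str] = []
    try:
        _, rev_rate = detect_reversals(track, fps,
                                       angle_threshold=angle_threshold,
                                       smooth_window=smooth_window,
                                       min_step=min_step)
    except ValueError:
        rev_rate = np.nan
        flags.append("too_short_for_reversals")
    cfrac = coil_fraction(track, fps, v_coil=v_coil)
    try:
        _, bend_rate = count_body_bends(track, fps, v_move=v_move)
    except ValueError:
        bend_rate = np.nan
        flags.append("no_midlines")
    return BehaviorSummary(
        track_id=track.track_id,
        mean_speed=mean_speed,
        speed_series=series,
        reversals_per_min=rev_rate,
        body_bends_per_min=bend_rate,
        coil_fraction=cfrac,
        observed_time=observed_time(track, fps),
        flags=flags,
    )


_METRICS = ["mean_speed", "reversals_per_min", "body_bends_per_min",
            "coil_fraction"]


def summarize_cohort(summaries: list[BehaviorSummary],
                     bin_width: float = 10.0
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cohort-level table: per-track rows, mean +/- SEM per metric, and a
    pooled per-step speed histogram.

    Returns ``(per_track, cohort, histogram)`` data frames.  SEM is NaN
    (flagged undefined) for a single-track cohort.
    """
    if not summaries:
        raise ValueError("summarize_cohort requires at least one summary")
    per_track = pd.DataFrame([
        {
            "track_id": s.track_id,
            "mean_speed": s.mean_speed,
            "reversals_per_min": s.reversals_per_min,
            "body_bends_per_min": s.body_bends_per_min,
            "coil_fraction": s.coil_fraction,
            "observed_time": s.observed_time,
        }
        for s in summaries
    ])
    rows = []
    for m in _METRICS:
        vals = per_track[m].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        n = len(vals)
        mean = float(vals.mean()) if n else np.nan
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"metric": m, "mean": mean, "sem": sem, "n": n})
    cohort = pd.DataFrame(rows)
    pooled = np.concatenate([s.speed_series for s in summaries])
    top = max(float(pooled.max()), bin_width) if len(pooled) else bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(pooled, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
    return per_track, cohort, hist
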