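"""End-to-end pipeline: simulate (or load) -> segment -> track -> metrics.

A single JSON-serializable :class:`PipelineConfig` drives every stage;
unknown keys are rejected so configs are round-trippable and misspellings
never pass silently.  Each run writes its intermediate tables and a
manifest (config hash, seed, package version, per-stage counts) so "what
ran" is always recoverable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as wio
from . import metrics as wmetrics
from . import segment as wsegment
from . import track as wtrack
from .simulate import GroundTruth, ImageStack, SimulationConfig, simulate_frames

log = logging.getLogger("wormtrack")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class SegmentConfig:
    sigma: float = 1.0
    method: str = "otsu"  # "otsu" | "fixed"
    threshold: float | None = None
    a_min: float | None = None  # default: 0.25 * expected worm area
    a_max: float | None = None  # default: 4 * expected worm area
    compute_midlines: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.method == "fixed" and self.threshold is None:
            raise ValueError("fixed threshold method requires a threshold")


@dataclass(frozen=True)
class TrackConfig:
    d_max: float | None = None  # um; default 3 * speed_mean / fps
    gap: int = 0
    min_track_len: int = 30
    max_speed: float = 500.0  # um/s
    min_coverage: float = 0.9


@dataclass(frozen=True)
class MetricsConfig:
    angle_threshold: float = 50.0
    smooth_window: int = 3
    min_step: float | None = None  # um; default 0.2 px equivalent
    v_coil: float | None = None  # um/s; default 10% of cohort median speed
    v_move: float | None = None  # um/s; default 20% of cohort median speed
    hist_bin_width: float = 10.0


def _from_dict(cls, d: dict):
    known = set(cls.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulate"] = self.simulate.to_dict()
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "simulate" in d:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        for key, sub in (("segment", SegmentConfig), ("track", TrackConfig),
                         ("metrics", MetricsConfig)):
            if key in d:
                d[key] = _from_dict(sub, d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def resolved_seed(self) -> "PipelineConfig":
        """Propagate the pipeline seed into the simulation config."""
        import dataclasses
        sim = dataclasses.replace(self.simulate, seed=self.seed)
        return dataclasses.replace(self, simulate=sim)


@dataclass
class PipelineResult:
    objects_by_frame: dict[int, list[wsegment.DetectedObject]]
    tracks: list[wtrack.Track]
    rejected: list[wtrack.RejectedTrack]
    orphans: list[wsegment.DetectedObject]
    summaries: list[wmetrics.BehaviorSummary]
    per_track: pd.DataFrame
    cohort: pd.DataFrame
    histogram: pd.DataFrame
    ground_truth: GroundTruth | None
    manifest: dict


def _segment_stage(frames_iter, sim: SimulationConfig, seg: SegmentConfig
                   ) -> dict[int, list[wsegment.DetectedObject]]:
    a_w = sim.worm_area_px()
    a_min = seg.a_min if seg.a_min is not None else 0.25 * a_w
    a_max = seg.a_max if seg.a_max is not None else 4.0 * a_w
    objects_by_frame: dict[int, list[wsegment.DetectedObject]] = {}
    n = 0
    for frame_index, pixels in frames_iter:
        frame = wsegment.Frame(pixels, frame_index=frame_index,
                               um_per_px=sim.um_per_px)
        objects_by_frame[frame_index] = wsegment.segment_frame(
            frame, sigma=seg.sigma, method=seg.method,
            threshold=seg.threshold, a_min=a_min, a_max=a_max,
            compute_midlines=seg.compute_midlines)
        n += 1
    if n == 0:
        raise StageError("segment", "no input frames")
    return objects_by_frame


def run_pipeline(config: PipelineConfig,
                 stack: ImageStack | None = None) -> PipelineResult:
    """Run segment -> track -> metrics on an image stack, simulating one
    (with ground truth attached to the result) when none is given."""
    config = config.resolved_seed()
    sim = config.simulate
    gt: GroundTruth | None = None

    if stack is None:
        def frames_iter():
            records = []

            def gen():
                for t, frame, recs in simulate_frames(sim, render=True):
                    records.append(recs)
                    yield t, frame
            return gen(), records

        gen, gt_records = frames_iter()
        try:
            objects_by_frame = _segment_stage(gen, sim, config.segment)
        except StageError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("segment", str(exc)) from exc
        flat = [rec for recs in gt_records for rec in recs]
        gt = GroundTruth(pd.DataFrame(
            flat, columns=["frame", "worm_id", "x_um", "y_um", "mode",
                           "speed_um_s", "cum_reversals", "cum_bends"]), sim)
    else:
        try:
            objects_by_frame = _segment_stage(
                ((i, stack[i]) for i in range(len(stack))), sim, config.segment)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("segment", str(exc)) from exc

    tcfg = config.track
    d_max = (tcfg.d_max if tcfg.d_max is not None
             else 3.0 * sim.speed_mean / sim.fps)
    try:
        linked = wtrack.link_tracks(objects_by_frame, d_max=d_max,
                                    gap=tcfg.gap,
                                    min_track_len=tcfg.min_track_len,
                                    um_per_px=sim.um_per_px)
        accepted, rejected = wtrack.validate_tracks(
            linked.tracks, fps=sim.fps, max_speed=tcfg.max_speed,
            min_coverage=tcfg.min_coverage)
    except Exception as exc:
        raise StageError("track", str(exc)) from exc

    mcfg = config.metrics
    try:
        if not accepted:
            raise ValueError("no accepted tracks")
        v_coil, v_move = mcfg.v_coil, mcfg.v_move
        if v_coil is None or v_move is None:
            d_coil, d_move = wmetrics.default_speed_cutoffs(accepted, sim.fps)
            v_coil = v_coil if v_coil is not None else d_coil
            v_move = v_move if v_move is not None else d_move
        summaries = [
            wmetrics.summarize_track(tr, fps=sim.fps, v_coil=v_coil,
                                     v_move=v_move,
                                     angle_threshold=mcfg.angle_threshold,
                                     smooth_window=mcfg.smooth_window,
                                     min_step=mcfg.min_step)
            for tr in accepted
        ]
        per_track, cohort, hist = wmetrics.summarize_cohort(
            summaries, bin_width=mcfg.hist_bin_width)
    except Exception as exc:
        raise StageError("metrics", str(exc)) from exc

    cfg_json = config.to_json()
    manifest = {
        "package": "wormtrack",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_frames": len(objects_by_frame),
        "n_objects": int(sum(len(v) for v in objects_by_frame.values())),
        "n_tracks_linked": len(linked.tracks),
        "n_tracks_accepted": len(accepted),
        "n_tracks_rejected": len(rejected),
        "n_orphans": len(linked.orphans),
        "v_coil_um_s": float(v_coil),
        "v_move_um_s": float(v_move),
        "config": config.to_dict(),
    }

    result = PipelineResult(
        objects_by_frame=objects_by_frame, tracks=accepted,
        rejected=rejected, orphans=linked.orphans, summaries=summaries,
        per_track=per_track, cohort=cohort, histogram=hist,
        ground_truth=gt, manifest=manifest)

    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    wio.objects_to_frame(result.objects_by_frame).to_csv(
        out_dir / "objects.csv", index=False)
    wio.tracks_to_frame(result.tracks).to_csv(
        out_dir / "tracks.csv", index=False)
    wio.rejections_to_frame(result.rejected).to_csv(
        out_dir / "rejected_tracks.csv", index=False)
    result.per_track.to_csv(out_dir / "behavior_per_track.csv", index=False)
    result.cohort.to_csv(out_dir / "behavior_cohort.csv", index=False)
    result.histogram.to_csv(out_dir / "speed_histogram.csv", index=False)
    if result.ground_truth is not None:
        result.ground_truth.to_csv(out_dir / "ground_truth.csv")
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True))
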