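"""Reading and writing of stacks and result tables.

Frames travel as 8-bit grayscale multi-page TIFF or a directory of
zero-padded PNGs; tabular results (ground truth, per-frame objects,
tracks, behavior summaries) are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .segment import DetectedObject
from .simulate import ImageStack
from .track import RejectedTrack, Track


def write_stack_tiff(stack: ImageStack, path) -> None:
    tifffile.imwrite(str(path), stack.frames, photometric="minisblack")


def write_stack_pngs(stack: ImageStack, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(len(stack) - 1)))
    for i in range(len(stack)):
        iio.imwrite(directory / f"frame_{i:0{width}d}.png", stack[i])


def read_stack(path, um_per_px: float, fps: float) -> ImageStack:
    """Read frames from a multi-page TIFF file or a directory of PNGs."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = tifffile.imread(str(path))
        if frames.ndim == 2:
            frames = frames[None]
    return ImageStack(frames=frames, um_per_px=um_per_px, fps=fps)


def objects_to_frame(objects_by_frame: dict[int, list[DetectedObject]]
                     ) -> pd.DataFrame:
    rows = []
    for f in sorted(objects_by_frame):
        for o in objects_by_frame[f]:
            rows.append({
                "frame": f, "obj_id": o.obj_id,
                "row": float(o.centroid_px[0]), "col": float(o.centroid_px[1]),
                "area_px": o.area_px, "n_holes": o.n_holes,
            })
    return pd.DataFrame(
        rows, columns=["frame", "obj_id", "row", "col", "area_px", "n_holes"])


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append({
                "track_id": tr.track_id, "frame": int(tr.frames[i]),
                "x_um": float(tr.centroids_um[i, 1]),
                "y_um": float(tr.centroids_um[i, 0]),
                "area_px": float(tr.areas_px[i]),
                "n_holes": int(tr.n_holes[i]),
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                       "area_px", "n_holes"])


def tracks_from_frame(df: pd.DataFrame, um_per_px: float) -> list[Track]:
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(Track(
            track_id=int(tid),
            frames=g["frame"].to_numpy(),
            centroids_um=np.stack([g["y_um"].to_numpy(),
                                   g["x_um"].to_numpy()], axis=1),
            areas_px=g["area_px"].to_numpy(),
            n_holes=g["n_holes"].to_numpy(),
            um_per_px=um_per_px,
        ))
    return tracks


def rejections_to_frame(rejected: list[RejectedTrack]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"track_id": r.track.track_id, "n_frames": len(r.track),
          "reason": r.reason} for r in rejected],
        columns=["track_id", "n_frames", "reason"])
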