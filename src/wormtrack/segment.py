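"""Per-frame image processing: smooth, threshold, extract size-gated blobs.

The stage mirrors the classic dark-object-on-light-background workflow for
nematode plate recordings: Gaussian smoothing, global thresholding (Otsu by
default, fixed threshold available for cross-frame reproducibility),
8-connected component labelling with an area gate that discards debris and
merged multi-worm blobs, per-object hole counting (coiled worms enclose
background), and a skeleton-based midline for posture readouts.

Conventions: image coordinates are (row, col), 0-based, pixel centers at
integer coordinates; objects are 8-connected, holes 4-connected (the
standard complementary pair); physical coordinates are pixel * um_per_px.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize


@dataclass
class Frame:
    """One grayscale frame with physical calibration."""

    pixels: np.ndarray
    frame_index: int = 0
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Frame.pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Frame.pixels must be finite")


@dataclass
class Midline:
    """Ordered midline points; ``simple`` is False when the blob has holes
    or otherwise admits no simple head-to-tail path."""

    points: np.ndarray  # (k, 2) float (row, col); empty when not simple
    simple: bool

    @property
    def length_px(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class DetectedObject:
    """One segmented blob in one frame."""

    frame_index: int
    centroid_px: np.ndarray  # (row, col), float
    centroid_um: np.ndarray  # (y_um, x_um)
    area_px: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    n_holes: int
    mask: np.ndarray  # binary crop within bbox
    midline_px: np.ndarray | None = None  # (k, 2) global (row, col), or None
    obj_id: int = 0

    def midline_um(self, um_per_px: float) -> np.ndarray | None:
        if self.midline_px is None:
            return None
        return self.midline_px * um_per_px


def preprocess(frame: Frame, sigma: float = 1.0) -> Frame:
    """Gaussian-smoothed copy of a frame; ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    pix = frame.pixels.astype(np.float32, copy=True)
    if sigma > 0:
        pix = ndimage.gaussian_filter(pix, sigma=sigma, mode="nearest")
    return Frame(pix, frame_index=frame.frame_index, um_per_px=frame.um_per_px)


def binarize(frame: Frame, method: str = "otsu",
             threshold: float | None = None) -> np.ndarray:
    """Foreground mask of dark objects: ``pixels < threshold``.

    ``method='otsu'`` picks the threshold per frame by Otsu's criterion;
    ``method='fixed'`` requires an explicit threshold.
    """
    if method == "otsu":
        pix = frame.pixels
        if np.ptp(pix) == 0:
            return np.zeros(pix.shape, dtype=bool)
        thr = threshold_otsu(pix)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown threshold method: {method!r}")
    return frame.pixels < thr


def count_holes(mask: np.ndarray) -> int:
    """Number of 4-connected background components fully enclosed by the
    object (the mask's topological holes)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    padded = np.pad(mask, 1, constant_values=False)
    bg_labels, n_bg = ndimage.label(~padded,
                                    structure=np.array([[0, 1, 0],
                                                        [1, 1, 1],
                                                        [0, 1, 0]]))
    outside = bg_labels[0, 0]
    enclosed = set(np.unique(bg_labels)) - {0, outside}
    return len(enclosed)


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path through an 8-connected skeleton (its diameter),
    found by double breadth-first search; returns (k, 2) pixel coordinates."""
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return np.empty((0, 2))
    if len(coords) == 1:
        return coords.astype(float)
    index = {tuple(c): i for i, c in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in coords]
    for i, (r, c) in enumerate(coords):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    nbrs[i].append(j)

    def bfs(start: int) -> tuple[int, dict[int, int]]:
        prev = {start: -1}
        q = deque([start])
        last = start
        while q:
            u = q.popleft()
            last = u
            for v in nbrs[u]:
                if v not in prev:
                    prev[v] = u
                    q.append(v)
        return last, prev

    a, _ = bfs(0)
    b, prev = bfs(a)
    path = []
    node = b
    while node != -1:
        path.append(coords[node])
        node = prev[node]
    pts = np.array(path, dtype=float)
    # deterministic orientation: lexicographically smaller endpoint first
    if tuple(pts[0]) > tuple(pts[-1]):
        pts = pts[::-1]
    return pts


def skeleton_midline(mask: np.ndarray) -> Midline:
    """One-pixel-wide midline of a single connected blob, ordered
    head-to-tail (orientation arbitrary but deterministic).

    Side branches of the skeleton are pruned by keeping only its longest
    geodesic path.  A blob with holes (a coiled worm) has no simple
    midline: the result is empty with ``simple=False``.
    """
    mask = np.asarray(mask, dtype=bool)
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        raise ValueError("skeleton_midline requires a single connected object")
    if count_holes(mask) > 0:
        return Midline(points=np.empty((0, 2)), simple=False)
    skel = skeletonize(mask)
    pts = _longest_skeleton_path(skel)
    if len(pts) < 2:
        return Midline(points=pts, simple=len(pts) > 0)
    return Midline(points=pts, simple=True)


def default_area_gate(expected_worm_area_px: float) -> tuple[float, float]:
    """Default blob-size gate [0.25 A, 4 A] around the expected worm area."""
    return 0.25 * expected_worm_area_px, 4.0 * expected_worm_area_px


def extract_objects(mask: np.ndarray, frame: Frame, a_min: float,
                    a_max: float, compute_midlines: bool = True
                    ) -> list[DetectedObject]:
    """Size-gated 8-connected components of a foreground mask.

    Components with area outside [a_min, a_max] (debris, merged multi-worm
    blobs) are discarded.  Each retained object carries its centroid (pixel
    and physical), bbox, hole count, mask crop and optionally a skeleton
    midline in global pixel coordinates.
    """
    if not a_min < a_max:
        raise ValueError("a_min must be < a_max")
    lab = label(np.asarray(mask, dtype=bool), connectivity=2)
    objects: list[DetectedObject] = []
    for region in regionprops(lab):
        if not (a_min <= region.area <= a_max):
            continue
        crop = region.image
        n_holes = count_holes(crop)
        midline = None
        if compute_midlines and n_holes == 0:
            ml = skeleton_midline(crop)
            if ml.simple and len(ml.points) >= 2:
                midline = ml.points + np.array(region.bbox[:2], dtype=float)
        centroid_px = np.array(region.centroid, dtype=float)
        objects.append(DetectedObject(
            frame_index=frame.frame_index,
            centroid_px=centroid_px,
            centroid_um=centroid_px * frame.um_per_px,
            area_px=int(region.area),
            bbox=tuple(region.bbox),
            n_holes=n_holes,
            mask=crop.copy(),
            midline_px=midline,
            obj_id=len(objects),
        ))
    return objects


def segment_frame(frame: Frame, sigma: float = 1.0, method: str = "otsu",
                  threshold: float | None = None, a_min: float = 1.0,
                  a_max: float = np.inf, compute_midlines: bool = True
                  ) -> list[DetectedObject]:
    """Convenience wrapper: preprocess -> binarize -> extract_objects."""
    smoothed = preprocess(frame, sigma=sigma)
    mask = binarize(smoothed, method=method, threshold=threshold)
    return extract_objects(mask, frame, a_min=a_min, a_max=a_max,
                           compute_midlines=compute_midlines)
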