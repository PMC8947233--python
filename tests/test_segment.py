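"""Segmentation: smoothing, thresholding, object extraction, holes, midlines."""

import numpy as np
import pytest

from wormtrack.segment import (Frame, binarize, count_holes, extract_objects,
                               preprocess, segment_frame, skeleton_midline)
from wormtrack.simulate import (SimulationConfig, WormState, render_frame,
                                simulate_frames)


def frame_of(pixels, um_per_px=1.0):
    return Frame(np.asarray(pixels, dtype=float), 0, um_per_px)


class TestPreprocess:
    def test_sigma_zero_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 255, (32, 32))
        out = preprocess(frame_of(img), sigma=0.0)
        np.testing.assert_array_equal(out.pixels, img.astype(np.float32))

    def test_constant_image_unchanged(self):
        img = np.full((40, 40), 77.0)
        out = preprocess(frame_of(img), sigma=3.0)
        np.testing.assert_allclose(out.pixels, 77.0, atol=1e-4)

    def test_impulse_response_matches_gaussian_kernel(self):
        """Smoothing an impulse yields the discretized 2-D Gaussian kernel
        (independent oracle: explicit kernel evaluation + normalization)."""
        sigma = 2.0
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = preprocess(frame_of(img), sigma=sigma).pixels
        # oracle: sampled, truncated, normalized Gaussian
        r = int(4 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        g1 = np.exp(-x**2 / (2 * sigma**2))
        g1 /= g1.sum()
        kernel = np.outer(g1, g1)
        np.testing.assert_allclose(out[20 - r:20 + r + 1, 20 - r:20 + r + 1],
                                   kernel, atol=1e-5)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            preprocess(frame_of(np.zeros((4, 4))), sigma=-1.0)


def otsu_oracle(values: np.ndarray) -> float:
    """Exhaustive-search Otsu: maximize between-class variance over all
    candidate thresholds."""
    levels = np.unique(values)
    best_t, best_var = levels[0], -1.0
    for t in (levels[:-1] + levels[1:]) / 2:
        lo = values[values < t]
        hi = values[values >= t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / values.size, len(hi) / values.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestBinarize:
    def test_otsu_separates_bimodal_image(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((64, 64)) < 0.2, 30.0, 220.0)
        mask = binarize(frame_of(img), method="otsu")
        oracle_thr = otsu_oracle(img.ravel())
        np.testing.assert_array_equal(mask, img < oracle_thr)
        np.testing.assert_array_equal(mask, img == 30.0)

    def test_all_background_empty_mask(self):
        mask = binarize(frame_of(np.full((16, 16), 200.0)), method="otsu")
        assert not mask.any()

    def test_fixed_threshold_checkerboard(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 255.0
        mask = binarize(frame_of(img), method="fixed", threshold=128.0)
        np.testing.assert_array_equal(mask, img == 0.0)

    def test_fixed_without_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(frame_of(np.zeros((4, 4))), method="fixed")


def holes_oracle(mask: np.ndarray) -> int:
    """Flood fill (4-connectivity) from the border; remaining background
    components are enclosed holes."""
    from collections import deque
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    visited = np.zeros_like(mask)
    q = deque()
    for r in range(H):
        for c in (0, W - 1):
            if not mask[r, c]:
                q.append((r, c))
    for c in range(W):
        for r in (0, H - 1):
            if not mask[r, c]:
                q.append((r, c))
    while q:
        r, c = q.popleft()
        if r < 0 or r >= H or c < 0 or c >= W or visited[r, c] or mask[r, c]:
            continue
        visited[r, c] = True
        q.extend([(r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)])
    n = 0
    for r in range(H):
        for c in range(W):
            if not mask[r, c] and not visited[r, c]:
                # new hole: flood it
                n += 1
                q = deque([(r, c)])
                while q:
                    rr, cc = q.popleft()
                    if (rr < 0 or rr >= H or cc < 0 or cc >= W
                            or visited[rr, cc] or mask[rr, cc]):
                        continue
                    visited[rr, cc] = True
                    q.extend([(rr + 1, cc), (rr - 1, cc),
                              (rr, cc + 1), (rr, cc - 1)])
    return n


def disk_mask(size, center, radius):
    yy, xx = np.mgrid[:size, :size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestCountHoles:
    def test_filled_disk_has_none(self):
        assert count_holes(disk_mask(31, (15, 15), 10)) == 0

    def test_annulus_has_one(self):
        m = disk_mask(31, (15, 15), 12) & ~disk_mask(31, (15, 15), 6)
        assert count_holes(m) == 1

    def test_figure_eight_matches_flood_fill_oracle(self):
        m = (disk_mask(61, (30, 18), 12) & ~disk_mask(61, (30, 18), 6)) | \
            (disk_mask(61, (30, 42), 12) & ~disk_mask(61, (30, 42), 6))
        assert count_holes(m) == holes_oracle(m) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_random_blobs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((24, 24)) < 0.55
        assert count_holes(m) == holes_oracle(m)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            count_holes(np.zeros((0, 0), dtype=bool))


class TestExtractObjects:
    def test_single_disk_centroid_at_center(self):
        m = disk_mask(41, (20, 20), 9)
        objs = extract_objects(m, frame_of(np.zeros((41, 41)), um_per_px=2.0),
                               a_min=50, a_max=500)
        assert len(objs) == 1
        np.testing.assert_allclose(objs[0].centroid_px, [20, 20], atol=0.5)
        np.testing.assert_allclose(objs[0].centroid_um,
                                   objs[0].centroid_px * 2.0)

    def test_small_speck_gated_out(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5, 5:8] = True  # 3-px speck
        objs = extract_objects(m, frame_of(np.zeros((20, 20))), a_min=50,
                               a_max=5000)
        assert objs == []

    def test_merged_oversized_blob_discarded(self):
        """Two touching worm-sized bars merged into one blob above a_max
        produce no objects (labelled-component oracle on the same mask)."""
        m = np.zeros((40, 120), dtype=bool)
        m[10:15, 5:65] = True    # worm 1: 300 px
        m[14:19, 60:115] = True  # worm 2 overlapping its tail
        from scipy import ndimage
        lab, n = ndimage.label(m, structure=np.ones((3, 3)))
        assert n == 1  # oracle confirms the blobs merged
        area = int(m.sum())
        objs = extract_objects(m, frame_of(np.zeros(m.shape)),
                               a_min=100, a_max=area - 1)
        assert objs == []

    def test_invalid_gate_rejected(self):
        with pytest.raises(ValueError):
            extract_objects(np.zeros((4, 4), dtype=bool),
                            frame_of(np.zeros((4, 4))), a_min=10, a_max=10)


def geodesic_diameter(mask: np.ndarray) -> int:
    """Oracle: longest 8-connected shortest path between mask pixels,
    via BFS from the two sweep endpoints."""
    from collections import deque
    coords = list(map(tuple, np.argwhere(mask)))
    cset = set(coords)

    def bfs(start):
        dist = {start: 0}
        q = deque([start])
        far, fard = start, 0
        while q:
            r, c = q.popleft()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in cset and nb not in dist:
                        dist[nb] = dist[(r, c)] + 1
                        if dist[nb] > fard:
                            far, fard = nb, dist[nb]
                        q.append(nb)
        return far, fard

    a, _ = bfs(coords[0])
    _, d = bfs(a)
    return d


class TestSkeletonMidline:
    def test_straight_bar_midline(self):
        m = np.zeros((20, 120), dtype=bool)
        m[8:13, 10:110] = True
        ml = skeleton_midline(m)
        assert ml.simple
        # collinear along the bar axis
        assert np.ptp(ml.points[:, 0]) <= 2
        assert 95 <= ml.length_px <= 105

    def test_annulus_has_no_simple_midline(self):
        m = disk_mask(41, (20, 20), 15) & ~disk_mask(41, (20, 20), 8)
        ml = skeleton_midline(m)
        assert not ml.simple
        assert len(ml.points) == 0

    def test_disconnected_mask_rejected(self):
        m = np.zeros((10, 10), dtype=bool)
        m[1, 1], m[8, 8] = True, True
        with pytest.raises(ValueError):
            skeleton_midline(m)

    def test_rendered_worm_midline_length_near_body_length(self):
        """Skeleton midline arc length of a rendered sinusoidal worm is
        within 10% of the true body length."""
        cfg = SimulationConfig(arena_size=(300, 300), n_worms=1,
                               noise_sd=0.0, steer_margin=1000.0)
        state = WormState(centroid=np.array([2200.0, 2300.0]), heading=0.5,
                          speed=50.0, phase=1.0)
        img = render_frame([state], cfg)
        mask = img < (cfg.worm_level + cfg.background_level) / 2
        ml = skeleton_midline(mask)
        assert ml.simple
        length_um = ml.length_px * cfg.um_per_px
        assert abs(length_um - cfg.body_length) < 0.10 * cfg.body_length
        # path hop count agrees with the geodesic-diameter oracle
        hops = len(ml.points) - 1
        assert abs(hops - geodesic_diameter(mask)) <= \
            0.15 * geodesic_diameter(mask)


class TestOnSimulatedFrames:
    def test_counts_holes_and_centroids_match_ground_truth(self):
        """Noise-free well-separated worms: one object per worm per frame,
        hole counts match the behavioral mode, centroids within 2 px."""
        cfg = SimulationConfig(arena_size=(700, 700), n_worms=2,
                               duration=30.0, noise_sd=0.0, coil_rate=0.0,
                               steer_margin=1500.0, seed=12)
        a_w = cfg.worm_area_px()
        for t, frame, recs in simulate_frames(cfg):
            fr = Frame(frame, t, cfg.um_per_px)
            objs = segment_frame(fr, a_min=0.25 * a_w, a_max=4 * a_w,
                                 compute_midlines=False)
            assert len(objs) == cfg.n_worms
            for rec in recs:
                gt_rc = np.array([rec[3], rec[2]]) / cfg.um_per_px
                errs = [np.linalg.norm(o.centroid_px - gt_rc) for o in objs]
                assert min(errs) <= 2.0
                nearest = objs[int(np.argmin(errs))]
                assert nearest.n_holes == 0  # RUN worms have no holes

    def test_centroid_recovery_under_heavy_noise(self):
        """Worm centroid recovered within 2 px at noise up to 10% of the
        8-bit dynamic range (spurious blobs allowed, worm still found)."""
        cfg = SimulationConfig(arena_size=(300, 300), n_worms=1,
                               duration=15.0, noise_sd=25.5,
                               steer_margin=1000.0, seed=3)
        a_w = cfg.worm_area_px()
        for t, frame, recs in simulate_frames(cfg):
            fr = Frame(frame, t, cfg.um_per_px)
            objs = segment_frame(fr, a_min=0.25 * a_w, a_max=4 * a_w,
                                 compute_midlines=False)
            gt_rc = np.array([recs[0][3], recs[0][2]]) / cfg.um_per_px
            errs = [np.linalg.norm(o.centroid_px - gt_rc) for o in objs]
            assert errs and min(errs) <= 2.0
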