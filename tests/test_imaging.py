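"""Chamber-image analytics: detection, circularity, motility, stain calls."""

import itertools
import math

import numpy as np
import pytest

from scgxe.imaging import (Blob, ChamberImage, circularity, classify_stain,
                           detect_blobs, detect_blobs_highres,
                           min_enclosing_circle, track_motility)


def disc_image(shape, centers, radius=2.0, amplitude=1000.0, background=10.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    # faint seeded noise keeps background intensities tie-free, like real
    # sensor noise (a flat background would tie at the top-n threshold)
    img = np.full(shape, background) + np.random.default_rng(0).normal(
        0, 0.5, shape)
    for cy, cx in centers:
        img[(rr - cy) ** 2 + (cc - cx) ** 2 <= radius ** 2] = amplitude
    return ChamberImage(pixels=img)


def brute_min_circle(pts):
    pts = [tuple(map(float, p)) for p in pts]

    def covers(c):
        return all(math.dist((c[0], c[1]), p) <= c[2] + 1e-9 for p in pts)

    if len(pts) == 1:
        return (pts[0][0], pts[0][1], 0.0)
    cands = []
    for a, b in itertools.combinations(pts, 2):
        cands.append(((a[0] + b[0]) / 2, (a[1] + b[1]) / 2, math.dist(a, b) / 2))
    for a, b, c in itertools.combinations(pts, 3):
        ax, ay = a
        bx, by = b
        cx, cy = c
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            continue
        ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
              + (cx * cx + cy * cy) * (ay - by)) / d
        uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
              + (cx * cx + cy * cy) * (bx - ax)) / d
        cands.append((ux, uy, math.dist((ux, uy), a)))
    return min((c for c in cands if covers(c)), key=lambda c: c[2])


def brute_circularity(pixels):
    cy, cx, r = brute_min_circle(sorted(pixels))
    n_in = n_blob = 0
    for rr in range(math.floor(cy - r - 1), math.ceil(cy + r + 1) + 1):
        for cc in range(math.floor(cx - r - 1), math.ceil(cx + r + 1) + 1):
            if (rr - cy) ** 2 + (cc - cx) ** 2 <= (r + 1e-9) ** 2:
                n_in += 1
                if (rr, cc) in pixels:
                    n_blob += 1
    return n_blob / n_in


def make_blob(pixels):
    pix = frozenset(pixels)
    rows = [p[0] for p in pix]
    cols = [p[1] for p in pix]
    return Blob(pix, (float(np.mean(rows)), float(np.mean(cols))), len(pix), 1.0)


class TestDetectBlobs:
    def test_single_disc_found_with_accurate_centroid(self):
        img = disc_image((40, 40), [(20, 20)], radius=1.6)  # 9-pixel disc
        blobs = detect_blobs(img)
        assert len(blobs) == 1
        assert blobs[0].size >= 4
        assert math.dist(blobs[0].centroid, (20, 20)) <= 1.0

    def test_two_discs_found(self):
        img = disc_image((40, 60), [(20, 15), (20, 35)], radius=1.8)
        assert len(detect_blobs(img)) == 2

    def test_small_groups_below_min_size_rejected(self):
        img = np.full((30, 30), 10.0)
        img[10:13, 10:19] = 1000.0                     # 27-pixel cluster
        for r, c in [(2, 2), (2, 25), (25, 2)]:        # 3 isolated bright pixels
            img[r, c] = 2000.0
        blobs = detect_blobs(ChamberImage(pixels=img), top_n=30, min_size=4)
        assert len(blobs) == 1
        assert blobs[0].size == 27

    def test_top_n_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            detect_blobs(ChamberImage(pixels=np.zeros((4, 4))), top_n=30)

    def test_intensity_shift_invariance(self):
        img = disc_image((40, 40), [(12, 30)], radius=1.8)
        shifted = ChamberImage(pixels=img.pixels + 123.0)
        b1 = detect_blobs(img)
        b2 = detect_blobs(shifted)
        assert [b.pixel_set for b in b1] == [b.pixel_set for b in b2]

    def test_blobs_disjoint_and_connected(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            img = ChamberImage(pixels=rng.normal(100, 10, (30, 30)))
            blobs = detect_blobs(img, top_n=30, min_size=2)
            seen = set()
            for b in blobs:
                assert not (b.pixel_set & seen)
                seen |= b.pixel_set
                # connectivity: flood fill within the pixel set
                pix = set(b.pixel_set)
                stack = [next(iter(pix))]
                comp = set()
                while stack:
                    p = stack.pop()
                    if p in comp:
                        continue
                    comp.add(p)
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            q = (p[0] + dr, p[1] + dc)
                            if q in pix and q not in comp:
                                stack.append(q)
                assert comp == pix


class TestHighres:
    def test_large_disc_detected_small_disc_not(self):
        big = disc_image((120, 120), [(60, 60)], radius=6.0)   # ~113 px
        assert len(detect_blobs_highres(big)) == 1
        small = disc_image((120, 120), [(60, 60)], radius=3.9)  # ~45 px
        assert len(detect_blobs_highres(small)) == 0

    def test_scale_consistency_with_lowres(self):
        rr, cc = np.mgrid[0:288, 0:384]
        hi = 20.0 + 4000.0 * np.exp(-((rr - 140) ** 2 + (cc - 230) ** 2) / (2 * 10.0 ** 2))
        hi_blobs = detect_blobs_highres(ChamberImage(pixels=hi))
        lo = hi.reshape(72, 4, 96, 4).mean(axis=(1, 3))
        lo_blobs = detect_blobs(ChamberImage(pixels=lo))
        assert len(hi_blobs) == len(lo_blobs) == 1
        scaled = (hi_blobs[0].centroid[0] / 4, hi_blobs[0].centroid[1] / 4)
        assert math.dist(scaled, lo_blobs[0].centroid) <= 1.0


class TestCircularity:
    def test_single_pixel(self):
        assert circularity(make_blob([(3, 3)])) == 1.0

    def test_filled_disc_matches_oracle_and_is_round(self):
        pix = {(r, c) for r in range(-6, 7) for c in range(-6, 7) if r * r + c * c <= 36}
        val = circularity(make_blob(pix))
        assert val == brute_circularity(pix)
        assert val > 0.9

    def test_line_matches_oracle_and_is_elongated(self):
        pix = {(0, c) for c in range(9)}
        val = circularity(make_blob(pix))
        assert val == brute_circularity(pix)
        assert val < 0.5

    def test_random_blobs_match_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            pix = {(0, 0)}
            cur = (0, 0)
            for _ in range(int(rng.integers(1, 22))):
                cur = (cur[0] + int(rng.integers(-1, 2)), cur[1] + int(rng.integers(-1, 2)))
                pix.add(cur)
            assert circularity(make_blob(pix)) == brute_circularity(pix)

    def test_min_enclosing_circle_covers_all_points(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pts = rng.integers(0, 15, size=(int(rng.integers(1, 30)), 2)).tolist()
            cy, cx, r = min_enclosing_circle(pts)
            assert all(math.dist((cy, cx), tuple(map(float, p))) <= r + 1e-9 for p in pts)


class TestMotility:
    def test_stationary(self):
        b = make_blob([(5, 5), (5, 6), (6, 5), (6, 6)])
        track = track_motility({0: [b], 1: [b], 2: [b]})
        assert track.displacements_px == [0.0, 0.0]

    def test_3_4_5_triangle(self):
        b0 = make_blob([(10, 10)])
        b1 = make_blob([(13, 14)])
        track = track_motility({0: [b0], 1: [b1]}, pixel_size_um=2.0)
        assert track.displacements_px[0] == pytest.approx(5.0)
        assert track.displacements_um[0] == pytest.approx(10.0)

    def test_gap_recorded_not_error(self):
        b = make_blob([(5, 5)])
        track = track_motility({0: [b], 1: [], 2: [b]})
        assert math.isnan(track.displacements_px[0])
        assert math.isnan(track.displacements_px[1])
        assert track.centroids[1][1] is None

    def test_random_walk_matches_rayleigh_mean(self):
        rng = np.random.default_rng(3)
        sigma = 2.0
        steps = 4000
        pos = np.cumsum(rng.normal(0, sigma, size=(steps + 1, 2)), axis=0) + 50
        blobs = {t: [make_blob([(float(pos[t, 0]), float(pos[t, 1]))])]
                 for t in range(steps + 1)}
        track = track_motility(blobs)
        mean_disp = np.mean(track.displacements_px)
        rayleigh_mean = sigma * math.sqrt(math.pi / 2)
        se = sigma * math.sqrt((2 - math.pi / 2) / steps)
        assert abs(mean_disp - rayleigh_mean) < 3 * se

    def test_needs_two_observed_timepoints(self):
        with pytest.raises(ValueError):
            track_motility({0: [make_blob([(1, 1)])], 1: []})


class TestStainClassification:
    def test_scheme_application(self):
        o = [make_blob([(10, 10)])]
        g = [make_blob([(10, 10)])]
        labels, anomalies = classify_stain(o, g, {"double": "KO"})
        assert labels == ["KO"] and not anomalies
        labels, _ = classify_stain(o, [], {"double": "KO"})
        assert labels == ["WT"]

    def test_tolerance(self):
        o = [make_blob([(10, 10)])]
        g = [make_blob([(11, 11)])]  # ~1.41 px apart
        labels, _ = classify_stain(o, g, {"double": "WT"}, tolerance_px=3.0)
        assert labels == ["WT"]
        labels, anomalies = classify_stain(o, g, {"double": "WT"}, tolerance_px=1.0)
        assert labels == ["KO"] and len(anomalies) == 1

    def test_green_only_flagged_anomalous(self):
        labels, anomalies = classify_stain([], [make_blob([(5, 5)])], {"double": "KO"})
        assert labels == [] and len(anomalies) == 1

    def test_bad_scheme_rejected(self):
        with pytest.raises(ValueError):
            classify_stain([], [], {"double": "HET"})
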