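"""Chamber-image analytics: brightest-pixel cell detection, stain typing,
motility and circularity.

Cells are detected as connected clusters (8-connectivity) of at least
``min_size`` of the ``top_n`` brightest pixels of the trimmed per-chamber
image: 4 of the brightest 30 at chip-scanner resolution, 60 of the brightest
411 at confocal resolution.  Ties at the top_n-th brightness are included, so
top_n is a lower bound on the number of thresholded pixels and the result is
order-independent.  Morphology is summarised by *circularity* — the fraction
of the pixels inside the blob's minimum enclosing circle that belong to the
blob — and motility by centroid displacement of the largest blob between
hourly imaging timepoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ChamberImage",
    "Blob",
    "CellTrack",
    "detect_blobs",
    "detect_blobs_highres",
    "min_enclosing_circle",
    "circularity",
    "track_motility",
    "classify_stain",
    "load_image",
    "detection_table",
]

_EIGHT = np.ones((3, 3), dtype=int)
_EPS = 1e-9  # boundary slack: "inside" means distance <= radius + _EPS


@dataclass
class ChamberImage:
    pixels: np.ndarray
    channel: str = "orange"            # brightfield | orange | green
    timepoint_hours: int = 0
    chamber_id: str = ""
    pixel_size_um: float = 5.5

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("chamber image must be 2-D")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("intensities must be finite")


@dataclass
class Blob:
    pixel_set: frozenset          # of (row, col)
    centroid: tuple               # (row, col), float
    size: int
    peak_intensity: float

    def __post_init__(self):
        if self.size != len(self.pixel_set):
            raise ValueError("size must equal |pixel_set|")


@dataclass
class CellTrack:
    centroids: list               # [(timepoint, (row, col) or None)]
    displacements_px: list        # per consecutive interval; NaN across gaps
    displacements_um: list = field(default_factory=list)


def detect_blobs(image: ChamberImage, top_n: int = 30, min_size: int = 4) -> list[Blob]:
    """Connected clusters of >= min_size among the top_n brightest pixels.

    Returned sorted by size descending, then peak intensity descending, then
    first pixel (row, col) ascending for determinism.
    """
    px = image.pixels.astype(float)
    if px.size < top_n:
        raise ValueError(f"image has {px.size} pixels < top_n={top_n}")
    flat = np.sort(px.ravel())[::-1]
    threshold = flat[top_n - 1]
    mask = px >= threshold      # ties at the cut are all included
    labels, n_lab = ndimage.label(mask, structure=_EIGHT)
    blobs = []
    for lab in range(1, n_lab + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < min_size:
            continue
        blobs.append(
            Blob(
                pixel_set=frozenset(zip(rows.tolist(), cols.tolist())),
                centroid=(float(rows.mean()), float(cols.mean())),
                size=int(rows.size),
                peak_intensity=float(px[rows, cols].max()),
            )
        )
    blobs.sort(key=lambda b: (-b.size, -b.peak_intensity, min(b.pixel_set)))
    return blobs


def detect_blobs_highres(image: ChamberImage) -> list[Blob]:
    """Confocal-resolution variant: clusters of >= 60 of the brightest 411."""
    return detect_blobs(image, top_n=411, min_size=60)


# ---------------------------------------------------------------------------
# minimum enclosing circle and circularity
# ---------------------------------------------------------------------------

def _circle_two(a, b):
    cx = (a[0] + b[0]) / 2.0
    cy = (a[1] + b[1]) / 2.0
    r = math.dist(a, b) / 2.0
    return (cx, cy, r)


def _circle_three(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    return (ux, uy, math.dist((ux, uy), a))


def _inside(circle, p):
    return math.dist((circle[0], circle[1]), p) <= circle[2] + _EPS


def min_enclosing_circle(points) -> tuple[float, float, float]:
    """Exact smallest circle enclosing the points; deterministic order.

    Incremental Welzl-style construction over the points in their given
    order: expected linear time, exact result (up to the declared 1e-9
    boundary slack).
    """
    pts = [tuple(map(float, p)) for p in points]
    if not pts:
        raise ValueError("need at least one point")
    circle = (pts[0][0], pts[0][1], 0.0)
    for i, p in enumerate(pts[1:], start=1):
        if _inside(circle, p):
            continue
        circle = (p[0], p[1], 0.0)
        for j in range(i):
            q = pts[j]
            if _inside(circle, q):
                continue
            circle = _circle_two(p, q)
            for l in range(j):
                s = pts[l]
                if _inside(circle, s):
                    continue
                c3 = _circle_three(p, q, s)
                if c3 is not None:
                    circle = c3
    return circle


def circularity(blob: Blob) -> float:
    """Fraction of grid pixels inside the minimum enclosing circle that belong
    to the blob (pixel membership judged by pixel centers)."""
    if not blob.pixel_set:
        raise ValueError("blob is empty")
    pts = sorted(blob.pixel_set)
    cy, cx, r = min_enclosing_circle(pts)
    r0 = math.floor(cy - r - 1)
    r1 = math.ceil(cy + r + 1)
    c0 = math.floor(cx - r - 1)
    c1 = math.ceil(cx + r + 1)
    rows, cols = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    inside = (rows - cy) ** 2 + (cols - cx) ** 2 <= (r + _EPS) ** 2
    n_inside = int(inside.sum())
    pset = blob.pixel_set
    in_blob = sum(
        1 for rr, cc in zip(rows[inside].ravel(), cols[inside].ravel())
        if (int(rr), int(cc)) in pset
    )
    return in_blob / n_inside


# ---------------------------------------------------------------------------
# motility and stain classification
# ---------------------------------------------------------------------------

def track_motility(blobs_by_time: dict, pixel_size_um: float = 5.5) -> CellTrack:
    """Link the largest blob per timepoint and measure centroid displacement.

    Timepoints with no blob are recorded as gaps; the displacement across an
    interval touching a gap is NaN.  Displacements are Euclidean, reported in
    pixels and micrometres.
    """
    tps = sorted(blobs_by_time)
    if sum(1 for t in tps if blobs_by_time[t]) < 2:
        raise ValueError("need at least two timepoints with a detected blob")
    centroids = []
    for t in tps:
        blobs = blobs_by_time[t]
        if blobs:
            best = sorted(blobs, key=lambda b: (-b.size, -b.peak_intensity, min(b.pixel_set)))[0]
            centroids.append((t, best.centroid))
        else:
            centroids.append((t, None))
    disp_px = []
    for (t0, c0), (t1, c1) in zip(centroids[:-1], centroids[1:]):
        if c0 is None or c1 is None:
            disp_px.append(float("nan"))
        else:
            disp_px.append(math.dist(c0, c1))
    disp_um = [d * pixel_size_um for d in disp_px]
    return CellTrack(centroids=centroids, displacements_px=disp_px, displacements_um=disp_um)


def classify_stain(
    orange: list[Blob],
    green: list[Blob],
    scheme: dict,
    tolerance_px: float = 3.0,
) -> tuple[list[str], list[Blob]]:
    """Map single/double staining to genotype.

    Every cell is stained orange; in each run one genotype is additionally
    stained green ("double").  ``scheme`` declares {"double": "KO"} (or "WT").
    Returns per-orange-blob genotype labels and the list of anomalous
    green-only blobs (no orange counterpart within tolerance).
    """
    if set(scheme) != {"double"} or scheme["double"] not in ("WT", "KO"):
        raise ValueError("scheme must be {'double': 'WT'|'KO'}")
    double_label = scheme["double"]
    single_label = "WT" if double_label == "KO" else "KO"
    labels = []
    matched_green = set()
    for ob in orange:
        hit = None
        for gi, gb in enumerate(green):
            if math.dist(ob.centroid, gb.centroid) <= tolerance_px:
                hit = gi
                break
        if hit is not None:
            matched_green.add(hit)
            labels.append(double_label)
        else:
            labels.append(single_label)
    anomalies = [gb for gi, gb in enumerate(green) if gi not in matched_green]
    return labels, anomalies


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------

def load_image(path, channel: str = "orange", timepoint_hours: int = 0,
               chamber_id: str = "", pixel_size_um: float = 5.5) -> ChamberImage:
    """Read a 16-bit grayscale TIFF or PNG into a ChamberImage."""
    import imageio.v3 as iio

    pixels = iio.imread(path)
    return ChamberImage(pixels=pixels, channel=channel, timepoint_hours=timepoint_hours,
                        chamber_id=chamber_id or str(path), pixel_size_um=pixel_size_um)


def detection_table(images: list[ChamberImage], top_n: int = 30, min_size: int = 4) -> pd.DataFrame:
    """Run detection over a set of chamber images; one row per blob."""
    rows = []
    for img in images:
        for bi, blob in enumerate(detect_blobs(img, top_n=top_n, min_size=min_size)):
            rows.append(
                {
                    "chamber_id": img.chamber_id,
                    "channel": img.channel,
                    "timepoint": img.timepoint_hours,
                    "blob_id": bi,
                    "centroid_row": blob.centroid[0],
                    "centroid_col": blob.centroid[1],
                    "size": blob.size,
                    "circularity": circularity(blob),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chamber_id", "channel", "timepoint", "blob_id",
                 "centroid_row", "centroid_col", "size", "circularity"],
    )
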