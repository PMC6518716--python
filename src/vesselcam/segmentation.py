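"""Bright-object segmentation: Otsu threshold, largest component, contour.

The vessel silhouette is assumed bright on a dark background.  A frame is
reduced to the pixel-count area of the largest 8-connected foreground
component, together with its closed boundary polyline (Moore border
following) and the maximum caliper width of that boundary.

Conventions, stated once and tested:
  * Otsu threshold t maximises the between-class variance of the 256-bin
    histogram; ties go to the SMALLEST maximiser; foreground is strictly > t.
  * connectivity is 8 (diagonal necks of noisy silhouettes stay connected);
  * the area is the foreground pixel COUNT of the component, not the polygon
    area of its contour (integer-exact; the contour is kept for caliper use);
  * component ties are broken by the smallest top-left bounding-box corner
    in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised for unsupported image layouts."""


class DegenerateHistogramError(ValueError):
    """Raised when an image has fewer than two distinct gray levels."""


class NoObjectError(ValueError):
    """Raised when a mask contains no foreground pixel."""


@dataclass
class ObjectMeasure:
    """Largest-object measurement of one frame."""

    contour: np.ndarray        # (K, 2) closed pixel polyline, (x, y) order
    area_px: int               # foreground pixel count of the component
    bbox: tuple[int, int, int, int]   # (min_row, min_col, max_row, max_col) inclusive
    max_caliper_px: float      # largest point-pair distance of the contour
    threshold: int | None = None


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse an 8-bit frame to a single luma channel.

    RGB input combines channels with the fixed weights 0.299/0.587/0.114 and
    rounds half-up; grayscale input passes through unchanged.
    """
    img = np.asarray(frame)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 3:
        y = (0.299 * img[..., 0].astype(float)
             + 0.587 * img[..., 1] + 0.114 * img[..., 2])
        return np.floor(y + 0.5).astype(np.uint8)
    raise FormatError(f"expected 1- or 3-channel image, got shape {img.shape}")


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's threshold of an 8-bit grayscale image.

    Returns the integer t in [0, 255] maximising the between-class variance
    w0(t) * w1(t) * (mu0(t) - mu1(t))^2 with classes {<= t} and {> t};
    the smallest maximiser wins ties.
    """
    img = np.asarray(image)
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256)[:256].astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("image has fewer than two distinct gray levels")
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    s0 = np.cumsum(hist * levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (s0[-1] - s0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -1.0
    return int(np.argmax(between))


def binarize(image: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground mask: pixels strictly greater than the threshold."""
    return np.asarray(image) > threshold


_EIGHT = np.ones((3, 3), dtype=int)

# Moore neighbourhood in clockwise order starting east, (dr, dc)
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def _trace_boundary(component: np.ndarray) -> np.ndarray:
    """Moore border following; returns the closed boundary as (x, y) points.

    Starts at the first foreground pixel in row-major order (whose west
    neighbour is guaranteed background) and walks the outer boundary
    clockwise.  The walk is a deterministic map on (pixel, backtrack) states,
    so it terminates exactly when a state repeats — a criterion that is robust
    for every component shape, including one-pixel bridges and spurs.
    """
    rows, cols = np.nonzero(component)
    start = (int(rows[0]), int(cols[0]))
    if len(rows) == 1:
        return np.array([[start[1], start[0]]], dtype=float)

    def at(r, c):
        return (0 <= r < component.shape[0] and 0 <= c < component.shape[1]
                and component[r, c])

    boundary = [start]
    cur = start
    backtrack = 4  # direction from cur towards its (background) west neighbour
    seen = {(cur, backtrack)}
    while True:
        for k in range(1, 9):
            d = (backtrack + k) % 8
            dr, dc = _MOORE[d]
            nr, nc = cur[0] + dr, cur[1] + dc
            if at(nr, nc):
                cur = (nr, nc)
                backtrack = (d + 4) % 8
                break
        else:  # no neighbour: unreachable for multi-pixel components
            break
        if ((cur, backtrack)) in seen:
            break
        seen.add((cur, backtrack))
        boundary.append(cur)
    return np.array([[c, r] for r, c in boundary], dtype=float)


def _boundary_pixels(component: np.ndarray) -> np.ndarray:
    """(x, y) centres of component pixels touching the background (4-adjacency)."""
    inner = ndimage.binary_erosion(component, structure=ndimage.generate_binary_structure(2, 1),
                                   border_value=0)
    rows, cols = np.nonzero(component & ~inner)
    return np.column_stack([cols, rows]).astype(float)


def _max_caliper(points: np.ndarray) -> float:
    """Largest pairwise distance among boundary points (via the convex hull)."""
    pts = np.unique(points, axis=0)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        from scipy.spatial import ConvexHull, QhullError
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: brute-force below
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def largest_object(mask: np.ndarray) -> ObjectMeasure:
    """Measure the largest 8-connected foreground component of a binary mask."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise NoObjectError("mask contains no foreground pixel")
    labels, n = ndimage.label(m, structure=_EIGHT)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    candidates = np.nonzero(counts == best)[0]
    if len(candidates) > 1:
        # tie-break: smallest top-left bbox corner, row-major
        slices = ndimage.find_objects(labels)
        candidates = sorted(candidates,
                            key=lambda l: (slices[l - 1][0].start, slices[l - 1][1].start))
    label = int(candidates[0])
    component = labels == label
    rows, cols = np.nonzero(component)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
    contour = _trace_boundary(component)
    return ObjectMeasure(contour=contour, area_px=int(best), bbox=bbox,
                         max_caliper_px=_max_caliper(_boundary_pixels(component)))


def segment_frame(frame: np.ndarray, min_object_px: int = 0) -> ObjectMeasure:
    """Full per-frame chain: grayscale -> Otsu -> binarize -> largest object.

    ``min_object_px`` optionally removes components smaller than the given
    pixel count before selecting the largest (off by default).
    """
    gray = to_grayscale(frame)
    t = otsu_threshold(gray)
    mask = binarize(gray, t)
    if min_object_px > 0:
        labels, _ = ndimage.label(mask, structure=_EIGHT)
        counts = np.bincount(labels.ravel())
        small = np.nonzero(counts < min_object_px)[0]
        mask &= ~np.isin(labels, small[small > 0])
    measure = largest_object(mask)
    measure.threshold = t
    return measure
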