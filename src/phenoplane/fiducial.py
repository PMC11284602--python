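"""Square-fiducial detection and pixel-to-metric plane calibration.

A single square marker of known physical side length (default 4.7 cm) is
located in the image, its four corners are refined to sub-pixel accuracy,
and an exact four-point projective transform is solved mapping image pixel
coordinates onto the marker plane in centimetres.  All trait measurements
downstream go through this homography; the scalar ``scale_cm_per_px`` is
reported for provenance only.

Coordinate conventions: pixel coordinates are 0-based and refer to pixel
centers, point arrays are ``(x, y)`` = ``(column, row)``.  Boxes are
half-open ``[x0, x1) x [y0, y1)``.  The marker-plane frame puts the
physical top-left corner at (0, 0) with x to the right and y downward, so
the corners in canonical order (TL, TR, BR, BL) map to
``(0,0), (s,0), (s,s), (0,s)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import (
    AmbiguousMarker,
    DegenerateCorners,
    MarkerNotFound,
    PointAtInfinity,
)

DEFAULT_SIDE_CM = 4.7

__all__ = [
    "DEFAULT_SIDE_CM",
    "MarkerDetection",
    "PlaneHomography",
    "RectifiedMask",
    "apply_homography",
    "detect_marker",
    "estimate_homography",
    "marker_plane_corners",
    "rectify_mask",
    "to_metric",
]


def marker_plane_corners(side_cm: float = DEFAULT_SIDE_CM) -> np.ndarray:
    """Physical marker corners (cm) in canonical TL, TR, BR, BL order."""
    s = float(side_cm)
    return np.array([[0.0, 0.0], [s, 0.0], [s, s], [0.0, s]])


def apply_homography(matrix: np.ndarray, points) -> np.ndarray:
    """Apply a 3x3 projective transform to ``(x, y)`` point(s).

    Raises :class:`PointAtInfinity` when any homogeneous coordinate has
    magnitude below 1e-12.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    homog = np.column_stack([pts, np.ones(len(pts))])
    mapped = homog @ np.asarray(matrix, dtype=float).T
    w = mapped[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise PointAtInfinity("homogeneous coordinate vanished")
    out = mapped[:, :2] / w[:, None]
    return out[0] if single else out


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _polygon_area(corners: np.ndarray) -> float:
    """Signed shoelace area (positive for TL,TR,BR,BL order in y-down images)."""
    x, y = corners[:, 0], corners[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _is_convex_quad(corners: np.ndarray) -> bool:
    # zero cross products (a straightened corner) are tolerated here; the
    # collinearity screen with a proper error lives in estimate_homography
    signs = []
    for i in range(4):
        a = corners[(i + 1) % 4] - corners[i]
        b = corners[(i + 2) % 4] - corners[(i + 1) % 4]
        signs.append(np.sign(_cross2(a, b)))
    signs = [s for s in signs if s != 0]
    return len(signs) > 0 and len(set(signs)) == 1


@dataclass(frozen=True)
class MarkerDetection:
    """Four ordered image-plane corners of the square fiducial.

    ``corners`` is a (4, 2) float array in canonical order TL, TR, BR, BL
    of the *physical* marker; ``side_cm`` is the physical side length.
    """

    corners: np.ndarray
    side_cm: float = DEFAULT_SIDE_CM

    def __post_init__(self):
        corners = np.asarray(self.corners, dtype=float)
        if corners.shape != (4, 2):
            raise ValueError("corners must be 4 2-D points")
        if not np.all(np.isfinite(corners)):
            raise ValueError("corners must be finite")
        if abs(_polygon_area(corners)) <= 0.0 or not _is_convex_quad(corners):
            raise ValueError("corners must form a convex, non-degenerate quad")
        if not self.side_cm > 0:
            raise ValueError("side_cm must be positive")
        object.__setattr__(self, "corners", corners)


@dataclass(frozen=True)
class PlaneHomography:
    """3x3 projective map from image pixels to marker-plane centimetres."""

    matrix: np.ndarray
    scale_cm_per_px: float
    side_cm: float = DEFAULT_SIDE_CM

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-15:
            raise ValueError("matrix must be invertible")
        if not self.scale_cm_per_px > 0:
            raise ValueError("scale_cm_per_px must be positive")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_json(self, corners: np.ndarray | None = None) -> str:
        payload = {
            "matrix": self.matrix.ravel().tolist(),
            "scale_cm_per_px": self.scale_cm_per_px,
            "side_cm": self.side_cm,
        }
        if corners is not None:
            payload["corners"] = np.asarray(corners, float).tolist()
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PlaneHomography":
        payload = json.loads(text)
        return cls(
            matrix=np.asarray(payload["matrix"], float).reshape(3, 3),
            scale_cm_per_px=float(payload["scale_cm_per_px"]),
            side_cm=float(payload.get("side_cm", DEFAULT_SIDE_CM)),
        )


# ---------------------------------------------------------------------------
# homography estimation
# ---------------------------------------------------------------------------

def _normalization(points: np.ndarray) -> np.ndarray:
    """Hartley similarity normalization (mean 0, RMS distance sqrt(2))."""
    centroid = points.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((points - centroid) ** 2, axis=1)))
    s = np.sqrt(2.0) / rms if rms > 0 else 1.0
    return np.array([
        [s, 0.0, -s * centroid[0]],
        [0.0, s, -s * centroid[1]],
        [0.0, 0.0, 1.0],
    ])


def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Exact direct linear transform for 4 point correspondences."""
    t_src = _normalization(src)
    t_dst = _normalization(dst)
    sn = apply_homography(t_src, src)
    dn = apply_homography(t_dst, dst)
    rows = []
    for (x, y), (u, v) in zip(sn, dn):
        rows.append([x, y, 1, 0, 0, 0, -u * x, -u * y, -u])
        rows.append([0, 0, 0, x, y, 1, -v * x, -v * y, -v])
    _, _, vt = np.linalg.svd(np.asarray(rows))
    hn = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_dst) @ hn @ t_src
    if abs(h[2, 2]) > 1e-12:
        h = h / h[2, 2]
    return h


def estimate_homography(marker: MarkerDetection) -> PlaneHomography:
    """Solve the exact 4-point pixel-to-cm homography for a detected marker.

    Four coplanar correspondences determine the projective map up to scale;
    the round-trip residual on the corners is at machine precision.  Raises
    :class:`DegenerateCorners` when any three corners are collinear.
    """
    src = marker.corners
    dst = marker_plane_corners(marker.side_cm)
    span = np.ptp(src, axis=0).max()
    for i in range(4):
        tri = np.delete(src, i, axis=0)
        area2 = abs(_cross2(tri[1] - tri[0], tri[2] - tri[0]))
        if area2 < 1e-9 * span**2:
            raise DegenerateCorners("three marker corners are collinear")
    h = _dlt(src, dst)
    side_px = np.linalg.norm(src - np.roll(src, -1, axis=0), axis=1)
    scale = marker.side_cm / float(side_px.mean())
    return PlaneHomography(matrix=h, scale_cm_per_px=scale, side_cm=marker.side_cm)


def to_metric(points, homography: PlaneHomography) -> np.ndarray:
    """Map image pixel point(s) onto the marker plane (cm)."""
    return apply_homography(homography.matrix, points)


# ---------------------------------------------------------------------------
# marker detection
# ---------------------------------------------------------------------------

def _initial_quad(points: np.ndarray) -> np.ndarray:
    """Rough 4-corner estimate of a convex quadrilateral point cloud."""
    centroid = points.mean(axis=0)
    p0 = points[np.argmax(np.linalg.norm(points - centroid, axis=1))]
    p1 = points[np.argmax(np.linalg.norm(points - p0, axis=1))]
    d = p1 - p0
    cross = d[0] * (points[:, 1] - p0[1]) - d[1] * (points[:, 0] - p0[0])
    p2 = points[np.argmax(cross)]
    p3 = points[np.argmin(cross)]
    quad = np.array([p0, p1, p2, p3])
    angles = np.arctan2(quad[:, 1] - centroid[1], quad[:, 0] - centroid[0])
    return quad[np.argsort(angles)]


def _point_line_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = b - a
    n = np.linalg.norm(d)
    if n == 0:
        return np.linalg.norm(points - a, axis=1)
    return np.abs(d[0] * (points[:, 1] - a[1]) - d[1] * (points[:, 0] - a[0])) / n


def _fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through points -> (point, unit direction)."""
    mean = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - mean)
    return mean, vt[0]


def _intersect(l1, l2) -> np.ndarray:
    (m1, d1), (m2, d2) = l1, l2
    a = np.column_stack([d1, -d2])
    t = np.linalg.solve(a, m2 - m1)
    return m1 + t[0] * d1


def _refine_quad(points: np.ndarray, quad: np.ndarray,
                 corner_margin: float = 4.0, edge_tol: float = 1.5) -> np.ndarray:
    lines = []
    for k in range(4):
        a, b = quad[k], quad[(k + 1) % 4]
        dist = _point_line_distance(points, a, b)
        near = (
            (dist < edge_tol)
            & (np.linalg.norm(points - a, axis=1) > corner_margin)
            & (np.linalg.norm(points - b, axis=1) > corner_margin)
        )
        if near.sum() >= 2:
            lines.append(_fit_line(points[near]))
        else:
            direction = (b - a) / np.linalg.norm(b - a)
            lines.append((a, direction))
    corners = np.array([_intersect(lines[k - 1], lines[k]) for k in range(4)])
    centroid = corners.mean(axis=0)
    angles = np.arctan2(corners[:, 1] - centroid[1], corners[:, 0] - centroid[0])
    return corners[np.argsort(angles)]


def detect_marker(
    image,
    side_cm: float = DEFAULT_SIDE_CM,
    dark_threshold: float = 60.0,
    min_area: int = 300,
) -> MarkerDetection:
    """Locate the synthetic square fiducial and return its ordered corners.

    The fiducial is a high-contrast (near-black) square carrying a bright
    orientation cue near its physical top-left corner, which disambiguates
    the canonical corner order.  Candidate dark components are screened for
    size, convexity and the presence of the cue hole; zero candidates raise
    :class:`MarkerNotFound`, several raise :class:`AmbiguousMarker`.  Corner
    localization fits total-least-squares lines to the sub-pixel outer
    contour and intersects adjacent edges, which keeps the error well under
    half a pixel on rendered scenes.
    """
    arr = np.asarray(image)
    gray = arr.mean(axis=2).astype(float) if arr.ndim == 3 else arr.astype(float)
    dark = gray < dark_threshold
    labels, n = ndimage.label(dark)
    candidates = []
    for idx in range(1, n + 1):
        comp = labels == idx
        if comp.sum() < min_area:
            continue
        filled = ndimage.binary_fill_holes(comp)
        holes = filled & ~comp
        if holes.sum() < 4:
            continue  # no orientation cue -> not our fiducial
        props = measure.regionprops(filled.astype(np.uint8))[0]
        if props.solidity < 0.85:
            continue
        candidates.append((comp, filled, holes))
    if not candidates:
        raise MarkerNotFound("no fiducial candidate found")
    if len(candidates) > 1:
        raise AmbiguousMarker(f"{len(candidates)} fiducial candidates found")

    comp, filled, holes = candidates[0]
    rows, cols = np.nonzero(filled)
    pad = 3
    r0 = max(rows.min() - pad, 0)
    r1 = min(rows.max() + pad + 1, gray.shape[0])
    c0 = max(cols.min() - pad, 0)
    c1 = min(cols.max() + pad + 1, gray.shape[1])
    gray_crop = gray[r0:r1, c0:c1].copy()
    filled_crop = filled[r0:r1, c0:c1]
    holes_crop = holes[r0:r1, c0:c1]

    interior = ndimage.binary_erosion(filled_crop, iterations=3) & ~ndimage.binary_dilation(
        holes_crop, iterations=3
    )
    black_est = float(np.median(gray_crop[interior])) if interior.any() else float(
        gray_crop[filled_crop].min()
    )
    ring = ndimage.binary_dilation(filled_crop, iterations=3) & ~filled_crop
    bg_est = float(np.median(gray_crop[ring])) if ring.any() else 235.0
    # suppress the cue hole so only the outer boundary crosses the level set
    gray_crop[ndimage.binary_dilation(holes_crop, iterations=2)] = black_est
    level = 0.5 * (black_est + bg_est)

    contours = measure.find_contours(gray_crop, level)
    if not contours:
        raise MarkerNotFound("no contour at fiducial boundary")
    contour = max(contours, key=len)
    points = contour[:, ::-1] + np.array([c0, r0])  # (row, col) -> (x, y)

    quad = _initial_quad(points)
    quad = _refine_quad(points, quad)
    quad = _refine_quad(points, quad)

    if _polygon_area(quad) < 0:  # enforce TL,TR,BR,BL winding (y-down)
        quad = quad[::-1]
    hole_rows, hole_cols = np.nonzero(holes)
    cue = np.array([hole_cols.mean(), hole_rows.mean()])
    start = int(np.argmin(np.linalg.norm(quad - cue, axis=1)))
    quad = np.roll(quad, -start, axis=0)
    return MarkerDetection(corners=quad, side_cm=side_cm)


# ---------------------------------------------------------------------------
# rectification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RectifiedMask:
    """Binary raster resampled onto a regular metric grid.

    Cell ``(i, j)`` has its center at
    ``origin_cm + (j + 0.5, i + 0.5) * resolution_cm_per_px``.
    """

    bitmap: np.ndarray
    origin_cm: tuple[float, float]
    resolution_cm_per_px: float

    @property
    def area_cm2(self) -> float:
        return float(self.bitmap.sum()) * self.resolution_cm_per_px**2

    def cell_centers_cm(self) -> np.ndarray:
        """(n, 2) cm coordinates of foreground cell centers."""
        ys, xs = np.nonzero(self.bitmap)
        res = self.resolution_cm_per_px
        ox, oy = self.origin_cm
        return np.column_stack([ox + (xs + 0.5) * res, oy + (ys + 0.5) * res])


def rectify_mask(
    mask,
    homography: PlaneHomography,
    resolution_cm_per_px: float,
    origin_px: tuple[float, float] = (0.0, 0.0),
) -> RectifiedMask:
    """Nearest-neighbour resample of an image-frame mask onto the metric plane.

    ``mask`` is a binary raster whose pixel ``(row, col)`` sits at image
    coordinates ``(origin_px[0] + col, origin_px[1] + row)``.  An empty mask
    yields an empty output (no error).
    """
    if not resolution_cm_per_px > 0:
        raise ValueError("resolution must be positive")
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    res = float(resolution_cm_per_px)
    if len(xs) == 0:
        return RectifiedMask(np.zeros((0, 0), dtype=bool), (0.0, 0.0), res)
    ox, oy = origin_px
    pts_cm = to_metric(np.column_stack([xs + ox, ys + oy]), homography)
    # pad past the extreme foreground *centers* by a full pixel footprint in
    # cm, else the outer half-pixel of boundary pixels is cropped and areas
    # come out systematically low
    pad = res + homography.scale_cm_per_px
    x0 = pts_cm[:, 0].min() - pad
    y0 = pts_cm[:, 1].min() - pad
    nx = int(np.ceil((pts_cm[:, 0].max() + pad - x0) / res)) + 1
    ny = int(np.ceil((pts_cm[:, 1].max() + pad - y0) / res)) + 1
    gx = x0 + (np.arange(nx) + 0.5) * res
    gy = y0 + (np.arange(ny) + 0.5) * res
    gxx, gyy = np.meshgrid(gx, gy)
    img_pts = apply_homography(homography.inverse,
                               np.column_stack([gxx.ravel(), gyy.ravel()]))
    # zero-pad by one pixel: map_coordinates treats coords in (-0.5, 0) as
    # outside instead of rounding to the border pixel, which would clip the
    # footprint of foreground pixels sitting on a tight crop's edge
    padded = np.pad(mask, 1).astype(np.uint8)
    coords = np.stack([img_pts[:, 1] - oy + 1, img_pts[:, 0] - ox + 1])
    sampled = ndimage.map_coordinates(
        padded, coords, order=0, mode="constant", cval=0
    )
    return RectifiedMask(sampled.reshape(ny, nx).astype(bool), (x0, y0), res)
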