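"""Synthetic scene rendering with exact ground truth.

Scenes emulate the capture geometry the measurement pipeline assumes: a
planar square fiducial of known physical side length imaged under a
projective pose, with coplanar flat-coloured plant-proxy parts (rectangle
crown, endpoint squares for plant-height/petiole spans, ellipse leaf, disk
flower and fruit) of known physical dimensions.  Rendering is deterministic
given the spec; all randomness lives in the scene builders and dataset
generators, which draw from one seeded generator.

Ground truth per part: a sub-pixel tight bounding box of the projected
shape, a pixelized mask (pixel center inside the shape), and the true trait
values in physical units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .backends import Mask
from .errors import PartOutOfFrame
from .fiducial import DEFAULT_SIDE_CM, apply_homography, marker_plane_corners

__all__ = [
    "PALETTE",
    "GroundTruth",
    "GroundTruthPart",
    "PartSpec",
    "PoseParams",
    "SceneSpec",
    "generate_validation_pairs",
    "generate_weight_dataset",
    "ground_truth_from_json",
    "ground_truth_to_json",
    "pose_homography",
    "render_scene",
    "trait_scene",
]

BACKGROUND = (235, 235, 235)
MARKER_COLOR = (15, 15, 15)
CUE_COLOR = (235, 235, 235)

# Flat part colours.  Gray means are kept >= 100 so no part trips the dark
# threshold used for fiducial screening; pairs of endpoint parts share one
# colour (they are told apart by image position, as a detector would).
PALETTE: dict[str, tuple[int, int, int]] = {
    "crown": (180, 100, 50),
    "plant_top": (60, 100, 230),
    "plant_bottom": (60, 100, 230),
    "petiole_top": (40, 190, 190),
    "petiole_bottom": (40, 190, 190),
    "leaf": (60, 170, 70),
    "flower": (250, 210, 60),
    "fruit": (230, 60, 60),
}

# cue square (cm, marker-plane frame) marking the physical top-left corner
_CUE_LO, _CUE_HI = 0.6, 1.5


@dataclass(frozen=True)
class PoseParams:
    """Projective pose of the marker plane relative to the camera.

    ``plane_anchor_cm`` is the plane point projected to ``image_anchor_px``;
    ``scale_px_per_cm`` is the pixel scale at that anchor.  Tilt is a
    rotation of the plane about an in-plane axis at ``tilt_azimuth_deg``;
    ``rotation_deg`` is in-plane (camera roll).
    """

    scale_px_per_cm: float
    rotation_deg: float = 0.0
    tilt_deg: float = 0.0
    tilt_azimuth_deg: float = 0.0
    distance_cm: float = 100.0
    plane_anchor_cm: tuple[float, float] = (0.0, 0.0)
    image_anchor_px: tuple[float, float] = (0.0, 0.0)


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def pose_homography(pose: PoseParams) -> np.ndarray:
    """3x3 matrix mapping marker-plane cm coordinates to image pixels."""
    if not 0 <= pose.tilt_deg < 90:
        raise ValueError("tilt must be in [0, 90) degrees")
    az = _rot_z(pose.tilt_azimuth_deg)
    r = az @ _rot_x(pose.tilt_deg) @ az.T @ _rot_z(pose.rotation_deg)
    ax, ay = pose.plane_anchor_cm
    t = np.array([0.0, 0.0, pose.distance_cm]) - r[:, :2] @ np.array([ax, ay])
    m = np.column_stack([r[:, 0], r[:, 1], t])
    f = pose.scale_px_per_cm * pose.distance_cm
    iax, iay = pose.image_anchor_px
    k = np.array([[f, 0.0, iax], [0.0, f, iay], [0.0, 0.0, 1.0]])
    return k @ m


@dataclass(frozen=True)
class PartSpec:
    """A flat coplanar plant-proxy part, dimensioned in cm on the marker plane.

    Shapes: ``rect`` with size ``(width, height)``, ``ellipse`` with size
    ``(major_x, minor_y)`` full axis lengths, ``disk`` with size ``(radius,)``.
    """

    label: str
    shape: str
    center_cm: tuple[float, float]
    size_cm: tuple[float, ...]
    color: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.shape not in ("rect", "ellipse", "disk"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(not s > 0 for s in self.size_cm):
            raise ValueError("physical dimensions must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center_cm
        if self.shape == "rect":
            w, h = self.size_cm
            return (np.abs(x - cx) <= w / 2) & (np.abs(y - cy) <= h / 2)
        if self.shape == "ellipse":
            a, b = self.size_cm[0] / 2, self.size_cm[1] / 2
            return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0
        r = self.size_cm[0]
        return (x - cx) ** 2 + (y - cy) ** 2 <= r**2

    def boundary_cm(self, n: int = 720) -> np.ndarray:
        cx, cy = self.center_cm
        if self.shape == "rect":
            w, h = self.size_cm
            t = np.linspace(0, 1, n // 4, endpoint=False)
            top = np.column_stack([cx - w / 2 + w * t, np.full_like(t, cy - h / 2)])
            right = np.column_stack([np.full_like(t, cx + w / 2), cy - h / 2 + h * t])
            bottom = np.column_stack([cx + w / 2 - w * t, np.full_like(t, cy + h / 2)])
            left = np.column_stack([np.full_like(t, cx - w / 2), cy + h / 2 - h * t])
            return np.vstack([top, right, bottom, left])
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        if self.shape == "ellipse":
            a, b = self.size_cm[0] / 2, self.size_cm[1] / 2
        else:
            a = b = self.size_cm[0]
        return np.column_stack([cx + a * np.cos(theta), cy + b * np.sin(theta)])

    @property
    def area_cm2(self) -> float:
        if self.shape == "rect":
            return self.size_cm[0] * self.size_cm[1]
        if self.shape == "ellipse":
            return np.pi * self.size_cm[0] * self.size_cm[1] / 4
        return np.pi * self.size_cm[0] ** 2

    @property
    def truth(self) -> dict[str, float]:
        """True trait values this single part supports, in reporting units."""
        if self.label == "crown":
            return {"CD": self.size_cm[0] * 10.0}  # mm
        if self.label == "leaf":
            ll = max(self.size_cm)
            lw = min(self.size_cm)
            return {"LA": self.area_cm2, "LL": ll, "LW": lw}
        if self.label == "flower":
            return {"FlA": self.area_cm2}
        if self.label == "fruit":
            return {"FrA": self.area_cm2}
        return {}


@dataclass(frozen=True)
class SceneSpec:
    image_size: tuple[int, int]  # (width, height) px
    pose: PoseParams
    parts: tuple[PartSpec, ...] = ()
    side_cm: float = DEFAULT_SIDE_CM
    truths: dict = field(default_factory=dict)  # scene-level trait truths
    seed: int | None = None

    def __post_init__(self):
        if not self.side_cm > 0:
            raise ValueError("side_cm must be positive")


@dataclass(frozen=True)
class GroundTruthPart:
    label: str
    box: tuple[float, float, float, float]  # sub-pixel tight (x0, y0, x1, y1)
    mask: Mask
    truth: dict[str, float]


@dataclass(frozen=True)
class GroundTruth:
    marker_corners: np.ndarray  # (4, 2) px, TL TR BR BL
    parts: tuple[GroundTruthPart, ...]
    truths: dict[str, float]
    side_cm: float = DEFAULT_SIDE_CM


def _mask_to_crop(mask_full: np.ndarray) -> Mask:
    rows, cols = np.nonzero(mask_full)
    x0, x1 = int(cols.min()), int(cols.max()) + 1
    y0, y1 = int(rows.min()), int(rows.max()) + 1
    return Mask(box=(x0, y0, x1, y1), bitmap=mask_full[y0:y1, x0:x1].copy())


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene and its ground truth.

    Deterministic for a given spec.  The fiducial's outer edges are
    anti-aliased by local supersampling so corner localization has sub-pixel
    information to work with; part edges are hard-thresholded (pixel center
    inside the shape), matching the ground-truth mask definition exactly.
    Raises :class:`PartOutOfFrame` when the marker or any part does not fit
    with a safety margin.
    """
    width, height = spec.image_size
    h_cm2px = pose_homography(spec.pose)
    h_px2cm = np.linalg.inv(h_cm2px)

    uu, vv = np.meshgrid(np.arange(width, dtype=float), np.arange(height, dtype=float))
    denom = h_px2cm[2, 0] * uu + h_px2cm[2, 1] * vv + h_px2cm[2, 2]
    x_cm = (h_px2cm[0, 0] * uu + h_px2cm[0, 1] * vv + h_px2cm[0, 2]) / denom
    y_cm = (h_px2cm[1, 0] * uu + h_px2cm[1, 1] * vv + h_px2cm[1, 2]) / denom

    img = np.empty((height, width, 3), dtype=np.uint8)
    img[:] = BACKGROUND

    s = spec.side_cm
    in_square = (x_cm >= 0) & (x_cm < s) & (y_cm >= 0) & (y_cm < s)
    in_cue = (
        (x_cm >= _CUE_LO) & (x_cm < _CUE_HI) & (y_cm >= _CUE_LO) & (y_cm < _CUE_HI)
    )
    img[in_square & ~in_cue] = MARKER_COLOR
    img[in_square & in_cue] = CUE_COLOR

    marker_corners = apply_homography(h_cm2px, marker_plane_corners(s))
    if (
        marker_corners.min() < 2
        or marker_corners[:, 0].max() > width - 3
        or marker_corners[:, 1].max() > height - 3
    ):
        raise PartOutOfFrame("fiducial marker does not fit in frame")

    gt_parts = []
    for part in spec.parts:
        mask_full = part.contains(x_cm, y_cm)
        if not mask_full.any():
            raise PartOutOfFrame(f"part {part.label!r} rendered empty")
        rows, cols = np.nonzero(mask_full)
        if (
            rows.min() == 0 or cols.min() == 0
            or rows.max() == height - 1 or cols.max() == width - 1
        ):
            raise PartOutOfFrame(f"part {part.label!r} touches the frame edge")
        color = part.color if part.color is not None else PALETTE[part.label]
        img[mask_full] = color
        boundary_px = apply_homography(h_cm2px, part.boundary_cm())
        box = (
            float(boundary_px[:, 0].min()),
            float(boundary_px[:, 1].min()),
            float(boundary_px[:, 0].max()),
            float(boundary_px[:, 1].max()),
        )
        gt_parts.append(
            GroundTruthPart(part.label, box, _mask_to_crop(mask_full), dict(part.truth))
        )

    _antialias_marker_edges(img, in_square, in_cue, h_px2cm, s)

    truths = dict(spec.truths)
    for part in spec.parts:
        for k, v in part.truth.items():
            truths.setdefault(k, v)
    gt = GroundTruth(
        marker_corners=marker_corners,
        parts=tuple(gt_parts),
        truths=truths,
        side_cm=s,
    )
    return img, gt


def _antialias_marker_edges(
    img: np.ndarray,
    in_square: np.ndarray,
    in_cue: np.ndarray,
    h_px2cm: np.ndarray,
    side_cm: float,
    sub: int = 8,
) -> None:
    """Blend pixels straddling the marker's outer boundary by supersampling."""
    body = in_square & ~in_cue
    band = ndimage.binary_dilation(in_square) & ~ndimage.binary_erosion(in_square)
    rows, cols = np.nonzero(band)
    if len(rows) == 0:
        return
    offsets = (np.arange(sub) + 0.5) / sub - 0.5
    du, dv = np.meshgrid(offsets, offsets)
    u = cols[:, None] + du.ravel()[None, :]
    v = rows[:, None] + dv.ravel()[None, :]
    denom = h_px2cm[2, 0] * u + h_px2cm[2, 1] * v + h_px2cm[2, 2]
    x = (h_px2cm[0, 0] * u + h_px2cm[0, 1] * v + h_px2cm[0, 2]) / denom
    y = (h_px2cm[1, 0] * u + h_px2cm[1, 1] * v + h_px2cm[1, 2]) / denom
    s = side_cm
    inside = (x >= 0) & (x < s) & (y >= 0) & (y < s)
    cue = (x >= _CUE_LO) & (x < _CUE_HI) & (y >= _CUE_LO) & (y < _CUE_HI)
    coverage = (inside & ~cue).mean(axis=1)
    blend = (
        (1 - coverage[:, None]) * np.array(BACKGROUND, float)
        + coverage[:, None] * np.array(MARKER_COLOR, float)
    )
    # only blend band pixels that are background or marker body (never parts)
    keep = (body | ~in_square)[rows, cols]
    img[rows[keep], cols[keep]] = np.clip(blend[keep] + 0.5, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# scene builders
# ---------------------------------------------------------------------------

def _content_bbox(parts, side_cm, margin=1.0):
    xs = [0.0, side_cm]
    ys = [0.0, side_cm]
    for p in parts:
        b = p.boundary_cm(n=64)
        xs += [b[:, 0].min(), b[:, 0].max()]
        ys += [b[:, 1].min(), b[:, 1].max()]
    return (min(xs) - margin, min(ys) - margin, max(xs) + margin, max(ys) + margin)


def _fitted_pose(
    parts,
    side_cm,
    image_size,
    rotation_deg,
    tilt_deg,
    tilt_azimuth_deg,
    distance_cm=100.0,
    pad=10.0,
    max_scale=None,
) -> PoseParams:
    """Choose a pixel scale that fits all content in frame under the pose."""
    x0, y0, x1, y1 = _content_bbox(parts, side_cm)
    width, height = image_size
    anchor = ((x0 + x1) / 2, (y0 + y1) / 2)
    scale = min((width - 2 * pad) / (x1 - x0), (height - 2 * pad) / (y1 - y0))
    if max_scale is not None:
        scale = min(scale, max_scale)
    t = np.linspace(0, 1, 16, endpoint=False)
    border = np.vstack([
        np.column_stack([x0 + (x1 - x0) * t, np.full_like(t, y0)]),
        np.column_stack([np.full_like(t, x1), y0 + (y1 - y0) * t]),
        np.column_stack([x1 - (x1 - x0) * t, np.full_like(t, y1)]),
        np.column_stack([np.full_like(t, x0), y1 - (y1 - y0) * t]),
    ])
    for _ in range(60):
        pose = PoseParams(
            scale_px_per_cm=scale,
            rotation_deg=rotation_deg,
            tilt_deg=tilt_deg,
            tilt_azimuth_deg=tilt_azimuth_deg,
            distance_cm=distance_cm,
            plane_anchor_cm=anchor,
            image_anchor_px=(width / 2, height / 2),
        )
        proj = apply_homography(pose_homography(pose), border)
        if (
            proj[:, 0].min() >= pad
            and proj[:, 0].max() <= width - pad
            and proj[:, 1].min() >= pad
            and proj[:, 1].max() <= height - pad
        ):
            return pose
        scale *= 0.92
    raise PartOutOfFrame("could not fit scene content in frame")


_TRAITS = ("CD", "PH", "PL", "LA", "LL", "LW", "FlA", "FrA")


def trait_scene(
    trait: str,
    rng: np.random.Generator,
    tilt_deg: float | None = None,
    tilt_azimuth_deg: float | None = None,
    rotation_deg: float = 0.0,
    n_fruits: int = 1,
) -> SceneSpec:
    """Randomized single-trait scene (marker beside the relevant part(s)).

    Part dimensions are drawn from ranges bracketing the magnitudes typical
    of field strawberries so recovered values are plausible.  The in-plane
    rotation defaults to 0 (upright camera), matching the assumption under
    which an axis-aligned crown box width equals the crown diameter.
    """
    if tilt_deg is None:
        tilt_deg = rng.uniform(0.0, 30.0)
    if tilt_azimuth_deg is None:
        tilt_azimuth_deg = rng.uniform(0.0, 360.0)
    side = DEFAULT_SIDE_CM
    truths: dict[str, float] = {}

    distance_cm = 100.0
    if trait == "CD":
        # Ellipse proxy for "the thickest part" of the crown: its projected
        # bounding box inflates far less under oblique tilt than a
        # rectangle's (no corners to stick out), keeping the box-width CD
        # semantics accurate across poses.  Larger camera distance damps
        # perspective variation across the small part.
        w = rng.uniform(1.2, 1.7)
        parts = [PartSpec("crown", "ellipse", (9.5, 2.5), (w, 0.4 * w))]
        image_size = (640, 480)
        distance_cm = 250.0
    elif trait in ("PH", "PL"):
        span = rng.uniform(18.0, 28.0) if trait == "PH" else rng.uniform(10.0, 18.0)
        dx = rng.uniform(-1.5, 1.5)
        labels = (
            ("plant_bottom", "plant_top") if trait == "PH"
            else ("petiole_bottom", "petiole_top")
        )
        e = 0.9  # endpoint square side (cm)
        distance_cm = 200.0  # damps Jacobian variation across the tall span
        # center the span on the marker height: calibration error grows with
        # plane distance from the marker, so keep the endpoints close
        bottom = (8.0, side / 2 + span / 2)
        top = (8.0 + dx, side / 2 - span / 2)
        parts = [
            PartSpec(labels[0], "rect", bottom, (e, e)),
            PartSpec(labels[1], "rect", top, (e, e)),
        ]
        truths[trait] = float(np.hypot(top[0] - bottom[0], top[1] - bottom[1]))
        image_size = (600, 900)
    elif trait in ("LA", "LL", "LW"):
        ll = rng.uniform(6.0, 8.0)
        lw = rng.uniform(4.5, min(6.0, ll - 0.2))
        parts = [PartSpec("leaf", "ellipse", (10.5, 3.2), (ll, lw))]
        image_size = (720, 480)
    elif trait == "FlA":
        r = rng.uniform(0.9, 1.2)
        parts = [PartSpec("flower", "disk", (9.0, 2.5), (r,))]
        image_size = (640, 480)
    elif trait == "FrA":
        parts = []
        for i in range(n_fruits):
            r = rng.uniform(1.2, 1.7)
            parts.append(PartSpec("fruit", "disk", (9.0 + 4.0 * i, 2.5), (r,)))
        image_size = (640 + 180 * (n_fruits - 1), 480)
    else:
        raise ValueError(f"unknown trait {trait!r}")

    pose = _fitted_pose(
        parts,
        side,
        image_size,
        rotation_deg=rotation_deg,
        tilt_deg=tilt_deg,
        tilt_azimuth_deg=tilt_azimuth_deg,
        distance_cm=distance_cm,
        max_scale=45.0,
    )
    return SceneSpec(
        image_size=image_size, pose=pose, parts=tuple(parts),
        side_cm=side, truths=truths,
    )


# ---------------------------------------------------------------------------
# tabular dataset generators
# ---------------------------------------------------------------------------

def generate_weight_dataset(
    n: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int | None = None,
    area_range: tuple[float, float] = (1.0, 14.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (fruit area cm^2, fresh weight g) samples on a known line."""
    rng = np.random.default_rng(seed)
    areas = rng.uniform(*area_range, size=n)
    weights = slope * areas + intercept + rng.normal(0.0, noise_sd, size=n)
    return areas, weights


def generate_validation_pairs(
    n: int,
    true_values,
    error_sd: float,
    dropout_rate: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Measured/predicted pairs with detection dropout.

    Each of the ``n`` attempts independently fails with probability
    ``dropout_rate`` (emulating a missed detection); surviving attempts pair
    the true value with a noisy prediction.  Returns
    ``(measured, predicted, attempts)`` with ``attempts == n``.
    """
    if not 0 <= dropout_rate <= 1:
        raise ValueError("dropout_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    true_values = np.asarray(true_values, dtype=float)
    if true_values.ndim == 0:
        true_values = np.full(n, float(true_values))
    if len(true_values) != n:
        raise ValueError("true_values must have length n")
    kept = rng.random(n) >= dropout_rate
    measured = true_values[kept]
    predicted = measured + rng.normal(0.0, error_sd, size=kept.sum())
    return measured, predicted, n


# ---------------------------------------------------------------------------
# ground-truth (de)serialization — JSON sidecar with run-length masks
# ---------------------------------------------------------------------------

def _rle_encode(bitmap: np.ndarray) -> list[int]:
    flat = np.asarray(bitmap, dtype=np.uint8).ravel()
    if len(flat) == 0:
        return []
    changes = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate([[0], changes, [len(flat)]]))
    counts = runs.tolist()
    if flat[0] == 1:  # RLE starts with a zero-run by convention
        counts = [0] + counts
    return counts


def _rle_decode(counts: list[int], shape: tuple[int, int]) -> np.ndarray:
    total = shape[0] * shape[1]
    flat = np.zeros(total, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    return flat.reshape(shape)


def ground_truth_to_json(gt: GroundTruth) -> str:
    parts = []
    for p in gt.parts:
        parts.append({
            "label": p.label,
            "box": list(p.box),
            "mask_box": list(p.mask.box),
            "mask_rle": _rle_encode(p.mask.bitmap),
            "truth": p.truth,
        })
    return json.dumps({
        "marker_corners": gt.marker_corners.tolist(),
        "side_cm": gt.side_cm,
        "truths": gt.truths,
        "parts": parts,
    })


def ground_truth_from_json(text: str) -> GroundTruth:
    payload = json.loads(text)
    parts = []
    for p in payload["parts"]:
        x0, y0, x1, y1 = [int(v) for v in p["mask_box"]]
        bitmap = _rle_decode(p["mask_rle"], (y1 - y0, x1 - x0))
        parts.append(GroundTruthPart(
            label=p["label"],
            box=tuple(p["box"]),
            mask=Mask(box=(x0, y0, x1, y1), bitmap=bitmap),
            truth=dict(p["truth"]),
        ))
    return GroundTruth(
        marker_corners=np.asarray(payload["marker_corners"], float),
        parts=tuple(parts),
        truths=dict(payload["truths"]),
        side_cm=float(payload["side_cm"]),
    )
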