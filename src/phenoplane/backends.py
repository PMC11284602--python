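"""Pluggable detection/segmentation backends.

The measurement pipeline only depends on the small contract defined here:
``detect(image, wanted_labels) -> [Detection]`` and
``segment(image, detection) -> Mask``.  Two desk-scale backends are
provided: an *oracle* that returns generator ground truth verbatim
(isolating the geometry pipeline from detector error) and a *classical*
backend that finds colour-coded proxy regions by thresholding and connected
components.  A learned-model backend can be slotted in behind the same
contract without touching the trait code.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import BoxOutOfBounds

LABELS = frozenset({
    "crown", "plant_top", "plant_bottom", "petiole_top", "petiole_bottom",
    "leaf", "flower", "fruit", "marker",
})

# endpoint labels that share one appearance and are told apart by position
_PAIRED = {
    "plant_top": ("plant_top", "plant_bottom"),
    "plant_bottom": ("plant_top", "plant_bottom"),
    "petiole_top": ("petiole_top", "petiole_bottom"),
    "petiole_bottom": ("petiole_top", "petiole_bottom"),
}

__all__ = ["LABELS", "Detection", "Mask", "DetectionBackend",
           "OracleBackend", "ClassicalBackend", "get_backend"]


@dataclass(frozen=True)
class Detection:
    """Class-labelled axis-aligned box in pixels, half-open, sub-pixel allowed."""

    label: str
    box: tuple[float, float, float, float]  # (x0, y0, x1, y1)
    confidence: float = 1.0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        x0, y0, x1, y1 = self.box
        if not (x1 > x0 and y1 > y0):
            raise ValueError("box must have positive area")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.box
        return ((x0 + x1) / 2, (y0 + y1) / 2)

    @property
    def width(self) -> float:
        return self.box[2] - self.box[0]

    @property
    def height(self) -> float:
        return self.box[3] - self.box[1]


@dataclass(frozen=True)
class Mask:
    """Binary raster registered to an integer pixel crop ``box``."""

    box: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    bitmap: np.ndarray

    def __post_init__(self):
        x0, y0, x1, y1 = self.box
        bitmap = np.asarray(self.bitmap, dtype=bool)
        if bitmap.shape != (y1 - y0, x1 - x0):
            raise ValueError("bitmap dimensions must equal box dimensions")
        object.__setattr__(self, "bitmap", bitmap)
        object.__setattr__(self, "box", (int(x0), int(y0), int(x1), int(y1)))

    @property
    def origin(self) -> tuple[int, int]:
        return (self.box[0], self.box[1])


def _check_box_in_image(box, image_shape) -> None:
    h, w = image_shape[:2]
    x0, y0, x1, y1 = box
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise BoxOutOfBounds(f"box {box} outside image {w}x{h}")


class DetectionBackend(ABC):
    """Contract shared by all detection/segmentation backends."""

    name = "abstract"

    @abstractmethod
    def detect(self, image, wanted_labels) -> list[Detection]:
        """Detections per wanted label, sorted by descending confidence.

        Absence of a label yields an empty list (never an error); this feeds
        the detection-frequency statistic downstream.
        """

    @abstractmethod
    def segment(self, image, detection: Detection) -> Mask:
        """Binary mask over the detection crop."""


class OracleBackend(DetectionBackend):
    """Returns the synthetic generator's ground truth verbatim."""

    name = "oracle"

    def __init__(self, ground_truth):
        self.ground_truth = ground_truth

    def detect(self, image, wanted_labels) -> list[Detection]:
        wanted = set(wanted_labels)
        out = [
            Detection(label=p.label, box=p.box, confidence=1.0)
            for p in self.ground_truth.parts
            if p.label in wanted
        ]
        return out  # all confidence 1.0; generator order is stable

    def segment(self, image, detection: Detection) -> Mask:
        _check_box_in_image(detection.box, np.asarray(image).shape)
        for p in self.ground_truth.parts:
            if p.label == detection.label and np.allclose(p.box, detection.box):
                return p.mask
        raise ValueError("detection does not correspond to a ground-truth part")


@dataclass(frozen=True)
class ClassicalConfig:
    """Colour thresholds for the classical backend."""

    palette: dict
    color_tolerance: int = 40
    dark_threshold: int = 60
    min_area: int = 25


def _default_config() -> ClassicalConfig:
    from .synthetic_scenes import PALETTE  # deferred: avoids import cycle

    return ClassicalConfig(palette=dict(PALETTE))


class ClassicalBackend(DetectionBackend):
    """Colour-threshold + connected-component stand-in detector.

    Endpoint pairs (plant/petiole top and bottom) share one colour; the two
    components are disambiguated by vertical image position, top = smaller
    row.  The ``marker`` label is matched by darkness rather than colour.
    """

    name = "classical"

    def __init__(self, config: ClassicalConfig | None = None):
        self.config = config if config is not None else _default_config()

    def _color_mask(self, image: np.ndarray, label: str) -> np.ndarray:
        if label == "marker":
            gray = image.mean(axis=2)
            return gray < self.config.dark_threshold
        color = np.asarray(self.config.palette[label], dtype=np.int16)
        diff = np.abs(image.astype(np.int16) - color)
        return (diff <= self.config.color_tolerance).all(axis=2)

    def _components(self, mask: np.ndarray):
        labels, n = ndimage.label(mask)
        comps = []
        for idx in range(1, n + 1):
            rows, cols = np.nonzero(labels == idx)
            if len(rows) < self.config.min_area:
                continue
            box = (int(cols.min()), int(rows.min()),
                   int(cols.max()) + 1, int(rows.max()) + 1)
            fill = len(rows) / ((box[2] - box[0]) * (box[3] - box[1]))
            comps.append((box, float(rows.mean()), min(1.0, fill)))
        return comps

    def detect(self, image, wanted_labels) -> list[Detection]:
        image = np.asarray(image)
        wanted = list(dict.fromkeys(wanted_labels))
        out: list[Detection] = []
        done_pairs = set()
        for label in wanted:
            if label in _PAIRED:
                pair = _PAIRED[label]
                if pair in done_pairs:
                    continue
                done_pairs.add(pair)
                comps = sorted(self._components(self._color_mask(image, label)),
                               key=lambda c: c[1])  # by centroid row
                if not comps:
                    continue
                top_label, bottom_label = pair
                if top_label in wanted:
                    out.append(Detection(top_label, comps[0][0], comps[0][2]))
                if bottom_label in wanted:
                    out.append(Detection(bottom_label, comps[-1][0], comps[-1][2]))
            else:
                for box, _, conf in self._components(self._color_mask(image, label)):
                    out.append(Detection(label, box, conf))
        return sorted(out, key=lambda d: -d.confidence)

    def segment(self, image, detection: Detection) -> Mask:
        image = np.asarray(image)
        _check_box_in_image(detection.box, image.shape)
        x0, y0, x1, y1 = [int(round(v)) for v in detection.box]
        crop = image[y0:y1, x0:x1]
        bitmap = self._color_mask(crop, detection.label)
        return Mask(box=(x0, y0, x1, y1), bitmap=bitmap)


def get_backend(name: str, ground_truth=None, config=None) -> DetectionBackend:
    """Backend factory used by the CLI (``--backend oracle|classical``)."""
    if name == "oracle":
        if ground_truth is None:
            raise ValueError("oracle backend requires ground truth")
        return OracleBackend(ground_truth)
    if name == "classical":
        return ClassicalBackend(config)
    raise ValueError(f"unknown backend {name!r}")
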