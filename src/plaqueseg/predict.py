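"""Inference and contour overlay.

One trained binary model per plaque class is run on the same image; each
softmax foreground probability map is thresholded (default 0.5) into a
mask — all-zero ("all-black") when that plaque type is absent.  Closed
contours are traced around every 8-connected component of each mask and
drawn over the original image in the class colours red (calcified),
blue (fibrous) and yellow (lipid); pixels off all contours are untouched.

Contours come from border-following on the binary mask itself, not from
gradient edge detection on the grayscale image: the model output is
already a segmentation, so its component boundaries are the plaque
outlines.  Components below ``min_area`` pixels are treated as speckle
and dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure, morphology
from skimage.draw import line as _draw_line

from .network import DACNet
from .phantom import PLAQUE_CLASSES

__all__ = ["ClassPrediction", "OverlaySpec", "predict_class",
           "extract_contours", "overlay", "predict_and_overlay",
           "contours_to_json"]

DEFAULT_MIN_AREA = 10

# draw priority: calcified over fibrous over lipid where contours overlap
_DRAW_ORDER = ("lipid", "fibrous", "calcified")


@dataclass
class ClassPrediction:
    """Thresholded output of one per-class model on one image."""

    plaque_class: str
    probability: np.ndarray          # (H, W) in [0, 1]
    mask: np.ndarray                 # (H, W) uint8, small components removed
    present: bool


@dataclass
class OverlaySpec:
    """Contour colours (RGB, 0-255) and line thickness in pixels."""

    colors: dict[str, tuple[int, int, int]] = field(default_factory=lambda: {
        "calcified": (255, 0, 0),
        "fibrous": (0, 0, 255),
        "lipid": (255, 255, 0),
    })
    thickness: int = 2

    def __post_init__(self):
        if len(set(self.colors.values())) != len(self.colors):
            raise ValueError("class colours must be distinct")


def predict_class(model: DACNet, image: np.ndarray, threshold: float = 0.5,
                  min_area: int = DEFAULT_MIN_AREA,
                  plaque_class: str = "") -> ClassPrediction:
    """Run one binary model on an (H, W, 3) image in [0, 1].

    ``present`` is False — and the mask all-black — when no surviving
    component reaches ``min_area`` pixels.
    """
    h, w = image.shape[:2]
    if h != w or h % (2 ** model.config.depth) != 0 or \
            image.shape[2] != model.config.input_channels:
        raise ValueError(
            f"image {image.shape} incompatible with model config "
            f"(depth {model.config.depth}, {model.config.input_channels} channels)")
    prob = model.predict_proba(image.transpose(2, 0, 1)[None])[0]
    mask = prob >= threshold
    if min_area > 1:
        # drop components strictly smaller than min_area
        mask = morphology.remove_small_objects(mask, max_size=min_area - 1,
                                               connectivity=2)
    return ClassPrediction(plaque_class=plaque_class, probability=prob,
                           mask=mask.astype(np.uint8), present=bool(mask.any()))


def extract_contours(mask: np.ndarray,
                     min_area: int = DEFAULT_MIN_AREA) -> list[np.ndarray]:
    """Closed boundary polygons of every 8-connected foreground component.

    Returns one (M, 2) float array of (x, y) pixel coordinates per
    component (x rightward, y downward), first point repeated last.
    Components under ``min_area`` pixels are dropped.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    polygons = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        comp = np.pad(labels == region.label, 1).astype(float)
        rings = measure.find_contours(comp, 0.5)
        ring = max(rings, key=len)                 # outer boundary
        ring = ring - 1.0                          # undo the padding offset
        polygons.append(ring[:, ::-1].copy())      # (row, col) -> (x, y)
    return polygons


def _draw_polyline(canvas: np.ndarray, poly: np.ndarray) -> None:
    pts = np.round(poly).astype(int)
    h, w = canvas.shape
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        canvas[rr[keep], cc[keep]] = True


def overlay(image: np.ndarray, predictions: dict[str, ClassPrediction],
            spec: OverlaySpec | None = None,
            min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Draw class-coloured contours over a copy of ``image`` (uint8 RGB out).

    Pixels off every contour keep their input value.  Where contours of
    two classes overlap, calcified is drawn over fibrous over lipid.
    """
    spec = spec or OverlaySpec()
    if image.dtype != np.uint8:
        out = np.round(np.clip(image, 0.0, 1.0) * 255.0).astype(np.uint8)
    else:
        out = image.copy()
    if out.ndim == 2:
        out = np.repeat(out[:, :, None], 3, axis=2)
    h, w = out.shape[:2]
    footprint = morphology.disk(max(spec.thickness // 2, 0))
    for cls in _DRAW_ORDER:
        pred = predictions.get(cls)
        if pred is None or not pred.present:
            continue
        if pred.mask.shape != (h, w):
            raise ValueError(f"mask of {cls!r} does not match the image size")
        canvas = np.zeros((h, w), bool)
        for poly in extract_contours(pred.mask, min_area):
            _draw_polyline(canvas, poly)
        if spec.thickness > 1:
            canvas = morphology.dilation(canvas, footprint)
        out[canvas] = spec.colors[cls]
    return out


def predict_and_overlay(models: dict[str, DACNet], image: np.ndarray,
                        threshold: float = 0.5,
                        min_area: int = DEFAULT_MIN_AREA,
                        spec: OverlaySpec | None = None
                        ) -> tuple[np.ndarray, dict[str, ClassPrediction]]:
    """Run all per-class models on one image and render the overlay."""
    preds = {cls: predict_class(model, image, threshold, min_area, cls)
             for cls, model in models.items()}
    return overlay(image, preds, spec, min_area), preds


def contours_to_json(predictions: dict[str, ClassPrediction], path,
                     min_area: int = DEFAULT_MIN_AREA) -> None:
    """Export per-class contour polygons as JSON lists of [x, y] points."""
    payload = {cls: [np.round(poly, 2).tolist()
                     for poly in extract_contours(p.mask, min_area)]
               for cls, p in predictions.items()}
    Path(path).write_text(json.dumps(payload))
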