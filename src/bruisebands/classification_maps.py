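"""Per-pixel bruise maps, morphological cleanup and apple-level scoring.

The workflow mirrors a practical sorting line: the background is masked on
the 553.9 nm band, a trained classifier labels only the apple pixels, the
binary map is cleaned by morphological opening then closing (removing
scattered false-positive pixels and filling small holes), positives are
painted red on the grayscale reference band for inspection, and an apple is
declared bruised when its largest connected positive component reaches a
minimum area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing, binary_fill_holes, binary_opening
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

__all__ = [
    "ClassificationMap",
    "DetectionReport",
    "mask_background",
    "classify_pixels",
    "clean_map",
    "render_overlay",
    "apple_decision",
    "score_map",
]


@dataclass(frozen=True)
class ClassificationMap:
    raw_map: np.ndarray      # bool, positives before morphology
    cleaned: np.ndarray      # bool, positives after open-close
    apple_mask: np.ndarray   # bool
    band_centers_nm: tuple[float, ...]


@dataclass(frozen=True)
class DetectionReport:
    decisions: list[bool]          # per apple: True = bruised
    truths: list[bool]
    pixel_confusion: np.ndarray    # 2x2 [[tn, fp], [fn, tp]] pooled over apples
    false_positive_pixels: int     # cleaned positives outside true bruises

    @property
    def apple_accuracy(self) -> float:
        d, t = np.asarray(self.decisions), np.asarray(self.truths)
        return float(np.mean(d == t))

    @property
    def pixel_accuracy(self) -> float:
        c = self.pixel_confusion
        return float((c[0, 0] + c[1, 1]) / c.sum())


def mask_background(band_image: np.ndarray) -> np.ndarray:
    """Apple mask from the 553.9 nm band: Otsu threshold, largest blob, holes filled."""
    img = np.asarray(band_image, dtype=float)
    thr = threshold_otsu(img)
    mask = img > thr
    if not mask.any():
        raise ValueError("background masking produced an empty apple mask")
    lab = cc_label(mask)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return binary_fill_holes(lab == largest)


def classify_pixels(multispectral: np.ndarray, model, apple_mask: np.ndarray,
                    band_centers_nm: tuple[float, ...],
                    model_bands_nm: tuple[float, ...] | None = None) -> ClassificationMap:
    """Apply a trained bruise/sound model to the apple pixels only.

    ``multispectral`` is (lines, samples, n_bands); ``model`` must have been
    trained on features in the same band order (checked against
    ``model_bands_nm`` when provided).
    """
    if multispectral.shape[2] != len(band_centers_nm):
        raise ValueError("band-center list does not match image depth")
    if model_bands_nm is not None and tuple(model_bands_nm) != tuple(band_centers_nm):
        raise ValueError("image bands do not match the model's training bands")
    apple_mask = np.asarray(apple_mask, dtype=bool)
    X = multispectral[apple_mask]
    pred = np.asarray(model.predict(X))
    raw = np.zeros(apple_mask.shape, dtype=bool)
    raw[apple_mask] = pred == "bruise"
    return ClassificationMap(raw, raw.copy(), apple_mask, tuple(band_centers_nm))


def clean_map(cmap: ClassificationMap, opening_radius: int = 1,
              closing_radius: int = 1) -> ClassificationMap:
    """Morphological opening then closing with disk structuring elements."""
    if opening_radius < 1 or closing_radius < 1:
        raise ValueError("structuring-element radii must be >= 1 pixel")
    cleaned = binary_opening(cmap.raw_map, structure=disk(opening_radius))
    cleaned = binary_closing(cleaned, structure=disk(closing_radius))
    cleaned &= cmap.apple_mask
    return ClassificationMap(cmap.raw_map, cleaned, cmap.apple_mask,
                             cmap.band_centers_nm)


def render_overlay(band_image: np.ndarray, cleaned: np.ndarray) -> np.ndarray:
    """Grayscale reference band with bruise positives painted pure red.

    Grayscale levels are compressed to 0..254 so that pure red (255, 0, 0)
    appears only at positives and the mask round-trips exactly from the
    overlay.
    """
    if band_image.shape != cleaned.shape:
        raise ValueError("image and map shapes differ")
    img = np.asarray(band_image, dtype=float)
    lo, hi = img.min(), img.max()
    gray = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo) * 254.0
    gray = gray.astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    rgb[cleaned] = (255, 0, 0)
    return rgb


def recover_mask(overlay: np.ndarray) -> np.ndarray:
    """Positives back out of an overlay (exact inverse of render_overlay)."""
    return (overlay[..., 0] == 255) & (overlay[..., 1] == 0) & (overlay[..., 2] == 0)


def apple_decision(cleaned: np.ndarray, min_area: int = 10) -> bool:
    """Bruised iff the largest connected positive component has >= min_area pixels."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if not cleaned.any():
        return False
    lab = cc_label(cleaned)
    return int(np.bincount(lab.ravel())[1:].max()) >= min_area


def score_map(cmap: ClassificationMap, truth_bruise: np.ndarray) -> dict:
    """Pixel confusion (apple pixels only) and false-positive count of one map."""
    m = cmap.apple_mask
    pred = cmap.cleaned[m]
    true = np.asarray(truth_bruise, dtype=bool)[m]
    tp = int(np.sum(pred & true))
    tn = int(np.sum(~pred & ~true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    return {"confusion": np.array([[tn, fp], [fn, tp]]), "false_positives": fp}
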