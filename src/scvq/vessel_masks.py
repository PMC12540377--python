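"""Vessel masks for MinIP slabs: annotation rasterization, a classical baseline
segmenter, mask evaluation and overlay rendering.

The trained semantic-segmentation model that produced the study-grade masks is
external to this package; its interface — a binary mask aligned to a slab — is the
contract here.  Masks can be ingested from polygon annotations (Labelme dialect),
from mask images, or produced by :func:`baseline_segment`, a classical
dark-threshold segmenter useful on phantoms and as a fallback.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import measure, morphology

from .io_minip import MinipSlab

__all__ = [
    "VesselMask",
    "SegmentationEval",
    "rasterize_annotation",
    "load_labelme",
    "baseline_segment",
    "evaluate_mask",
    "overlay",
]


class MaskAlignmentError(ValueError):
    """Two rasters that must share a shape do not."""


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel raster aligned to one MinIP slab; 8-connected foreground."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (0.8, 0.8)
    provenance: str = "annotation"  # annotation | model | baseline

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels)
        if pix.ndim != 2:
            raise ValueError("mask must be 2D")
        if not np.isin(pix, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        object.__setattr__(self, "pixels", pix.astype(bool))
        object.__setattr__(
            self, "pixel_spacing_mm", tuple(float(s) for s in self.pixel_spacing_mm)
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SegmentationEval:
    pixel_accuracy: float
    dice: float
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.pixel_accuracy <= 1.0
        assert 0.0 <= self.dice <= 1.0


def _points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd inclusion of pixel centers in a closed polygon, boundary inclusive.

    ``points`` are (x, y) pixel-center coordinates, ``vertices`` the polygon's
    (x, y) vertices.  A point on an edge counts as inside.
    """
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    on_edge = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # even-odd ray cast (ray toward +x)
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, x_int, np.inf))
        # boundary test: distance from point to the segment
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        if seg_len2 == 0:
            dist2 = (x - x1) ** 2 + (y - y1) ** 2
        else:
            t = np.clip(((x - x1) * dx + (y - y1) * dy) / seg_len2, 0.0, 1.0)
            dist2 = (x - (x1 + t * dx)) ** 2 + (y - (y1 + t * dy)) ** 2
        on_edge |= dist2 <= 1e-18
    return inside | on_edge


def rasterize_annotation(
    polygons: list[np.ndarray] | list[list],
    image_shape: tuple[int, int],
    spacing: tuple[float, float] = (0.8, 0.8),
) -> VesselMask:
    """Fill polygon annotations into a binary mask.

    Each polygon is a sequence of (x, y) vertices in pixel coordinates
    (x = column, the Labelme convention).  Each polygon is filled by the
    even-odd rule with pixel-center inclusion (boundary pixels included);
    polygons are unioned.  Degenerate polygons (< 3 vertices) are skipped
    with a warning.
    """
    h, w = image_shape
    mask = np.zeros((h, w), dtype=bool)
    for poly in polygons:
        verts = np.asarray(poly, dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3:
            warnings.warn("skipping degenerate polygon (< 3 vertices)", stacklevel=2)
            continue
        c0 = int(np.clip(np.floor(verts[:, 0].min()), 0, w - 1))
        c1 = int(np.clip(np.ceil(verts[:, 0].max()), 0, w - 1))
        r0 = int(np.clip(np.floor(verts[:, 1].min()), 0, h - 1))
        r1 = int(np.clip(np.ceil(verts[:, 1].max()), 0, h - 1))
        cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
        pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
        hit = _points_in_polygon(pts, verts)
        mask[rows.ravel()[hit], cols.ravel()[hit]] = True
    return VesselMask(pixels=mask, pixel_spacing_mm=spacing, provenance="annotation")


def load_labelme(
    path: str | Path, image_shape: tuple[int, int] | None = None,
    spacing: tuple[float, float] = (0.8, 0.8),
) -> VesselMask:
    """Read a Labelme-dialect JSON annotation and rasterize its polygon shapes."""
    with open(path) as fh:
        doc = json.load(fh)
    if image_shape is None:
        image_shape = (int(doc["imageHeight"]), int(doc["imageWidth"]))
    polys = [
        s["points"] for s in doc.get("shapes", [])
        if s.get("shape_type", "polygon") == "polygon"
    ]
    return rasterize_annotation(polys, image_shape, spacing)


def baseline_segment(
    slab: MinipSlab,
    threshold_percentile: float = 10.0,
    min_object_px: int = 20,
) -> VesselMask:
    """Segment dark tubular structures by intensity percentile.

    Foreground is every pixel *strictly* darker than the given within-image
    intensity percentile (veins are hypointense on SWI), after removing
    8-connected objects smaller than ``min_object_px``.  Deterministic for
    fixed parameters; a uniform slab yields an empty mask.
    """
    if not slab.windowed:
        raise RuntimeError("baseline_segment expects a windowed slab")
    if not 0.0 < threshold_percentile < 100.0:
        raise ValueError("threshold_percentile must lie in (0, 100)")
    thr = np.percentile(slab.pixels, threshold_percentile)
    fg = slab.pixels < thr
    # objects strictly smaller than min_object_px are removed
    fg = morphology.remove_small_objects(fg, max_size=min_object_px - 1, connectivity=2)
    return VesselMask(
        pixels=fg, pixel_spacing_mm=slab.pixel_spacing_mm, provenance="baseline"
    )


def evaluate_mask(predicted: VesselMask, truth: VesselMask) -> SegmentationEval:
    """Pixel accuracy and Dice of a predicted mask against a reference mask.

    Dice of two empty masks is defined as 1.  Pixel accuracy is inflated by
    background on sparse vessel images, which is why Dice is reported alongside.
    """
    if predicted.shape != truth.shape:
        raise MaskAlignmentError(
            f"shape mismatch {predicted.shape} vs {truth.shape}"
        )
    p, t = predicted.pixels, truth.pixels
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    total = tp + fp + fn + tn
    acc = (tp + tn) / total
    denom = 2 * tp + fp + fn
    dice = 1.0 if denom == 0 else 2 * tp / denom
    return SegmentationEval(pixel_accuracy=acc, dice=dice, tp=tp, fp=fp, tn=tn, fn=fn)


def overlay(
    slab: MinipSlab,
    mask: VesselMask,
    color: tuple[int, int, int] = (255, 0, 0),
    alpha: float = 1.0,
) -> np.ndarray:
    """Superimpose a mask on a grayscale slab; returns an (H, W, 3) uint8 image."""
    if slab.pixels.shape != mask.shape:
        raise MaskAlignmentError(
            f"shape mismatch {slab.pixels.shape} vs {mask.shape}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    gray = slab.pixels.astype(float)
    rgb = np.stack([gray] * 3, axis=-1)
    col = np.asarray(color, dtype=float)
    rgb[mask.pixels] = (1.0 - alpha) * rgb[mask.pixels] + alpha * col
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def mask_components(mask: VesselMask) -> np.ndarray:
    """Label 8-connected components of a mask (shared connectivity convention)."""
    return measure.label(mask.pixels, connectivity=2)
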