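"""Four-step top-view vision workflow.

(i) detect the calibrated region of interest (the black reference
floor), (ii) segment the bird inside it, (iii) count foreground pixels,
(iv) export QC overlays; plus replicate averaging.

Floor detection thresholds at a fixed low intensity (default < 60/255)
and fits the minimum-area quadrilateral of the largest dark component.
Bird/floor separation uses Otsu's threshold computed within the ROI,
followed by 3x3 opening and closing, largest-component selection and
hole filling. Coordinates are 0-based (row, col); masks are boolean in
memory and 0/255 on disk.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon
from skimage import draw as skdraw
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "FloorNotFoundError",
    "NoBirdError",
    "SegmentationResult",
    "ReplicateSet",
    "detect_roi",
    "segment_bird",
    "average_replicates",
    "export_overlay",
]

FLOOR_ASPECT = 600.0 / 400.0
MIN_BIRD_PX = 50


class FloorNotFoundError(RuntimeError):
    pass


class NoBirdError(RuntimeError):
    pass


@dataclass
class SegmentationResult:
    roi: np.ndarray  # (4, 2) corner array, (row, col)
    mask: np.ndarray  # boolean foreground raster, image-sized
    pixel_count: int
    overlay_path: Optional[str] = None
    flags: list[str] = field(default_factory=list)


@dataclass
class ReplicateSet:
    bird_id: str
    day: int
    counts: list[float]
    mean_count: float
    cv: float
    flags: list[str] = field(default_factory=list)


def _to_gray(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(float)


def detect_roi(image: np.ndarray, floor_threshold: float = 60.0) -> np.ndarray:
    """Locate the black reference floor; returns its 4 corners (row, col).

    Thresholds at ``floor_threshold``, keeps the largest dark connected
    component and fits its minimum-area rotated rectangle. Raises
    ``FloorNotFoundError`` if no dark region covers >= 20% of the frame.
    An aspect ratio deviating more than 25% from 600:400 is tolerated
    but reported via a warning printed into the corner array's companion
    flag (see ``segment_bird`` callers); here we only validate size.
    """
    gray = _to_gray(image)
    dark = gray < floor_threshold
    if dark.sum() < 0.2 * dark.size:
        raise FloorNotFoundError(
            f"floor not found: dark pixels cover {dark.sum() / dark.size:.1%} "
            "of the frame (< 20%)"
        )
    labels = measure.label(dark)
    props = measure.regionprops(labels)
    largest = max(props, key=lambda p: p.area)
    if largest.area < 0.2 * dark.size:
        raise FloorNotFoundError("floor not found: largest dark component < 20% of frame")
    comp = labels == largest.label
    boundary = comp & ~ndimage.binary_erosion(comp)
    coords = np.argwhere(boundary)  # (row, col)
    hull = MultiPoint([(c, r) for r, c in coords])
    rect = hull.convex_hull.minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4]
    return np.column_stack([xy[:, 1], xy[:, 0]])  # back to (row, col)


def roi_aspect_flag(roi: np.ndarray) -> Optional[str]:
    """Warning string when the quad's aspect ratio strays >25% from 3:2."""
    sides = np.linalg.norm(np.diff(np.vstack([roi, roi[:1]]), axis=0), axis=1)
    long_side = (sides[0] + sides[2]) / 2.0
    short_side = (sides[1] + sides[3]) / 2.0
    if short_side == 0:
        return "degenerate_roi"
    ratio = max(long_side, short_side) / min(long_side, short_side)
    if abs(ratio - FLOOR_ASPECT) / FLOOR_ASPECT > 0.25:
        return f"roi_aspect_{ratio:.2f}"
    return None


def _roi_mask(shape: tuple[int, int], roi: np.ndarray) -> np.ndarray:
    rr, cc = skdraw.polygon(roi[:, 0], roi[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def segment_bird(
    image: np.ndarray,
    roi: np.ndarray,
    min_pixels: int = MIN_BIRD_PX,
    footprint: Optional[np.ndarray] = None,
) -> SegmentationResult:
    """Segment the bird within the ROI and count its pixels.

    Otsu threshold inside the ROI (bird lighter than the black floor),
    3x3 opening then closing, largest connected component, hole fill.
    Raises ``NoBirdError`` when the largest component is < ``min_pixels``;
    flags (not errors) border contact and odd ROI aspect ratios.
    """
    gray = _to_gray(image)
    inside = _roi_mask(gray.shape, roi)
    if not inside.any():
        raise ValueError("empty ROI")
    flags: list[str] = []
    aspect = roi_aspect_flag(roi)
    if aspect:
        flags.append(aspect)

    vals = gray[inside]
    if vals.max() == vals.min():
        raise NoBirdError("no bird detected: ROI has uniform intensity")
    thresh = threshold_otsu(vals)
    fg = inside & (gray > thresh)

    fp = footprint if footprint is not None else np.ones((3, 3), dtype=bool)
    fg = morphology.opening(fg, fp)
    fg = morphology.closing(fg, fp)
    labels = measure.label(fg)
    if labels.max() == 0:
        raise NoBirdError("no bird detected: no foreground after cleanup")
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_pixels:
        raise NoBirdError(
            f"no bird detected: largest component {sizes[best - 1]} px < {min_pixels}"
        )
    comp = labels == best
    comp = ndimage.binary_fill_holes(comp)
    comp &= inside  # mask nonzero only inside roi

    interior = ndimage.binary_erosion(inside, np.ones((3, 3), dtype=bool))
    if np.any(comp & ~interior):
        flags.append("roi_border_contact")

    return SegmentationResult(
        roi=np.asarray(roi, dtype=float),
        mask=comp,
        pixel_count=int(comp.sum()),
        flags=flags,
    )


def average_replicates(
    results: Sequence[SegmentationResult],
    bird_id: str = "",
    day: int = 0,
    cv_warn: float = 0.10,
) -> ReplicateSet:
    """Arithmetic mean of replicate pixel counts; flags dispersion > 10%."""
    if not results:
        raise ValueError("need at least one segmentation result")
    counts = [float(r.pixel_count) for r in results]
    mean = float(np.mean(counts))
    cv = float(np.std(counts) / mean) if mean > 0 else 0.0
    flags = [f for r in results for f in r.flags]
    if cv > cv_warn:
        flags.append(f"replicate_cv_{cv:.3f}")
    return ReplicateSet(bird_id=bird_id, day=day, counts=counts, mean_count=mean, cv=cv, flags=flags)


def export_overlay(
    image: np.ndarray,
    result: SegmentationResult,
    out_dir: str,
    bird_id: str,
    day: int,
    replicate: int,
) -> str:
    """Burn ROI outline and mask contour into the image and save as PNG.

    Deterministic naming: ``<bird>_<day>_<rep>.overlay.png``. Flag text,
    if any, is annotated in the top-left corner. Returns the path.
    """
    os.makedirs(out_dir, exist_ok=True)
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    pil = Image.fromarray(arr.astype(np.uint8))
    dr = ImageDraw.Draw(pil)
    poly = [(float(c), float(r)) for r, c in result.roi]
    dr.polygon(poly, outline=(255, 0, 0), width=2)
    for contour in measure.find_contours(result.mask.astype(float), 0.5):
        dr.line([(c, r) for r, c in contour], fill=(0, 255, 0), width=1)
    if result.flags:
        dr.text((5, 5), "; ".join(result.flags), fill=(255, 255, 0))
    path = os.path.join(out_dir, f"{bird_id}_{day}_{replicate}.overlay.png")
    pil.save(path)
    result.overlay_path = path
    return path


def mask_to_png(mask: np.ndarray, path: str) -> None:
    """Write a boolean mask as single-channel 0/255 PNG."""
    Image.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(path)
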