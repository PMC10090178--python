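"""Preprocessing: raw slides + ROI polygons -> inverted 8-bit partitions.

The pipeline order is fixed and deterministic: 8-bit grayscale conversion,
bounding-box crop with polygon rasterization, inversion (stained somata
become bright), then percentile-based auto-contrast. All statistics are
mask-aware: pixels outside the partition polygon carry fill value 0 on the
inverted image and are never read downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

__all__ = [
    "RawSlide",
    "PartitionImage",
    "SUBREGION_LABELS",
    "to_8bit_gray",
    "invert",
    "autocontrast",
    "crop_partition",
    "preprocess_rendered",
]

#: hippocampal subregion labels (lateral + uncal)
SUBREGION_LABELS = ("CA1", "CA1u", "CA2", "CA2u", "CA3", "CA3u", "CA4", "Sub", "Subu")

# Rec.601 luma weights for RGB collapse
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class RawSlide:
    """A digitized slide: 8/16-bit grayscale or RGB image with pixel size."""

    image: np.ndarray
    pixel_size_um: float = 0.75
    case: str | None = None
    level: str | None = None

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class PartitionImage:
    """Preprocessed, inverted 8-bit view of one subregion's pyramidal layer."""

    image: np.ndarray  # uint8, inverted, 0 outside valid_mask
    valid_mask: np.ndarray  # bool, polygon interior
    polygon: np.ndarray  # (n, 2) vertices in (row, col), crop coordinates
    label: str = "CA1"
    pixel_size_um: float = 0.75
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.dtype != np.uint8:
            raise ValueError("partition image must be 8-bit")
        if self.image.shape != self.valid_mask.shape:
            raise ValueError("image / valid_mask shape mismatch")

    def valid_pixels(self) -> np.ndarray:
        return self.image[self.valid_mask]


def to_8bit_gray(image: np.ndarray) -> np.ndarray:
    """Collapse RGB by Rec.601 luma and rescale 16-bit linearly to [0, 255]."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        if arr.shape[-1] != 3:
            raise ValueError(f"unsupported channel count {arr.shape[-1]}")
        arr = arr.astype(float) @ _LUMA
        if image.dtype == np.uint16:
            arr = _rescale_minmax(arr)
        return np.clip(np.round(arr), 0, 255).astype(np.uint8)
    if arr.ndim != 2:
        raise ValueError("expected a 2D grayscale or 3-channel image")
    if arr.dtype == np.uint8:
        return arr.copy()
    if arr.dtype == np.uint16 or np.issubdtype(arr.dtype, np.integer):
        return np.clip(np.round(_rescale_minmax(arr.astype(float))), 0, 255).astype(
            np.uint8
        )
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(np.round(_rescale_minmax(arr.astype(float))), 0, 255).astype(
            np.uint8
        )
    raise ValueError(f"unsupported dtype {arr.dtype}")


def _rescale_minmax(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        # constant image: keep its 8-bit value if representable, else mid-gray
        v = lo if 0 <= lo <= 255 else 127.0
        return np.full_like(arr, v, dtype=float)
    return (arr - lo) * (255.0 / (hi - lo))


def invert(image: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """8-bit inversion ``v -> 255 - v``, applied inside ``mask`` only."""
    if image.dtype != np.uint8:
        raise ValueError("invert expects an 8-bit image")
    out = image.copy()
    if mask is None:
        return 255 - out
    out[mask] = 255 - out[mask]
    return out


def autocontrast(
    image: np.ndarray,
    saturate_frac: float = 0.0035,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Linear stretch mapping the saturate quantiles to 0/255 with clipping.

    ``saturate_frac`` is the per-side saturated fraction (default 0.35%).
    Quantiles are computed over ``mask`` pixels only; pixels outside the mask
    are left untouched. A constant (within the mask) image is returned
    unchanged.
    """
    if image.dtype != np.uint8:
        raise ValueError("autocontrast expects an 8-bit image")
    if not (0.0 <= saturate_frac < 0.5):
        raise ValueError("saturate_frac must be in [0, 0.5)")
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    vals = image[mask].astype(float)
    if vals.size == 0:
        raise ValueError("empty mask")
    lo = np.quantile(vals, saturate_frac)
    hi = np.quantile(vals, 1.0 - saturate_frac)
    if hi <= lo:
        return image.copy()
    out = image.astype(float)
    stretched = np.clip((out - lo) * (255.0 / (hi - lo)), 0, 255)
    out[mask] = stretched[mask]
    return np.round(out).astype(np.uint8)


def crop_partition(
    slide: RawSlide,
    polygon_px: np.ndarray,
    label: str = "CA1",
    saturate_frac: float = 0.0035,
) -> PartitionImage:
    """Full preprocessing chain for one partition.

    ``polygon_px`` is an (n, 2) array of (row, col) vertices on the slide.
    Order: 8-bit conversion -> bounding-box crop + polygon rasterization ->
    inversion inside the mask (outside filled with 0) -> auto-contrast over
    the mask.
    """
    poly = np.asarray(polygon_px, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    shoelace = Polygon(poly).area
    if shoelace <= 0:
        raise ValueError("degenerate polygon (zero area)")

    gray = to_8bit_gray(slide.image)
    h, w = gray.shape
    r0 = int(np.floor(poly[:, 0].min()))
    r1 = int(np.ceil(poly[:, 0].max()))
    c0 = int(np.floor(poly[:, 1].min()))
    c1 = int(np.ceil(poly[:, 1].max()))
    r0c, r1c = max(r0, 0), min(r1 + 1, h)
    c0c, c1c = max(c0, 0), min(c1 + 1, w)
    if r1c <= r0c or c1c <= c0c:
        raise ValueError("polygon lies outside the image")

    crop = gray[r0c:r1c, c0c:c1c]
    local = poly - np.array([r0c, c0c])
    mask = polygon2mask(crop.shape, local)
    if not mask.any():
        raise ValueError("polygon rasterizes to an empty mask inside the image")

    inv = invert(crop, mask)
    inv[~mask] = 0
    out = autocontrast(inv, saturate_frac, mask)
    out[~mask] = 0
    return PartitionImage(
        image=out,
        valid_mask=mask,
        polygon=local,
        label=label,
        pixel_size_um=slide.pixel_size_um,
        provenance={
            "case": slide.case,
            "level": slide.level,
            "crop_origin": [r0c, c0c],
            "order": "to_8bit_gray>crop>invert>autocontrast",
            "saturate_frac": saturate_frac,
        },
    )


def preprocess_rendered(rendered, label: str = "synthetic") -> PartitionImage:
    """Run the preprocessing chain on a synthetic rendered partition.

    The rendered image is already 8-bit grayscale; the partition polygon is
    the full image rectangle, so this applies inversion and auto-contrast.
    """
    h, w = rendered.image.shape
    slide = RawSlide(rendered.image, pixel_size_um=rendered.pixel_size_um)
    poly = np.array([[0, 0], [0, w - 1], [h - 1, w - 1], [h - 1, 0]], dtype=float)
    part = crop_partition(slide, poly, label=label)
    # the rectangular polygon rasterization may shave border pixels; widen to
    # the full frame so synthetic ground truth at the border stays visible
    full = np.ones((h, w), dtype=bool)
    if part.image.shape == (h, w) and not part.valid_mask.all():
        inv = invert(rendered.image, full)
        out = autocontrast(inv, 0.0035, full)
        part = PartitionImage(
            image=out,
            valid_mask=full,
            polygon=poly,
            label=label,
            pixel_size_um=rendered.pixel_size_um,
            provenance={"order": "invert>autocontrast", "synthetic": True},
        )
    return part
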