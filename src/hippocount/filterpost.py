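"""Automated false-positive filtering of segmented neuron candidates.

Segmented objects that are not in-plane pyramidal neurons fall into four
classes: faint extracellular blobs, glial cells, partial neuron profiles,
and overlapping neuron pairs. The filter removes the first three and
deliberately keeps overlaps as single objects:

1. *Intensity filter* — objects whose mean inverted gray value falls below
   the partition's mean inverted gray (i.e. more faintly stained than the
   partition overall) are removed.
2. *Diameter filter* — each surviving object is fitted with its
   moment-matched ellipse; the minor-axis length in µm stands in for the
   neuron diameter. Objects below ``mean - k_sd * SD`` of the surviving
   diameters (default ``k_sd = 0.75``) are removed. There is no upper
   threshold, so touching neurons count as one.
3. *Edge exclusion* (vignette mode only) — objects touching the image
   border are removed, matching the convention used when comparing against
   manual raters.

Every object keeps a persistent id, a kept/removed status, and a removal
reason, so tallies are fully trackable from the unfiltered map to the final
per-partition estimate (``n_kept``).

Diameter statistics are computed over the intensity-surviving objects only;
including background artifacts would corrupt the mean and SD the threshold
is built from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .preprocess import PartitionImage
from .segment import InstanceMap

__all__ = [
    "EllipseFit",
    "SegmentRecord",
    "FilterParams",
    "PartitionTally",
    "fit_ellipse",
    "extract_records",
    "intensity_filter",
    "diameter_filter",
    "edge_exclusion",
    "run_filters",
    "records_to_frame",
    "filtered_label_map",
]

KEPT = "kept"
REMOVED = "removed"
REASONS = ("intensity", "diameter", "edge", "none")
PILOT_K_SD = (1.0, 0.75, 0.5)


@dataclass
class EllipseFit:
    """Moment-matched ellipse of one pixel set (full axis lengths, px)."""

    centroid: tuple
    major_px: float
    minor_px: float
    angle: float

    def minor_um(self, pixel_size_um: float) -> float:
        return self.minor_px * pixel_size_um


@dataclass
class SegmentRecord:
    """One segmented object, trackable through every filtering pass."""

    id: int
    pixel_count: int
    mean_gray: float
    ellipse: EllipseFit
    diameter_um: float
    status: str = KEPT
    removal_reason: str = "none"
    coords: np.ndarray | None = None  # (n, 2) pixel coordinates, not serialized

    def remove(self, reason: str):
        if reason not in REASONS or reason == "none":
            raise ValueError(f"invalid removal reason {reason!r}")
        self.status = REMOVED
        self.removal_reason = reason


@dataclass
class FilterParams:
    k_sd: float = 0.75  # piloted set: 1.0, 0.75, 0.5
    apply_edge_exclusion: bool = False
    pixel_size_um: float = 0.75

    def __post_init__(self):
        if self.k_sd < 0:
            raise ValueError("k_sd must be >= 0")


@dataclass
class PartitionTally:
    """Bookkeeping for one partition: totals, kept fraction, reasons."""

    n_unfiltered: int
    n_kept: int
    removed_by_reason: dict = field(default_factory=dict)
    diameter_threshold_um: float | None = None

    @property
    def pct_kept(self) -> float | None:
        if self.n_unfiltered == 0:
            return None
        return 100.0 * self.n_kept / self.n_unfiltered

    @property
    def pct_excluded(self) -> float | None:
        if self.n_unfiltered == 0:
            return None
        return 100.0 - self.pct_kept

    def __post_init__(self):
        if self.n_kept > self.n_unfiltered:
            raise ValueError("n_kept cannot exceed n_unfiltered")
        removed = sum(self.removed_by_reason.values())
        if self.removed_by_reason and removed != self.n_unfiltered - self.n_kept:
            raise ValueError("removal reasons do not conserve totals")


def fit_ellipse(coords: np.ndarray) -> EllipseFit:
    """Ellipse from central second moments of a pixel coordinate set.

    Full axis length = 4 * sqrt(eigenvalue of the 2x2 central covariance)
    (population moments), which matches a uniform filled ellipse exactly:
    a disc of radius r has coordinate variance r^2/4, giving axis 2r.
    Degenerate sets (single pixel, collinear pixels) get ``minor_px = 1``.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("need a nonempty (n, 2) pixel set")
    centroid = pts.mean(axis=0)
    if pts.shape[0] == 1:
        return EllipseFit(tuple(centroid), 1.0, 1.0, 0.0)
    centered = pts - centroid
    cov = centered.T @ centered / pts.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    minor = 4.0 * np.sqrt(max(eigvals[0], 0.0))
    major = 4.0 * np.sqrt(max(eigvals[1], 0.0))
    if minor < 1.0:
        minor = 1.0
    if major < minor:
        major = minor
    vmaj = eigvecs[:, 1]
    angle = float(np.arctan2(vmaj[0], vmaj[1]))  # vs. column axis
    return EllipseFit(tuple(centroid), float(major), float(minor), angle)


def extract_records(
    instances: InstanceMap, partition: PartitionImage, params: FilterParams
) -> list:
    """Measure every instance: pixels, mean inverted gray, fitted ellipse."""
    labels = instances.labels
    n = instances.n_instances
    records = []
    if n == 0:
        return records
    px = partition.pixel_size_um or params.pixel_size_um
    objects = ndi.find_objects(labels, max_label=n)
    img = partition.image
    for idx in range(1, n + 1):
        sl = objects[idx - 1]
        if sl is None:
            continue
        local = labels[sl] == idx
        rr, cc = np.nonzero(local)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        coords = np.column_stack([rr, cc])
        ellipse = fit_ellipse(coords)
        records.append(
            SegmentRecord(
                id=idx,
                pixel_count=int(coords.shape[0]),
                mean_gray=float(img[rr, cc].mean()),
                ellipse=ellipse,
                diameter_um=ellipse.minor_um(px),
                coords=coords,
            )
        )
    return records


def intensity_filter(records: list, partition: PartitionImage) -> list:
    """Remove objects fainter than the partition's mean inverted gray.

    The threshold is the mean over the valid mask (background and somata
    together); objects with ``mean_gray`` strictly below it are removed.
    """
    vals = partition.valid_pixels()
    if vals.size == 0:
        raise ValueError("partition has an empty valid mask")
    threshold = float(vals.mean())
    for rec in records:
        if rec.status == KEPT and rec.mean_gray < threshold:
            rec.remove("intensity")
    return records


def diameter_filter(
    records: list,
    params: FilterParams,
    frozen_stats: tuple | None = None,
) -> tuple:
    """Remove objects below ``mean - k_sd * SD`` of surviving diameters.

    The mean and sample SD (n-1 denominator) are computed over currently
    kept records unless ``frozen_stats=(mu, sd)`` is supplied (used to test
    idempotence under fixed thresholds). Returns ``(records, threshold)``.
    With fewer than two kept records the filter is a warned no-op.
    """
    kept = [r for r in records if r.status == KEPT]
    if frozen_stats is not None:
        mu, sd = frozen_stats
    else:
        if len(kept) < 2:
            warnings.warn("fewer than 2 surviving records; diameter filter skipped")
            return records, None
        diams = np.array([r.diameter_um for r in kept])
        mu = float(diams.mean())
        sd = float(diams.std(ddof=1))
    threshold = mu - params.k_sd * sd
    for rec in kept:
        if rec.diameter_um < threshold:
            rec.remove("diameter")
    return records, float(threshold)


def edge_exclusion(records: list, image_shape: tuple) -> list:
    """Remove objects with any pixel on the image border (vignette mode)."""
    h, w = image_shape
    for rec in records:
        if rec.status != KEPT or rec.coords is None:
            continue
        rr = rec.coords[:, 0]
        cc = rec.coords[:, 1]
        if (rr == 0).any() or (rr == h - 1).any() or (cc == 0).any() or (cc == w - 1).any():
            rec.remove("edge")
    return records


def run_filters(
    instances: InstanceMap, partition: PartitionImage, params: FilterParams
) -> tuple:
    """Full filtering pass: intensity -> diameter -> (edge). Returns
    ``(records, PartitionTally)``; ``tally.n_kept`` is the partition's
    automated neuron estimate."""
    records = extract_records(instances, partition, params)
    threshold = None
    if records:
        intensity_filter(records, partition)
        records, threshold = diameter_filter(records, params)
        if params.apply_edge_exclusion:
            edge_exclusion(records, partition.image.shape)
    reasons = {}
    for rec in records:
        if rec.status == REMOVED:
            reasons[rec.removal_reason] = reasons.get(rec.removal_reason, 0) + 1
    n_kept = sum(1 for r in records if r.status == KEPT)
    tally = PartitionTally(
        n_unfiltered=len(records),
        n_kept=n_kept,
        removed_by_reason=reasons,
        diameter_threshold_um=threshold,
    )
    return records, tally


def records_to_frame(records: list, partition_id: str = "") -> pd.DataFrame:
    """Ledger DataFrame, one row per object (CSV-ready, no pixel data)."""
    rows = [
        {
            "partition_id": partition_id,
            "segment_id": r.id,
            "pixel_count": r.pixel_count,
            "mean_gray": r.mean_gray,
            "minor_px": r.ellipse.minor_px,
            "diameter_um": r.diameter_um,
            "status": r.status,
            "removal_reason": r.removal_reason,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "partition_id", "segment_id", "pixel_count", "mean_gray",
            "minor_px", "diameter_um", "status", "removal_reason",
        ],
    )


def filtered_label_map(instances: InstanceMap, records: list) -> np.ndarray:
    """Label map with removed ids zeroed; kept ids retain their numbers."""
    keep = {r.id for r in records if r.status == KEPT}
    labels = instances.labels
    out = np.where(np.isin(labels, list(keep)), labels, 0).astype(np.int32)
    return out
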