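"""File I/O: TIFF images and label maps, JSON sidecars, CSV ledgers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import PartitionImage
from .segment import InstanceMap


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_sidecar(path: Path, payload: dict):
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def save_partition(path: Path, partition: PartitionImage):
    """Partition TIFF + JSON sidecar (polygon, label, pixel size, provenance)."""
    path = Path(path)
    tifffile.imwrite(path, partition.image)
    write_sidecar(
        path.with_suffix(".json"),
        {
            "label": partition.label,
            "pixel_size_um": partition.pixel_size_um,
            "polygon_px": partition.polygon,
            "provenance": partition.provenance,
        },
    )


def load_partition(path: Path) -> PartitionImage:
    from skimage.draw import polygon2mask

    path = Path(path)
    image = tifffile.imread(path)
    if image.dtype != np.uint8:
        raise ValueError(f"corrupt or unsupported partition TIFF: {path}")
    meta = json.loads(path.with_suffix(".json").read_text())
    poly = np.asarray(meta["polygon_px"], dtype=float)
    mask = polygon2mask(image.shape, poly)
    if not mask.any():
        mask = np.ones(image.shape, dtype=bool)
    return PartitionImage(
        image=image,
        valid_mask=mask,
        polygon=poly,
        label=meta.get("label", "CA1"),
        pixel_size_um=float(meta.get("pixel_size_um", 0.75)),
        provenance=meta.get("provenance", {}),
    )


def save_labels(path: Path, instances: InstanceMap):
    labels = instances.labels
    dtype = np.uint16 if labels.max() < 2**16 else np.int32
    tifffile.imwrite(Path(path), labels.astype(dtype))
    write_sidecar(Path(path).with_suffix(".json"), instances.provenance)


def load_labels(path: Path) -> InstanceMap:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    side = path.with_suffix(".json")
    prov = json.loads(side.read_text()) if side.exists() else {}
    return InstanceMap(labels, int(labels.max()), prov)


def save_cells_csv(path: Path, slab):
    slab.cells.to_csv(Path(path), index=False)


def save_roi_json(path: Path, roi, label: str = "", pixel_size_um: float | None = None):
    payload = {"label": label, "vertices_um": list(map(list, roi.exterior.coords))}
    if pixel_size_um is not None:
        payload["pixel_size_um"] = pixel_size_um
    write_sidecar(Path(path), payload)


def load_roi_json(path: Path):
    from shapely.geometry import Polygon

    meta = json.loads(Path(path).read_text())
    if "vertices_um" in meta:
        return Polygon(meta["vertices_um"]), meta
    return np.asarray(meta["vertices_px"], dtype=float), meta


def save_ledger(path: Path, ledger: pd.DataFrame):
    ledger.to_csv(Path(path), index=False)
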