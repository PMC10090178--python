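"""End-to-end orchestration: configuration, provenance, pipeline runs.

The unit of work is a partition: preprocess -> segment -> filter -> tally.
``run_synthetic_study`` generates a cohort of synthetic partitions spanning
a density range, runs both the 2D pipeline and the in-silico stereology
probe on the same slabs, and returns the paired method table the
``compare`` stage consumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filterpost, io, preprocess, segment, stereology, synthgen

__all__ = [
    "RunConfig",
    "estimate_partition",
    "run_synth",
    "run_estimate",
    "run_synthetic_study",
    "score_filter_recovery",
]


@dataclass
class RunConfig:
    """Serializable run configuration; config + seed reproduce a run."""

    outdir: str = "hippocount_out"
    seed: int = 0
    pixel_size_um: float = 0.75
    slab: synthgen.SlabSpec = field(default_factory=synthgen.SlabSpec)
    segmentation: segment.SegmentationParams = field(
        default_factory=segment.SegmentationParams
    )
    filtering: filterpost.FilterParams = field(default_factory=filterpost.FilterParams)
    fractionator: stereology.FractionatorParams = field(
        default_factory=stereology.FractionatorParams
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = (
            yaml.safe_load(path.read_text())
            if path.suffix in (".yml", ".yaml")
            else json.loads(path.read_text())
        ) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        if "slab" in raw:
            slab = dict(raw["slab"])
            if "neuron_diam_dist" in slab:
                slab["neuron_diam_dist"] = synthgen.DiameterDist(**slab["neuron_diam_dist"])
            if "glia_diam_dist" in slab:
                slab["glia_diam_dist"] = synthgen.DiameterDist(**slab["glia_diam_dist"])
            kwargs["slab"] = synthgen.SlabSpec(**slab)
        if "segmentation" in raw:
            kwargs["segmentation"] = segment.SegmentationParams(**raw["segmentation"])
        if "filtering" in raw:
            kwargs["filtering"] = filterpost.FilterParams(**raw["filtering"])
        if "fractionator" in raw:
            kwargs["fractionator"] = stereology.FractionatorParams(**raw["fractionator"])
        for key in ("outdir", "seed", "pixel_size_um"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return io.config_hash(self.to_dict())


def estimate_partition(
    partition: preprocess.PartitionImage,
    seg_params: segment.SegmentationParams,
    filt_params: filterpost.FilterParams,
):
    """Segment + filter one preprocessed partition.

    Returns ``(instances, records, tally)``; ``tally.n_kept`` is the
    partition's automated neuron estimate.
    """
    instances = segment.segment(partition, seg_params)
    records, tally = filterpost.run_filters(instances, partition, filt_params)
    return instances, records, tally


def score_filter_recovery(
    rendered: synthgen.RenderedPartition,
    instances: segment.InstanceMap,
    records: list,
) -> dict:
    """Judge the kept set against the synthetic class ledger.

    A planted cell counts as *kept* when its center pixel lies inside a kept
    instance. This deliberately credits merged overlapping neurons — the
    filtering method counts touching neurons as one object rather than
    removing them — so sensitivity measures what the filter removed, not
    what the segmentation split.

    Returns ``neuron_sensitivity`` (kept planted in-plane neurons over
    planted) and ``non_neuron_rejection`` (planted glia/profiles/debris not
    kept over planted).
    """
    kept_ids = [r.id for r in records if r.status == filterpost.KEPT]
    kept_mask = np.isin(instances.labels, kept_ids)
    tab = rendered.gt_table
    h, w = rendered.image.shape
    rr = tab["row_px"].round().astype(int).clip(0, h - 1)
    cc = tab["col_px"].round().astype(int).clip(0, w - 1)
    covered = kept_mask[rr, cc]
    in_plane = tab["in_plane"].to_numpy()
    non_neuron = (tab["cls"] != synthgen.CLASS_PYRAMIDAL).to_numpy()
    return {
        "neuron_sensitivity": float(covered[in_plane].mean()) if in_plane.any() else None,
        "non_neuron_rejection": (
            float(1.0 - covered[non_neuron].mean()) if non_neuron.any() else None
        ),
        "n_in_plane": int(in_plane.sum()),
        "n_non_neuron": int(non_neuron.sum()),
    }


def run_synth(config: RunConfig) -> dict:
    """Generate a slab + rendered partition and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = dataclasses.replace(config.slab, seed=config.seed)
    slab = synthgen.generate_slab(spec)
    rendered = synthgen.render_partition(
        slab, pixel_size_um=config.pixel_size_um, seed=config.seed
    )
    io.save_cells_csv(outdir / "cells.csv", slab)
    io.save_roi_json(outdir / "roi.json", slab.roi, label="slab")
    import tifffile

    tifffile.imwrite(outdir / "partition_raw.tif", rendered.image)
    dtype = np.uint16 if rendered.gt_labels.max() < 2**16 else np.int32
    tifffile.imwrite(outdir / "gt_labels.tif", rendered.gt_labels.astype(dtype))
    rendered.gt_table.to_csv(outdir / "gt_instances.csv", index=False)
    io.write_sidecar(
        outdir / "synth_run.json",
        {
            "seed": config.seed,
            "config_hash": config.hash(),
            "true_neuron_count": slab.true_neuron_count,
            "n_rendered_instances": rendered.n_instances,
        },
    )
    return {"slab": slab, "rendered": rendered, "outdir": outdir}


def run_estimate(config: RunConfig, partition_paths: list) -> pd.DataFrame:
    """Pipeline over stored partitions -> tallies CSV (one row each)."""
    if not partition_paths:
        raise FileNotFoundError("no partitions to process")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    ledgers = []
    for path in partition_paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"missing partition: {path}")
        part = io.load_partition(path)
        _, records, tally = estimate_partition(part, config.segmentation, config.filtering)
        ledgers.append(filterpost.records_to_frame(records, partition_id=path.stem))
        rows.append(
            {
                "partition_id": path.stem,
                "subregion": part.label,
                "n_unfiltered": tally.n_unfiltered,
                "n_kept": tally.n_kept,
                "pct_kept": tally.pct_kept,
            }
        )
    tallies = pd.DataFrame(rows)
    tallies.to_csv(outdir / "tallies.csv", index=False)
    if ledgers:
        io.save_ledger(outdir / "ledger.csv", pd.concat(ledgers, ignore_index=True))
    io.write_sidecar(
        outdir / "estimate_run.json",
        {"seed": config.seed, "config_hash": config.hash(), "n_partitions": len(rows)},
    )
    return tallies


def run_synthetic_study(
    n_partitions: int = 30,
    density_range: tuple = (200.0, 2000.0),
    partition_um: float = 600.0,
    seed: int = 0,
    seg_params: segment.SegmentationParams | None = None,
    filt_params: filterpost.FilterParams | None = None,
    frac_params: stereology.FractionatorParams | None = None,
    subregions: tuple = preprocess.SUBREGION_LABELS,
) -> pd.DataFrame:
    """Paired automated-vs-stereology table over a density gradient.

    Generates ``n_partitions`` synthetic slabs whose pyramidal density is
    log-spaced across ``density_range`` (a 10-fold span by default), runs
    the 2D pipeline (classical backend) on the rendered partition of each
    slab and the optical-fractionator probe on the same slab, and returns a
    method table with columns ``partition_id, subregion, case, level,
    automated, manual, true_count``.
    """
    seg_params = seg_params or segment.SegmentationParams()
    filt_params = filt_params or filterpost.FilterParams()
    frac_params = frac_params or stereology.FractionatorParams(target_frames=25)
    densities = np.geomspace(density_range[0], density_range[1], n_partitions)
    rng = np.random.default_rng(seed)
    rows = []
    for i, dens in enumerate(densities):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = synthgen.SlabSpec(
            width_um=partition_um,
            height_um=partition_um,
            densities={
                synthgen.CLASS_PYRAMIDAL: float(dens),
                synthgen.CLASS_GLIAL: float(dens) * 0.28,
                synthgen.CLASS_PROFILE: float(dens) * 0.17,
                synthgen.CLASS_DEBRIS: float(dens) * 0.17,
            },
            seed=sub_seed,
        )
        slab = synthgen.generate_slab(spec)
        rendered = synthgen.render_partition(slab, seed=sub_seed)
        part = preprocess.preprocess_rendered(rendered)
        _, _, tally = estimate_partition(part, seg_params, filt_params)
        stereo = stereology.run_stereology(
            slab, params=frac_params, n_replicates=1, seed=sub_seed
        )
        rows.append(
            {
                "partition_id": f"synth{i:03d}",
                "subregion": subregions[i % len(subregions)],
                "case": f"case{i // len(subregions)}",
                "level": str(i % 5 + 1),
                "automated": int(tally.n_kept),
                "manual": float(stereo["N"].iloc[0]),
                "true_count": slab.true_neuron_count,
                "density_per_mm2": float(dens),
            }
        )
    return pd.DataFrame(rows)
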