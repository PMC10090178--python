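"""Synthetic Nissl-like tissue with exact ground truth.

This module generates 3D "slabs" of mounted tissue populated with cells and
renders them into 2D grayscale partitions resembling thionin-stained
hippocampal pyramidal layers: dark somata on a light background, plus the
false-positive object classes an automated counting pipeline must reject —
glial cells, partial neuron profiles, faint extracellular debris, and
overlapping neuron pairs.

Every cell carries a nucleolus point, so the same slab serves both the 2D
segmentation pipeline (via :func:`render_partition`) and the in-silico
optical-fractionator stereology probe (which counts nucleoli in 3D).

Coordinate conventions
----------------------
Slab coordinates are in micrometers, origin at the slab's lower-left-top
corner; ``z`` increases downward from the section top surface. Rendered
images are indexed ``(row, col)``, 0-based, row 0 at the top; column maps to
``x`` and row to ``y``.

Depth sampling is "nucleolus first": nucleolus points are uniform over
``[0, thickness]`` and the soma center is displaced from the nucleolus by a
uniform draw inside a concentric ball of half the somal radius. This keeps
the countable points uniform in depth (soma centers may protrude slightly
beyond the faces, as real somata cut by the microtome do), which is what
makes disector counting with guard zones unbiased on this material.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "CLASS_PYRAMIDAL",
    "CLASS_GLIAL",
    "CLASS_PROFILE",
    "CLASS_DEBRIS",
    "DiameterDist",
    "SlabSpec",
    "GroundTruth3D",
    "RenderedPartition",
    "generate_slab",
    "slab_from_cells",
    "render_partition",
    "make_vignette",
    "class_separation_error",
]

CLASS_PYRAMIDAL = "pyramidal"
CLASS_GLIAL = "glial"
CLASS_PROFILE = "profile"
CLASS_DEBRIS = "debris"

#: columns of the ground-truth cell ledger
CELL_COLUMNS = [
    "cell_id", "cls", "x_um", "y_um", "z_um", "diam_um",
    "nucleolus_x_um", "nucleolus_y_um", "nucleolus_z_um",
]


@dataclass(frozen=True)
class DiameterDist:
    """Lognormal somal-diameter distribution, parameterized by its median (µm).

    ``sigma_ln`` is the standard deviation of ``log(diameter)``; the median
    of a lognormal equals ``exp(mu)`` so sampling is
    ``median * exp(sigma_ln * N(0, 1))``.
    """

    median_um: float = 18.0
    sigma_ln: float = 0.10
    name: str = "lognormal"

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.name != "lognormal":
            raise ValueError(f"unknown diameter distribution {self.name!r}")
        return self.median_um * np.exp(rng.normal(0.0, self.sigma_ln, n))


def _default_densities() -> dict:
    # cells per mm^2 of tissue in plane; chosen to produce a touching-but-
    # resolvable pyramidal layer with the documented false-positive classes.
    return {
        CLASS_PYRAMIDAL: 350.0,
        CLASS_GLIAL: 100.0,
        CLASS_PROFILE: 60.0,
        CLASS_DEBRIS: 60.0,
    }


@dataclass(frozen=True)
class SlabSpec:
    """Parameters of one synthetic tissue slab.

    Attributes
    ----------
    width_um, height_um : float
        In-plane extent of the slab (µm).
    thickness_um : float
        Mounted section thickness (µm). Must leave room for two guard zones
        plus the disector when the slab is used for stereology.
    densities : dict
        Cells per mm² per class (``pyramidal``, ``glial``, ``profile``,
        ``debris``). ``profile`` cells model somata mostly removed by
        sectioning; ``debris`` models faintly stained extracellular blobs.
    neuron_diam_dist, glia_diam_dist : DiameterDist
        Somal diameter distributions (µm).
    profile_frac_range : (float, float)
        Rendered fraction of a profile cell's somal diameter.
    overlap_fraction : float
        Fraction of pyramidal cells placed as touching pairs (center
        distance below the mean somal radius), emulating overlapping
        neurons counted as one.
    seed : int
        RNG seed; identical spec + seed reproduce the slab exactly.
    """

    width_um: float = 1000.0
    height_um: float = 1000.0
    thickness_um: float = 20.39
    densities: dict = field(default_factory=_default_densities)
    neuron_diam_dist: DiameterDist = DiameterDist(18.0, 0.10)
    glia_diam_dist: DiameterDist = DiameterDist(7.0, 0.15)
    profile_frac_range: tuple = (0.25, 0.50)
    overlap_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.width_um <= 0 or self.height_um <= 0 or self.thickness_um <= 0:
            raise ValueError("slab extents must be positive")
        for cls, dens in self.densities.items():
            if not np.isfinite(dens) or dens < 0:
                raise ValueError(f"density for {cls!r} must be finite and >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")


@dataclass
class GroundTruth3D:
    """A populated slab: the exact cell ledger plus the counting ROI.

    ``cells`` is a DataFrame with :data:`CELL_COLUMNS`. ``roi`` is a shapely
    polygon in µm (defaults to the full slab rectangle).
    ``thickness_field``, if set, is a callable ``(x_um, y_um) -> t_um``
    giving locally varying mounted thickness; otherwise thickness is the
    constant ``thickness_um``.
    """

    cells: pd.DataFrame
    roi: Polygon
    width_um: float
    height_um: float
    thickness_um: float
    seed: int | None = None
    thickness_field: object = None

    @property
    def true_neuron_count(self) -> int:
        """Number of pyramidal cells whose nucleolus lies inside the ROI."""
        return int(self._neuron_in_roi_mask().sum())

    def _neuron_in_roi_mask(self) -> np.ndarray:
        from shapely import intersects_xy  # vectorized, boundary-inclusive

        cells = self.cells
        if len(cells) == 0:
            return np.zeros(0, dtype=bool)
        pyramidal = (cells["cls"] == CLASS_PYRAMIDAL).to_numpy()
        inside = intersects_xy(
            self.roi,
            cells["nucleolus_x_um"].to_numpy(),
            cells["nucleolus_y_um"].to_numpy(),
        )
        return pyramidal & inside

    def thickness_at(self, x_um: float, y_um: float) -> float:
        if self.thickness_field is not None:
            return float(self.thickness_field(x_um, y_um))
        return float(self.thickness_um)


@dataclass
class RenderedPartition:
    """A rendered 2D view of a slab: image, instance labels, and a ledger.

    ``image`` is pre-inversion 8-bit grayscale (dark somata on light
    background). ``gt_labels`` is an instance label map (0 = background,
    instances 1..n). ``gt_table`` has one row per rendered instance with
    columns ``label, cell_id, cls, in_plane, drawn_diam_um``.
    """

    image: np.ndarray
    gt_labels: np.ndarray
    gt_table: pd.DataFrame
    pixel_size_um: float
    background_gray: int = 205

    @property
    def n_instances(self) -> int:
        return int(len(self.gt_table))


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in CELL_COLUMNS}).astype(
        {"cell_id": int, "cls": object}
    )


def slab_from_cells(
    cells: pd.DataFrame | list,
    width_um: float,
    height_um: float,
    thickness_um: float = 20.39,
    roi: Polygon | None = None,
) -> GroundTruth3D:
    """Build a :class:`GroundTruth3D` from an explicit cell list.

    Intended for deterministic constructions (regular grids, single cells,
    hand-placed nucleoli) where Poisson placement would get in the way.
    ``cells`` may be a DataFrame with :data:`CELL_COLUMNS` or a list of
    dicts; missing nucleolus columns default to the soma center.
    """
    df = pd.DataFrame(cells)
    if len(df) == 0:
        df = _empty_cells()
    else:
        if "cell_id" not in df:
            df["cell_id"] = np.arange(len(df))
        if "cls" not in df:
            df["cls"] = CLASS_PYRAMIDAL
        for axis in ("x", "y", "z"):
            col = f"nucleolus_{axis}_um"
            if col not in df:
                df[col] = df[f"{axis}_um"]
        df = df[CELL_COLUMNS].reset_index(drop=True)
    if roi is None:
        roi = box(0.0, 0.0, width_um, height_um)
    return GroundTruth3D(df, roi, width_um, height_um, thickness_um)


def generate_slab(spec: SlabSpec) -> GroundTruth3D:
    """Populate a slab with homogeneous Poisson placement per class.

    For each class, the number of cells is Poisson with mean
    ``density * area`` and positions are uniform over the slab; nucleolus
    points are uniform over ``[0, thickness]`` in depth (see module notes).
    A fraction ``overlap_fraction`` of pyramidal cells is re-placed as
    touching pairs. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    area_mm2 = spec.width_um * spec.height_um / 1e6
    rows = []
    next_id = 0
    for cls in (CLASS_PYRAMIDAL, CLASS_GLIAL, CLASS_PROFILE, CLASS_DEBRIS):
        dens = float(spec.densities.get(cls, 0.0))
        n = int(rng.poisson(dens * area_mm2))
        if n == 0:
            continue
        if cls == CLASS_GLIAL:
            diam = spec.glia_diam_dist.sample(rng, n)
        elif cls == CLASS_DEBRIS:
            diam = rng.uniform(3.0, 8.0, n)  # faint blobs, decidedly sub-somal
        else:
            diam = spec.neuron_diam_dist.sample(rng, n)
        nx = rng.uniform(0.0, spec.width_um, n)
        ny = rng.uniform(0.0, spec.height_um, n)
        nz = rng.uniform(0.0, spec.thickness_um, n)
        # soma center = nucleolus + uniform offset in a ball of half radius
        offs = _uniform_ball(rng, n) * (diam / 4.0)[:, None]
        cx, cy, cz = nx + offs[:, 0], ny + offs[:, 1], nz + offs[:, 2]
        for i in range(n):
            rows.append(
                (next_id, cls, cx[i], cy[i], cz[i], diam[i], nx[i], ny[i], nz[i])
            )
            next_id += 1
    cells = pd.DataFrame(rows, columns=CELL_COLUMNS) if rows else _empty_cells()

    # re-place a fraction of pyramidal cells as touching pairs
    pyr_idx = cells.index[cells["cls"] == CLASS_PYRAMIDAL].to_numpy()
    n_pairs = int(np.floor(spec.overlap_fraction * len(pyr_idx) / 2.0))
    if n_pairs > 0:
        chosen = rng.choice(pyr_idx, size=2 * n_pairs, replace=False)
        mean_radius = spec.neuron_diam_dist.median_um / 2.0
        for a, b in zip(chosen[:n_pairs], chosen[n_pairs:]):
            dist = rng.uniform(0.5, 1.0) * mean_radius  # < mean somal radius
            theta = rng.uniform(0.0, 2.0 * np.pi)
            cells.loc[b, "x_um"] = cells.loc[a, "x_um"] + dist * np.cos(theta)
            cells.loc[b, "y_um"] = cells.loc[a, "y_um"] + dist * np.sin(theta)
            cells.loc[b, "z_um"] = cells.loc[a, "z_um"]
            # resample the nucleolus offset until its depth stays inside the
            # section; a clipped depth would pile mass on the faces
            for _ in range(64):
                off = _uniform_ball(rng, 1)[0] * cells.loc[b, "diam_um"] / 4.0
                nz = cells.loc[b, "z_um"] + off[2]
                if 0.0 <= nz < spec.thickness_um:
                    break
            else:
                off = np.zeros(3)
                nz = float(np.clip(cells.loc[b, "z_um"], 0.0, spec.thickness_um))
            cells.loc[b, "nucleolus_x_um"] = cells.loc[b, "x_um"] + off[0]
            cells.loc[b, "nucleolus_y_um"] = cells.loc[b, "y_um"] + off[1]
            cells.loc[b, "nucleolus_z_um"] = float(nz)

    roi = box(0.0, 0.0, spec.width_um, spec.height_um)
    return GroundTruth3D(
        cells, roi, spec.width_um, spec.height_um, spec.thickness_um, seed=spec.seed
    )


def _uniform_ball(rng: np.random.Generator, n: int) -> np.ndarray:
    """n points uniform in the unit ball (rejection-free: direction × radius)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0)
    return v * r[:, None]


# ---------------------------------------------------------------------------
# rendering

_CLASS_GRAY = {
    # pre-inversion staining intensity ranges (8-bit gray). Somata are darker
    # than the background by >= 30 gray levels; debris sits near background
    # to exercise the downstream intensity filter.
    CLASS_PYRAMIDAL: (60, 140),
    CLASS_PROFILE: (60, 140),
    CLASS_GLIAL: (100, 160),
    CLASS_DEBRIS: (180, 200),
}
_DRAW_ORDER = [CLASS_DEBRIS, CLASS_GLIAL, CLASS_PROFILE, CLASS_PYRAMIDAL]


def render_partition(
    slab: GroundTruth3D,
    focal_center_um: float | None = None,
    depth_of_field_um: float | None = None,
    pixel_size_um: float = 0.75,
    background_gray: int = 205,
    noise_sd: float = 4.0,
    aspect_range: tuple = (1.0, 1.6),
    profile_frac_range: tuple = (0.25, 0.50),
    seed: int = 0,
) -> RenderedPartition:
    """Render the cells intersecting a focal slab into a 2D partition image.

    Somata are drawn as filled ellipses whose area matches the circle of the
    cell's visible cross-section diameter (aspect ratio sampled from
    ``aspect_range``, split evenly between the axes so the equivalent-circle
    diameter is preserved). Cells whose center lies outside the focal depth
    interval, profile-class cells, and cells clipped by the image border are
    partial profiles flagged ``in_plane=False``. Additive Gaussian noise is
    applied last.

    Defaults image the whole mounted thickness (focal center mid-slab, depth
    of field equal to the thickness), which is the brightfield situation the
    2D pipeline sees.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    t = slab.thickness_um
    if focal_center_um is None:
        focal_center_um = t / 2.0
    if depth_of_field_um is None:
        depth_of_field_um = t
    zlo = focal_center_um - depth_of_field_um / 2.0
    zhi = focal_center_um + depth_of_field_um / 2.0
    if not (0.0 <= focal_center_um <= t):
        raise ValueError("focal plane must lie inside the slab")

    rng = np.random.default_rng(seed)
    h_px = int(round(slab.height_um / pixel_size_um))
    w_px = int(round(slab.width_um / pixel_size_um))
    image = np.full((h_px, w_px), float(background_gray))
    labels = np.zeros((h_px, w_px), dtype=np.int32)

    cells = slab.cells
    records = []
    label = 0
    for cls in _DRAW_ORDER:
        sub = cells[cells["cls"] == cls]
        for _, cell in sub.iterrows():
            r_um = cell["diam_um"] / 2.0
            z = cell["z_um"]
            if cls == CLASS_PROFILE:
                frac = rng.uniform(*_as_pair("profile fraction", profile_frac_range))
                dcs = cell["diam_um"] * frac
                full = False
            elif zlo <= z <= zhi:
                dcs = cell["diam_um"]
                full = True
            else:
                dz = min(abs(z - zlo), abs(z - zhi))
                if dz >= r_um:
                    continue  # soma does not reach the focal slab
                dcs = 2.0 * np.sqrt(r_um**2 - dz**2)
                full = False
            aspect = rng.uniform(*aspect_range)
            angle = rng.uniform(0.0, np.pi)
            a_px = max((dcs / 2.0) * np.sqrt(aspect) / pixel_size_um, 0.6)
            b_px = max((dcs / 2.0) / np.sqrt(aspect) / pixel_size_um, 0.6)
            row_c = cell["y_um"] / pixel_size_um
            col_c = cell["x_um"] / pixel_size_um
            rr, cc = _draw_ellipse(
                row_c, col_c, a_px, b_px, shape=image.shape, rotation=angle
            )
            if rr.size == 0:
                continue
            lo, hi = _CLASS_GRAY[cls]
            gray = rng.uniform(lo, hi)
            label += 1
            image[rr, cc] = gray
            labels[rr, cc] = label
            extent = max(a_px, b_px)
            inside_image = (
                row_c - extent >= 0
                and col_c - extent >= 0
                and row_c + extent <= h_px - 1
                and col_c + extent <= w_px - 1
            )
            records.append(
                {
                    "label": label,
                    "cell_id": int(cell["cell_id"]),
                    "cls": cls,
                    "in_plane": bool(cls == CLASS_PYRAMIDAL and full and inside_image),
                    "drawn_diam_um": float(dcs),
                    "row_px": float(row_c),
                    "col_px": float(col_c),
                }
            )

    table = pd.DataFrame(
        records,
        columns=[
            "label", "cell_id", "cls", "in_plane", "drawn_diam_um",
            "row_px", "col_px",
        ],
    )
    # drop instances fully overdrawn by later cells, then relabel contiguous
    labels, table = _compact_labels(labels, table)

    image += rng.normal(0.0, noise_sd, image.shape)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return RenderedPartition(image, labels, table, pixel_size_um, background_gray)


def _as_pair(name, value):
    lo, hi = value
    if lo > hi:
        raise ValueError(f"{name} range inverted")
    return lo, hi


def _compact_labels(labels: np.ndarray, table: pd.DataFrame):
    """Drop empty instances and relabel 1..n preserving order."""
    present = np.unique(labels)
    present = present[present > 0]
    table = table[table["label"].isin(present)].reset_index(drop=True)
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    for new, old in enumerate(table["label"].to_numpy(), start=1):
        remap[old] = new
    labels = remap[labels]
    table = table.assign(label=np.arange(1, len(table) + 1))
    return labels, table


def make_vignette(
    partition: RenderedPartition,
    side_um: float = 750.0,
    min_neurons: int = 75,
    seed: int = 0,
    max_attempts: int = 200,
) -> RenderedPartition:
    """Random square crop containing at least ``min_neurons`` in-plane neurons.

    Retries uniformly random offsets up to ``max_attempts`` times and raises
    if the partition is too sparse to satisfy the requirement.
    """
    side_px = int(round(side_um / partition.pixel_size_um))
    h, w = partition.image.shape
    if side_px > h or side_px > w:
        raise ValueError("partition smaller than requested vignette")
    rng = np.random.default_rng(seed)
    table = partition.gt_table
    for _ in range(max_attempts):
        r0 = int(rng.integers(0, h - side_px + 1))
        c0 = int(rng.integers(0, w - side_px + 1))
        inside = (
            (table["row_px"] >= r0)
            & (table["row_px"] < r0 + side_px)
            & (table["col_px"] >= c0)
            & (table["col_px"] < c0 + side_px)
            & table["in_plane"]
        )
        if int(inside.sum()) >= min_neurons:
            img = partition.image[r0 : r0 + side_px, c0 : c0 + side_px].copy()
            lab = partition.gt_labels[r0 : r0 + side_px, c0 : c0 + side_px].copy()
            sub = table.copy()
            sub["row_px"] = sub["row_px"] - r0
            sub["col_px"] = sub["col_px"] - c0
            lab, sub = _compact_labels(lab, sub)
            return RenderedPartition(
                img, lab, sub, partition.pixel_size_um, partition.background_gray
            )
    raise RuntimeError(
        f"cannot satisfy min_neurons={min_neurons} within {max_attempts} attempts"
    )


def class_separation_error(
    neuron_minors_um: np.ndarray, other_minors_um: np.ndarray
) -> float:
    """Best-threshold misclassification rate between two diameter samples.

    Scans thresholds over the pooled values and returns the minimum achievable
    fraction of misclassified objects when everything below the threshold is
    called "not a neuron". Used to assert that in-plane neuron minor diameters
    and the glia/profile population are separable.
    """
    a = np.asarray(neuron_minors_um, dtype=float)
    b = np.asarray(other_minors_um, dtype=float)
    if a.size == 0 or b.size == 0:
        return 0.0
    candidates = np.unique(np.concatenate([a, b]))
    best = 1.0
    total = a.size + b.size
    for thr in candidates:
        err = ((a < thr).sum() + (b >= thr).sum()) / total
        best = min(best, err)
    return float(best)
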