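"""In-silico optical fractionator: systematic uniform random sampling,
disector counting with guard zones, and the fractionator estimate

    N = sum(Q) * (t / h) * (1 / asf) * (1 / ssf)

where Q are per-frame disector counts, t the locally measured section
thickness, h the disector height, asf the area sampling fraction (frame
area over grid-cell area), and ssf the section sampling fraction.

Sampling design
---------------
A square grid of spacing ``s`` receives a single uniform random offset in
``[0, s)^2``; a counting frame of the configured size hangs off every grid
node whose frame rectangle intersects the ROI polygon. A nucleolus is
counted when it falls inside the half-open frame

    x in (x0, x0 + w],   y in [y0, y0 + h_frame)

— the point-particle reduction of the classic unbiased counting frame with
left+bottom exclusion lines — and its depth lies inside the disector
``z in [guard, guard + h)``, and the point itself lies inside the ROI.

With this rule every ROI point belongs to exactly one frame of the offset
grid (no double counting, no omission), which makes the estimator exactly
unbiased: each nucleolus is sampled with probability ``asf * h / t``, and
the fractionator equation divides that probability back out. When the grid
spacing equals the frame size the frames tile the plane and, with a
full-thickness disector and no guard zones, every replicate returns the
true count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import intersects_xy
from shapely.geometry import Polygon, box

from .synthgen import CLASS_PYRAMIDAL, GroundTruth3D

__all__ = [
    "FractionatorParams",
    "FrameResult",
    "FractionatorEstimate",
    "place_frames",
    "count_frame",
    "fractionator_estimate",
    "run_stereology",
]


@dataclass(frozen=True)
class FractionatorParams:
    """Optical fractionator probe geometry and sampling intensity.

    Defaults: 50 µm × 50 µm counting frames, 10 µm disector, 3 µm guard
    zones top and bottom, ssf = 1 (all sections of interest sampled), and a
    target of ~10 frames per ROI unless an explicit grid spacing is given.
    """

    frame_w_um: float = 50.0
    frame_h_um: float = 50.0
    disector_h_um: float = 10.0
    guard_um: float = 3.0
    ssf: float = 1.0
    target_frames: int = 10
    grid_spacing_um: float | None = None
    thickness_weighting: str = "number"  # "number" (Q-weighted) | "arithmetic"

    def __post_init__(self):
        if min(self.frame_w_um, self.frame_h_um, self.disector_h_um) <= 0:
            raise ValueError("frame dimensions and disector height must be positive")
        if self.guard_um < 0:
            raise ValueError("guard_um must be >= 0")
        if not 0 < self.ssf <= 1:
            raise ValueError("ssf must be in (0, 1]")
        if self.thickness_weighting not in ("number", "arithmetic"):
            raise ValueError("thickness_weighting must be 'number' or 'arithmetic'")

    def validate_against(self, thickness_um: float):
        if 2 * self.guard_um + self.disector_h_um > thickness_um + 1e-9:
            raise ValueError(
                "guard zones plus disector height exceed the section thickness"
            )


@dataclass
class FrameResult:
    x0_um: float
    y0_um: float
    Q: int
    t_um: float

    def __post_init__(self):
        if self.Q < 0 or self.t_um <= 0:
            raise ValueError("Q must be >= 0 and t_um > 0")


@dataclass
class FractionatorEstimate:
    sum_Q: int
    t_bar_um: float
    h_um: float
    asf: float
    ssf: float
    N: float


def place_frames(
    roi: Polygon,
    params: FractionatorParams,
    rng: np.random.Generator,
) -> tuple:
    """Systematic uniform random placement of counting frames over an ROI.

    Returns ``(origins, spacing, asf)`` where ``origins`` is a list of
    ``(x0, y0)`` frame origins (µm). The spacing is ``grid_spacing_um`` or
    ``sqrt(roi area / target_frames)``; a single random offset in
    ``[0, s)^2`` shifts the whole grid. A frame is placed at every node
    whose frame rectangle intersects the ROI, so the frames jointly cover
    the ROI regardless of the offset.
    """
    area = roi.area
    if area <= 0:
        raise ValueError("ROI area must be positive")
    s = params.grid_spacing_um
    if s is None:
        s = float(np.sqrt(area / params.target_frames))
    if s < max(params.frame_w_um, params.frame_h_um) - 1e-9:
        raise ValueError("grid spacing smaller than the counting frame")
    off_x, off_y = rng.uniform(0.0, s, 2)
    minx, miny, maxx, maxy = roi.bounds
    k0 = int(np.floor((minx - params.frame_w_um - off_x) / s))
    k1 = int(np.ceil((maxx - off_x) / s))
    l0 = int(np.floor((miny - params.frame_h_um - off_y) / s))
    l1 = int(np.ceil((maxy - off_y) / s))
    origins = []
    for k in range(k0, k1 + 1):
        x0 = off_x + k * s
        for l in range(l0, l1 + 1):
            y0 = off_y + l * s
            frame = box(x0, y0, x0 + params.frame_w_um, y0 + params.frame_h_um)
            if frame.intersects(roi):
                origins.append((x0, y0))
    asf = (params.frame_w_um * params.frame_h_um) / (s * s)
    return origins, s, asf


def count_frame(
    origin: tuple,
    slab: GroundTruth3D,
    params: FractionatorParams,
    roi: Polygon | None = None,
) -> FrameResult:
    """Disector count of pyramidal nucleoli in one counting frame.

    Applies the half-open frame rule (module notes), the guard-zone /
    disector depth window, and ROI membership of the nucleolus point.
    The local thickness is measured at the frame center.
    """
    x0, y0 = origin
    if roi is None:
        roi = slab.roi
    cells = slab.cells
    t_local = slab.thickness_at(
        x0 + params.frame_w_um / 2.0, y0 + params.frame_h_um / 2.0
    )
    params.validate_against(t_local)
    if len(cells) == 0:
        return FrameResult(x0, y0, 0, t_local)
    pyr = (cells["cls"] == CLASS_PYRAMIDAL).to_numpy()
    nx = cells["nucleolus_x_um"].to_numpy()
    ny = cells["nucleolus_y_um"].to_numpy()
    nz = cells["nucleolus_z_um"].to_numpy()
    in_frame = (
        (nx > x0)
        & (nx <= x0 + params.frame_w_um)
        & (ny >= y0)
        & (ny < y0 + params.frame_h_um)
    )
    in_disector = (nz >= params.guard_um) & (
        nz < params.guard_um + params.disector_h_um
    )
    candidate = pyr & in_frame & in_disector
    if candidate.any():
        candidate[candidate] = intersects_xy(roi, nx[candidate], ny[candidate])
    return FrameResult(x0, y0, int(candidate.sum()), t_local)


def fractionator_estimate(
    frames: list,
    params: FractionatorParams,
    asf: float,
) -> FractionatorEstimate:
    """Apply the optical fractionator equation to a set of frame results.

    The mean thickness is Q-weighted (number-weighted) by default; frames
    with Q = 0 fall back to the arithmetic mean when no neuron was counted
    anywhere.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if params.disector_h_um <= 0 or asf <= 0:
        raise ValueError("disector height and asf must be positive")
    q = np.array([f.Q for f in frames], dtype=float)
    t = np.array([f.t_um for f in frames], dtype=float)
    sum_q = float(q.sum())
    if params.thickness_weighting == "number" and sum_q > 0:
        t_bar = float((q * t).sum() / sum_q)
    else:
        t_bar = float(t.mean())
    n = sum_q * (t_bar / params.disector_h_um) * (1.0 / asf) * (1.0 / params.ssf)
    return FractionatorEstimate(
        sum_Q=int(sum_q),
        t_bar_um=t_bar,
        h_um=params.disector_h_um,
        asf=asf,
        ssf=params.ssf,
        N=float(n),
    )


def run_stereology(
    slab: GroundTruth3D,
    roi: Polygon | None = None,
    params: FractionatorParams | None = None,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeat the full probe with independent grid offsets.

    Returns a DataFrame with one row per replicate: ``N``, ``sum_Q``,
    ``n_frames``, ``t_bar_um``, ``asf``. The replicate mean of ``N`` is an
    unbiased estimate of the true nucleolus count inside the ROI.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if roi is None:
        roi = slab.roi
    if params is None:
        params = FractionatorParams()
    params.validate_against(slab.thickness_um)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        origins, spacing, asf = place_frames(roi, params, rng)
        frames = [count_frame(o, slab, params, roi) for o in origins]
        est = fractionator_estimate(frames, params, asf)
        rows.append(
            {
                "replicate": rep,
                "N": est.N,
                "sum_Q": est.sum_Q,
                "n_frames": len(frames),
                "t_bar_um": est.t_bar_um,
                "asf": asf,
                "spacing_um": spacing,
            }
        )
    return pd.DataFrame(rows)
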