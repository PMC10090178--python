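"""Optical fractionator: frame placement, counting rules, unbiasedness."""

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from hippocount.stereology import (
    FractionatorParams,
    FrameResult,
    count_frame,
    fractionator_estimate,
    place_frames,
    run_stereology,
)
from hippocount.synthgen import (
    CLASS_GLIAL,
    CLASS_PYRAMIDAL,
    SlabSpec,
    generate_slab,
    slab_from_cells,
)


def point_slab(points, side=200.0, thickness=20.39, cls=CLASS_PYRAMIDAL):
    cells = [
        {"cell_id": i, "cls": cls, "x_um": x, "y_um": y, "z_um": z,
         "diam_um": 18.0, "nucleolus_x_um": x, "nucleolus_y_um": y,
         "nucleolus_z_um": z}
        for i, (x, y, z) in enumerate(points)
    ]
    return slab_from_cells(cells, side, side, thickness)


class TestPlaceFrames:
    def test_exhaustive_tiling_has_unit_asf(self):
        roi = box(0, 0, 200, 200)
        params = FractionatorParams(grid_spacing_um=50.0)
        _, spacing, asf = place_frames(roi, params, np.random.default_rng(0))
        assert asf == pytest.approx(1.0)
        assert spacing == 50.0

    def test_zero_area_roi_rejected(self):
        roi = Polygon([(0, 0), (10, 0), (20, 0)])
        with pytest.raises(ValueError):
            place_frames(roi, FractionatorParams(), np.random.default_rng(0))

    def test_spacing_below_frame_rejected(self):
        roi = box(0, 0, 100, 100)
        with pytest.raises(ValueError):
            place_frames(roi, FractionatorParams(grid_spacing_um=30.0),
                         np.random.default_rng(0))

    def test_mean_frame_count_matches_coverage(self):
        """E[#frames] = ((L + w) / s)^2 for frames intersecting an L-square."""
        roi = box(0, 0, 500, 500)
        params = FractionatorParams(target_frames=10)
        rng = np.random.default_rng(1)
        counts = [len(place_frames(roi, params, rng)[0]) for _ in range(200)]
        s = np.sqrt(500 * 500 / 10)
        expected = ((500 + 50) / s) ** 2
        assert np.mean(counts) == pytest.approx(expected, abs=0.35)


class TestCountFrame:
    def test_tiling_counts_each_point_exactly_once(self):
        """Half-open frame rule: a tiling partitions the nucleoli."""
        rng = np.random.default_rng(7)
        pts = [(x, y, 10.0) for x, y in rng.uniform(0, 200, (100, 2))]
        slab = point_slab(pts)
        params = FractionatorParams(grid_spacing_um=50.0,
                                    disector_h_um=20.39, guard_um=0.0)
        origins, _, _ = place_frames(slab.roi, params, rng)
        total = sum(count_frame(o, slab, params).Q for o in origins)
        assert total == 100

    def test_guard_zone_excludes_shallow_nucleoli(self):
        slab = point_slab([(100.0, 100.0, 1.0)])  # 1 um deep: inside top guard
        params = FractionatorParams()
        q = count_frame((75.0, 75.0), slab, params).Q
        assert q == 0

    def test_disector_counts_mid_depth_nucleoli(self):
        slab = point_slab([(100.0, 100.0, 8.0)])  # within [3, 13)
        q = count_frame((75.0, 75.0), slab, FractionatorParams()).Q
        assert q == 1

    def test_non_neurons_never_counted(self):
        slab = point_slab([(100.0, 100.0, 8.0)], cls=CLASS_GLIAL)
        q = count_frame((75.0, 75.0), slab, FractionatorParams()).Q
        assert q == 0

    def test_exclusion_edges(self):
        """Left and bottom edges excluded, right and top included."""
        params = FractionatorParams(grid_spacing_um=50.0)
        slab = point_slab([(50.0, 60.0, 8.0)])
        assert count_frame((50.0, 50.0), slab, params).Q == 0  # x == x0
        assert count_frame((0.0, 50.0), slab, params).Q == 1   # x == x0 + w
        slab = point_slab([(60.0, 50.0, 8.0)])
        assert count_frame((50.0, 50.0), slab, params).Q == 1  # y == y0
        assert count_frame((50.0, 0.0), slab, params).Q == 0   # y == y0 + h


class TestFractionatorEstimate:
    def test_zero_counts_give_zero_estimate(self):
        frames = [FrameResult(0, 0, 0, 20.39), FrameResult(50, 0, 0, 20.39)]
        est = fractionator_estimate(frames, FractionatorParams(), asf=0.1)
        assert est.N == 0.0
        assert est.t_bar_um == pytest.approx(20.39)

    def test_identity_when_fractions_are_one(self):
        params = FractionatorParams(disector_h_um=20.39, guard_um=0.0)
        frames = [FrameResult(0, 0, 30, 20.39), FrameResult(50, 0, 27, 20.39)]
        est = fractionator_estimate(frames, params, asf=1.0)
        assert est.N == pytest.approx(57.0)

    def test_hand_evaluated_example(self):
        """sum Q 100, t 20.39, h 10, asf 0.01, ssf 1 -> N = 20390."""
        frames = [FrameResult(0, 0, 100, 20.39)]
        est = fractionator_estimate(frames, FractionatorParams(), asf=0.01)
        assert est.N == pytest.approx(20390.0)

    def test_q_weighted_mean_thickness(self):
        frames = [FrameResult(0, 0, 3, 10.0), FrameResult(50, 0, 1, 30.0)]
        params = FractionatorParams(disector_h_um=10.0, guard_um=0.0,
                                    thickness_weighting="number")
        est = fractionator_estimate(frames, params, asf=1.0)
        assert est.t_bar_um == pytest.approx((3 * 10 + 1 * 30) / 4)

    def test_scaling_in_asf_and_thickness_ratio(self):
        frames = [FrameResult(0, 0, 10, 20.0)]
        p1 = FractionatorParams(disector_h_um=10.0)
        base = fractionator_estimate(frames, p1, asf=0.1).N
        assert fractionator_estimate(frames, p1, asf=0.05).N == pytest.approx(2 * base)
        p2 = FractionatorParams(disector_h_um=5.0)
        assert fractionator_estimate(frames, p2, asf=0.1).N == pytest.approx(2 * base)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            fractionator_estimate([], FractionatorParams(), asf=0.1)
        with pytest.raises(ValueError):
            fractionator_estimate([FrameResult(0, 0, 1, 20.0)],
                                  FractionatorParams(), asf=0.0)


@pytest.fixture(scope="module")
def dense_slab():
    return generate_slab(
        SlabSpec(width_um=1000, height_um=1000,
                 densities={CLASS_PYRAMIDAL: 1000.0}, seed=11)
    )


class TestRunStereology:
    def test_seed_reproducibility(self, dense_slab):
        a = run_stereology(dense_slab, n_replicates=5, seed=3)
        b = run_stereology(dense_slab, n_replicates=5, seed=3)
        assert np.array_equal(a["N"].to_numpy(), b["N"].to_numpy())

    def test_unbiased_over_replicates(self, dense_slab):
        """Mean fractionator estimate within 5% of the true count."""
        res = run_stereology(dense_slab, n_replicates=200, seed=3)
        truth = dense_slab.true_neuron_count
        assert abs(res["N"].mean() - truth) / truth < 0.05

    def test_exhaustive_full_depth_recovers_truth_exactly(self, dense_slab):
        params = FractionatorParams(grid_spacing_um=50.0,
                                    disector_h_um=dense_slab.thickness_um,
                                    guard_um=0.0)
        res = run_stereology(dense_slab, params=params, n_replicates=5, seed=4)
        assert (res["sum_Q"] == dense_slab.true_neuron_count).all()
        assert res["N"].to_numpy() == pytest.approx(
            float(dense_slab.true_neuron_count)
        )

    def test_guard_disector_must_fit_thickness(self, dense_slab):
        params = FractionatorParams(disector_h_um=16.0, guard_um=3.0)
        with pytest.raises(ValueError):
            run_stereology(dense_slab, params=params, seed=0)

    def test_varying_thickness_measured_per_frame(self):
        slab = generate_slab(
            SlabSpec(width_um=500, height_um=500,
                     densities={CLASS_PYRAMIDAL: 500.0}, seed=5)
        )
        slab.thickness_field = lambda x, y: 18.0 + 4.0 * x / 500.0
        res = run_stereology(slab, n_replicates=20, seed=6)
        assert res["t_bar_um"].between(18.0, 22.0).all()
        assert res["t_bar_um"].nunique() > 1
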