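"""False-positive filtering: ellipse fits, thresholds, tallies, invariants."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_records, partition_from_image
from hippocount import filterpost
from hippocount.filterpost import (
    KEPT,
    REMOVED,
    FilterParams,
    PartitionTally,
    diameter_filter,
    edge_exclusion,
    extract_records,
    filtered_label_map,
    fit_ellipse,
    intensity_filter,
    run_filters,
)
from hippocount.segment import InstanceMap


def disc_coords(radius):
    c = radius + 10
    yy, xx = np.mgrid[: 2 * c + 1, : 2 * c + 1]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return np.column_stack(np.nonzero(mask))


class TestFitEllipse:
    def test_disc_minor_axis_is_the_diameter(self):
        """Variance of a uniform disc is r^2/4, so the fitted axis is 2r."""
        fit = fit_ellipse(disc_coords(20))
        assert fit.minor_px == pytest.approx(40.0, abs=1.0)
        assert fit.major_px == pytest.approx(40.0, abs=1.0)

    def test_rectangle_minor_axis(self):
        """A 10 px wide strip has variance w^2/12 -> axis 10 * 4 / sqrt(12)."""
        rr, cc = np.mgrid[0:10, 0:30]
        fit = fit_ellipse(np.column_stack([rr.ravel(), cc.ravel()]))
        assert fit.minor_px == pytest.approx(10 * 4 / np.sqrt(12), abs=0.2)

    def test_single_pixel_degenerate_rule(self):
        fit = fit_ellipse(np.array([[5, 7]]))
        assert fit.minor_px == 1.0

    def test_collinear_pixels_degenerate_rule(self):
        fit = fit_ellipse(np.array([[0, 0], [0, 1], [0, 2], [0, 3]]))
        assert fit.minor_px == 1.0
        assert fit.major_px > 1.0

    def test_empty_pixel_set_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.empty((0, 2)))

    def test_major_at_least_minor(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.integers(0, 30, 50), rng.integers(0, 60, 50)])
        fit = fit_ellipse(np.unique(pts, axis=0))
        assert fit.major_px >= fit.minor_px > 0


class TestIntensityFilter:
    def _partition_with_mean(self, mean=100):
        img = np.full((20, 20), 255 - mean, dtype=np.uint8)  # inverted later
        return partition_from_image(img)

    def test_fainter_than_partition_mean_removed(self):
        part = self._partition_with_mean(100)
        recs = make_records([15.0])
        recs[0].mean_gray = 80.0
        intensity_filter(recs, part)
        assert recs[0].status == REMOVED
        assert recs[0].removal_reason == "intensity"

    def test_exactly_at_threshold_kept(self):
        part = self._partition_with_mean(100)
        recs = make_records([15.0])
        recs[0].mean_gray = float(part.valid_pixels().mean())
        intensity_filter(recs, part)
        assert recs[0].status == KEPT

    def test_faint_blobs_removed_bright_somata_kept(self):
        """10 dark discs + 5 near-background blobs: exactly the blobs go."""
        img = np.full((150, 300), 205, dtype=np.uint8)
        yy, xx = np.mgrid[:150, :300]
        labels = np.zeros(img.shape, dtype=np.int32)
        k = 0
        for i in range(2):
            for j in range(5):
                k += 1
                r0, c0 = 35 + 65 * i, 30 + 60 * j
                m = (yy - r0) ** 2 + (xx - c0) ** 2 <= 16**2
                img[m] = 90
                labels[m] = k
        blob_ids = []
        for j in range(5):
            k += 1
            r0, c0 = 135, 30 + 60 * j
            m = (yy - r0) ** 2 + (xx - c0) ** 2 <= 8**2
            img[m] = 195  # barely darker than background
            labels[m] = k
            blob_ids.append(k)
        part = partition_from_image(img)
        inst = InstanceMap(labels, k)
        recs = extract_records(inst, part, FilterParams())
        intensity_filter(recs, part)
        removed = {r.id for r in recs if r.status == REMOVED}
        assert removed == set(blob_ids)


class TestDiameterFilter:
    def test_worked_example(self):
        """mean 14, sample SD sqrt(10): threshold 11.628 removes only 10 um."""
        recs = make_records([10.0, 12.0, 14.0, 16.0, 18.0])
        recs, threshold = diameter_filter(recs, FilterParams(k_sd=0.75))
        assert threshold == pytest.approx(14.0 - 0.75 * np.sqrt(10.0), abs=1e-9)
        assert threshold == pytest.approx(11.628, abs=1e-3)
        removed = [r.diameter_um for r in recs if r.status == REMOVED]
        assert removed == [10.0]

    def test_equal_diameters_none_removed(self):
        recs = make_records([14.0] * 6)
        recs, threshold = diameter_filter(recs, FilterParams(k_sd=0.75))
        assert threshold == pytest.approx(14.0)
        assert all(r.status == KEPT for r in recs)

    def test_vacuous_negative_threshold(self):
        recs = make_records([5.0, 10.0, 15.0, 20.0])
        recs, threshold = diameter_filter(recs, FilterParams(k_sd=10.0))
        assert threshold < 0
        assert all(r.status == KEPT for r in recs)

    def test_single_survivor_is_noop_with_warning(self):
        recs = make_records([12.0])
        with pytest.warns(UserWarning):
            recs, threshold = diameter_filter(recs, FilterParams())
        assert threshold is None
        assert recs[0].status == KEPT

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        diams=st.lists(st.floats(1.0, 40.0), min_size=2, max_size=30),
        k_lo=st.floats(0.0, 2.0),
        k_hi=st.floats(0.0, 2.0),
    )
    def test_monotonicity_in_k_sd(self, diams, k_lo, k_hi):
        """Raising k_sd (tighter threshold) never removes fewer records."""
        k_lo, k_hi = sorted((k_lo, k_hi))
        removed = {}
        for k in (k_lo, k_hi):
            recs, _ = diameter_filter(make_records(diams), FilterParams(k_sd=k))
            removed[k] = sum(r.status == REMOVED for r in recs)
        assert removed[k_lo] >= removed[k_hi]


class TestEdgeExclusion:
    def _record_with_coords(self, coords):
        recs = make_records([15.0])
        recs[0].coords = np.asarray(coords)
        return recs

    def test_border_touching_removed(self):
        recs = self._record_with_coords([[0, 5], [1, 5]])
        edge_exclusion(recs, (10, 10))
        assert recs[0].removal_reason == "edge"

    def test_interior_one_pixel_from_border_kept(self):
        recs = self._record_with_coords([[1, 1], [1, 2]])
        edge_exclusion(recs, (10, 10))
        assert recs[0].status == KEPT

    def test_full_tile_instance_removed(self):
        rr, cc = np.mgrid[0:10, 0:10]
        recs = self._record_with_coords(np.column_stack([rr.ravel(), cc.ravel()]))
        edge_exclusion(recs, (10, 10))
        assert recs[0].status == REMOVED


class TestRunFilters:
    def test_empty_map_gives_empty_tally(self):
        part = partition_from_image(np.full((30, 30), 205, dtype=np.uint8))
        inst = InstanceMap(np.zeros((30, 30), dtype=np.int32), 0)
        records, tally = run_filters(inst, part, FilterParams())
        assert (tally.n_unfiltered, tally.n_kept) == (0, 0)
        assert tally.pct_kept is None

    def test_reason_counts_conserve_totals(self, default_partition,
                                           default_instances):
        records, tally = run_filters(default_instances, default_partition,
                                     FilterParams())
        assert tally.n_unfiltered == default_instances.n_instances
        assert sum(tally.removed_by_reason.values()) == (
            tally.n_unfiltered - tally.n_kept
        )
        for rec in records:
            if rec.status == REMOVED:
                assert rec.removal_reason != "none"

    def test_filters_never_alter_pixel_sets(self, default_partition,
                                            default_instances):
        before = default_instances.labels.copy()
        run_filters(default_instances, default_partition, FilterParams())
        assert np.array_equal(default_instances.labels, before)

    def test_frozen_threshold_idempotence(self, default_partition,
                                          default_instances):
        """Re-filtering the kept set under frozen stats removes nothing."""
        records, _ = run_filters(default_instances, default_partition,
                                 FilterParams())
        # freeze mu/sd as the first pass computed them: over the
        # intensity-surviving set, before any diameter removal
        survivors = [r for r in records if r.removal_reason != "intensity"]
        pre = np.array([r.diameter_um for r in survivors])
        frozen = (float(pre.mean()), float(pre.std(ddof=1)))
        kept = [r for r in records if r.status == KEPT]
        kept2, _ = diameter_filter(kept, FilterParams(), frozen_stats=frozen)
        assert all(r.status == KEPT for r in kept2)

    def test_filtered_label_map_zeroes_removed(self, default_partition,
                                               default_instances):
        records, tally = run_filters(default_instances, default_partition,
                                     FilterParams())
        out = filtered_label_map(default_instances, records)
        kept_ids = {r.id for r in records if r.status == KEPT}
        assert set(np.unique(out)) - {0} == kept_ids

    def test_edge_mode_adds_edge_removals(self, default_partition,
                                          default_instances):
        _, plain = run_filters(default_instances, default_partition,
                               FilterParams())
        _, edged = run_filters(default_instances, default_partition,
                               FilterParams(apply_edge_exclusion=True))
        assert edged.n_kept <= plain.n_kept
        assert edged.removed_by_reason.get("edge", 0) > 0


class TestPartitionTally:
    def test_percentages(self):
        tally = PartitionTally(n_unfiltered=200, n_kept=150)
        assert tally.pct_kept == 75.0
        assert tally.pct_excluded == 25.0

    def test_inconsistent_reasons_rejected(self):
        with pytest.raises(ValueError):
            PartitionTally(10, 8, {"intensity": 5})
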