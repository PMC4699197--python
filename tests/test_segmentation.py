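"""Gradient weights, shortest-path solver, five-interface protocol, correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import enumerate_min_path
from octenface import (
    GraphParams,
    InterfaceId,
    Polarity,
    SearchRegion,
    apply_manual_correction,
    edge_weight,
    min_weight_path,
    normalized_gradient,
    segment_five_interfaces,
    segment_volume,
    shortest_path_boundary,
    validate_boundary_set,
    vertical_gradient,
)
from octenface.core import InfeasibleRegionError, ShapeError
from octenface.phantom import PhantomSpec, generate_phantom


class TestVerticalGradient:
    def test_constant_image_has_zero_gradient(self):
        assert np.all(vertical_gradient(np.full((6, 4), 0.3), 0.0) == 0.0)

    def test_step_edge_yields_half_at_adjacent_rows(self):
        img = np.zeros((8, 3))
        img[4:] = 1.0
        grad = vertical_gradient(img, smooth_sigma=0.0)
        assert np.allclose(grad[3], 0.5)
        assert np.allclose(grad[4], 0.5)
        mask = np.ones(8, dtype=bool)
        mask[[3, 4]] = False
        assert np.allclose(grad[mask], 0.0)

    def test_matches_finite_differences(self, rng):
        img = rng.random((6, 6))
        grad = vertical_gradient(img, smooth_sigma=0.0)
        for r in range(1, 5):
            for c in range(6):
                assert grad[r, c] == pytest.approx((img[r + 1, c] - img[r - 1, c]) / 2)
        assert np.allclose(grad[0], img[1] - img[0])
        assert np.allclose(grad[5], img[5] - img[4])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ShapeError):
            vertical_gradient(np.zeros((2, 5)), 0.0)


class TestNormalizedGradient:
    def test_all_negative_is_zero_for_dark_to_bright(self):
        g = normalized_gradient(np.full((4, 4), -0.5), Polarity.DARK_TO_BRIGHT)
        assert np.all(g == 0.0)

    def test_maximum_pixel_maps_to_one(self, rng):
        grad = rng.random((5, 5)) * 0.5
        grad[2, 3] = 0.9
        g = normalized_gradient(grad, Polarity.DARK_TO_BRIGHT)
        assert g[2, 3] == 1.0
        assert g.max() == 1.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_sign_symmetry(self, seed):
        grad = np.random.default_rng(seed).normal(size=(6, 7))
        a = normalized_gradient(grad, Polarity.BRIGHT_TO_DARK)
        b = normalized_gradient(-grad, Polarity.DARK_TO_BRIGHT)
        assert np.array_equal(a, b)


class TestEdgeWeight:
    def test_extremes(self):
        assert edge_weight(1.0, 1.0, 1e-5) == pytest.approx(1e-5)
        assert edge_weight(0.0, 0.0, 1e-5) == pytest.approx(2.0 + 1e-5)

    def test_monotone_decreasing_in_gradient_sum(self):
        grid = np.arange(17) / 16.0  # dyadic: sums are exact in binary
        pairs = [(a, b) for a in grid for b in grid]
        pairs.sort(key=lambda p: p[0] + p[1])
        weights = [edge_weight(a, b) for a, b in pairs]
        sums = [a + b for a, b in pairs]
        for (w1, s1), (w2, s2) in zip(zip(weights, sums), zip(weights[1:], sums[1:])):
            if s2 > s1:
                assert w2 < w1
        assert min(weights) > 0


class TestMinWeightPathOracle:
    """DP solver vs exhaustive path enumeration (cost *and* path)."""

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(120):
            n_rows = int(rng.integers(2, 9))
            n_cols = int(rng.integers(2, 9))
            max_step = int(rng.integers(1, 3))
            if max_step == 2 and n_cols > 6:
                n_cols = 6  # keep enumeration tractable
            g = rng.random((n_rows, n_cols))
            if rng.random() < 0.5:
                lo = np.zeros(n_cols, dtype=int)
                hi = np.full(n_cols, n_rows)
            else:
                lo = rng.integers(0, n_rows - 1, size=n_cols)
                hi = rng.integers(lo + 1, n_rows + 1)
            region = SearchRegion(lo, hi)
            ref_path, ref_cost = enumerate_min_path(g, lo, hi, 1e-5, max_step)
            if ref_path is None:
                with pytest.raises(InfeasibleRegionError):
                    min_weight_path(g, region, 1e-5, max_step)
                continue
            path, cost = min_weight_path(g, region, 1e-5, max_step)
            assert cost == pytest.approx(ref_cost, abs=1e-9), f"trial {trial}"
            assert path.tolist() == ref_path, f"trial {trial}"

    def test_bright_band_recovered_and_matches_enumeration(self):
        img = np.zeros((8, 8))
        img[5:] = 1.0  # step edge at row 5 in every column
        grad = vertical_gradient(img, 0.0)
        g = normalized_gradient(grad, Polarity.DARK_TO_BRIGHT)
        region = SearchRegion.full(8, 8)
        path, cost = min_weight_path(g, region, 1e-5, 1)
        ref_path, ref_cost = enumerate_min_path(
            g, region.min_row, region.max_row, 1e-5, 1)
        assert path.tolist() == ref_path
        assert cost == pytest.approx(ref_cost, abs=1e-9)
        assert set(path.tolist()) <= {4, 5}  # the two half-gradient rows

    def test_uniform_image_ties_break_to_topmost_row(self):
        g = np.zeros((6, 5))
        region = SearchRegion(np.full(5, 2), np.full(5, 6))
        path, _ = min_weight_path(g, region, 1e-5, 5)
        assert path.tolist() == [2] * 5

    def test_restriction_soundness(self, rng):
        for _ in range(20):
            g = rng.random((12, 10))
            lo = rng.integers(0, 10, size=10)
            hi = rng.integers(lo + 1, 13)
            path, _ = min_weight_path(g, SearchRegion(lo, hi), 1e-5, 12)
            assert np.all(path >= lo) and np.all(path < hi)

    def test_empty_region_column_rejected(self):
        with pytest.raises(InfeasibleRegionError):
            SearchRegion(np.array([0, 3]), np.array([4, 3]))


class TestShortestPathBoundary:
    def test_integer_rows_within_image(self, small_phantom):
        vol, _ = small_phantom
        rows = shortest_path_boundary(vol.bscan(0), Polarity.DARK_TO_BRIGHT)
        assert rows.dtype.kind == "i"
        assert rows.shape == (vol.meta.n_ascans,)
        assert np.all((rows >= 0) & (rows < vol.meta.n_depth))


class TestFiveInterfaceProtocol:
    def test_exactly_five_interfaces_in_order(self, small_phantom):
        vol, _ = small_phantom
        paths = segment_five_interfaces(vol.bscan(3))
        assert set(paths) == set(InterfaceId)
        ilm, inl = paths[InterfaceId.VITREOUS_ILM], paths[InterfaceId.INL_OPL]
        onl, ise = paths[InterfaceId.ONL_ISE], paths[InterfaceId.ISE_RPE]
        rpe = paths[InterfaceId.RPE_CHOROID]
        assert np.all(ilm <= inl) and np.all(inl <= onl)
        assert np.all(onl <= ise) and np.all(ise <= rpe)

    def test_flat_phantom_recovered_within_one_pixel(self, flat_phantom):
        vol, truth = flat_phantom
        paths = segment_five_interfaces(vol.bscan(5))
        for iid in InterfaceId:
            err = np.abs(paths[iid] - truth[iid].rows[5])
            assert err.max() <= 1.0, iid

    def test_polarity_symmetry_of_inverted_image(self, flat_phantom):
        """Inverting intensities and swapping polarity yields the same path."""
        vol, _ = flat_phantom
        b = vol.bscan(2)
        region = SearchRegion.full(*b.shape)
        p1 = shortest_path_boundary(b, Polarity.DARK_TO_BRIGHT, region)
        p2 = shortest_path_boundary(1.0 - b, Polarity.BRIGHT_TO_DARK, region)
        assert np.array_equal(p1, p2)

    def test_too_shallow_image_raises(self):
        bscan = np.linspace(0, 1, 8)[:, None] * np.ones((1, 6))
        with pytest.raises(InfeasibleRegionError):
            segment_five_interfaces(bscan, GraphParams(exclude_margin=4))


class TestSegmentVolume:
    def test_grid_shape_and_validity(self, small_phantom):
        vol, _ = small_phantom
        bs = segment_volume(vol)
        assert bs.meta.grid_shape == vol.meta.grid_shape
        assert bs.joint_valid.all()
        assert validate_boundary_set(bs) == []

    def test_identical_bscans_give_identical_rows(self, flat_spec):
        from dataclasses import replace
        from octenface import OCTVolume
        vol, _ = generate_phantom(flat_spec)
        stacked = np.repeat(vol.intensity[:1], 4, axis=0)
        meta = replace(flat_spec.meta, n_bscans=4)
        bs = segment_volume(OCTVolume(intensity=stacked, meta=meta))
        for iid in InterfaceId:
            assert np.all(bs[iid].rows == bs[iid].rows[0])

    def test_failed_bscan_marked_invalid_not_fatal(self, small_phantom):
        from dataclasses import replace
        from octenface import OCTVolume
        vol, _ = small_phantom
        sub = np.array(vol.intensity[:3], copy=True)
        meta = replace(vol.meta, n_bscans=3)
        # an exclude margin larger than the space below the retina makes the
        # RPE/choroid restriction infeasible on every B-scan
        bs = segment_volume(OCTVolume(intensity=sub, meta=meta),
                            GraphParams(exclude_margin=120))
        assert not bs.joint_valid.any()
        assert validate_boundary_set(bs) == []  # invalid rows are excluded


class TestManualCorrection:
    def test_optimal_path_unchanged_by_agreeing_polyline(self, flat_phantom):
        vol, truth = flat_phantom
        b = vol.bscan(1)
        current = shortest_path_boundary(b, Polarity.DARK_TO_BRIGHT)
        poly = [(20.0, float(current[20])), (60.0, float(current[60]))]
        # only meaningful if the current path is straight between the anchors
        assert np.ptp(current[20:61]) == 0
        revised = apply_manual_correction(b, current, poly,
                                          Polarity.DARK_TO_BRIGHT)
        assert np.array_equal(revised, current)

    def test_corrupted_segment_restored_to_truth(self, flat_phantom):
        vol, truth = flat_phantom
        y = 4
        b = vol.bscan(y)
        true_rows = truth[InterfaceId.ONL_ISE].rows[y]
        corrupted = np.array(true_rows, copy=True)
        corrupted[30:70] += 25  # simulated segmentation failure
        poly = [(30.0, true_rows[30]), (69.0, true_rows[69])]
        revised = apply_manual_correction(b, corrupted, poly,
                                          Polarity.DARK_TO_BRIGHT)
        assert np.abs(revised[30:70] - true_rows[30:70]).max() <= 1.0

    def test_columns_outside_range_untouched(self, flat_phantom, rng):
        vol, _ = flat_phantom
        b = vol.bscan(0)
        current = rng.integers(50, 200, size=b.shape[1]).astype(float)
        poly = [(40.0, 100.0), (55.0, 110.0)]
        revised = apply_manual_correction(b, current, poly,
                                          Polarity.DARK_TO_BRIGHT)
        outside = np.ones(b.shape[1], dtype=bool)
        outside[40:56] = False
        assert np.array_equal(revised[outside], current[outside])

    def test_zero_halfwidth_forces_rounded_polyline(self, flat_phantom):
        vol, _ = flat_phantom
        b = vol.bscan(0)
        current = np.full(b.shape[1], 100.0)
        poly = [(10.0, 120.0), (20.0, 130.0)]
        params = GraphParams(correction_halfwidth=0)
        revised = apply_manual_correction(b, current, poly,
                                          Polarity.DARK_TO_BRIGHT, params)
        expected = np.round(np.interp(np.arange(10, 21), [10, 20], [120, 130]))
        assert np.array_equal(revised[10:21], expected)

    def test_polyline_outside_image_rejected(self, flat_phantom):
        vol, _ = flat_phantom
        b = vol.bscan(0)
        with pytest.raises(ValueError):
            apply_manual_correction(b, np.full(b.shape[1], 10.0),
                                    [(5.0, -3.0), (9.0, 4.0)],
                                    Polarity.DARK_TO_BRIGHT)
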