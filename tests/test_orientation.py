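"""Fiber extraction, angle classification and ROI-level orientation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberweave.core import FiberSet, ShgStack, polyline_angle_deg
from fiberweave.orientation import (
    classify_orientation,
    extract_fibers,
    ridge_response,
    roi_orientation_analysis,
    salience_threshold,
)
from fiberweave.phantom import PhantomTruth, gen_fiber_stack, render_fiber_set


class TestClassify:
    def test_four_angle_hand_count(self):
        s = classify_orientation(np.array([0.0, 90.0, 45.0, 178.0]))
        assert s.pct_perpendicular == 50.0       # 0 and 178
        assert s.pct_parallel == 25.0            # 90
        assert s.bimodal is True

    def test_all_parallel(self):
        s = classify_orientation(np.full(20, 90.0))
        assert s.pct_parallel == 100.0
        assert s.pct_perpendicular == 0.0
        assert s.bimodal is False

    def test_no_fibers_summary(self):
        s = classify_orientation(np.array([]))
        assert s.no_fibers
        assert s.pct_perpendicular is None and s.pct_parallel is None
        assert s.bimodal is False

    def test_window_edges_inclusive(self):
        s = classify_orientation(np.array([5.0, 175.0, 85.0, 95.0]))
        assert s.pct_perpendicular == 50.0
        assert s.pct_parallel == 50.0

    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 180, 137)
        s = classify_orientation(a)
        assert s.histogram.sum() == s.n_fibers == 137

    @given(st.lists(st.floats(min_value=0, max_value=179.99), min_size=1,
                    max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_windows_disjoint_no_double_count(self, angles):
        a = np.asarray(angles)
        s = classify_orientation(a)
        in_perp = (a <= 5) | (a >= 175)
        in_par = np.abs(a - 90) <= 5
        assert not np.any(in_perp & in_par)
        assert s.pct_perpendicular + s.pct_parallel <= 100.0 + 1e-9


class TestExtraction:
    def _render(self, fibers, shape=(1, 512, 512), noise=0.0, seed=0):
        fs = FiberSet(fibers=fibers, radius_um=np.full(len(fibers), 5.0))
        return render_fiber_set(fs, shape, (10.62, 1.21, 1.21), 600.0,
                                noise_sigma=noise,
                                rng=np.random.default_rng(seed))

    def test_parallel_tubes_all_90deg(self):
        # 50 tubes along the surface direction across 10 section planes
        fibers = []
        for k in range(10):
            for i in range(5):
                y = (60 + 100 * i) * 1.21
                fibers.append(np.array([[k * 10.62, y, 40.0],
                                        [k * 10.62, y, 580.0]]))
        stack = self._render(fibers, shape=(10, 512, 512))
        fs = extract_fibers(stack, voxel_um=stack.voxel_um)
        assert len(fs) == 50
        assert np.all(np.abs(fs.angles_deg - 90.0) <= 1.0)

    def test_empty_image_gives_empty_fiberset(self):
        stack = ShgStack(data=np.zeros((1, 128, 128)))
        fs = extract_fibers(stack, voxel_um=(10.62, 1.21, 1.21))
        assert len(fs) == 0
        assert classify_orientation(fs).no_fibers

    def test_keep_fraction_one_keeps_all_responding_pixels(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 100, (64, 64))
        resp = ridge_response(img, [2.0])
        cut = salience_threshold(resp, 1.0)
        assert np.array_equal(resp >= cut, resp > 0)

    def test_angle_recovery_matched_fibers(self):
        # ≥90% of traced fibers match a planted fiber within 3°
        truth = PhantomTruth(n_fibers=200, mixture_weights=(0.25, 0.25, 0.5),
                             seed=13)
        stack, fs, _ = gen_fiber_stack(truth, shape_px=(20, 512, 512))
        ext = extract_fibers(stack, voxel_um=stack.voxel_um)
        assert len(ext) > 150
        ok = 0
        true_mids = np.stack([f.mean(axis=0) for f in fs.fibers])
        for poly, ang in zip(ext.fibers, ext.angles_deg):
            mid = poly.mean(axis=0)
            d = np.linalg.norm(true_mids - mid, axis=1)
            candidates = np.argsort(d)[:3]
            best = min(
                min(abs(ang - fs.angles_deg[c]),
                    180 - abs(ang - fs.angles_deg[c]))
                for c in candidates
            )
            ok += best <= 3.0
        assert ok / len(ext) >= 0.9

    def test_percentages_invariant_to_intensity_scaling(self):
        truth = PhantomTruth(n_fibers=60, seed=4)
        stack, _, _ = gen_fiber_stack(truth, shape_px=(6, 512, 512))
        s1 = classify_orientation(extract_fibers(stack, voxel_um=stack.voxel_um))
        scaled = ShgStack(data=stack.data * 0.5, voxel_um=stack.voxel_um)
        s2 = classify_orientation(extract_fibers(scaled, voxel_um=stack.voxel_um))
        assert s1.pct_perpendicular == s2.pct_perpendicular
        assert s1.pct_parallel == s2.pct_parallel

    def test_uniform_mixture_windows_balanced(self):
        # fully diffuse mixture: both 10°-wide windows hold ~10/160 of the
        # diffuse mass; difference within 3 binomial SE
        truth = PhantomTruth(n_fibers=300, mixture_weights=(0.0, 0.0, 1.0),
                             seed=21)
        _, fs, _ = gen_fiber_stack(truth, shape_px=(30, 512, 512))
        s = classify_orientation(fs)
        p = 10.0 / 160.0
        se = 100 * np.sqrt(2 * p * (1 - p) / 300)
        assert abs(s.pct_perpendicular - s.pct_parallel) <= 3 * se + 1e-9


class TestRoiAnalysis:
    def test_homogeneous_phantom_low_pooled_sd(self):
        truth = PhantomTruth(n_fibers=260, mixture_weights=(0.3, 0.3, 0.4),
                             seed=8)
        stack, _, _ = gen_fiber_stack(truth, shape_px=(8, 1000, 1000))
        pooled = roi_orientation_analysis(
            stack, n_rois=3, size_um=(400, 300), margin_px=40, seed=1
        )
        assert pooled.sd_pct_perpendicular < 15
        assert pooled.sd_pct_parallel < 15
        assert len(pooled.per_roi) == 3

    def test_single_roi_degenerate_warning(self):
        truth = PhantomTruth(n_fibers=80, seed=9)
        stack, _, _ = gen_fiber_stack(truth, shape_px=(4, 512, 512))
        with pytest.warns(UserWarning, match="single ROI"):
            pooled = roi_orientation_analysis(
                stack, n_rois=1, size_um=(300, 250), margin_px=20, seed=2
            )
        assert pooled.sd_pct_perpendicular == 0.0


def test_polyline_angle_convention():
    # along the outward normal (y) → 0°; along the surface (x) → 90°
    assert polyline_angle_deg(np.array([[0, 0, 0], [0, 10, 0]])) == pytest.approx(0.0)
    assert polyline_angle_deg(np.array([[0, 0, 0], [0, 0, 10]])) == pytest.approx(90.0)
    assert polyline_angle_deg(np.array([[0, 0, 0], [0, 10, 10]])) == pytest.approx(45.0)
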