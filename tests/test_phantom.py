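"""Phantom generators: determinism, ground-truth consistency, mixtures."""

import numpy as np
import pytest

from fiberweave.core import LAYER_LABELS
from fiberweave.phantom import (
    GenerationError,
    PhantomTruth,
    SizingError,
    gen_fiber_stack,
    gen_layer_image,
    gen_paired_stacks,
    render_fiber_set,
    render_fiber_support,
    sample_mixture_angles,
)

PERP = lambda a: (a <= 5) | (a >= 175)  # noqa: E731
PAR = lambda a: np.abs(a - 90) <= 5     # noqa: E731


class TestLayerImage:
    def test_constant_thickness_exact_counts(self):
        # dorsal 3 cm conditions: SC 0.39, VE 0.05, D 0.8 mm
        truth = PhantomTruth(
            layer_thickness_mm={"SC": 0.39, "VE": 0.05, "D": 0.8},
            boundary_undulation_mm=0.0, seed=0,
        )
        img = gen_layer_image(truth, width_px=100, pixel_size_mm=0.01)
        sc = (img.labels == LAYER_LABELS["SC"]).sum(axis=0)
        assert np.all(sc == round(0.39 / 0.01))

    def test_single_layer_case(self):
        truth = PhantomTruth(
            layer_thickness_mm={"SC": 0.0, "VE": 0.0, "D": 1.0},
            boundary_undulation_mm=0.0, seed=0,
        )
        img = gen_layer_image(truth, width_px=50, pixel_size_mm=0.01)
        assert np.all((img.labels == LAYER_LABELS["D"]).sum(axis=0) == 100)
        assert np.all((img.labels == LAYER_LABELS["SC"]).sum(axis=0) == 0)
        assert np.all((img.labels == LAYER_LABELS["VE"]).sum(axis=0) == 0)

    def test_undulation_mean_recovers_requested_thickness(self):
        truth = PhantomTruth(
            layer_thickness_mm={"SC": 0.5, "VE": 0.0, "D": 0.0},
            boundary_undulation_mm=0.1, seed=7,
        )
        img = gen_layer_image(truth, width_px=1000, pixel_size_mm=0.005)
        sc_mm = (img.labels == LAYER_LABELS["SC"]).sum(axis=0) * 0.005
        assert abs(sc_mm.mean() - 0.5) < 0.01

    def test_sizing_error_names_layer(self):
        truth = PhantomTruth(
            layer_thickness_mm={"SC": 0.1, "VE": 0.1, "D": 5.0},
            boundary_undulation_mm=0.0, seed=0,
        )
        with pytest.raises(SizingError, match="'D'"):
            gen_layer_image(truth, width_px=50, pixel_size_mm=0.01, height_px=100)

    def test_deterministic_given_seed(self):
        truth = PhantomTruth(boundary_undulation_mm=0.05, seed=3)
        a = gen_layer_image(truth, width_px=80, pixel_size_mm=0.01)
        b = gen_layer_image(truth, width_px=80, pixel_size_mm=0.01)
        assert np.array_equal(a.labels, b.labels)


class TestMixtureAngles:
    def test_degenerate_perpendicular_mixture(self):
        truth = PhantomTruth(n_fibers=50, mixture_weights=(1, 0, 0), seed=0)
        _, fs, _ = gen_fiber_stack(truth, shape_px=(6, 256, 256))
        assert np.all(PERP(fs.angles_deg))

    def test_window_fraction_matches_weight(self):
        rng = np.random.default_rng(3)
        a = sample_mixture_angles(rng, 400, (0.25, 0.25, 0.5))
        assert abs(PERP(a).mean() - 0.25) <= 0.05
        assert abs(PAR(a).mean() - 0.25) <= 0.05

    def test_mixture_recovery_converges(self):
        # 3 binomial standard errors at n=1000
        rng = np.random.default_rng(11)
        w = (0.3, 0.3, 0.4)
        a = sample_mixture_angles(rng, 1000, w)
        se = np.sqrt(0.3 * 0.7 / 1000)
        assert abs(PERP(a).mean() - 0.3) <= 3 * se
        assert abs(PAR(a).mean() - 0.3) <= 3 * se

    def test_proximal_dorsal_like_mixture(self):
        # the bimodal ~25%/25% composition reported for the proximal dorsal trunk
        truth = PhantomTruth(n_fibers=400, mixture_weights=(0.25, 0.25, 0.5), seed=5)
        _, fs, em = gen_fiber_stack(truth, shape_px=(20, 380, 380))
        assert abs(PERP(em.fiber_angles_deg).mean() - 0.25) <= 0.07
        assert abs(PAR(em.fiber_angles_deg).mean() - 0.25) <= 0.07


class TestFiberStack:
    def test_bit_identical_given_seed(self):
        truth = PhantomTruth(n_fibers=30, seed=9)
        s1, f1, e1 = gen_fiber_stack(truth, shape_px=(4, 256, 256))
        s2, f2, e2 = gen_fiber_stack(truth, shape_px=(4, 256, 256))
        assert np.array_equal(s1.data, s2.data)
        assert all(np.array_equal(a, b) for a, b in zip(f1.fibers, f2.fibers))
        assert e1.crossing_count == e2.crossing_count

    def test_ground_truth_consistency(self):
        # rendering the emitted FiberSet with zero blur/noise reproduces
        # the stack's binary support exactly
        truth = PhantomTruth(n_fibers=25, seed=2, noise_sigma_frac=0.0,
                             psf_sigma_um=(0, 0, 0))
        stack, fs, _ = gen_fiber_stack(truth, shape_px=(5, 256, 256))
        support = render_fiber_support(fs.fibers, truth.fiber_radius_um,
                                       stack.data.shape, stack.voxel_um)
        assert np.array_equal(stack.data > 0, support)

    def test_planted_crossings_match_bruteforce(self):
        from fiberweave.entanglement import detect_crossings

        truth = PhantomTruth(n_fibers=40, planted_crossing_count=12, seed=4)
        _, fs, emitted = gen_fiber_stack(truth, shape_px=(6, 512, 512))
        res = detect_crossings(fs)
        assert res.crossing_count == emitted.crossing_count == 12

    def test_unreachable_planting_raises(self):
        # an all-parallel mixture cannot produce transversal crossings
        truth = PhantomTruth(n_fibers=10, mixture_weights=(0, 1, 0),
                             planted_crossing_count=3, seed=0)
        with pytest.raises(GenerationError):
            gen_fiber_stack(truth, shape_px=(4, 256, 256), retry_budget=40)

    def test_stack_intensities_within_12bit(self):
        truth = PhantomTruth(n_fibers=30, intensity_scale=4000.0, seed=1)
        stack, _, _ = gen_fiber_stack(truth, shape_px=(4, 256, 256))
        assert stack.data.min() >= 0 and stack.data.max() <= 4095


class TestPairedStacks:
    def test_identity_ratio(self):
        base = PhantomTruth(n_fibers=30, intensity_scale=500.0,
                            noise_sigma_frac=0.0, psf_sigma_um=(0, 0, 0), seed=6)
        v, d = gen_paired_stacks(base, 1.0, shape_px=(2, 256, 256))
        assert np.allclose(v.data, d.data)

    @pytest.mark.parametrize("ratio", [2.0, 6.0])
    def test_true_onfiber_ratio_exact_before_noise(self, ratio):
        base = PhantomTruth(n_fibers=40, intensity_scale=500.0,
                            noise_sigma_frac=0.0, psf_sigma_um=(0, 0, 0), seed=6)
        v, d = gen_paired_stacks(base, ratio, shape_px=(2, 256, 256))
        on = d.data > 0
        assert np.allclose(v.data[on] / d.data[on], ratio)

    def test_clip_warning_above_ceiling(self):
        base = PhantomTruth(n_fibers=10, intensity_scale=1000.0, seed=0)
        v, _ = gen_paired_stacks(base, 6.0, shape_px=(1, 256, 256))
        assert any(e.get("clip_warning") for e in v.processing_log)

    def test_no_warning_within_ceiling(self):
        base = PhantomTruth(n_fibers=10, intensity_scale=500.0, seed=0)
        v, _ = gen_paired_stacks(base, 2.0, shape_px=(1, 256, 256))
        assert not any(e.get("clip_warning") for e in v.processing_log)


def test_truth_invariants_validated():
    with pytest.raises(ValueError):
        PhantomTruth(mixture_weights=(0.5, 0.6, 0.1))
    with pytest.raises(ValueError):
        PhantomTruth(planted_crossing_count=-1)
    with pytest.raises(ValueError):
        PhantomTruth(layer_thickness_mm={"SC": -0.1})
    with pytest.raises(ValueError):
        PhantomTruth(fiber_angles_deg=[181.0])
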