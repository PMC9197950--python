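import numpy as np
import pytest
from scipy import ndimage

from conftest import quiet_config
from funduschange.synthetic import (SimConfig, apply_illumination,
                                    generate_background,
                                    generate_background_with_vessel_map,
                                    generate_pair, inject_lesions)


class TestBackground:
    def test_vignette_only_is_radially_monotone(self):
        cfg = quiet_config(height=101, width=101, n_vessels=0)
        img = generate_background(cfg)
        cy = cx = 50
        for row, col in [(img[cy, cx:], None), (img[cy, cx::-1], None),
                         (img[cy:, cx], None), (img[cy::-1, cx], None),
                         (np.diagonal(img[cy:, cx:]), None)]:
            assert np.all(np.diff(row) <= 1e-12)

    def test_deterministic_per_seed(self):
        cfg = SimConfig(seed=7)
        assert np.array_equal(generate_background(cfg),
                              generate_background(cfg))

    def test_different_seeds_differ(self):
        a = generate_background(SimConfig(seed=1))
        b = generate_background(SimConfig(seed=2))
        assert not np.array_equal(a, b)

    def test_vessels_darker_than_local_background(self):
        cfg = quiet_config(height=128, width=128, seed=3)
        img, centerline = generate_background_with_vessel_map(cfg)
        assert centerline.sum() > 50
        local_bg = ndimage.median_filter(img, size=15)
        darker = img[centerline] < local_bg[centerline]
        assert darker.mean() > 0.9
        assert img[centerline].mean() < local_bg[centerline].mean()

    def test_values_in_unit_range(self):
        img = generate_background(SimConfig(seed=11))
        assert img.min() >= 0 and img.max() <= 1


class TestIllumination:
    def test_no_op_configuration_is_identity(self, rng):
        img = rng.random((32, 32))
        cfg = quiet_config(height=32, width=32)
        assert np.array_equal(apply_illumination(img, cfg, "current"), img)

    def test_output_clipped_to_unit_range(self):
        cfg = SimConfig(seed=4, gain_amplitude=0.5, bias_amplitude=0.3)
        img = generate_background(cfg)
        out = apply_illumination(img, cfg, "current")
        assert out.min() >= 0 and out.max() <= 1

    def test_mean_change_bounded_by_amplitudes(self):
        cfg = SimConfig(seed=5, gain_amplitude=0.15, bias_amplitude=0.04,
                        bump_count=0)
        img = generate_background(cfg)
        out = apply_illumination(img, cfg, "reference")
        assert np.mean(np.abs(out - img)) <= 0.15 + 0.04 + 1e-12

    def test_reference_and_current_draws_differ(self):
        cfg = SimConfig(seed=6)
        img = generate_background(cfg)
        a = apply_illumination(img, cfg, "reference")
        b = apply_illumination(img, cfg, "current")
        assert not np.array_equal(a, b)

    def test_invalid_which_rejected(self):
        with pytest.raises(ValueError):
            apply_illumination(np.zeros((4, 4)), SimConfig(), "future")


class TestLesions:
    def test_no_lesions_is_identity(self):
        cfg = quiet_config(n_lesions=0)
        img = generate_background(cfg)
        out, truth = inject_lesions(img, cfg)
        assert np.array_equal(out, img) and not truth.any()

    def test_blend_is_exact_half_mix(self):
        # 41x41 lesion blended with coefficient 0.5: inside the support
        # out = (background + texture) / 2 exactly
        from funduschange.synthetic import (_inject_lesions_meta,
                                            lesion_texture)
        cfg = quiet_config(height=128, width=128, seed=9, n_lesions=1,
                           lesion_size_range=(41, 41), blend_alpha=0.5,
                           lesion_contrast=0.3)
        img = generate_background(cfg)
        out, truth, lesions = _inject_lesions_meta(img, cfg)
        texture = lesion_texture(img, truth, tuple(lesions[0]["offset"]),
                                 cfg.lesion_contrast)
        assert np.allclose(out[truth], (img[truth] + texture[truth]) / 2,
                           atol=1e-12)
        assert np.all(out[~truth] == img[~truth])
        # deep interior carries displaced anatomy at the full contrast shift
        interior = ndimage.binary_erosion(truth, iterations=4)
        delta_interior = out[interior] - img[interior]
        assert delta_interior.mean() > 0.05

    def test_truth_area_equals_sum_of_supports(self):
        cfg = SimConfig(seed=12)
        sp = generate_pair(cfg)
        assert sp.truth.sum() == sum(l["area"] for l in sp.metadata["lesions"])

    def test_lesions_avoid_border(self):
        cfg = SimConfig(seed=13, n_lesions=5)
        sp = generate_pair(cfg)
        assert not sp.truth[0].any() and not sp.truth[-1].any()
        assert not sp.truth[:, 0].any() and not sp.truth[:, -1].any()

    def test_impossible_placement_raises(self):
        cfg = quiet_config(height=40, width=40, n_lesions=1,
                           lesion_size_range=(30, 30))
        with pytest.raises((ValueError, RuntimeError)):
            inject_lesions(generate_background(cfg), cfg)


class TestGeneratePair:
    def test_degenerate_pair_is_identical(self):
        sp = generate_pair(quiet_config(seed=1))
        assert np.array_equal(sp.pair.reference, sp.pair.current)
        assert not sp.truth.any()

    def test_determinism_contract(self):
        a = generate_pair(SimConfig(seed=21))
        b = generate_pair(SimConfig(seed=21))
        assert np.allclose(a.pair.reference, b.pair.reference, atol=1e-12)
        assert np.allclose(a.pair.current, b.pair.current, atol=1e-12)
        assert np.array_equal(a.truth, b.truth)

    def test_lesion_pixels_differ_from_reference(self):
        deltas = []
        for seed in range(5):
            sp = generate_pair(SimConfig(seed=seed, jitter=0.0))
            deltas.append(
                np.abs(sp.pair.current - sp.pair.reference)[sp.truth].mean())
        assert np.mean(deltas) >= 0.05

    def test_each_nuisance_is_independently_switchable(self):
        base = generate_pair(quiet_config(seed=2))
        noisy = generate_pair(quiet_config(seed=2, noise_sigma=0.01))
        lit = generate_pair(quiet_config(seed=2, gain_amplitude=0.1))
        assert np.array_equal(base.pair.reference, base.pair.current)
        assert not np.array_equal(noisy.pair.reference, noisy.pair.current)
        assert not np.array_equal(lit.pair.reference, lit.pair.current)
        # anatomy shared: lesion truth empty in all three
        assert not (base.truth.any() or noisy.truth.any() or lit.truth.any())

    def test_jitter_shifts_current_subpixel(self):
        still = generate_pair(quiet_config(seed=3))
        moved = generate_pair(quiet_config(seed=3, jitter=0.8))
        assert not np.array_equal(moved.pair.current, still.pair.current)
        assert np.array_equal(moved.pair.reference, still.pair.reference)
        assert max(abs(s) for s in moved.metadata["jitter_shift"]) <= 0.8


@pytest.mark.parametrize("kwargs", [
    {"blend_alpha": 1.5},
    {"lesion_size_range": (10, 5)},
    {"gain_amplitude": -0.1},
    {"height": 0},
])
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)
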