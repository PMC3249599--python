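"""Texture feature suite: registry inventory, per-family semantics and
oracle equivalence against brute-force implementations."""

import numpy as np
import pytest

from ustex.features import (
    blanket_areas,
    dbc_box_counts,
    dbc_fd,
    default_registry,
    ecm_features,
    extract_all,
    fos_features,
    fourier_features,
    gabor_features,
    glcm_matrix,
    haralick_features,
    laws_features,
    morph_fd,
    mrfd_features,
    ngtdm_features,
    ngtdm_table,
    phase_congruency_map,
    phasecong_features,
    quantize,
    synthesize_fbm_surface,
    tfcm_features,
)
from ustex.features.registry import GABOR_FREQUENCIES, GABOR_ORIENTATIONS

import oracles


def patches(rng, n, side=64, lo=0, hi=256):
    return [rng.integers(lo, hi, (side, side)) for _ in range(n)]


class TestRegistry:
    def test_inventory_is_234(self):
        reg = default_registry()
        assert len(reg) == 234
        assert len(set(reg.names)) == 234
        by_family = {fam: len(names) for fam, names in reg.families.items()}
        assert by_family == {
            "fos": 6, "ngtdm": 5, "glcm": 104, "mrfd": 5, "dbc": 1,
            "morph": 4, "fourier": 14, "gabor": 48, "laws": 25,
            "ecm": 13, "pc": 5, "tfcm": 4,
        }

    def test_extract_all_length_and_finiteness(self, random_patch):
        v = extract_all(random_patch)
        assert v.shape == (234,)
        assert np.all(np.isfinite(v))

    def test_extract_all_deterministic(self, random_patch):
        np.testing.assert_array_equal(
            extract_all(random_patch), extract_all(random_patch)
        )

    def test_extract_all_rejects_wrong_size(self):
        with pytest.raises(ValueError, match="64x64"):
            extract_all(np.zeros((32, 32)))

    @pytest.mark.parametrize(
        "make",
        [
            lambda: np.zeros((64, 64), dtype=int),
            lambda: np.full((64, 64), 255, dtype=int),
            lambda: np.indices((64, 64)).sum(0) % 2 * 255,  # checkerboard
            lambda: np.eye(64, dtype=int) * 255,
            lambda: np.pad(np.array([[255]]), ((30, 33), (30, 33))),  # impulse
        ],
        ids=["black", "white", "checkerboard", "diagonal", "impulse"],
    )
    def test_totality_on_degenerate_patches(self, make):
        v = extract_all(make())
        assert np.all(np.isfinite(v))


class TestQuantize:
    def test_uniform_binning(self):
        assert quantize(np.array([[255]]), 32)[0, 0] == 31
        assert quantize(np.array([[0]]), 32)[0, 0] == 0
        assert quantize(np.array([[8]]), 32)[0, 0] == 1

    def test_histogram_equals_rebinned(self, random_patch):
        q = quantize(random_patch, 32)
        hist_q = np.bincount(q.ravel(), minlength=32)
        hist_raw = np.bincount(random_patch.ravel(), minlength=256)
        np.testing.assert_array_equal(hist_q, hist_raw.reshape(32, 8).sum(1))

    def test_rejects_small_levels(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((4, 4)), 1)


class TestFirstOrder:
    def test_constant_patch(self, constant_patch):
        np.testing.assert_allclose(
            fos_features(constant_patch), [100, 0, 0, 0, 1, 0], atol=1e-12
        )

    def test_two_value_symmetry(self):
        patch = np.zeros((64, 64), dtype=int)
        patch[:32] = 255
        mean, std, skew, kurt, energy, entropy = fos_features(patch)
        assert entropy == pytest.approx(1.0)
        assert energy == pytest.approx(0.5)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_matches_moment_oracle(self, rng):
        for patch in patches(rng, 20, side=16):
            np.testing.assert_allclose(
                fos_features(patch), oracles.fos_moments_naive(patch), atol=1e-9
            )


class TestGlcm:
    def test_toy_example_counts(self):
        toy = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])
        mat = glcm_matrix(toy, 1, 0, levels=4)
        counts = mat * 24  # total symmetric pair count
        expected = np.array(
            [[4, 2, 1, 0], [2, 4, 0, 0], [1, 0, 6, 1], [0, 0, 1, 2]]
        )
        np.testing.assert_allclose(counts, expected, atol=1e-9)

    def test_constant_patch_single_cell(self, constant_patch):
        mat = glcm_matrix(quantize(constant_patch, 32), 1, 0)
        assert mat[12, 12] == pytest.approx(1.0)
        assert mat.sum() == pytest.approx(1.0)

    def test_normalization_and_symmetry(self, rng):
        for patch in patches(rng, 20, side=16):
            q = quantize(patch, 32)
            for d in (1, 2):
                for a in (0, 45, 90, 135):
                    mat = glcm_matrix(q, d, a)
                    assert mat.sum() == pytest.approx(1.0, abs=1e-12)
                    np.testing.assert_allclose(mat, mat.T, atol=1e-15)

    def test_matches_enumeration_oracle(self, rng):
        for patch in patches(rng, 25, side=12):
            q = quantize(patch, 8)
            for d in (1, 2):
                for a in (0, 45, 90, 135):
                    np.testing.assert_allclose(
                        glcm_matrix(q, d, a, levels=8),
                        oracles.glcm_naive(q, d, a, 8),
                        atol=1e-9,
                    )


class TestHaralick:
    def test_constant_patch_conventions(self, constant_patch):
        feats = haralick_features(glcm_matrix(quantize(constant_patch, 32), 1, 0))
        asm, contrast, correlation, _, idm = feats[:5]
        entropy = feats[8]
        assert asm == pytest.approx(1.0)
        assert contrast == pytest.approx(0.0)
        assert correlation == 0.0  # zero-variance convention
        assert idm == pytest.approx(1.0)
        assert entropy == pytest.approx(0.0)

    def test_checkerboard_contrast_is_one(self):
        # two adjacent quantization bins alternating -> every horizontal
        # pair differs by exactly one level
        board = np.indices((64, 64)).sum(0) % 2  # values 0 / 1
        mat = glcm_matrix(board, 1, 0, levels=2)
        contrast = haralick_features(mat)[1]
        assert contrast == pytest.approx(1.0)

    def test_all_finite_on_random_patches(self, rng):
        for patch in patches(rng, 100, side=16):
            feats = haralick_features(glcm_matrix(quantize(patch, 32), 1, 45))
            assert np.all(np.isfinite(feats))

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            haralick_features(np.ones((4, 4)))


class TestNgtdm:
    def test_constant_patch_guards(self, constant_patch):
        q = quantize(constant_patch, 32)
        coarse, contrast, busy, complexity, strength = ngtdm_features(q)
        assert contrast == 0.0
        assert busy == 0.0

    def test_single_bright_pixel_contrast_positive(self):
        q = np.zeros((64, 64), dtype=int)
        q[30, 30] = 20
        assert ngtdm_features(q)[1] > 0

    def test_matches_loop_oracle(self, rng):
        for patch in patches(rng, 12, side=16):
            q = quantize(patch, 16)
            s, n = ngtdm_table(q, 16)
            s_ref, n_ref = oracles.ngtdm_naive(q, 16)
            np.testing.assert_allclose(s, s_ref, atol=1e-9)
            np.testing.assert_allclose(n, n_ref, atol=1e-9)


class TestFractal:
    def test_constant_patch_dimensions(self, constant_patch):
        np.testing.assert_allclose(
            mrfd_features(constant_patch), [2, 2, 2, 2, 0], atol=1e-12
        )
        assert dbc_fd(constant_patch) == pytest.approx(2.0, abs=0.05)
        np.testing.assert_allclose(morph_fd(constant_patch), [2, 2, 2, 2], atol=0.05)

    def test_mrfd_increments_match_pair_loop(self, rng):
        patch = rng.integers(0, 256, (16, 16))
        from ustex.features.fractal import _chebyshev_increment_means

        m = _chebyshev_increment_means(patch, lags=(1, 2, 4))
        for k, got in zip((1, 2, 4), m):
            assert got == pytest.approx(oracles.mrfd_increment_naive(patch, k))

    def test_fbm_dimension_recovery(self, rng):
        fds = []
        for _ in range(5):
            surface = synthesize_fbm_surface(64, 0.5, rng)
            fds.append(mrfd_features(surface)[3])
        assert np.mean(fds) == pytest.approx(2.5, abs=0.15)

    def test_mrfd_range_clipped(self, rng):
        for patch in patches(rng, 50):
            fd = mrfd_features(patch)[3]
            assert 2.0 <= fd <= 3.0

    def test_dbc_counts_match_cell_loop(self, rng):
        for patch in patches(rng, 10):
            np.testing.assert_allclose(
                dbc_box_counts(patch),
                oracles.dbc_counts_naive(patch, (2, 4, 8, 16, 32)),
                atol=1e-9,
            )

    def test_dbc_monotone_under_noise(self, rng):
        base = (127 + 60 * np.sin(np.arange(64) / 6.0))[None, :] * np.ones((64, 1))
        noisy = np.clip(base + rng.normal(0, 40, (64, 64)), 0, 255)
        assert dbc_fd(noisy) > dbc_fd(np.clip(base, 0, 255))

    def test_blanket_area_non_increasing(self, rng):
        for patch in patches(rng, 20, side=32):
            areas = blanket_areas(patch)
            assert np.all(np.diff(areas) <= 1e-9)

    def test_blanket_first_step_matches_loop(self, rng):
        patch = rng.integers(0, 256, (16, 16))
        assert blanket_areas(patch)[0] == pytest.approx(
            oracles.blanket_area1_naive(patch)
        )


class TestFourier:
    def test_constant_patch_all_zero(self, constant_patch):
        np.testing.assert_array_equal(fourier_features(constant_patch), np.zeros(14))

    def test_sinusoid_lands_in_expected_bands(self):
        x = np.arange(64)
        patch = 127 + 100 * np.sin(2 * np.pi * x / 8.0)[None, :] * np.ones((64, 1))
        feats = fourier_features(np.clip(patch, 0, 255))
        rings, wedges = feats[:8], feats[8:]
        expected_ring = np.digitize(8.0, 4.0 * np.arange(1, 8))
        assert rings[expected_ring] > 0.9
        assert np.argmax(wedges) == 0  # horizontal wave vector

    def test_bands_sum_to_one(self, rng):
        for patch in patches(rng, 20):
            feats = fourier_features(patch)
            assert feats[:8].sum() == pytest.approx(1.0, abs=1e-9)
            assert feats[8:].sum() == pytest.approx(1.0, abs=1e-9)


class TestGabor:
    def test_constant_patch_silent(self, constant_patch):
        np.testing.assert_allclose(gabor_features(constant_patch), 0, atol=1e-9)

    @pytest.mark.parametrize("orientation", [0, 60, 120])
    def test_oriented_sinusoid_peaks_at_matched_filter(self, orientation):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        t = np.radians(float(orientation))
        grating = 127 + 100 * np.sin(
            2 * np.pi * 0.1 * (xx * np.cos(t) + yy * np.sin(t))
        )
        feats = gabor_features(np.clip(grating, 0, 255))
        means = feats[0::2].reshape(len(GABOR_FREQUENCIES), len(GABOR_ORIENTATIONS))
        f_idx, o_idx = np.unravel_index(np.argmax(means), means.shape)
        assert GABOR_FREQUENCIES[f_idx] == 0.1
        assert GABOR_ORIENTATIONS[o_idx] == orientation

    def test_offset_invariance(self, rng):
        patch = rng.integers(0, 200, (64, 64))
        shifted = patch + 50
        np.testing.assert_allclose(
            gabor_features(patch), gabor_features(shifted), atol=1e-8
        )


class TestPhaseCongruency:
    def test_constant_patch_zero_map(self, constant_patch):
        np.testing.assert_array_equal(
            phasecong_features(constant_patch), np.zeros(5)
        )

    def test_map_range(self, rng):
        for patch in patches(rng, 10):
            pc = phase_congruency_map(patch)
            assert pc.min() >= 0.0 and pc.max() <= 1.0

    def test_step_edge_dominates(self):
        patch = np.zeros((64, 64))
        patch[:, 32:] = 200.0
        pc = phase_congruency_map(patch)
        on_edge = pc[:, 30:34].mean()
        off_edge = pc[:, list(range(8, 24)) + list(range(40, 56))].mean()
        assert on_edge >= 3 * off_edge


class TestLaws:
    def test_constant_patch_zero(self, constant_patch):
        np.testing.assert_allclose(laws_features(constant_patch), 0, atol=1e-9)

    def test_vertical_step_edge_direction(self):
        patch = np.zeros((64, 64))
        patch[:, 32:] = 200.0
        feats = dict(zip(default_registry().families["laws"], laws_features(patch)))
        # a vertical edge varies horizontally: the L5(row) x E5(col) mask
        # must respond more than its transpose
        assert feats["laws_L5E5"] > feats["laws_E5L5"]

    def test_l5e5_matches_convolution_loop(self, rng):
        patch = rng.integers(0, 256, (12, 12))
        feats = dict(zip(default_registry().families["laws"], laws_features(patch)))
        assert feats["laws_L5E5"] == pytest.approx(
            oracles.laws_energy_naive(patch, "L5", "E5")
        )

    def test_random_patches_match_loop(self, rng):
        names = default_registry().families["laws"]
        for patch in patches(rng, 3, side=10):
            feats = dict(zip(names, laws_features(patch)))
            for pair in (("E5", "S5"), ("R5", "L5")):
                assert feats[f"laws_{pair[0]}{pair[1]}"] == pytest.approx(
                    oracles.laws_energy_naive(patch, *pair)
                )


class TestEdgeCooccurrence:
    def test_constant_patch(self, constant_patch):
        feats = ecm_features(constant_patch)
        assert feats[0] == pytest.approx(1.0)  # ASM
        assert feats[1] == pytest.approx(0.0)  # contrast

    def test_compositional_oracle(self, rng):
        from ustex.features.cooccurrence import sobel_magnitude

        patch = rng.integers(0, 256, (64, 64))
        mag = sobel_magnitude(patch)
        q = np.minimum((mag * 16 / mag.max()).astype(int), 15)
        mats = [oracles.glcm_naive(q, 1, a, 16) for a in (0, 45, 90, 135)]
        expected = haralick_features(np.mean(mats, axis=0))
        np.testing.assert_allclose(ecm_features(patch), expected, atol=1e-9)

    def test_gray_inversion_invariance(self, rng):
        patch = rng.integers(0, 256, (64, 64))
        np.testing.assert_allclose(
            ecm_features(patch), ecm_features(255 - patch), atol=1e-9
        )


class TestTfcm:
    def test_constant_patch(self, constant_patch):
        coarse, homog, conv, var = tfcm_features(constant_patch)
        assert homog == pytest.approx(1.0)
        assert var == pytest.approx(0.0)

    def test_tolerance_absorbs_small_stripes(self, constant_patch):
        stripes = constant_patch + (np.arange(64)[None, :] % 2)  # contrast 1 <= delta
        np.testing.assert_array_equal(
            tfcm_features(stripes), tfcm_features(constant_patch)
        )

    def test_matches_per_pixel_oracle(self, rng):
        for patch in patches(rng, 15, side=8):
            np.testing.assert_allclose(
                tfcm_features(patch),
                oracles.tfcm_features_naive(patch),
                atol=1e-9,
            )


class TestDiscriminativeSanity:
    def test_correlation_length_classes_separate(self, rng):
        """Two texture classes with different correlation lengths must move
        a substantial share of the registry (no dead feature families)."""
        from scipy import ndimage

        def sample(corr):
            f = ndimage.gaussian_filter(rng.standard_normal((64, 64)), corr)
            f = (f - f.mean()) / f.std() * 40 + 127
            return np.clip(f, 0, 255).astype(int)

        a = np.array([extract_all(sample(1.0)) for _ in range(15)])
        b = np.array([extract_all(sample(3.0)) for _ in range(15)])
        pooled_sd = np.sqrt((a.var(0, ddof=1) + b.var(0, ddof=1)) / 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.abs(a.mean(0) - b.mean(0)) / pooled_sd
        assert np.sum(d[np.isfinite(d)] > 1.0) >= 20
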