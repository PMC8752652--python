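import numpy as np
import pytest

from mammofeat.io import LAWS_MASK_NAMES
from mammofeat.synthetic import fbm_texture
from mammofeat.texture import (
    SGLCM_KEYS,
    _haralick,
    compute_fos_features,
    compute_fps_features,
    compute_fractal_features,
    compute_glds_features,
    compute_ltem_features,
    compute_sfm_features,
    compute_sglcm_features,
    compute_texture_features,
    glcm_matrices,
    laws_mask_bank,
    quantize,
    sfm_dissimilarity,
)

CONSTANT = np.full((16, 16), 120, np.uint8)


def random_roi(seed, shape=(24, 24)):
    return np.random.default_rng(seed).integers(0, 256, shape).astype(np.uint8)


class TestQuantize:
    def test_small_range_preserved(self):
        img = np.array([[5, 6], [7, 8]])
        np.testing.assert_array_equal(quantize(img, 32), [[0, 1], [2, 3]])

    def test_wide_range_compressed(self):
        img = np.arange(256).reshape(16, 16)
        q = quantize(img, 32)
        assert q.min() == 0 and q.max() == 31


class TestSGLCM:
    def test_worked_image_horizontal_pair_count(self):
        """Symmetric count of horizontally adjacent (0,0) pairs is 4."""
        img = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])
        mats = glcm_matrices(img)
        n_pairs = 2 * 3 * 4  # symmetric: 12 ordered horizontal pairs, twice
        assert mats[0, 0, 0] * n_pairs == pytest.approx(4.0)

    def test_checkerboard_horizontal_contrast(self):
        """Every horizontal pair differs by G-1, so contrast = (G-1)^2."""
        g = 32
        cb = np.tile(np.array([[0, g - 1], [g - 1, 0]], np.uint8), (4, 4))
        mats = glcm_matrices(cb, levels=g)
        assert _haralick(mats[:, :, 0])["Contrast"] == pytest.approx((g - 1) ** 2)

    def test_constant_roi_degenerates(self):
        f = compute_sglcm_features(CONSTANT)
        assert f["ASM"] == pytest.approx(1.0)
        assert f["Entropy"] == pytest.approx(0.0)
        assert f["Contrast"] == pytest.approx(0.0)
        assert f["Inverse diff moment"] == pytest.approx(1.0)
        assert f["Correlation"] == 0.0 and f["Max Corr Coff"] == 0.0

    def test_matrices_are_distributions(self):
        mats = glcm_matrices(random_roi(0))
        for a in range(4):
            m = mats[:, :, a]
            assert m.min() >= 0
            assert m.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(m, m.T, atol=1e-12)

    def test_probability_invariants(self):
        f = compute_sglcm_features(random_roi(1))
        assert 0 < f["ASM"] <= 1
        assert f["Entropy"] >= 0 and f["Sum entropy"] >= 0 and f["Diff entropy"] >= 0
        assert len(f) == 14 and list(f) == SGLCM_KEYS


class TestGLDS:
    def test_constant_roi(self):
        f = compute_glds_features(CONSTANT)
        assert f == {
            "Homogeneity": 1.0, "Contrast": 0.0, "Mean": 0.0,
            "Energy": 1.0, "Entropy": 0.0,
        }

    def test_checkerboard_single_delta(self):
        """All horizontal differences equal 1 (verified by enumerating pairs)."""
        cb = np.tile(np.array([[0, 1], [1, 0]], np.uint8), (4, 4))
        f = compute_glds_features(cb, deltas=((0, 1),))
        assert f["Mean"] == pytest.approx(1.0)
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Energy"] == pytest.approx(1.0)
        assert f["Entropy"] == pytest.approx(0.0)
        assert f["Homogeneity"] == pytest.approx(0.5)

    def test_density_axioms(self):
        from mammofeat.texture import _difference_histogram

        q = quantize(random_roi(2), 32)
        for delta in ((0, 1), (1, 0), (1, 1), (1, -1)):
            p = _difference_histogram(q, delta)
            assert p.min() >= 0
            assert p.sum() == pytest.approx(1.0)
        f = compute_glds_features(random_roi(2))
        assert f["Entropy"] >= 0

    def test_offset_invariance(self):
        roi = random_roi(3) // 2  # keep headroom for the offset
        f1 = compute_glds_features(roi)
        f2 = compute_glds_features(roi + 20)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k])


class TestFOS:
    def test_worked_example(self):
        f = compute_fos_features(np.array([[1, 1], [3, 3]]))
        assert f == {"Mean": 2.0, "Variance": 1.0, "Skewness": 0.0, "Kurtosis": 1.0}

    def test_constant_fallback(self):
        f = compute_fos_features(np.full((4, 4), 9))
        assert f == {"Mean": 9.0, "Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}

    def test_histogram_equals_pixelwise_moments(self):
        """Histogram-form moments agree with the raw pixelwise oracle."""
        roi = random_roi(4)
        x = roi.astype(float).ravel()
        f = compute_fos_features(roi)
        assert f["Mean"] == pytest.approx(x.mean())
        assert f["Variance"] == pytest.approx(np.mean((x - x.mean()) ** 2))
        sd = x.std()
        assert f["Skewness"] == pytest.approx(np.mean((x - x.mean()) ** 3) / sd**3)


class TestSFM:
    def test_zero_displacement_dissimilarity(self):
        q = quantize(random_roi(5), 32)
        dss, _ = sfm_dissimilarity(q, 4, 4)
        assert dss[0, 0] == 0.0

    def test_constant_roi(self):
        f = compute_sfm_features(CONSTANT)
        assert f["Contrast"] == 0.0 and f["Coarseness"] == 0.0

    def test_striped_more_periodic_than_noise(self):
        """Period-2 stripes produce deep dissimilarity valleys; white noise
        of matched variance does not (20 paired trials)."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            stripes = np.tile(np.array([0, 200], np.uint8), (24, 12))
            noise = rng.integers(0, 2, (24, 24)).astype(np.uint8) * 200
            ps = compute_sfm_features(stripes)["Periodicity"]
            pn = compute_sfm_features(noise)["Periodicity"]
            wins += ps > pn
        assert wins == 20

    def test_offset_invariance(self):
        roi = random_roi(6) // 2
        f1 = compute_sfm_features(roi)
        f2 = compute_sfm_features(roi + 30)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k])


class TestLTEM:
    def test_bank_structure(self):
        bank = laws_mask_bank()
        assert list(bank) == LAWS_MASK_NAMES and len(bank) == 14
        for name, mask in bank.items():
            assert mask.shape == (5, 5)
            if set(name) & set("ESWR"):
                assert mask.sum() == pytest.approx(0.0)

    def test_constant_roi_zero_energy(self):
        f = compute_ltem_features(CONSTANT)
        assert all(v == pytest.approx(0.0) for v in f.values())

    def test_ramp_el_energy_closed_form(self):
        """On I(x,y)=x the L5(col)E5(row) arm responds 16*8 = 128 everywhere
        and the E5(col)L5(row) arm responds 0; the averaged energy is 64."""
        ramp = np.tile(np.arange(16, dtype=float), (16, 1))
        f = compute_ltem_features(ramp)
        assert f["EL"] == pytest.approx(64.0)
        assert f["EE"] == pytest.approx(0.0)

    def test_too_small_roi_rejected(self):
        with pytest.raises(ValueError):
            compute_ltem_features(np.zeros((4, 6)))

    def test_offset_invariance(self):
        roi = random_roi(7).astype(float)
        f1 = compute_ltem_features(roi)
        f2 = compute_ltem_features(roi + 55.0)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9)


class TestFractal:
    def test_constant_fallback(self):
        assert compute_fractal_features(CONSTANT) == {"H1": 0.0, "H2": 0.0}

    def test_hurst_ordering(self):
        """Rougher synthesized textures yield lower estimated H (5 seeds)."""
        means = {}
        for h in (0.3, 0.7):
            est = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                img = 128 + 25 * fbm_texture((64, 64), h, rng)
                est.append(compute_fractal_features(img)["H1"])
            means[h] = np.mean(est)
        assert means[0.3] < means[0.7]

    def test_estimates_clipped(self):
        f = compute_fractal_features(random_roi(8, (32, 32)))
        assert 0 <= f["H1"] <= 1 and 0 <= f["H2"] <= 1

    def test_offset_invariance(self):
        roi = random_roi(9, (32, 32)).astype(float)
        f1 = compute_fractal_features(roi)
        f2 = compute_fractal_features(roi + 40.0)
        assert f1 == pytest.approx(f2)


class TestFPS:
    def test_constant_roi(self):
        assert compute_fps_features(CONSTANT) == {"Sr": 0.0, "Stheta": 0.0}

    def test_horizontal_sinusoid_in_annulus(self):
        x = np.arange(64)
        img = 128 + 100 * np.sin(2 * np.pi * (12 / 64) * x)[None, :] * np.ones((64, 1))
        f = compute_fps_features(img)
        assert f["Sr"] >= 0.99
        assert f["Stheta"] >= 0.99  # horizontal variation lies in the wedge

    def test_parseval_identity(self):
        img = random_roi(10).astype(float)
        spec = np.abs(np.fft.fft2(img)) ** 2
        assert spec.sum() == pytest.approx(img.size * np.sum(img**2), rel=1e-6)

    def test_fractions_bounded(self):
        f = compute_fps_features(random_roi(11))
        assert 0 <= f["Sr"] <= 1 and 0 <= f["Stheta"] <= 1


class TestAssembly:
    def test_45_values_in_catalog_order(self, small_dataset):
        sample = small_dataset.to_lesion_samples()[0]
        v = compute_texture_features(sample)
        assert v.shape == (45,)
        assert np.all(np.isfinite(v))
        f = compute_fos_features(sample)
        assert v[19] == pytest.approx(f["Mean"])  # F20
        assert v[42] == pytest.approx(compute_fractal_features(sample)["H2"])  # F43
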