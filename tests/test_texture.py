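"""Texture feature core: patch extraction, scans, bands, AR fits."""

import numpy as np
import pytest

from thyrotex.synthetic import LABEL_CYSTIC, LABEL_SOLID
from thyrotex.texture import (
    LOG_VAR_FLOOR,
    TexturePatch,
    ar_fit,
    decompose_bands,
    extract_patches,
    feature_names,
    patch_features,
    patch_to_signals,
)

RNG = np.random.default_rng(123)


def make_patch(pixels):
    return TexturePatch(np.asarray(pixels, float), (0, 0), 1.0)


class TestExtractPatches:
    @pytest.mark.parametrize("stride,expected", [(20, 4), (10, 9)])
    def test_full_mask_tiling(self, stride, expected):
        img = RNG.random((40, 40))
        mask = np.ones((40, 40), bool)
        patches = extract_patches(img, mask, stride_px=stride, min_inside_fraction=1.0)
        assert len(patches) == expected
        origins = [p.origin_px for p in patches]
        assert origins == sorted(origins)  # row-major determinism

    def test_empty_mask(self):
        assert extract_patches(RNG.random((40, 40)), np.zeros((40, 40), bool)) == []

    def test_too_small_mask_warns(self):
        mask = np.zeros((40, 40), bool)
        mask[5:10, 5:10] = True  # smaller than one patch
        with pytest.warns(UserWarning, match="too small"):
            assert extract_patches(RNG.random((40, 40)), mask) == []

    def test_inside_fraction_filtering(self):
        mask = np.zeros((60, 60), bool)
        mask[10:40, 10:40] = True
        strict = extract_patches(RNG.random((60, 60)), mask, 10, 1.0)
        loose = extract_patches(RNG.random((60, 60)), mask, 10, 0.5)
        assert len(loose) >= len(strict)
        assert all(p.inside_fraction >= 0.5 for p in loose)


class TestPatchToSignals:
    def test_constant_patch(self):
        sigs = patch_to_signals(make_patch(np.full((20, 20), 0.7))).signals
        for s in sigs:
            assert s.size == 400
            np.testing.assert_allclose(s, 0.7)

    def test_each_signal_is_permutation_of_pixels(self):
        patch = make_patch(RNG.random((20, 20)))
        ref = np.sort(patch.pixels.ravel())
        for s in patch_to_signals(patch).signals:
            np.testing.assert_array_equal(np.sort(s), ref)

    def test_stripes_read_differently_by_direction(self):
        stripes = np.tile([0.0, 1.0], (20, 10))  # vertical stripes, period 2
        row_sig, col_sig, *_ = patch_to_signals(make_patch(stripes)).signals
        assert np.all(np.abs(np.diff(row_sig)) == 1.0)  # alternates every sample
        segments = col_sig.reshape(20, 20)  # 20-sample-constant pieces
        assert all(np.ptp(seg) == 0.0 for seg in segments)

    def test_scans_are_distinct_orderings(self):
        patch = make_patch(np.arange(400).reshape(20, 20) / 400)
        sigs = patch_to_signals(patch).signals
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.array_equal(sigs[i], sigs[j])


class TestDecomposeBands:
    def test_constant_signal_is_pure_dc(self):
        bands = decompose_bands(patch_to_signals(make_patch(np.full((20, 20), 0.3))))
        for low, mid, high in bands.bands:
            np.testing.assert_allclose(low, 0.3, atol=1e-9)
            assert np.abs(mid).max() < 1e-9
            assert np.abs(high).max() < 1e-9

    def test_high_frequency_tone_lands_in_high_band(self):
        tone = np.sin(2 * np.pi * 0.30 * np.arange(400))
        patch = make_patch(tone.reshape(20, 20))
        # the row-major signal is exactly the tone
        low, mid, high = decompose_bands(patch_to_signals(patch)).bands[0]
        total = float(tone @ tone)
        assert float(high @ high) / total > 0.95

    def test_bands_partition_signal_energy(self):
        noise = RNG.standard_normal((20, 20))
        sigs = patch_to_signals(make_patch(noise))
        for per_signal, sig in zip(decompose_bands(sigs).bands, sigs.signals):
            np.testing.assert_allclose(sum(per_signal), sig, atol=1e-10)
            band_energy = sum(float(b @ b) for b in per_signal)
            assert band_energy == pytest.approx(float(sig @ sig), rel=0.05)


class TestArFit:
    def test_constant_sequence_degenerates_cleanly(self):
        fit = ar_fit(np.full(400, 2.5), order=2)
        np.testing.assert_array_equal(fit.coefficients, [0.0, 0.0])
        assert fit.residual_variance == 0.0

    def test_recovers_known_ar2_process(self):
        rng = np.random.default_rng(42)
        x = np.zeros(4000)
        e = rng.standard_normal(4000)
        for i in range(2, 4000):
            x[i] = 0.5 * x[i - 1] - 0.3 * x[i - 2] + e[i]
        fit = ar_fit(x, order=2)
        np.testing.assert_allclose(fit.coefficients, [0.5, -0.3], atol=0.05)
        assert fit.residual_variance == pytest.approx(1.0, rel=0.1)

    def test_white_noise_has_no_structure(self):
        x = np.random.default_rng(7).standard_normal(4000)
        fit = ar_fit(x, order=2)
        np.testing.assert_allclose(fit.coefficients, [0.0, 0.0], atol=0.1)

    def test_matches_independent_burg_oracle(self):
        burg = pytest.importorskip("statsmodels.regression.linear_model").burg
        x = np.random.default_rng(5).standard_normal(500).cumsum() * 0.1
        x += np.random.default_rng(6).standard_normal(500)
        fit = ar_fit(x, order=2)
        oracle_coef, oracle_s2 = burg(x, 2, demean=False)
        np.testing.assert_allclose(fit.coefficients, oracle_coef, atol=1e-8)
        assert fit.residual_variance == pytest.approx(oracle_s2, rel=1e-2)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ar_fit(np.arange(20.0), order=2)


class TestPatchFeatures:
    def test_feature_vector_has_36_entries(self):
        patch = make_patch(RNG.random((20, 20)))
        vec = patch_features(patch).values
        assert vec.shape == (36,)
        assert len(feature_names()) == 36

    def test_constant_patch_sits_at_floor(self):
        vec = patch_features(make_patch(np.full((20, 20), 0.5))).values
        layout = vec.reshape(12, 3)
        np.testing.assert_array_equal(layout[:, :2], 0.0)
        np.testing.assert_allclose(layout[:, 2], np.log(LOG_VAR_FLOOR))

    def test_deterministic(self):
        patch = make_patch(RNG.random((20, 20)))
        np.testing.assert_array_equal(
            patch_features(patch).values, patch_features(patch).values
        )


class TestDiscrimination:
    def test_best_feature_separates_solid_from_cystic(self, small_suite):
        """On default phantoms the AR features must distinguish compartment
        textures: AUROC of the single best feature > 0.7."""
        from sklearn.metrics import roc_auc_score

        from thyrotex.regions import CLASS_CYSTIC, build_training_set

        data = build_training_set(small_suite)
        labels = data.labels
        assert min((labels == CLASS_CYSTIC).sum(), (labels != CLASS_CYSTIC).sum()) >= 100
        aucs = [
            max(a := roc_auc_score(labels, data.features[:, j]), 1 - a)
            for j in range(data.features.shape[1])
        ]
        assert max(aucs) > 0.7
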