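import numpy as np
import pytest

from bct_texture.imaging import ImageStack
from bct_texture.phantom import generate_phantom_exam
from bct_texture.pipeline import phantom_roi
from bct_texture.texture import (
    FEATURE_NAMES,
    TextureParams,
    compute_glcm,
    compute_glrlm,
    extract_features,
    first_order_features,
    glcm_features,
    glrlm_features,
    normalize_and_quantize,
)

from oracles import brute_all_19, brute_glcm, brute_glrlm

DIRS4 = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


class TestQuantization:
    def test_constant_region_maps_to_level_one(self):
        stack = ImageStack(np.full((2, 8, 8), 37.0))
        mask = np.ones((2, 8, 8), dtype=bool)
        q = normalize_and_quantize(stack, mask, n_g=64)
        assert (q.levels[mask] == 1).all()

    def test_two_valued_region_maps_symmetrically(self):
        # values {0, 100} in equal proportion: mu=50, sigma=50, window
        # [-100, 200]; the affine map puts them at levels 22 and 43,
        # symmetric about the bin midrange 32.5
        vals = np.array([[0.0, 100.0]] * 8)
        stack = ImageStack(vals[np.newaxis])
        mask = np.ones_like(stack.voxels, dtype=bool)
        q = normalize_and_quantize(stack, mask, n_g=64)
        levels = set(q.levels[mask].tolist())
        assert levels == {22, 43}
        assert 22 + 43 == pytest.approx(2 * 32.5)

    def test_outliers_stay_within_level_range(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, size=(3, 16, 16))
        vals[0, 0, 0] = 1e9
        vals[1, 1, 1] = -1e9
        stack = ImageStack(vals)
        mask = np.ones_like(vals, dtype=bool)
        q = normalize_and_quantize(stack, mask, n_g=16)
        masked = q.levels[mask]
        assert masked.min() >= 1 and masked.max() <= 16

    def test_empty_mask_rejected(self):
        stack = ImageStack(np.zeros((1, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            normalize_and_quantize(stack, np.zeros((1, 4, 4), dtype=bool), 8)


class TestFirstOrder:
    def test_hand_computed_two_level_histogram(self, qroi_factory):
        f = first_order_features(qroi_factory([[1, 1, 2, 2]]))
        assert f["variance"] == pytest.approx(0.25)
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert f["kurtosis"] == pytest.approx(-2.0)
        assert f["entropy"] == pytest.approx(1.0)

    def test_constant_levels_all_zero_by_convention(self, qroi_factory):
        f = first_order_features(qroi_factory([[5, 5, 5, 5]], n_g=8))
        assert f == {"variance": 0.0, "skewness": 0.0, "kurtosis": 0.0, "entropy": 0.0}

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_histogram_has_zero_skewness(self, qroi_factory, seed):
        rng = np.random.default_rng(seed)
        half = rng.integers(1, 9, size=200)
        sym = np.concatenate([half, 17 - half])  # mirror about 8.5
        f = first_order_features(qroi_factory(sym.reshape(20, 20), n_g=16))
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)


class TestGlcm:
    def test_two_by_two_horizontal_example(self, qroi_factory):
        q = qroi_factory([[1, 2], [1, 2]])
        g = compute_glcm(q, distance=1, directions=[(0, 1)])
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(g.p, expected)
        f = glcm_features(g)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(0.5)
        assert f["homogeneity"] == pytest.approx(0.5)

    def test_constant_region_degenerate_matrix(self, qroi_factory):
        q = qroi_factory(np.full((4, 4), 3), n_g=4)
        g = compute_glcm(q, directions=DIRS4)
        assert g.p[2, 2] == pytest.approx(1.0)
        f = glcm_features(g)
        assert f["contrast"] == 0.0
        assert f["energy"] == pytest.approx(1.0)
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["correlation"] == 1.0  # sigma_x sigma_y = 0 convention

    def test_duplicated_slice_leaves_probabilities_unchanged(self, qroi_factory):
        rng = np.random.default_rng(1)
        sl = rng.integers(1, 5, size=(6, 6))
        one = compute_glcm(qroi_factory(sl, n_g=4), directions=DIRS4)
        two = compute_glcm(qroi_factory(np.stack([sl, sl]), n_g=4), directions=DIRS4)
        np.testing.assert_allclose(one.p, two.p, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_probabilities_sum_to_one_and_symmetric(self, qroi_factory, seed):
        rng = np.random.default_rng(seed)
        lvl = rng.integers(1, 5, size=(2, 10, 10))
        msk = rng.random((2, 10, 10)) > 0.3
        g = compute_glcm(qroi_factory(lvl, msk, n_g=4), directions=DIRS4)
        assert g.p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(g.p, g.p.T)

    def test_matches_skimage_on_full_mask(self, qroi_factory):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(7)
        img = rng.integers(0, 4, size=(12, 12)).astype(np.uint8)
        ours = compute_glcm(qroi_factory(img + 1, n_g=4), distance=1, directions=DIRS4)
        sk = graycomatrix(img, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4], levels=4, symmetric=True)
        sk_counts = sk[:, :, 0, :].sum(axis=2).astype(float)
        np.testing.assert_allclose(ours.p, sk_counts / sk_counts.sum(), atol=1e-12)


class TestGlrlm:
    def test_hand_run_length_encoding(self, qroi_factory):
        q = qroi_factory([[1, 1, 1, 2, 2, 3]])
        r = compute_glrlm(q, directions=[(0, 1)])
        assert r.n_r == 3
        assert r.n_p == 6
        assert r.p[0, 2] == 1  # level 1, length 3
        assert r.p[1, 1] == 1  # level 2, length 2
        assert r.p[2, 0] == 1  # level 3, length 1
        f = glrlm_features(r)
        assert f["SRE"] == pytest.approx((1 / 9 + 1 / 4 + 1) / 3)
        assert f["LRE"] == pytest.approx(14 / 3)
        assert f["GLN"] == pytest.approx(1.0)
        assert f["RLN"] == pytest.approx(1.0)
        assert f["RP"] == pytest.approx(0.5)

    def test_mask_gap_splits_a_run(self, qroi_factory):
        q = qroi_factory([[1, 1, 1, 2, 2, 3]], mask=[[1, 0, 1, 1, 1, 1]])
        r = compute_glrlm(q, directions=[(0, 1)])
        assert r.n_r == 4  # (1,1),(1,1),(2,2),(3,1)
        assert r.p[0, 0] == 2
        assert r.n_p == 5

    def test_checkerboard_runs_are_all_length_one(self, qroi_factory):
        board = np.indices((8, 8)).sum(axis=0) % 2 + 1
        r = compute_glrlm(qroi_factory(board, n_g=2), directions=[(0, 1)])
        assert r.p.shape[1] == 1  # no run longer than 1
        assert r.n_r == r.n_p

    def test_single_run_collapses_every_feature_to_one(self, qroi_factory):
        q = qroi_factory([[1]])
        f = glrlm_features(compute_glrlm(q, directions=[(0, 1)]))
        for name, value in f.items():
            assert value == pytest.approx(1.0), name

    @pytest.mark.parametrize("seed", range(4))
    def test_pixel_count_conservation(self, qroi_factory, seed):
        rng = np.random.default_rng(seed)
        lvl = rng.integers(1, 4, size=(3, 9, 9))
        msk = rng.random((3, 9, 9)) > 0.4
        r = compute_glrlm(qroi_factory(lvl, msk, n_g=3), directions=DIRS4)
        j = np.arange(1, r.p.shape[1] + 1)
        assert int((r.p * j).sum()) == r.n_p


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_19_match_brute_force(self, qroi_factory, seed):
        rng = np.random.default_rng(seed)
        n_g = int(rng.integers(2, 5))
        lvl = rng.integers(1, n_g + 1, size=(8, 8))
        msk = rng.random((8, 8)) > 0.25
        if not msk.any():
            msk[0, 0] = True
        ours = {}
        q = qroi_factory(lvl, msk, n_g=n_g)
        ours.update(first_order_features(q))
        ours.update(glcm_features(compute_glcm(q, 1, DIRS4)))
        ours.update(glrlm_features(compute_glrlm(q, DIRS4)))
        ref = brute_all_19([lvl.tolist()], [msk.tolist()], n_g, 1, DIRS4)
        for name in FEATURE_NAMES:
            assert ours[name] == pytest.approx(ref[name], abs=1e-9), name

    def test_multislice_matrices_match_brute_force(self, qroi_factory):
        rng = np.random.default_rng(11)
        lvl = rng.integers(1, 4, size=(3, 7, 7))
        msk = rng.random((3, 7, 7)) > 0.3
        q = qroi_factory(lvl, msk, n_g=3)
        g = compute_glcm(q, 1, DIRS4)
        ref_p = brute_glcm([s.tolist() for s in lvl], [m.tolist() for m in msk], 3, 1, DIRS4)
        np.testing.assert_allclose(g.p, np.array(ref_p), atol=1e-12)
        r = compute_glrlm(q, DIRS4)
        ref_runs, ref_nr, ref_np = brute_glrlm(
            [s.tolist() for s in lvl], [m.tolist() for m in msk], DIRS4
        )
        assert r.n_r == ref_nr and r.n_p == ref_np
        for (i, j), n in ref_runs.items():
            assert r.p[i - 1, j - 1] == n


class TestExtractFeatures:
    def test_returns_all_19_names_in_order(self, small_config):
        exam = generate_phantom_exam(small_config, "b", seed=5)
        feats = extract_features(exam.stack, phantom_roi(small_config))
        assert tuple(feats) == FEATURE_NAMES

    def test_skewness_sign_tracks_density(self, small_config):
        # class a: mostly fat, long right tail -> positive skewness;
        # class d: mostly gland -> negative skewness
        roi = phantom_roi(small_config)
        fa = extract_features(generate_phantom_exam(small_config, "a", 5).stack, roi)
        fd = extract_features(generate_phantom_exam(small_config, "d", 5).stack, roi)
        assert fa["skewness"] > 0
        assert fd["skewness"] < 0

    def test_intensity_shift_invariance(self, small_config):
        exam = generate_phantom_exam(small_config, "c", seed=9)
        roi = phantom_roi(small_config)
        base = extract_features(exam.stack, roi)
        shifted_stack = ImageStack(exam.stack.voxels + 123.456, exam.stack.pixel_spacing_mm)
        shifted = extract_features(shifted_stack, roi)
        for name in FEATURE_NAMES:
            assert shifted[name] == pytest.approx(base[name], rel=1e-9), name

    def test_per_direction_average_mode_runs(self, qroi_factory, small_config):
        exam = generate_phantom_exam(small_config, "b", seed=2)
        params = TextureParams(per_direction_average=True)
        feats = extract_features(exam.stack, phantom_roi(small_config), params)
        assert tuple(feats) == FEATURE_NAMES
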