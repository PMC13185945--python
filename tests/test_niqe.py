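import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.stats import gennorm

from climbfocus.niqe import (
    DegenerateDistributionError,
    NiqeModel,
    TrainingError,
    extract_features,
    fit_aggd,
    mscn,
    niqe_score,
    paired_products,
    sample_aggd,
    select_final_focus,
    train_model,
)
from climbfocus.simulate import natural_texture


def brute_force_mscn(im, c=1.0, size=7, sigma=7.0 / 6.0):
    """Sliding-window double-loop MSCN evaluation (edge-replicated)."""
    half = size // 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    w = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    w /= w.sum()
    padded = np.pad(im, half, mode="edge")
    out = np.empty_like(im, dtype=float)
    for i in range(im.shape[0]):
        for j in range(im.shape[1]):
            win = padded[i:i + size, j:j + size]
            mu = (w * win).sum()
            var = (w * win * win).sum() - mu * mu
            out[i, j] = (im[i, j] - mu) / (np.sqrt(max(var, 0.0)) + c)
    return out


class TestMscn:
    def test_constant_image_gives_zero(self):
        assert np.allclose(mscn(np.full((16, 16), 42.0)), 0.0)

    def test_offset_invariance(self, rng):
        im = rng.uniform(0, 100, (20, 20))
        assert np.allclose(mscn(im), mscn(im + 55.0), atol=1e-9)

    def test_matches_windowed_double_loop(self, rng):
        im = rng.uniform(0, 100, (14, 14))
        assert np.allclose(mscn(im), brute_force_mscn(im), atol=1e-10)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            mscn(np.zeros((4, 4)))


class TestPairedProducts:
    def test_all_ones(self):
        pp = paired_products(np.ones((5, 5)))
        assert all(np.all(v == 1.0) for v in pp.values())

    def test_checkerboard_sign_pattern(self):
        m = np.indices((6, 6)).sum(axis=0) % 2 * 2.0 - 1.0
        pp = paired_products(m)
        assert np.all(pp["horizontal"] == -1) and np.all(pp["vertical"] == -1)
        assert np.all(pp["diagonal"] == 1) and np.all(pp["anti_diagonal"] == 1)

    def test_matches_shift_oracle(self, rng):
        m = rng.normal(size=(8, 9))
        pp = paired_products(m)
        assert np.array_equal(pp["horizontal"], m[:, :-1] * m[:, 1:])
        assert np.array_equal(pp["anti_diagonal"], m[1:, :-1] * m[:-1, 1:])


class TestAggd:
    def test_gaussian_samples_give_alpha_two(self):
        x = gennorm.rvs(2.0, scale=1.0, size=100_000, random_state=7)
        g = fit_aggd(x)
        assert g.alpha == pytest.approx(2.0, rel=0.05)
        assert g.beta_left == pytest.approx(g.beta_right, rel=0.05)

    def test_laplacian_samples_give_alpha_one(self):
        x = gennorm.rvs(1.0, scale=1.0, size=100_000, random_state=8)
        assert fit_aggd(x).alpha == pytest.approx(1.0, rel=0.05)

    def test_mirrored_samples_are_exactly_symmetric(self, rng):
        x = rng.normal(size=5000)
        both = np.concatenate([x, -x])
        g = fit_aggd(both)
        assert g.beta_left == g.beta_right
        assert g.mean_offset == 0.0

    def test_zero_spread_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            fit_aggd(np.full(100, 3.0))

    def test_asymmetric_sampler_roundtrip(self, rng):
        x = sample_aggd(2.0, 0.5, 1.5, 100_000, rng)
        g = fit_aggd(x)
        assert g.alpha == pytest.approx(2.0, rel=0.1)
        assert g.beta_left == pytest.approx(0.5, rel=0.1)
        assert g.beta_right == pytest.approx(1.5, rel=0.1)


class TestFeatures:
    def test_feature_dimension_is_36(self):
        tex = natural_texture((128, 128), seed=1)
        feats, skipped = extract_features(tex, patch_size=64)
        assert feats.shape == (4, 36)
        assert skipped == 0

    def test_deterministic(self):
        tex = natural_texture((128, 128), seed=2)
        f1, _ = extract_features(tex, patch_size=64)
        f2, _ = extract_features(tex, patch_size=64)
        assert np.array_equal(f1, f2)

    def test_mirror_image_same_mscn_alpha(self):
        tex = natural_texture((128, 128), seed=3)
        f, _ = extract_features(tex, patch_size=128)
        f_m, _ = extract_features(tex[:, ::-1], patch_size=128)
        assert f[0, 0] == pytest.approx(f_m[0, 0], rel=1e-6)


class TestModel:
    def test_training_is_deterministic(self):
        corpus = [natural_texture((192, 192), seed=10 + i) for i in range(10)]
        m1 = train_model(corpus, patch_size=64)
        m2 = train_model(corpus, patch_size=64)
        assert np.array_equal(m1.mean_vec, m2.mean_vec)
        assert np.array_equal(m1.cov_mat, m2.cov_mat)

    def test_covariance_symmetric_psd(self):
        corpus = [natural_texture((192, 192), seed=20 + i) for i in range(10)]
        m = train_model(corpus, patch_size=64)
        assert np.allclose(m.cov_mat, m.cov_mat.T)
        assert np.linalg.eigvalsh(m.cov_mat).min() >= -1e-10

    def test_too_few_images_rejected(self):
        with pytest.raises(TrainingError):
            train_model([natural_texture((128, 128), seed=1)] * 5, patch_size=64)

    def test_json_round_trip(self, tmp_path, default_model):
        path = tmp_path / "model.json"
        default_model.to_json(path)
        loaded = NiqeModel.from_json(path)
        assert np.array_equal(loaded.mean_vec, default_model.mean_vec)
        assert np.array_equal(loaded.cov_mat, default_model.cov_mat)
        assert loaded.patch_size == default_model.patch_size

    def test_inconsistent_covariance_rejected(self):
        with pytest.raises(ValueError):
            NiqeModel(mean_vec=np.zeros(3), cov_mat=np.eye(4))


class TestScoring:
    def test_score_deterministic(self, default_model):
        tex = natural_texture((256, 256), seed=30)
        assert niqe_score(tex, default_model) == niqe_score(tex, default_model)

    def test_blur_raises_score(self, default_model):
        tex = natural_texture((256, 256), seed=31)
        assert niqe_score(tex, default_model) < niqe_score(
            gaussian_filter(tex, 4.0), default_model
        )

    def test_blur_monotone_over_sigma(self, default_model):
        tex = natural_texture((256, 256), seed=32)
        scores = [niqe_score(gaussian_filter(tex, s) if s else tex, default_model)
                  for s in (0, 1, 2, 4)]
        assert scores[0] < scores[-1]

    def test_select_prefers_sharp_member(self, default_model):
        tex = natural_texture((256, 256), seed=33)
        blurred = gaussian_filter(tex, 4.0)
        z, scores = select_final_focus(blurred, 1.0, tex, 2.0, default_model)
        assert z == 2.0
        z, _ = select_final_focus(tex, 1.0, blurred, 2.0, default_model)
        assert z == 1.0

    def test_exact_tie_prefers_measured_peak(self, default_model):
        tex = natural_texture((256, 256), seed=34)
        z, (sa, sb) = select_final_focus(tex, 1.0, tex, 2.0, default_model)
        assert sa == sb
        assert z == 2.0
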