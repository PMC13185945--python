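"""No-reference image quality scoring (NIQE) used as the autofocus error check.

The Naturalness Image Quality Evaluator compares natural-scene-statistics
features of a test image with those of a model trained on pristine images:

* MSCN coefficients — mean-subtracted, contrast-normalised pixels computed
  with a 7x7 Gaussian-weighted local window, ``(I - mu) / (sigma + 1)``;
* pairwise products of neighbouring MSCN coefficients in four orientations,
  capturing local correlation structure;
* asymmetric generalised Gaussian distribution (AGGD) fits of those
  coefficient histograms, whose shape/scale parameters form the feature
  vector (18 per scale, 2 scales, 36 per patch);
* the quality score is the Mahalanobis-type distance between the model's
  multivariate-Gaussian feature summary (nu1, Sigma1) and the test image's
  (nu2, Sigma2):  sqrt( d^T ((Sigma1+Sigma2)/2)^-1 d ),  d = nu1 - nu2.

Lower scores indicate better (more natural, less distorted) images.  Scores
are only comparable under a single model; the package ships a model trained
by :func:`train_model` on seeded synthetic natural textures and supports
retraining on user-supplied pristine micrographs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import pinvh
from scipy.ndimage import correlate
from scipy.special import gamma as _gamma

__all__ = [
    "AggdParams",
    "NiqeModel",
    "DegenerateDistributionError",
    "mscn",
    "paired_products",
    "fit_aggd",
    "sample_aggd",
    "extract_features",
    "train_model",
    "niqe_score",
    "select_final_focus",
    "load_default_model",
]

FEATURES_PER_SCALE = 18  # 2 (MSCN AGGD) + 4 orientations x 4 params


class DegenerateDistributionError(ValueError):
    """Raised when an AGGD fit is attempted on spread-free samples."""


@dataclass(frozen=True)
class AggdParams:
    """Asymmetric generalised Gaussian parameters (moment-matching estimate)."""

    alpha: float
    beta_left: float
    beta_right: float
    mean_offset: float


def _gaussian_window(size: int = 7, sigma: float = 7.0 / 6.0) -> np.ndarray:
    half = (size - 1) / 2.0
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    w = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    return w / w.sum()


_WINDOW = _gaussian_window()


def mscn(image, c: float = 1.0) -> np.ndarray:
    """Mean-subtracted contrast-normalised coefficients.

    Local mean and deviation come from a 7x7 Gaussian-weighted window
    (nearest-edge padding); ``c`` is the stabilising constant in the divisor.
    """
    im = np.asarray(image, dtype=np.float64)
    if im.ndim != 2:
        raise ValueError("mscn expects a 2-D grayscale image")
    if min(im.shape) < _WINDOW.shape[0]:
        raise ValueError("image smaller than the normalisation window")
    mu = correlate(im, _WINDOW, mode="nearest")
    var = correlate(im * im, _WINDOW, mode="nearest") - mu * mu
    sigma = np.sqrt(np.clip(var, 0.0, None))
    return (im - mu) / (sigma + c)


def local_deviation(image) -> np.ndarray:
    """The sigma field of the MSCN construction (used for patch selection)."""
    im = np.asarray(image, dtype=np.float64)
    mu = correlate(im, _WINDOW, mode="nearest")
    var = correlate(im * im, _WINDOW, mode="nearest") - mu * mu
    return np.sqrt(np.clip(var, 0.0, None))


def paired_products(coeffs) -> dict:
    """Products of each MSCN coefficient with its neighbour in 4 orientations.

    Returns arrays for horizontal, vertical, main-diagonal and
    secondary-diagonal neighbours (each one row/column smaller).
    """
    m = np.asarray(coeffs, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("paired_products expects a 2-D array of at least 2x2")
    return {
        "horizontal": m[:, :-1] * m[:, 1:],
        "vertical": m[:-1, :] * m[1:, :],
        "diagonal": m[:-1, :-1] * m[1:, 1:],
        "anti_diagonal": m[1:, :-1] * m[:-1, 1:],
    }


# --- AGGD moment-matching fit ------------------------------------------------

_ALPHA_GRID = np.arange(0.2, 10.0 + 1e-9, 0.001)
_RHO_GRID = (_gamma(2.0 / _ALPHA_GRID) ** 2) / (
    _gamma(1.0 / _ALPHA_GRID) * _gamma(3.0 / _ALPHA_GRID)
)


def fit_aggd(samples) -> AggdParams:
    """Moment-matching AGGD estimate (shape via ratio-function grid inversion).

    Left and right second moments give the scale asymmetry; the generalised
    Gaussian ratio function rho(alpha) is inverted by nearest-neighbour
    lookup over a fixed alpha grid (0.2 to 10, step 0.001).
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 2 or np.ptp(x) == 0.0:
        raise DegenerateDistributionError("AGGD fit needs >= 2 samples with spread")
    neg = x[x < 0]
    pos = x[x > 0]
    if neg.size == 0 or pos.size == 0:
        raise DegenerateDistributionError("AGGD fit needs mass on both sides of 0")
    sigma_l = float(np.sqrt(np.mean(neg * neg)))
    sigma_r = float(np.sqrt(np.mean(pos * pos)))
    gamma_hat = sigma_l / sigma_r
    r_hat = float(np.mean(np.abs(x)) ** 2 / np.mean(x * x))
    big_r = r_hat * (gamma_hat**3 + 1.0) * (gamma_hat + 1.0) / (gamma_hat**2 + 1.0) ** 2
    alpha = float(_ALPHA_GRID[np.argmin(np.abs(_RHO_GRID - big_r))])
    conv = np.sqrt(_gamma(1.0 / alpha) / _gamma(3.0 / alpha))
    beta_l = sigma_l * conv
    beta_r = sigma_r * conv
    mean_offset = (beta_r - beta_l) * _gamma(2.0 / alpha) / _gamma(1.0 / alpha)
    return AggdParams(alpha=alpha, beta_left=beta_l, beta_right=beta_r,
                      mean_offset=float(mean_offset))


def sample_aggd(alpha: float, beta_left: float, beta_right: float, size: int,
                rng: np.random.Generator) -> np.ndarray:
    """Draw samples from an AGGD (inverse-CDF via the gamma distribution).

    If ``U ~ Gamma(1/alpha, 1)`` then ``U**(1/alpha) * beta`` is a half
    generalised Gaussian; the side is picked with probability proportional
    to its scale.
    """
    if alpha <= 0 or beta_left <= 0 or beta_right <= 0:
        raise ValueError("AGGD parameters must be positive")
    u = rng.gamma(1.0 / alpha, 1.0, size=size) ** (1.0 / alpha)
    side = rng.random(size) < beta_left / (beta_left + beta_right)
    return np.where(side, -u * beta_left, u * beta_right)


# --- feature extraction and model --------------------------------------------


@dataclass
class NiqeModel:
    """Pristine-image natural-scene-statistics model (feature mean + covariance)."""

    mean_vec: np.ndarray
    cov_mat: np.ndarray
    patch_size: int = 96
    sharpness_fraction: float = 0.75
    n_scales: int = 2
    c: float = 1.0

    def __post_init__(self) -> None:
        self.mean_vec = np.asarray(self.mean_vec, dtype=float)
        self.cov_mat = np.asarray(self.cov_mat, dtype=float)
        d = self.mean_vec.size
        if self.cov_mat.shape != (d, d):
            raise ValueError("covariance shape inconsistent with mean vector")
        if not np.allclose(self.cov_mat, self.cov_mat.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov_mat).min() < -1e-8 * max(
            1.0, float(np.abs(self.cov_mat).max())
        ):
            raise ValueError("covariance must be positive semi-definite")

    def to_json(self, path) -> None:
        payload = {
            "mean_vec": self.mean_vec.tolist(),
            "cov_mat": self.cov_mat.tolist(),
            "config": {
                "patch_size": self.patch_size,
                "sharpness_fraction": self.sharpness_fraction,
                "n_scales": self.n_scales,
                "c": self.c,
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "NiqeModel":
        payload = json.loads(Path(path).read_text())
        cfg = payload.get("config", {})
        return cls(
            mean_vec=np.array(payload["mean_vec"], dtype=float),
            cov_mat=np.array(payload["cov_mat"], dtype=float),
            patch_size=int(cfg.get("patch_size", 96)),
            sharpness_fraction=float(cfg.get("sharpness_fraction", 0.75)),
            n_scales=int(cfg.get("n_scales", 2)),
            c=float(cfg.get("c", 1.0)),
        )


def _downscale2(im: np.ndarray) -> np.ndarray:
    h, w = (im.shape[0] // 2) * 2, (im.shape[1] // 2) * 2
    a = im[:h, :w]
    return 0.25 * (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2])


def _patch_features(m: np.ndarray, pp: dict, r0: int, r1: int, c0: int, c1: int):
    sub = m[r0:r1, c0:c1]
    g = fit_aggd(sub)
    feats = [g.alpha, 0.5 * (g.beta_left + g.beta_right)]
    for key in ("horizontal", "vertical", "diagonal", "anti_diagonal"):
        arr = pp[key]
        p = fit_aggd(arr[r0 : min(r1, arr.shape[0]), c0 : min(c1, arr.shape[1])])
        feats.extend([p.alpha, p.mean_offset, p.beta_left, p.beta_right])
    return feats


def extract_features(
    image, patch_size: int = 96, n_scales: int = 2, c: float = 1.0
):
    """Per-patch NSS feature matrix (n_patches x 18*n_scales).

    Patches are tiled on a grid defined at full scale; the same spatial
    regions are re-used at each downscaled level.  Patches whose AGGD fit is
    degenerate (e.g. constant regions) are skipped; the number skipped is
    returned alongside the features.

    Returns ``(features, n_skipped)``.
    """
    im = np.asarray(image, dtype=np.float64)
    if im.ndim != 2:
        raise ValueError("extract_features expects a 2-D grayscale image")
    if im.shape[0] < patch_size or im.shape[1] < patch_size:
        raise ValueError(
            f"image {im.shape} smaller than patch_size {patch_size}"
        )
    feats_idx, skipped = _features_with_indices(im, patch_size, n_scales, c)
    if feats_idx:
        return np.asarray([f for _, f in feats_idx], dtype=float), skipped
    return np.empty((0, FEATURES_PER_SCALE * n_scales)), skipped


class TrainingError(RuntimeError):
    """Raised when the pristine corpus yields too few usable patches."""


def train_model(
    pristine_images,
    patch_size: int = 96,
    n_scales: int = 2,
    sharpness_fraction: float = 0.75,
    c: float = 1.0,
) -> NiqeModel:
    """Train a pristine-image model from a corpus of sharp, textured images.

    Per image, patches are ranked by their mean local deviation (the sigma
    field of the MSCN construction) and only the sharpest
    ``sharpness_fraction`` are pooled; the model is the pooled features'
    sample mean and covariance.
    """
    images = list(pristine_images)
    if len(images) < 10:
        raise TrainingError("training needs at least 10 pristine images")
    pooled = []
    for im in images:
        im = np.asarray(im, dtype=np.float64)
        if np.ptp(im) == 0.0:
            raise TrainingError("constant image in the training corpus")
        dev = local_deviation(im)
        n_by = im.shape[0] // patch_size
        n_bx = im.shape[1] // patch_size
        patch_dev = np.array([
            dev[i * patch_size : (i + 1) * patch_size,
                j * patch_size : (j + 1) * patch_size].mean()
            for i in range(n_by) for j in range(n_bx)
        ])
        keep_n = max(1, int(np.ceil(sharpness_fraction * patch_dev.size)))
        sharp_set = set(np.argsort(patch_dev)[::-1][:keep_n].tolist())
        feats_idx, _ = _features_with_indices(im, patch_size, n_scales, c)
        for idx, f in feats_idx:
            if idx in sharp_set:
                pooled.append(f)
    pooled_arr = np.asarray(pooled, dtype=float)
    dim = FEATURES_PER_SCALE * n_scales
    if pooled_arr.shape[0] <= dim:
        raise TrainingError(
            f"only {pooled_arr.shape[0]} usable patches for {dim}-dim features"
        )
    mean_vec = pooled_arr.mean(axis=0)
    cov = np.cov(pooled_arr, rowvar=False)
    cov = 0.5 * (cov + cov.T)
    return NiqeModel(mean_vec=mean_vec, cov_mat=cov, patch_size=patch_size,
                     sharpness_fraction=sharpness_fraction, n_scales=n_scales, c=c)


def _features_with_indices(im, patch_size, n_scales, c):
    """Like extract_features but returns (patch_index, feature_row) pairs."""
    n_by = im.shape[0] // patch_size
    n_bx = im.shape[1] // patch_size
    per_scale = []
    level = im
    for s in range(n_scales):
        if s > 0:
            level = _downscale2(level)
        m = mscn(level, c=c)
        per_scale.append({"m": m, "pp": paired_products(m), "p": patch_size >> s})
    out, skipped = [], 0
    for i in range(n_by):
        for j in range(n_bx):
            feats = []
            try:
                for sc in per_scale:
                    p = sc["p"]
                    feats.extend(
                        _patch_features(sc["m"], sc["pp"], i * p, (i + 1) * p,
                                        j * p, (j + 1) * p)
                    )
            except DegenerateDistributionError:
                skipped += 1
                continue
            out.append((i * n_bx + j, np.asarray(feats)))
    return out, skipped


class ScoringError(RuntimeError):
    """Raised when an image yields no usable patches for scoring."""


def niqe_score(image, model: NiqeModel) -> float:
    """NIQE quality score of one image under a trained model (lower = better)."""
    feats, _ = extract_features(image, model.patch_size, model.n_scales, model.c)
    if feats.shape[0] == 0:
        raise ScoringError("no usable patches in the test image")
    nu2 = feats.mean(axis=0)
    if feats.shape[0] > 1:
        sigma2 = np.cov(feats, rowvar=False)
        sigma2 = 0.5 * (sigma2 + sigma2.T)
    else:
        sigma2 = np.zeros_like(model.cov_mat)
    d = model.mean_vec - nu2
    pooled = 0.5 * (model.cov_mat + sigma2)
    q = float(d @ pinvh(pooled) @ d)
    return float(np.sqrt(max(q, 0.0)))


def select_final_focus(image_a, z_a_um: float, image_b, z_b_um: float,
                       model: NiqeModel):
    """Choose the output focus plane by NIQE comparison.

    ``image_a`` is the capture at the fitted-curve peak, ``image_b`` the
    acquired image with the highest sharpness.  The lower-scoring (better)
    plane wins; an exact tie prefers the measured peak B, since B is
    empirical while A is a model extrapolation.

    Returns ``(z_um, (score_a, score_b))``.
    """
    score_a = niqe_score(image_a, model)
    score_b = niqe_score(image_b, model)
    z = z_a_um if score_a < score_b else z_b_um
    return float(z), (score_a, score_b)


def load_default_model() -> NiqeModel:
    """The bundled model trained on seeded synthetic natural textures."""
    from importlib.resources import files

    path = files("climbfocus").joinpath("data/niqe_model_synthetic.json")
    return NiqeModel.from_json(path)
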