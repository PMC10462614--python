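"""Decoding from brain activity: image reconstruction and identification.

Reconstruction scores every image of a large prior set by the Gaussian
likelihood of the observed response given that image,

    p(r | s)  proportional to  exp{ -(r - r_hat(s)) Sigma^-1 (r - r_hat(s))' },

where r_hat(s) is the encoding model's predicted response and Sigma the
noise covariance of the training residuals.  The pixel average of the top-n
prior images is the reconstruction.  Identification simply returns the
candidate whose predicted response correlates best with the observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from skimage.metrics import structural_similarity

from .encoding import EncodingModel, ResponseMatrix, compute_feature_volumes, predict_from_features
from .errors import ConfigurationError, DataError, DimensionError, NotFittedError, NumericError
from .frontend import ImageStimulus

__all__ = [
    "PriorImageSet",
    "ReconstructionResult",
    "estimate_noise_covariance",
    "log_likelihood",
    "predict_prior_responses",
    "reconstruct_image",
    "identify_image",
    "evaluate_reconstruction",
]


@dataclass
class PriorImageSet:
    """A pool of candidate images with lazily cached predicted responses."""

    images: list[ImageStimulus]
    predicted_responses: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.images:
            raise DataError("prior image set must contain at least one image")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class ReconstructionResult:
    """Reconstruction plus the full likelihood ranking of the prior set."""

    reconstruction: ImageStimulus
    ranked_ids: np.ndarray
    log_likelihoods: np.ndarray


def estimate_noise_covariance(
    meas_train: ResponseMatrix | np.ndarray,
    pred_train: ResponseMatrix | np.ndarray,
    shrinkage: float = 0.1,
) -> np.ndarray:
    """Shrunk sample covariance of the training residuals.

    ``Sigma = (1 - lam) * cov(r - r_hat) + lam * diag(cov(r - r_hat))``.
    A little shrinkage toward the diagonal keeps Sigma invertible when the
    number of selected voxels approaches the number of training trials.
    """
    M = meas_train.values if isinstance(meas_train, ResponseMatrix) else np.asarray(meas_train, float)
    P = pred_train.values if isinstance(pred_train, ResponseMatrix) else np.asarray(pred_train, float)
    if M.shape != P.shape:
        raise DimensionError("measured and predicted shapes differ")
    if M.shape[0] < 2:
        raise DataError("need at least 2 trials to estimate a covariance")
    if not (0.0 <= shrinkage <= 1.0):
        raise ConfigurationError("shrinkage must lie in [0, 1]")
    resid = M - P
    S = np.atleast_2d(np.cov(resid, rowvar=False, ddof=1))
    return (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))


def log_likelihood(r: np.ndarray, r_hat: np.ndarray, sigma: np.ndarray) -> float:
    """Gaussian log likelihood up to a constant: ``-(r - r_hat) Sigma^-1 (r - r_hat)'``.

    Computed with a symmetric positive-definite solve rather than an
    explicit inverse; maximal (0) exactly when ``r == r_hat``.
    """
    d = np.asarray(r, float).ravel() - np.asarray(r_hat, float).ravel()
    try:
        factor = cho_factor(np.asarray(sigma, float))
    except LinAlgError as exc:
        raise NumericError(
            "noise covariance is singular; increase the shrinkage"
        ) from exc
    return float(-d @ cho_solve(factor, d))


def predict_prior_responses(
    model: EncodingModel, prior: PriorImageSet
) -> np.ndarray:
    """Predicted responses of the model's voxels to every prior image (cached)."""
    if prior.predicted_responses is None:
        features = compute_feature_volumes(
            prior.images, model.bank, model.layer, T=model.T
        )
        prior.predicted_responses = predict_from_features(model, features)
    return prior.predicted_responses


def reconstruct_image(
    model: EncodingModel,
    r_obs: np.ndarray,
    prior: PriorImageSet,
    top_n: int = 15,
) -> ReconstructionResult:
    """Reconstruct a stimulus as the pixel average of the likeliest priors.

    Every prior image is scored by :func:`log_likelihood` of its predicted
    response against the observed response; the pixel arrays of the ``top_n``
    best images are averaged.  The model must carry a fitted noise
    covariance over its (selected) voxels.
    """
    if top_n < 1 or top_n > len(prior):
        raise ConfigurationError(
            f"top_n={top_n} outside [1, {len(prior)}]"
        )
    if model.noise_cov is None:
        raise NotFittedError("encoding model carries no noise covariance")
    preds = predict_prior_responses(model, prior)
    r_obs = np.asarray(r_obs, float).ravel()
    if preds.shape[1] != r_obs.size:
        raise DimensionError("observed response length does not match model voxels")
    ll = np.array(
        [log_likelihood(r_obs, preds[k], model.noise_cov) for k in range(len(prior))]
    )
    ranked = np.argsort(-ll, kind="stable")  # ties -> lower prior index
    top = ranked[:top_n]
    recon = np.mean([prior.images[k].pixels for k in top], axis=0)
    return ReconstructionResult(ImageStimulus(recon), ranked, ll)


def identify_image(
    model: EncodingModel,
    r_obs: np.ndarray,
    candidates: list[ImageStimulus],
) -> tuple[int, np.ndarray]:
    """Identify which candidate image evoked the observed response.

    Returns the index of the candidate whose predicted response has the
    highest Pearson correlation with ``r_obs`` (ties toward the lowest
    index) along with the full correlation vector.  A candidate with a
    zero-variance prediction is scored ``-inf``.
    """
    if len(candidates) < 2:
        raise DataError("identification needs at least 2 candidates")
    if len(model.voxel_models) < 3:
        raise DataError("identification needs at least 3 voxels")
    features = compute_feature_volumes(candidates, model.bank, model.layer, T=model.T)
    preds = predict_from_features(model, features)
    r = np.asarray(r_obs, float).ravel()
    rc = r - r.mean()
    r_ss = np.sqrt((rc**2).sum())
    pc = preds - preds.mean(axis=1, keepdims=True)
    p_ss = np.sqrt((pc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = pc @ rc / (p_ss * r_ss)
    corr = np.where((p_ss == 0.0) | (r_ss == 0.0), -np.inf, corr)
    return int(np.argmax(corr)), corr


def evaluate_reconstruction(
    recon: ImageStimulus, truth: ImageStimulus
) -> tuple[float, float]:
    """Pixelwise Pearson correlation and SSIM between two images.

    SSIM uses the standard constants with the library's default local
    window and ``data_range=255``.
    """
    a = recon.pixels
    b = truth.pixels
    if a.shape != b.shape:
        raise DimensionError("reconstruction and truth dimensions differ")
    ac = a.ravel() - a.mean()
    bc = b.ravel() - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    pcc = float((ac @ bc) / denom) if denom > 0 else 0.0
    ssim = float(structural_similarity(a, b, data_range=255.0))
    return pcc, ssim
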