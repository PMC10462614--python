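"""Monte-Carlo noise-ceiling estimation from repeated presentations.

A voxel's trial-to-trial noise bounds how well any model can predict its
responses.  From repeated presentations of the same test images the noise
standard deviation is estimated as

    sigma_N = sqrt( mean over images of the across-repeat variance ),

and the response (signal) variance as the variance of the per-image mean
response minus the noise variance.  The ceiling itself is obtained by
simulation: draw responses ~ N(0, sigma_R^2) and noise ~ N(0, sigma_N^2)
for n images, correlate signal+noise with signal, and average the Pearson
correlation over many simulations.  The Monte-Carlo mean converges to the
closed form sigma_R / sqrt(sigma_R^2 + sigma_N^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, DimensionError

__all__ = [
    "RepeatedResponses",
    "estimate_noise_sd",
    "estimate_response_variance",
    "simulate_noise_ceiling",
    "noise_ceiling_per_voxel",
]


@dataclass
class RepeatedResponses:
    """Responses to repeated presentations, ``(n_images, n_repeats, n_voxels)``."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError(
                "RepeatedResponses requires (n_images, n_repeats, n_voxels)"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("repeated responses contain non-finite values")

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[2]


def estimate_noise_sd(rr: RepeatedResponses, voxel: int) -> float:
    """Noise SD: sqrt of the mean (over images) across-repeat variance."""
    if rr.n_repeats < 2:
        raise DataError("noise estimation needs at least 2 repeats")
    var_r = rr.values[:, :, voxel].var(axis=1, ddof=1)
    return float(np.sqrt(var_r.mean()))


def estimate_response_variance(
    rr: RepeatedResponses, voxel: int, correct_repeat_mean: bool = False
) -> float:
    """Response (signal) variance of one voxel.

    The canonical estimator subtracts the full noise variance from the
    variance of the per-image mean response::

        sigma_R^2 = var(mu_R) - sigma_N^2

    Because ``mu_R`` is an average over ``n_repeats`` trials, its noise
    contribution is actually ``sigma_N^2 / n_repeats``; pass
    ``correct_repeat_mean=True`` to subtract that instead.  A negative
    estimate (noise-dominated voxel) is clipped to 0 with a warning.
    """
    mu = rr.values[:, :, voxel].mean(axis=1)
    s2n = estimate_noise_sd(rr, voxel) ** 2
    if correct_repeat_mean:
        s2n = s2n / rr.n_repeats
    s2r = float(mu.var(ddof=1) - s2n)
    if s2r < 0.0:
        warnings.warn(
            f"negative response-variance estimate ({s2r:.4g}) clipped to 0",
            stacklevel=2,
        )
        s2r = 0.0
    return s2r


def simulate_noise_ceiling(
    sigma2_r: float,
    sigma2_n: float,
    n_images: int,
    n_sims: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo noise ceiling: mean PCC(signal+noise, signal).

    Each simulation draws ``n_images`` responses ~ N(0, sigma2_r) and noise
    ~ N(0, sigma2_n); the mean Pearson correlation over ``n_sims``
    simulations is returned.  The degenerate cases are exact: with no noise
    the ceiling is 1, with no signal it is 0 (the constant-series
    convention).  Simulated means are 0 -- the correlation is
    location-invariant, so the choice is immaterial.
    """
    if sigma2_r < 0 or sigma2_n < 0:
        raise DataError("variances must be non-negative")
    if sigma2_r == 0.0 and sigma2_n == 0.0:
        raise DataError("sigma2_r and sigma2_n cannot both be 0")
    if n_images < 3:
        raise DataError("need at least 3 images per simulation")
    if sigma2_n == 0.0:
        return 1.0  # PCC(x, x) = 1 for every draw
    if sigma2_r == 0.0:
        return 0.0  # constant signal: PCC defined as 0
    rng = np.random.default_rng(seed)
    resp = rng.normal(0.0, np.sqrt(sigma2_r), size=(n_sims, n_images))
    noise = rng.normal(0.0, np.sqrt(sigma2_n), size=(n_sims, n_images))
    signal = resp + noise
    rc = resp - resp.mean(axis=1, keepdims=True)
    sc = signal - signal.mean(axis=1, keepdims=True)
    denom = np.sqrt((rc**2).sum(axis=1) * (sc**2).sum(axis=1))
    pcc = (rc * sc).sum(axis=1) / denom
    return float(pcc.mean())


def noise_ceiling_per_voxel(
    rr: RepeatedResponses,
    n_sims: int = 1000,
    seed: int = 0,
    correct_repeat_mean: bool = False,
) -> np.ndarray:
    """Noise ceiling of every voxel of a repeated-response tensor."""
    out = np.empty(rr.n_voxels)
    for v in range(rr.n_voxels):
        s2n = estimate_noise_sd(rr, v) ** 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s2r = estimate_response_variance(rr, v, correct_repeat_mean)
        if s2r == 0.0 and s2n == 0.0:
            out[v] = 0.0
            continue
        out[v] = simulate_noise_ceiling(
            s2r, s2n, rr.n_images, n_sims=n_sims, seed=seed + v
        )
    return out
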