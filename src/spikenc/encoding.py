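"""Voxel-wise encoding models: receptive-field search and linear regression.

Each fMRI voxel in early visual cortex pools input from a restricted region
of visual space (its population receptive field).  The encoding model
therefore regresses a voxel's response on the network feature vector at a
single spatial location ``(i, j)`` of the feature maps:

    y_v = w . f_ij + b + eps.

Every location of the map is examined; threefold cross-validation on the
training trials scores each candidate with the coefficient of determination
R^2 of pooled out-of-fold predictions, and the best-scoring location becomes
the voxel's receptive field.  The regression is then refit on the entire
training set at that location.  Restricting each voxel to one location both
matches the retinotopic organisation of V1-V3 and controls overfitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, DimensionError, NotFittedError
from .frontend import DoGFilterBank, ImageStimulus, encode_image, DEFAULT_T
from .scnn import IFConvLayer, extract_features

__all__ = [
    "ResponseMatrix",
    "VoxelModel",
    "EncodingModel",
    "feature_vectors_at",
    "cross_validated_r2",
    "annotate_receptive_field",
    "fit_voxel_models",
    "fit_encoding_model",
    "compute_feature_volumes",
    "predict_from_features",
    "predict_responses",
    "encoding_accuracy",
    "select_top_voxels",
    "select_submodel",
]


@dataclass
class ResponseMatrix:
    """Per-trial voxel responses, ``(n_trials, n_voxels)`` with voxel labels."""

    values: np.ndarray
    voxel_ids: list[str] | None = None
    roi: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise DataError("response matrix contains non-finite values")
        if self.voxel_ids is None:
            self.voxel_ids = [f"v{i:04d}" for i in range(self.values.shape[1])]
        if len(self.voxel_ids) != self.values.shape[1]:
            raise DimensionError("voxel_ids length must match column count")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class VoxelModel:
    """One voxel's fitted receptive-field regression."""

    voxel_id: str
    rf_location: tuple[int, int]
    weights: np.ndarray
    intercept: float
    cv_r2: float


@dataclass
class EncodingModel:
    """Trained network plus the ordered collection of voxel models."""

    bank: DoGFilterBank
    layer: IFConvLayer
    voxel_models: list[VoxelModel] = field(default_factory=list)
    T: int = DEFAULT_T
    noise_cov: np.ndarray | None = None
    preset: str | None = None

    @property
    def voxel_ids(self) -> list[str]:
        return [vm.voxel_id for vm in self.voxel_models]


def feature_vectors_at(
    features: np.ndarray | list[np.ndarray], loc: tuple[int, int]
) -> np.ndarray:
    """Stack the per-trial feature vectors at one map location.

    ``features`` is an ``(n_trials, C, h, w)`` array (or list of ``(C, h, w)``
    volumes); returns ``(n_trials, C)`` where row k is ``F_k[:, i, j]``.
    """
    arr = np.asarray(features, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    i, j = loc
    if not (0 <= i < arr.shape[2] and 0 <= j < arr.shape[3]):
        raise IndexError(f"location {loc} outside feature map {arr.shape[2:]}")
    return arr[:, :, i, j]


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks of a seeded shuffle; deterministic for fixed seed."""
    perm = np.random.default_rng(seed).permutation(n)
    return np.array_split(perm, folds)


def _ols(Xa: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares fit; rank-deficient designs fall back to a tiny ridge."""
    beta, _, rank, _ = np.linalg.lstsq(Xa, Y, rcond=None)
    if rank < Xa.shape[1]:
        warnings.warn(
            "rank-deficient design; using a tiny ridge penalty", stacklevel=3
        )
        p = Xa.shape[1]
        beta = np.linalg.solve(Xa.T @ Xa + 1e-8 * np.eye(p), Xa.T @ Y)
    return beta


def _augment(X: np.ndarray, intercept: bool) -> np.ndarray:
    return np.column_stack([X, np.ones(len(X))]) if intercept else X


def _cv_oof_predictions(
    X: np.ndarray, Y: np.ndarray, folds: list[np.ndarray], intercept: bool
) -> np.ndarray:
    """Pooled out-of-fold OLS predictions, multi-target."""
    n = len(X)
    oof = np.empty((n, Y.shape[1]))
    Xa = _augment(X, intercept)
    for test_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        beta = _ols(Xa[mask], Y[mask])
        oof[test_idx] = Xa[test_idx] @ beta
    return oof


def _r2(oof: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-column R^2 of pooled out-of-fold predictions; zero-variance -> 0."""
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    ss_res = np.sum((Y - oof) ** 2, axis=0)
    # zero-variance targets (up to rounding) are scored 0 by convention
    degenerate = ss_tot <= 1e-12 * np.maximum(1.0, np.sum(Y**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    return np.where(degenerate, 0.0, r2)


def cross_validated_r2(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 3,
    seed: int = 0,
    intercept: bool = True,
) -> float:
    """Cross-validated R^2 of an OLS regression of ``y`` on ``X``.

    Folds are contiguous blocks of a seeded shuffle; the returned R^2 is
    computed on the pooled out-of-fold predictions, ``1 - SS_res/SS_tot``.
    A zero-variance target is scored 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise DimensionError("X and y disagree on the number of trials")
    if y.size < folds:
        raise DataError(f"need at least {folds} trials for {folds}-fold CV")
    idx = _fold_indices(y.size, folds, seed)
    oof = _cv_oof_predictions(X, y[:, None], idx, intercept)
    return float(_r2(oof, y[:, None])[0])


def _scan_locations(
    features: np.ndarray,
    Y: np.ndarray,
    folds: int,
    seed: int,
    intercept: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive receptive-field search, vectorized across voxels.

    Returns per-voxel best locations ``(V, 2)`` and CV R^2 ``(V,)``.  Ties
    resolve to the smallest ``(i, j)`` in row-major scan order.
    """
    n, _, h, w = features.shape
    V = Y.shape[1]
    idx = _fold_indices(n, folds, seed)
    best_r2 = np.full(V, -np.inf)
    best_loc = np.zeros((V, 2), dtype=int)
    for i in range(h):
        for j in range(w):
            X = features[:, :, i, j]
            r2 = _r2(_cv_oof_predictions(X, Y, idx, intercept), Y)
            better = r2 > best_r2  # strict: first (smallest) location wins ties
            best_r2[better] = r2[better]
            best_loc[better] = (i, j)
    return best_loc, best_r2


def _refit(
    features: np.ndarray,
    Y: np.ndarray,
    locs: np.ndarray,
    intercept: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Refit OLS on all trials at each voxel's chosen location."""
    V = Y.shape[1]
    C = features.shape[1]
    weights = np.zeros((V, C))
    intercepts = np.zeros(V)
    for loc in np.unique(locs, axis=0):
        cols = np.nonzero((locs == loc).all(axis=1))[0]
        Xa = _augment(features[:, :, loc[0], loc[1]], intercept)
        beta = _ols(Xa, Y[:, cols])
        weights[cols] = beta[:C].T
        if intercept:
            intercepts[cols] = beta[C]
    return weights, intercepts


def annotate_receptive_field(
    features: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    folds: int = 3,
    intercept: bool = True,
    voxel_id: str = "v0000",
) -> VoxelModel:
    """Locate one voxel's receptive field and fit its regression.

    Every location of the feature maps is scored with
    :func:`cross_validated_r2`; the argmax (ties toward the smallest
    ``(i, j)``) becomes the receptive-field location, and the weights and
    intercept are refit on all training trials at that location.
    """
    arr = np.asarray(features, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    locs, r2 = _scan_locations(arr, y, folds, seed, intercept)
    weights, intercepts = _refit(arr, y, locs, intercept)
    return VoxelModel(
        voxel_id, (int(locs[0, 0]), int(locs[0, 1])), weights[0],
        float(intercepts[0]), float(r2[0]),
    )


def fit_voxel_models(
    features: np.ndarray,
    responses: ResponseMatrix,
    folds: int = 3,
    seed: int = 0,
    intercept: bool = True,
) -> list[VoxelModel]:
    """Receptive-field search plus refit for every voxel of a response matrix."""
    arr = np.asarray(features, dtype=float)
    Y = responses.values
    if arr.shape[0] != Y.shape[0]:
        raise DimensionError("trial counts of features and responses differ")
    if Y.shape[0] < 2 * folds:
        raise DataError(f"{folds}-fold CV needs at least {2 * folds} trials")
    locs, r2 = _scan_locations(arr, Y, folds, seed, intercept)
    weights, intercepts = _refit(arr, Y, locs, intercept)
    return [
        VoxelModel(
            responses.voxel_ids[v],
            (int(locs[v, 0]), int(locs[v, 1])),
            weights[v],
            float(intercepts[v]),
            float(r2[v]),
        )
        for v in range(Y.shape[1])
    ]


def compute_feature_volumes(
    images: list[ImageStimulus],
    bank: DoGFilterBank,
    layer: IFConvLayer,
    T: int = DEFAULT_T,
) -> np.ndarray:
    """Run the full network on a list of images; ``(n, C, h, w)`` features."""
    return np.stack(
        [extract_features(encode_image(img, bank, T=T), layer) for img in images]
    )


def fit_encoding_model(
    images: list[ImageStimulus],
    responses: ResponseMatrix,
    bank: DoGFilterBank,
    layer: IFConvLayer,
    T: int = DEFAULT_T,
    folds: int = 3,
    seed: int = 0,
    intercept: bool = True,
    preset: str | None = None,
) -> EncodingModel:
    """End-to-end fit: extract features, then fit every voxel model."""
    features = compute_feature_volumes(images, bank, layer, T=T)
    vms = fit_voxel_models(features, responses, folds=folds, seed=seed,
                           intercept=intercept)
    return EncodingModel(bank, layer, vms, T=T, preset=preset)


def predict_from_features(
    model: EncodingModel, features: np.ndarray
) -> np.ndarray:
    """Predicted responses ``(n_trials, n_voxels)`` from feature volumes."""
    if not model.voxel_models:
        raise NotFittedError("encoding model has no fitted voxel models")
    arr = np.asarray(features, dtype=float)
    if arr.ndim == 3:
        arr = arr[None]
    out = np.empty((arr.shape[0], len(model.voxel_models)))
    for v, vm in enumerate(model.voxel_models):
        i, j = vm.rf_location
        out[:, v] = arr[:, :, i, j] @ vm.weights + vm.intercept
    return out


def predict_responses(
    model: EncodingModel, images: list[ImageStimulus]
) -> ResponseMatrix:
    """Predict per-voxel responses for a list of stimulus images."""
    if not model.voxel_models:
        raise NotFittedError("encoding model has no fitted voxel models")
    features = compute_feature_volumes(images, model.bank, model.layer, T=model.T)
    return ResponseMatrix(predict_from_features(model, features),
                          voxel_ids=list(model.voxel_ids))


def encoding_accuracy(
    pred: ResponseMatrix | np.ndarray, meas: ResponseMatrix | np.ndarray
) -> np.ndarray:
    """Per-voxel Pearson correlation between predicted and measured responses.

    Computed across trials; a constant series yields 0 with a warning.
    """
    P = pred.values if isinstance(pred, ResponseMatrix) else np.asarray(pred, float)
    M = meas.values if isinstance(meas, ResponseMatrix) else np.asarray(meas, float)
    if P.shape != M.shape:
        raise DimensionError("prediction and measurement shapes differ")
    if P.shape[0] < 3:
        raise DataError("need at least 3 trials for a correlation")
    Pc = P - P.mean(axis=0)
    Mc = M - M.mean(axis=0)
    denom = np.sqrt((Pc**2).sum(axis=0) * (Mc**2).sum(axis=0))
    degenerate = denom == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant series scored as PCC 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        pcc = (Pc * Mc).sum(axis=0) / denom
    return np.where(degenerate, 0.0, pcc)


def select_top_voxels(models: list[VoxelModel], k: int) -> list[str]:
    """IDs of the top-k voxels by training-set CV R^2, descending.

    Selection deliberately uses the train-set criterion (never test-set
    accuracy) to avoid circularity in downstream decoding.  Ties are broken
    by voxel id.
    """
    if k <= 0:
        raise ConfigurationError("k must be positive")
    if k > len(models):
        raise ConfigurationError(f"k={k} exceeds voxel count {len(models)}")
    ranked = sorted(models, key=lambda m: (-m.cv_r2, m.voxel_id))
    return [m.voxel_id for m in ranked[:k]]


def select_submodel(model: EncodingModel, k: int) -> EncodingModel:
    """Encoding model restricted to its top-k voxels (by train CV R^2)."""
    ids = select_top_voxels(model.voxel_models, k)
    by_id = {vm.voxel_id: vm for vm in model.voxel_models}
    return EncodingModel(
        model.bank, model.layer, [by_id[i] for i in ids], T=model.T,
        preset=model.preset,
    )
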