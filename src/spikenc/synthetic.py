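"""Synthetic stimuli and ground-truth voxel responses.

Every stage of the pipeline can be exercised without any fMRI download: the
generators here produce high-contrast stimulus images (oriented bars,
Gaussian blobs, or character-like glyph strokes) and voxel responses that
are, by construction, a noisy linear readout of the network feature vector
at one spatial location,

    y_v = w . F[:, i, j] + b + N(0, noise_sd^2),

independently per trial and per repeat.  This mirrors the generative
assumption of the encoding model exactly, so round-trip tests probe the
estimation machinery (receptive-field search, regression, decoding), not
the biological validity of the model.  All generators are pure functions of
their seeds.

The default scale mirrors the handwritten-character experiments: 56x56
images, 270 training and 90 test trials, 35 repeats of each test image for
noise-ceiling work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import ResponseMatrix
from .errors import ConfigurationError, DataError
from .frontend import DoGFilterBank, ImageStimulus, encode_image, DEFAULT_T
from .noise_ceiling import RepeatedResponses
from .scnn import IFConvLayer, extract_features

__all__ = [
    "GroundTruthVoxel",
    "SyntheticDataset",
    "generate_stimuli",
    "generate_ground_truth_voxels",
    "simulate_responses",
]

#: Orientations (degrees) used by the bar generator.
BAR_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)


@dataclass
class GroundTruthVoxel:
    """The generative parameters behind one synthetic voxel."""

    rf_location: tuple[int, int]
    weights: np.ndarray
    intercept: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """A complete synthetic image--response dataset."""

    train_images: list[ImageStimulus]
    test_images: list[ImageStimulus]
    train_responses: ResponseMatrix
    test_responses: ResponseMatrix
    repeated_test: RepeatedResponses
    voxels: list[GroundTruthVoxel]
    seed: int


def _draw_stroke(canvas, center, angle_deg, length, thickness, intensity):
    """Stamp one high-contrast stroke onto a canvas (in place)."""
    H, W = canvas.shape
    yy, xx = np.mgrid[0:H, 0:W]
    theta = np.deg2rad(angle_deg)
    dy = yy - center[0]
    dx = xx - center[1]
    along = dx * np.cos(theta) + dy * np.sin(theta)
    across = -dx * np.sin(theta) + dy * np.cos(theta)
    mask = (np.abs(along) <= length / 2.0) & (np.abs(across) <= thickness / 2.0)
    canvas[mask] = np.maximum(canvas[mask], intensity)


def generate_stimuli(
    kind: str,
    n: int,
    size: tuple[int, int] = (56, 56),
    seed: int = 0,
    return_params: bool = False,
):
    """Generate synthetic stimulus images.

    ``bars`` are single oriented high-contrast strokes (orientation drawn
    uniformly from four axes) that drive DoG filtering and STDP feature
    learning; ``blobs`` are sums of Gaussian bumps; ``glyphs`` are composite
    2-4 stroke patterns with style jitter, loosely imitating handwritten
    characters.  Pixels lie in [0, 255].  Deterministic for a fixed seed;
    with ``return_params`` the per-image generation parameters are returned
    alongside the images.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if kind not in ("bars", "blobs", "glyphs"):
        raise ConfigurationError(f"unknown stimulus kind {kind!r}")
    H, W = size
    rng = np.random.default_rng(seed)
    images: list[ImageStimulus] = []
    params: list[dict] = []
    for _ in range(n):
        canvas = np.zeros((H, W))
        if kind == "bars":
            angle = BAR_ORIENTATIONS[rng.integers(len(BAR_ORIENTATIONS))]
            center = (
                H / 2 + rng.uniform(-0.2, 0.2) * H,
                W / 2 + rng.uniform(-0.2, 0.2) * W,
            )
            length = rng.uniform(0.5, 0.9) * min(H, W)
            thickness = rng.uniform(2.0, 4.0)
            intensity = rng.uniform(200.0, 255.0)
            _draw_stroke(canvas, center, angle, length, thickness, intensity)
            params.append({"orientation": angle, "center": center})
        elif kind == "blobs":
            k = int(rng.integers(1, 4))
            centers = []
            for _ in range(k):
                cy = rng.uniform(0.15, 0.85) * H
                cx = rng.uniform(0.15, 0.85) * W
                s = rng.uniform(2.0, 6.0)
                amp = rng.uniform(150.0, 255.0)
                yy, xx = np.mgrid[0:H, 0:W]
                canvas += amp * np.exp(
                    -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2)
                )
                centers.append((cy, cx))
            canvas = np.clip(canvas, 0.0, 255.0)
            params.append({"n_blobs": k, "centers": centers})
        else:  # glyphs
            k = int(rng.integers(2, 5))
            angles = []
            for _ in range(k):
                angle = rng.uniform(0.0, 180.0)
                center = (
                    H / 2 + rng.uniform(-0.25, 0.25) * H,
                    W / 2 + rng.uniform(-0.25, 0.25) * W,
                )
                length = rng.uniform(0.3, 0.6) * min(H, W)
                thickness = rng.uniform(2.0, 3.5)
                intensity = rng.uniform(220.0, 255.0)
                _draw_stroke(canvas, center, angle, length, thickness, intensity)
                angles.append(angle)
            params.append({"n_strokes": k, "angles": angles})
        images.append(ImageStimulus(canvas))
    return (images, params) if return_params else images


def generate_ground_truth_voxels(
    n_voxels: int,
    map_shape: tuple[int, int, int],
    sparsity: float = 0.3,
    noise_sd: float = 0.5,
    seed: int = 0,
    center_weighted: bool = False,
) -> list[GroundTruthVoxel]:
    """Draw generative voxel parameters for a feature map of ``map_shape``.

    Receptive-field locations are uniform over the map, or concentrated
    toward the map centre when ``center_weighted`` (imitating the alignment
    of informative voxels with high stimulus intensity).  Weight vectors are
    sparse Gaussian: each channel weight is nonzero with probability
    ``sparsity`` (at least one channel is always active).
    """
    if n_voxels < 1:
        raise ConfigurationError("n_voxels must be >= 1")
    C, h, w = map_shape
    rng = np.random.default_rng(seed)
    voxels = []
    for _ in range(n_voxels):
        if center_weighted:
            i = int(np.clip(round(rng.normal((h - 1) / 2, h / 6)), 0, h - 1))
            j = int(np.clip(round(rng.normal((w - 1) / 2, w / 6)), 0, w - 1))
        else:
            i = int(rng.integers(h))
            j = int(rng.integers(w))
        mask = rng.random(C) < sparsity
        if not mask.any():
            mask[rng.integers(C)] = True
        weights = rng.normal(0.0, 1.0, C) * mask
        intercept = float(rng.normal(0.0, 1.0))
        voxels.append(GroundTruthVoxel((i, j), weights, intercept, noise_sd))
    return voxels


def simulate_responses(
    stimuli: list[ImageStimulus],
    bank: DoGFilterBank,
    layer: IFConvLayer,
    voxels: list[GroundTruthVoxel],
    n_train: int,
    T: int = DEFAULT_T,
    n_repeats: int = 35,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate the full synthetic dataset from stimuli and voxel truths.

    The first ``n_train`` stimuli form the training set, the rest the test
    set.  Responses are the voxel's linear readout of the network feature
    vector at its receptive-field location plus i.i.d. Gaussian noise; the
    test images additionally receive ``n_repeats`` independent repeat
    presentations for noise-ceiling estimation.
    """
    if not (0 < n_train < len(stimuli)):
        raise ConfigurationError("n_train must split the stimuli non-trivially")
    features = np.stack(
        [extract_features(encode_image(img, bank, T=T), layer) for img in stimuli]
    )
    n = len(stimuli)
    V = len(voxels)
    signal = np.empty((n, V))
    noise_sd = np.array([vox.noise_sd for vox in voxels])
    for v, vox in enumerate(voxels):
        i, j = vox.rf_location
        signal[:, v] = features[:, :, i, j] @ vox.weights + vox.intercept
    rng = np.random.default_rng(seed)
    train = signal[:n_train] + rng.normal(0.0, 1.0, (n_train, V)) * noise_sd
    n_test = n - n_train
    test = signal[n_train:] + rng.normal(0.0, 1.0, (n_test, V)) * noise_sd
    repeats = (
        signal[n_train:, None, :]
        + rng.normal(0.0, 1.0, (n_test, n_repeats, V)) * noise_sd
    )
    ids = [f"v{v:04d}" for v in range(V)]
    return SyntheticDataset(
        train_images=list(stimuli[:n_train]),
        test_images=list(stimuli[n_train:]),
        train_responses=ResponseMatrix(train, voxel_ids=list(ids)),
        test_responses=ResponseMatrix(test, voxel_ids=list(ids)),
        repeated_test=RepeatedResponses(repeats),
        voxels=voxels,
        seed=seed,
    )
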