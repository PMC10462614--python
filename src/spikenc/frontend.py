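"""Retinal front end: grayscale preprocessing, DoG filtering, latency coding.

The first stage of the network mimics retinal ganglion cells.  Images are
convolved with ON/OFF-centre difference-of-Gaussians (DoG) kernels at one or
more spatial scales, strong filter responses are converted into early spikes
by intensity-to-latency coding, and the resulting spike wave is down-sampled
with temporal max pooling before it reaches the cortical layer.

Conventions
-----------
* Pixel intensities live in ``[0, 255]``; images are single-channel 2-D
  arrays after :func:`preprocess_image`.
* Every DoG kernel is the difference of two unit-mass Gaussians, so its
  coefficients sum to zero and a constant image elicits no response.
* All kernels of a bank are embedded centred in a single common window (the
  largest kernel size) and applied with one zero-padding amount, so every
  channel of the output shares the same spatial grid.
* A spike wave is a binary tensor ``(T, C, H, W)``; each site spikes at most
  once, and stronger DoG responses spike in earlier time bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image

from .errors import ConfigurationError, DataError, DimensionError, FormatError

__all__ = [
    "ImageStimulus",
    "DoGKernel",
    "DoGFilterBank",
    "SpikeWave",
    "preprocess_image",
    "build_dog_bank",
    "apply_dog",
    "intensity_to_latency",
    "max_pool_spikes",
    "encode_image",
]

# Rec. 601 luma weights for RGB -> grayscale conversion.
_REC601 = np.array([0.299, 0.587, 0.114])

#: Default number of latency-coding time steps.
DEFAULT_T = 30
#: Default DoG response threshold for spike eligibility.
DEFAULT_SPIKE_THRESHOLD = 50.0


@dataclass
class ImageStimulus:
    """A single-channel stimulus image with intensities in ``[0, 255]``."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DimensionError("ImageStimulus requires a 2-D pixel array")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("ImageStimulus pixels must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class DoGKernel:
    """One ON- or OFF-centre difference-of-Gaussians kernel."""

    weights: np.ndarray
    polarity: str  # "ON" | "OFF"
    size: int
    sigmas: tuple[float, float]


@dataclass
class DoGFilterBank:
    """A set of DoG kernels sharing one canvas window and padding amount."""

    kernels: list[DoGKernel]
    common_window: int
    pad: int
    spike_threshold: float = DEFAULT_SPIKE_THRESHOLD

    @property
    def n_channels(self) -> int:
        return len(self.kernels)


@dataclass
class SpikeWave:
    """Binary spike tensor ``(T, C, H, W)``; at most one spike per site."""

    spikes: np.ndarray

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=bool)
        if self.spikes.ndim != 4:
            raise DimensionError("SpikeWave requires a (T, C, H, W) tensor")
        if self.spikes.sum(axis=0).max(initial=0) > 1:
            raise DataError("each spike-wave site may spike at most once")

    @property
    def T(self) -> int:
        return self.spikes.shape[0]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.spikes.shape

    def spike_times(self) -> np.ndarray:
        """Per-site first (and only) spike time; ``T`` marks a silent site."""
        fired = self.spikes.any(axis=0)
        return np.where(fired, self.spikes.argmax(axis=0), self.T)

    def spike_counts(self) -> np.ndarray:
        """Total spike count per site (0 or 1), as float ``(C, H, W)``."""
        return self.spikes.sum(axis=0, dtype=float)


def preprocess_image(raw, target_size: tuple[int, int]) -> ImageStimulus:
    """Load, grayscale-convert and resize a raster image.

    Parameters
    ----------
    raw
        Path to a raster file (PNG/TIFF/BMP), a ``PIL.Image.Image``, or a
        numpy array of shape ``(H, W)`` or ``(H, W, 3)``.
    target_size
        Desired ``(height, width)``.

    Notes
    -----
    RGB images are converted with the Rec. 601 luminance weighting; resizing
    uses bilinear interpolation.  A grayscale image already at the target
    size is returned unchanged.
    """
    if isinstance(raw, (str, Path)):
        with Image.open(raw) as im:
            arr = np.asarray(im, dtype=float)
    elif isinstance(raw, Image.Image):
        arr = np.asarray(raw, dtype=float)
    else:
        arr = np.asarray(raw, dtype=float)

    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise FormatError(
                f"expected 1 or 3 channels, got {arr.shape[2]}"
            )
        arr = arr @ _REC601
    elif arr.ndim != 2:
        raise FormatError(f"unsupported raster dimensionality {arr.ndim}")

    if arr.shape != tuple(target_size):
        h, w = target_size
        im = Image.fromarray(arr.astype(np.float32), mode="F")
        arr = np.asarray(im.resize((w, h), Image.BILINEAR), dtype=float)
    return ImageStimulus(arr)


def _gaussian(size: int, sigma: float) -> np.ndarray:
    """Unit-mass isotropic Gaussian on a ``size x size`` grid."""
    r = (size - 1) / 2.0
    coords = np.arange(size) - r
    g1 = np.exp(-(coords**2) / (2.0 * sigma**2))
    g = np.outer(g1, g1)
    return g / g.sum()


def dog_kernel(size: int, sigma_center: float, sigma_surround: float) -> np.ndarray:
    """ON-centre DoG kernel: difference of two unit-mass Gaussians."""
    return _gaussian(size, sigma_center) - _gaussian(size, sigma_surround)


_PRESETS = {
    # (sizes, sigma pairs, padding)
    "character_natural": (
        [3, 7, 13],
        [(3 / 9, 6 / 9), (7 / 9, 14 / 9), (13 / 9, 26 / 9)],
        6,
    ),
    "digit": ([7], [(1.0, 2.0)], 3),
}


def build_dog_bank(preset: str) -> DoGFilterBank:
    """Build the DoG filter bank for a named stimulus preset.

    ``character_natural`` yields six kernels (ON+OFF at sizes 3, 7 and 13
    with sigma pairs (3/9, 6/9), (7/9, 14/9) and (13/9, 26/9)) with padding 6;
    ``digit`` yields two kernels (ON+OFF, size 7, sigmas (1, 2)) with
    padding 3.  The spike threshold is 50 in both cases.
    """
    if preset not in _PRESETS:
        raise ConfigurationError(
            f"unknown DoG preset {preset!r}; expected one of {sorted(_PRESETS)}"
        )
    sizes, sigma_pairs, pad = _PRESETS[preset]
    kernels: list[DoGKernel] = []
    for size, sigmas in zip(sizes, sigma_pairs):
        on = dog_kernel(size, *sigmas)
        kernels.append(DoGKernel(on, "ON", size, sigmas))
        kernels.append(DoGKernel(-on, "OFF", size, sigmas))
    return DoGFilterBank(kernels, common_window=max(sizes), pad=pad)


def _embedded_kernels(bank: DoGFilterBank) -> np.ndarray:
    """Stack all kernels centred in the bank's common window, ``(C, cw, cw)``."""
    cw = bank.common_window
    out = np.zeros((bank.n_channels, cw, cw))
    for c, k in enumerate(bank.kernels):
        if k.size > cw:
            raise ConfigurationError("kernel larger than the bank's common window")
        o = (cw - k.size) // 2
        out[c, o : o + k.size, o : o + k.size] = k.weights
    return out


def apply_dog(img: ImageStimulus, bank: DoGFilterBank) -> np.ndarray:
    """Convolve an image with every kernel of the bank.

    All kernels are embedded centred in the bank's common window and applied
    with the bank's zero padding, so all output channels share one spatial
    size.  Returns a feature volume ``(C, H', W')`` where
    ``H' = H + 2*pad - common_window + 1``.
    """
    kernels = _embedded_kernels(bank)
    cw = bank.common_window
    padded = np.pad(img.pixels, bank.pad)
    if padded.shape[0] < cw or padded.shape[1] < cw:
        raise DimensionError(
            f"common window {cw} exceeds padded image {padded.shape}"
        )
    windows = sliding_window_view(padded, (cw, cw))
    # correlation convention (no kernel flip); DoG kernels are symmetric
    return np.einsum("hwkl,ckl->chw", windows, kernels, optimize=True)


def intensity_to_latency(
    features: np.ndarray,
    T: int = DEFAULT_T,
    threshold: float = DEFAULT_SPIKE_THRESHOLD,
) -> SpikeWave:
    """Convert a feature volume into a rank-order spike wave.

    Exactly the sites whose feature value exceeds ``threshold`` spike.  They
    are sorted in descending value order (ties broken by row-major site
    index) and split into ``T`` rank-contiguous bins as equal as possible,
    the earliest bins taking the remainder; a site's bin index is its spike
    time.  Larger values therefore never spike later than smaller ones.
    """
    if T < 1:
        raise ConfigurationError("T must be >= 1")
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise DataError("feature volume contains non-finite values")
    flat = features.ravel()
    eligible = np.nonzero(flat > threshold)[0]
    spikes = np.zeros((T,) + features.shape, dtype=bool)
    n = eligible.size
    if n:
        # stable sort on -value keeps ascending site index within ties
        order = eligible[np.argsort(-flat[eligible], kind="stable")]
        base, rem = divmod(n, T)
        sizes = np.full(T, base)
        sizes[:rem] += 1
        times = np.repeat(np.arange(T), sizes)
        spikes.reshape(T, -1)[times, order] = True
    return SpikeWave(spikes)


def max_pool_spikes(sw: SpikeWave, window: int = 2, stride: int = 2) -> SpikeWave:
    """Temporal max pooling: each pooled site spikes at the earliest spike
    time over its spatial window (max pooling of cumulative spike trains).

    Output spatial size is ``((H - window)//stride + 1, ...)``; ragged edges
    are dropped.  The at-most-one-spike invariant is preserved.
    """
    if window < 1 or stride < 1:
        raise ConfigurationError("window and stride must be >= 1")
    T = sw.T
    times = sw.spike_times()  # (C, H, W), T == silent
    if times.shape[1] < window or times.shape[2] < window:
        raise DimensionError("pooling window larger than spike map")
    wins = sliding_window_view(times, (window, window), axis=(1, 2))
    pooled_t = wins[:, ::stride, ::stride].min(axis=(-2, -1))
    C, Ho, Wo = pooled_t.shape
    spikes = np.zeros((T, C, Ho, Wo), dtype=bool)
    c, h, w = np.nonzero(pooled_t < T)
    spikes[pooled_t[c, h, w], c, h, w] = True
    return SpikeWave(spikes)


def encode_image(
    img: ImageStimulus,
    bank: DoGFilterBank,
    T: int = DEFAULT_T,
    pool_window: int = 2,
    pool_stride: int = 2,
) -> SpikeWave:
    """Full retinal pipeline: DoG filtering, latency coding, spike pooling."""
    features = apply_dog(img, bank)
    sw = intensity_to_latency(features, T=T, threshold=bank.spike_threshold)
    return max_pool_spikes(sw, window=pool_window, stride=pool_stride)
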