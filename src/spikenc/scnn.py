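"""Integrate-and-Fire spiking convolutional layer with STDP learning.

The cortical layer of the network: 64 convolutional kernels of
Integrate-and-Fire (IF) neurons integrate the retinal spike wave.  Each
neuron's voltage accumulates the weighted presynaptic spikes of the previous
time step,

    v_i(t) = v_i(t-1) + sum_j w_ij * s_j(t-1),

and the neuron emits a spike and resets to zero when ``v_i(t) >= v_th``.
Neurons fire at most once per image.  Lateral inhibition keeps only the
earliest spike at each spatial position across channels, and a simplified
STDP rule updates the winner's afferent weights,

    dw = a+ * w * (1 - w)   if the presynaptic spike precedes (or ties) the
                            postsynaptic one,
    dw = a- * w * (1 - w)   otherwise (including silent presynaptic sites),

which drives weights toward {0, 1}.  Training stops when the convergence
measure C = sum_ij w_ij (1 - w_ij) / N falls below a threshold.

After training, features are read out with an infinite threshold: with no
firing and no reset the final voltage is simply the weight kernel correlated
with the total spike-count map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, DataError, DimensionError
from .frontend import SpikeWave

__all__ = [
    "IFConvLayer",
    "STDPConfig",
    "SpikeEvent",
    "TrainResult",
    "if_convolve_spikes",
    "lateral_inhibition",
    "select_stdp_winners",
    "stdp_update",
    "convergence_measure",
    "train_layer",
    "extract_features",
]


@dataclass
class IFConvLayer:
    """Synaptic weight tensor ``(n_out, n_in, kh, kw)`` with firing threshold.

    Weights live in ``[0, 1]``.  Default geometry follows the network used
    throughout this package: 64 output kernels, 5x5 windows, padding 2,
    threshold 10.
    """

    weights: np.ndarray
    v_th: float = 10.0
    pad: int = 2

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 4:
            raise DimensionError("weights must be (n_out, n_in, kh, kw)")
        if not np.all(np.isfinite(self.weights)):
            raise DataError("weights must be finite")
        if self.weights.min() < 0.0 or self.weights.max() > 1.0:
            raise DataError("weights must lie in [0, 1]")

    @classmethod
    def initialize(
        cls,
        n_out: int = 64,
        n_in: int = 6,
        kernel_size: int = 5,
        seed: int = 0,
        mean: float = 0.8,
        sd: float = 0.05,
        v_th: float = 10.0,
        pad: int = 2,
    ) -> "IFConvLayer":
        """Random initialization: normal(mean, sd) clipped to [0, 1]."""
        rng = np.random.default_rng(seed)
        w = rng.normal(mean, sd, size=(n_out, n_in, kernel_size, kernel_size))
        return cls(np.clip(w, 0.0, 1.0), v_th=v_th, pad=pad)

    @property
    def n_out(self) -> int:
        return self.weights.shape[0]

    @property
    def n_in(self) -> int:
        return self.weights.shape[1]

    @property
    def kernel_size(self) -> tuple[int, int]:
        return self.weights.shape[2], self.weights.shape[3]


@dataclass
class STDPConfig:
    """STDP training hyper-parameters.

    ``a_plus``/``a_minus`` are the initial potentiation/depression rates.
    Following the convention of the unsupervised spiking-CNN literature the
    rates are doubled every ``rate_boost_every`` weight updates (preserving
    their ratio) until ``a_plus`` reaches ``a_plus_cap``, which accelerates
    the late, saturating phase of learning; set ``rate_boost_every=None``
    to keep the rates fixed.
    """

    a_plus: float = 0.004
    a_minus: float = -0.003
    convergence_stop: float = 0.01
    winners_per_image: int = 1
    inhibition_radius: int = 2
    max_epochs: int = 64
    seed: int = 0
    rate_boost_every: int | None = 500
    a_plus_cap: float = 0.15

    def __post_init__(self) -> None:
        if self.a_plus <= 0 or self.a_minus >= 0:
            raise ConfigurationError("require a_plus > 0 and a_minus < 0")
        if not (0.0 < self.convergence_stop < 0.25):
            raise ConfigurationError("convergence_stop must lie in (0, 0.25)")
        if self.winners_per_image < 1:
            raise ConfigurationError("winners_per_image must be >= 1")
        if self.inhibition_radius < 0:
            raise ConfigurationError("inhibition_radius must be >= 0")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")


@dataclass(frozen=True)
class SpikeEvent:
    """One output spike: time step, site coordinates and voltage at firing."""

    t: int
    channel: int
    row: int
    col: int
    potential: float


@dataclass
class TrainResult:
    """Outcome of :func:`train_layer`."""

    layer: IFConvLayer
    trace: np.ndarray  # convergence measure after each image presentation
    converged: bool
    epochs_run: int
    n_updates: int


def _simulate_events(
    sw: SpikeWave, layer: IFConvLayer, min_channels: int | None = None
) -> list[SpikeEvent]:
    """Time-stepped IF simulation returning each site's first-crossing event.

    Because neurons fire at most once per image and are not revisited after
    firing, the event set is exactly the set of first threshold crossings of
    the un-reset voltage.  Spikes are accumulated sparsely: each presynaptic
    spike adds one (reversed) kernel patch to the voltage canvas.

    ``min_channels`` allows early stopping once events cover that many
    distinct output channels (sufficient to pick that many winners, since
    winners occupy distinct channels and later events never outrank earlier
    ones); the full per-timestep event order is preserved.
    """
    T, C, H, W = sw.shape
    if C != layer.n_in:
        raise DimensionError(
            f"spike wave has {C} channels but layer expects {layer.n_in}"
        )
    kh, kw = layer.kernel_size
    pad = layer.pad
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    if Ho < 1 or Wo < 1:
        raise DimensionError("kernel larger than padded input")

    wrev = layer.weights[:, :, ::-1, ::-1]
    vbig = np.zeros((layer.n_out, Hp + kh - 1, Wp + kw - 1))
    v = vbig[:, kh - 1 : kh - 1 + Ho, kw - 1 : kw - 1 + Wo]  # view
    fired = np.zeros((layer.n_out, Ho, Wo), dtype=bool)
    events: list[SpikeEvent] = []
    channels_fired: set[int] = set()

    for t in range(1, T):
        cs, ys, xs = np.nonzero(sw.spikes[t - 1])
        for c, y, x in zip(cs, ys + pad, xs + pad):
            vbig[:, y : y + kh, x : x + kw] += wrev[:, c]
        newly = (v >= layer.v_th) & ~fired
        if newly.any():
            for ch, r, cc in zip(*np.nonzero(newly)):
                events.append(
                    SpikeEvent(t, int(ch), int(r), int(cc), float(v[ch, r, cc]))
                )
                channels_fired.add(int(ch))
            fired |= newly
            if min_channels is not None and len(channels_fired) >= min_channels:
                break
    return events


def if_convolve_spikes(sw: SpikeWave, layer: IFConvLayer) -> list[SpikeEvent]:
    """Simulate the IF convolutional layer over a spike wave.

    Voltage at step ``t`` integrates the presynaptic spikes of step ``t-1``;
    a site fires once its voltage reaches ``v_th`` and never again within the
    image.  Returns all spike events in (time, channel, row, col) order.
    Input spikes at the final step influence only the infinite-threshold
    voltage readout (:func:`extract_features`), never an output spike.
    """
    return _simulate_events(sw, layer)


def lateral_inhibition(events: list[SpikeEvent]) -> list[SpikeEvent]:
    """Keep, at each (row, col), only the earliest event across channels.

    Ties in spike time are resolved toward the lowest channel index.
    """
    best: dict[tuple[int, int], SpikeEvent] = {}
    for e in sorted(events, key=lambda e: (e.t, e.channel, e.row, e.col)):
        best.setdefault((e.row, e.col), e)
    return sorted(best.values(), key=lambda e: (e.t, e.channel, e.row, e.col))


def select_stdp_winners(
    events: list[SpikeEvent], cfg: STDPConfig
) -> list[SpikeEvent]:
    """Pick at most ``winners_per_image`` learning winners.

    Events are ranked by earliest spike time, ties by highest potential at
    firing (then channel/site index for determinism).  At most one winner is
    allowed per output channel, which also enforces the same-channel
    suppression within ``inhibition_radius``.
    """
    ranked = sorted(
        events, key=lambda e: (e.t, -e.potential, e.channel, e.row, e.col)
    )
    winners: list[SpikeEvent] = []
    r = cfg.inhibition_radius
    for e in ranked:
        if len(winners) >= cfg.winners_per_image:
            break
        same_channel = [w for w in winners if w.channel == e.channel]
        if same_channel:
            continue  # one winner per channel (covers the radius rule too)
        if any(
            w.channel == e.channel
            and max(abs(w.row - e.row), abs(w.col - e.col)) <= r
            for w in winners
        ):
            continue
        winners.append(e)
    return winners


def stdp_update(
    layer: IFConvLayer,
    winner: SpikeEvent,
    sw: SpikeWave,
    cfg: STDPConfig,
    a_plus: float | None = None,
    a_minus: float | None = None,
) -> IFConvLayer:
    """Apply the simplified STDP rule to the winner's afferent weights.

    For every synapse in the winner's receptive field, the weight change is
    multiplicative: ``a+ * w * (1 - w)`` when the presynaptic site spiked at
    or before the winner's spike time, ``a- * w * (1 - w)`` otherwise.
    Presynaptic sites that never spike (including zero-padding sites outside
    the canvas) are depressed.  Weights remain in ``[0, 1]``; 0 and 1 are
    fixed points of the rule.  The layer is updated in place and returned.

    Explicit ``a_plus``/``a_minus`` override the config rates (used by
    :func:`train_layer` for rate boosting).
    """
    ap = cfg.a_plus if a_plus is None else a_plus
    am = cfg.a_minus if a_minus is None else a_minus
    kh, kw = layer.kernel_size
    pad = layer.pad
    T = sw.T
    times = np.pad(
        sw.spike_times(), ((0, 0), (pad, pad), (pad, pad)), constant_values=T
    )
    rf_times = times[:, winner.row : winner.row + kh, winner.col : winner.col + kw]
    potentiate = rf_times <= winner.t  # silent sites carry time T > winner.t
    w = layer.weights[winner.channel]
    w += np.where(potentiate, ap, am) * w * (1.0 - w)
    np.clip(w, 0.0, 1.0, out=w)
    return layer


def convergence_measure(layer: IFConvLayer) -> float:
    """Learning convergence C = sum_ij w_ij (1 - w_ij) / N, in [0, 0.25]."""
    w = layer.weights
    return float(np.mean(w * (1.0 - w)))


def train_layer(
    images: list[SpikeWave], layer: IFConvLayer, cfg: STDPConfig
) -> TrainResult:
    """Unsupervised STDP training of an IF convolutional layer.

    Loops over the spike-encoded images (reshuffled each epoch with
    ``cfg.seed``): simulate the layer, apply lateral inhibition, select the
    STDP winners and update their afferent weights.  The convergence measure
    is recorded after every image presentation and training stops as soon as
    it drops below ``cfg.convergence_stop`` or when ``cfg.max_epochs`` is
    exhausted (the latter yields a warning, not an error).
    """
    if not images:
        raise DataError("need at least one training image")
    rng = np.random.default_rng(cfg.seed)
    ap, am = cfg.a_plus, cfg.a_minus
    ratio = cfg.a_minus / cfg.a_plus
    trace: list[float] = []
    n_updates = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(images))
        for idx in order:
            sw = images[idx]
            events = _simulate_events(
                sw, layer, min_channels=cfg.winners_per_image
            )
            events = lateral_inhibition(events)
            for winner in select_stdp_winners(events, cfg):
                stdp_update(layer, winner, sw, cfg, a_plus=ap, a_minus=am)
                n_updates += 1
                if (
                    cfg.rate_boost_every is not None
                    and n_updates % cfg.rate_boost_every == 0
                    and ap < cfg.a_plus_cap
                ):
                    ap = min(2.0 * ap, cfg.a_plus_cap)
                    am = ratio * ap
            c = convergence_measure(layer)
            trace.append(c)
            if c < cfg.convergence_stop:
                return TrainResult(layer, np.asarray(trace), True, epoch + 1, n_updates)
    warnings.warn(
        "STDP training did not reach the convergence threshold "
        f"{cfg.convergence_stop} within {cfg.max_epochs} epochs "
        f"(final C = {trace[-1]:.4f})",
        stacklevel=2,
    )
    return TrainResult(layer, np.asarray(trace), False, cfg.max_epochs, n_updates)


def extract_features(sw: SpikeWave, layer: IFConvLayer) -> np.ndarray:
    """Infinite-threshold voltage readout: the network's feature volume.

    With ``v_th = inf`` no neuron fires or resets, so the voltage after the
    final time step equals the weight kernel correlated with the total
    spike-count map.  Returns ``(n_out, Ho, Wo)``.
    """
    T, C, H, W = sw.shape
    if C != layer.n_in:
        raise DimensionError(
            f"spike wave has {C} channels but layer expects {layer.n_in}"
        )
    kh, kw = layer.kernel_size
    pad = layer.pad
    counts = np.pad(sw.spike_counts(), ((0, 0), (pad, pad), (pad, pad)))
    if counts.shape[1] < kh or counts.shape[2] < kw:
        raise DimensionError("kernel larger than padded input")
    windows = sliding_window_view(counts, (kh, kw), axis=(1, 2))
    return np.einsum("ockl,chwkl->ohw", layer.weights, windows, optimize=True)
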