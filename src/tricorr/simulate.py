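"""Synthetic rasters for validating the motif-class analysis.

Three generators cover the validation conditions: thresholded-sine
rasters (network-wide periodic synchrony, optionally degraded by
per-channel uniform noise at a controlled SNR), single-triplet tilings
(one motif exemplar stamped on a grid far enough apart that analysis
windows never straddle two copies), and i.i.d. Bernoulli rasters (the
Poisson-per-bin null).  All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .lags import LagPair
from .raster import SpikeRaster

__all__ = [
    "PeriodicRasterSpec",
    "TripletTilingSpec",
    "periodic_raster",
    "triplet_tiling",
    "bernoulli_raster",
]


@dataclass(frozen=True)
class PeriodicRasterSpec:
    """Thresholded sine raster with SNR-controlled uniform noise.

    The shared signal is s(t) = sin(2*pi*freq*t); each channel adds
    i.i.d. Uniform(-a, a) noise with a set so that the pre-threshold
    power ratio mean(s^2)/mean(u^2) equals 10^(snr_db/10) (a = 0 for
    infinite SNR, making all channels identical).  A bin spikes when
    s(t) + u >= threshold.
    """

    n_channels: int = 150
    n_time_bins: int = 150
    freq: float = 0.08
    threshold: float = 0.9
    snr_db: float = math.inf
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.freq < 0.5):
            raise ValueError("freq must lie in (0, 0.5) cycles per bin")
        if not (-1.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (-1, 1)")
        if self.n_channels < 1 or self.n_time_bins < 1:
            raise ValueError("raster dimensions must be positive")


def periodic_raster(spec: PeriodicRasterSpec) -> SpikeRaster:
    """Generate the thresholded-sine raster described by ``spec``."""
    t = np.arange(spec.n_time_bins)
    signal = np.sin(2.0 * np.pi * spec.freq * t)
    if math.isinf(spec.snr_db):
        amp = 0.0
        grid = np.broadcast_to(signal, (spec.n_channels, spec.n_time_bins))
    else:
        power = float(np.mean(signal**2))
        amp = math.sqrt(3.0 * power / 10.0 ** (spec.snr_db / 10.0))
        rng = np.random.default_rng(spec.seed)
        noise = rng.uniform(-amp, amp, size=(spec.n_channels, spec.n_time_bins))
        grid = signal[None, :] + noise
    if spec.threshold >= signal.max() + amp:
        warnings.warn(
            f"threshold {spec.threshold} is unreachable (max attainable "
            f"{signal.max() + amp:.3f}); raster is empty",
            stacklevel=2,
        )
    return SpikeRaster((grid >= spec.threshold).astype(np.uint8))


@dataclass(frozen=True)
class TripletTilingSpec:
    """A single triplet motif stamped on a regular grid.

    ``lags`` is the motif exemplar (use
    :data:`~tricorr.motifs.EXEMPLAR_LAG_PAIRS` for canonical class
    exemplars); ``spacing`` is the anchor step per dimension (spatial
    dims then time; an int applies to all).  ``max_analysis_lag``, when
    given, asserts that no analysis window of that extent can straddle
    two tiles.
    """

    lags: LagPair
    n_channels: int = 150
    n_time_bins: int = 150
    spacing: tuple[int, ...] | int = 50
    max_analysis_lag: int | None = None

    @property
    def spacing_per_dim(self) -> tuple[int, ...]:
        d = self.lags.d_s + 1
        if isinstance(self.spacing, int):
            return (self.spacing,) * d
        if len(self.spacing) != d:
            raise ValueError(f"need {d} spacing entries, got {len(self.spacing)}")
        return tuple(int(s) for s in self.spacing)


def triplet_tiling(spec: TripletTilingSpec) -> SpikeRaster:
    """Tile one triplet motif across the raster.

    The three events A, A + lag1, A + lag2 are stamped at every anchor of
    the spacing grid for which all three fall inside the raster.
    """
    lags = spec.lags
    if lags.d_s != 1:
        raise ValueError("triplet tilings are generated for one spatial dimension")
    events = np.array(
        [(0, 0), (lags.n1[0], lags.t1), (lags.n2[0], lags.t2)], dtype=np.int64
    )
    extent = events.max(axis=0) - events.min(axis=0)  # motif footprint per dim
    spacing = spec.spacing_per_dim
    if spec.max_analysis_lag is not None:
        for d, s in enumerate(spacing):
            if s - extent[d] <= spec.max_analysis_lag:
                raise ValueError(
                    f"spacing {s} in dim {d} leaves inter-tile gaps of "
                    f"{s - extent[d]} bins, within the analysis lag "
                    f"{spec.max_analysis_lag}; cross-tile motifs would appear"
                )
    base = -events.min(axis=0)  # shift so all events are non-negative
    shape = (spec.n_channels, spec.n_time_bins)
    values = np.zeros(shape, dtype=np.uint8)
    for d, s in enumerate(spacing):
        if extent[d] >= s:
            raise ValueError(
                f"motif extent {extent[d]} in dim {d} does not fit in "
                f"spacing {s}"
            )
    anchors_n = range(base[0], shape[0], spacing[0])
    anchors_t = range(base[1], shape[1], spacing[1])
    for an in anchors_n:
        for at in anchors_t:
            pts = events + (an, at)
            if (pts[:, 0] < shape[0]).all() and (pts[:, 1] < shape[1]).all():
                values[pts[:, 0], pts[:, 1]] = 1
    return SpikeRaster(values)


def bernoulli_raster(
    n_channels: int | tuple[int, ...],
    n_time_bins: int,
    p: float,
    seed: int = 0,
) -> SpikeRaster:
    """I.i.d. Bernoulli(p) raster — the Poisson-per-bin null.

    ``n_channels`` may be a tuple for multi-dimensional spatial layouts
    (e.g. ``(4, 4)`` for an MEA grid).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    spatial = (n_channels,) if np.isscalar(n_channels) else tuple(n_channels)
    rng = np.random.default_rng(seed)
    values = (rng.random((*spatial, n_time_bins)) < p).astype(np.uint8)
    return SpikeRaster(values)
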