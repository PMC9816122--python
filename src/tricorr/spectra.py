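"""Containers for motif-class spectra, expectations and comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lags import LagWindow
from .motifs import CLASS_LABELS, MOTIF_CLASSES

__all__ = [
    "RasterMeta",
    "MotifClassSpectrum",
    "ExpectationSpectrum",
    "SurrogateEnsemble",
    "ComparisonResult",
]


@dataclass(frozen=True)
class RasterMeta:
    """Shape metadata of the analyzed raster."""

    n_channels: int  # N
    n_time_bins: int  # T

    @property
    def size(self) -> int:
        """NT."""
        return self.n_channels * self.n_time_bins


@dataclass
class MotifClassSpectrum:
    """The 14 motif-class contributions M_i of one raster.

    ``m`` is indexed by class code (0..13, labels in
    :data:`~tricorr.motifs.CLASS_LABELS`); ``m[0]`` equals the raster's
    total spike count.
    """

    m: np.ndarray
    window: LagWindow
    meta: RasterMeta
    boundary: str = "zero_pad"

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (len(MOTIF_CLASSES),):
            raise ValueError(f"expected {len(MOTIF_CLASSES)} contributions")
        if (self.m < 0).any():
            raise ValueError("contributions must be non-negative")

    @property
    def n_spikes(self) -> int:
        return int(round(self.m[0]))

    @property
    def rate(self) -> float:
        """p: spikes per bin."""
        return self.m[0] / self.meta.size

    def __getitem__(self, label: str) -> float:
        return float(self.m[CLASS_LABELS.index(label)])


@dataclass
class ExpectationSpectrum:
    """Poisson and constituent-controlled expectations with the ratio.

    ``ratio`` holds M_i / E_c[M_i] - 1; entries where M_i > 0 but
    E_c = 0 are +inf and flagged in ``undefined``; M = E_c = 0 yields 0.
    ``ratio[0]`` is identically 0 (class 0 is the spike rate, controlled
    for by N and T).
    """

    e: np.ndarray
    e_c: np.ndarray
    ratio: np.ndarray
    undefined: np.ndarray = field(default=None)

    def __post_init__(self):
        self.e = np.asarray(self.e, dtype=float)
        self.e_c = np.asarray(self.e_c, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.undefined is None:
            self.undefined = np.isinf(self.ratio)
        self.undefined = np.asarray(self.undefined, dtype=bool)

    def __getitem__(self, label: str) -> float:
        return float(self.ratio[CLASS_LABELS.index(label)])


@dataclass
class SurrogateEnsemble:
    """Spectra of randomized rasters plus a per-class ratio summary.

    ``ratios`` has one row per surrogate: each surrogate's own
    constituent-controlled ratio spectrum (mu_hat / mu_c - 1).
    ``summary`` maps quantile names to per-class values.
    """

    method: str
    n_surrogates: int
    seed: int
    spectra: list[MotifClassSpectrum]
    ratios: np.ndarray
    summary: dict[str, np.ndarray]


@dataclass
class ComparisonResult:
    """Per-class treatment/baseline quotients with absent flags.

    ``quotient`` is NaN where ``absent`` is True (e.g. the baseline ratio
    is zero, or a condition lacks spiking for that class).
    """

    quotient: np.ndarray
    absent: np.ndarray

    def __getitem__(self, label: str) -> float:
        return float(self.quotient[CLASS_LABELS.index(label)])
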