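"""End-to-end analysis: raster -> c3 -> spectrum -> null -> ratios.

Documents are plain dicts (JSON-serializable, human-diffable) carrying
the full provenance: configuration echo, seed, and package version.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import __version__
from .correlation import BOUNDARIES, class_contributions, compute_c3
from .lags import LagWindow
from .motifs import MOTIF_CLASSES, N_CLASSES, motif_count_table
from .nulls import compare_conditions, make_surrogates, ratio_spectrum
from .raster import SpikeRaster, SpikeTimesTable, bin_spike_times

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_spectrum", "run_compare", "run_compare_batch"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one spectrum run.

    ``max_lag_time`` and ``spatial_ranges`` define the lag window
    (``spatial_ranges`` is one inclusive ``(lo, hi)`` pair per spatial
    dimension, e.g. ``((-1, 2), (-1, 2))`` for a 4x4 electrode array);
    temporal lags quoted in milliseconds are converted via
    ``bin_rate_hz`` by the CLI before this object is built.
    """

    max_lag_time: int
    spatial_ranges: tuple[tuple[int, int], ...] = ((-1, 2),)
    boundary: str = "zero_pad"
    control: str = "poisson"
    surrogate_method: str | None = None
    n_surrogates: int = 100
    seed: int = 0
    bin_rate_hz: float | None = None
    duration_s: float | None = None

    def __post_init__(self):
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}")
        if self.max_lag_time < 0:
            raise ValueError("max_lag_time must be non-negative")
        if self.surrogate_method is not None and self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1 when surrogates requested")

    @property
    def window(self) -> LagWindow:
        return LagWindow(
            spatial=self.spatial_ranges,
            time=(-self.max_lag_time, self.max_lag_time),
        )

    def to_dict(self) -> dict:
        return {
            "max_lag_time": self.max_lag_time,
            "spatial_ranges": [list(r) for r in self.spatial_ranges],
            "boundary": self.boundary,
            "control": self.control,
            "surrogate_method": self.surrogate_method,
            "n_surrogates": self.n_surrogates,
            "seed": self.seed,
            "bin_rate_hz": self.bin_rate_hz,
            "duration_s": self.duration_s,
        }


def _as_raster(data, config: AnalysisConfig) -> SpikeRaster:
    if isinstance(data, SpikeRaster):
        return data
    if isinstance(data, SpikeTimesTable):
        if config.bin_rate_hz is None:
            raise ValueError("spike-time input requires bin_rate_hz")
        duration = config.duration_s
        if duration is None:
            duration = float(data.records["time_s"].max()) + 1.0 / config.bin_rate_hz
        return bin_spike_times(data, config.bin_rate_hz, duration)
    raise TypeError(f"cannot analyze {type(data).__name__}")


def run_spectrum(data, config: AnalysisConfig) -> dict:
    """Full analysis of one raster (or spike-time table): the spectrum document.

    The document carries per-class M, E, E_c, ratio and motif counts,
    plus the surrogate ensemble summary when requested.  An empty raster
    yields all-zero contributions and ratios, with a logged warning.
    """
    raster = _as_raster(data, config)
    window = config.window
    if raster.n_spikes == 0:
        logger.warning("raster has no spikes; spectrum is all zeros")
    c3 = compute_c3(raster, window, boundary=config.boundary)
    spectrum = class_contributions(c3)
    expect = ratio_spectrum(spectrum, control=config.control)
    counts = motif_count_table(window)
    doc = {
        "package": "tricorr",
        "version": __version__,
        "config": config.to_dict(),
        "raster": {
            "spatial_shape": list(raster.spatial_shape),
            "n_channels": raster.n_channels,
            "n_time_bins": raster.n_time_bins,
            "n_spikes": raster.n_spikes,
            "rate": raster.rate,
        },
        "classes": [
            {
                "label": cls.label,
                "name": cls.name,
                "order": cls.order,
                "constituents": sorted(cls.constituents),
                "n_motifs": int(counts[cls.index]),
                "M": float(spectrum.m[cls.index]),
                "E": float(expect.e[cls.index]),
                "E_c": float(expect.e_c[cls.index]),
                "ratio": float(expect.ratio[cls.index]),
                "undefined": bool(expect.undefined[cls.index]),
            }
            for cls in MOTIF_CLASSES
        ],
    }
    if config.surrogate_method is not None:
        ensemble = make_surrogates(
            raster,
            window,
            method=config.surrogate_method,
            n=config.n_surrogates,
            seed=config.seed,
            boundary=config.boundary,
            control=config.control,
        )
        doc["surrogates"] = {
            "method": ensemble.method,
            "n": ensemble.n_surrogates,
            "seed": ensemble.seed,
            "summary": {k: list(map(float, v)) for k, v in ensemble.summary.items()},
        }
    return doc


def _config_signature(doc: dict) -> dict:
    cfg = doc["config"]
    return {k: cfg[k] for k in ("max_lag_time", "spatial_ranges", "boundary", "control")}


def _doc_ratios(doc: dict) -> np.ndarray:
    ratios = np.full(N_CLASSES, np.nan)
    for entry in doc["classes"]:
        idx = next(c.index for c in MOTIF_CLASSES if c.label == entry["label"])
        ratios[idx] = np.inf if entry["undefined"] else entry["ratio"]
    return ratios


def run_compare(baseline_doc: dict, treatment_doc: dict) -> dict:
    """Per-class treatment/baseline quotients of the ratio spectra.

    Both documents must share the window/boundary configuration; classes
    without a usable quotient (zero or undefined baseline, missing
    spiking) carry an absent flag rather than a value.
    """
    if _config_signature(baseline_doc) != _config_signature(treatment_doc):
        raise ValueError(
            "baseline and treatment were analyzed with different window/"
            "boundary configurations; re-run with matching configs"
        )
    result = compare_conditions(_doc_ratios(treatment_doc), _doc_ratios(baseline_doc))
    return {
        "package": "tricorr",
        "version": __version__,
        "config": _config_signature(baseline_doc),
        "classes": [
            {
                "label": cls.label,
                "quotient": None
                if result.absent[cls.index]
                else float(result.quotient[cls.index]),
                "absent": bool(result.absent[cls.index]),
            }
            for cls in MOTIF_CLASSES
        ],
    }


def run_compare_batch(pairs: list[tuple[dict, dict]]) -> dict:
    """Five-number summaries of per-class quotients over matched well pairs.

    ``pairs`` holds (baseline_doc, treatment_doc) tuples, one per matched
    well pair; per class, quotients from pairs where the class is absent
    are dropped, and the summary reports min/q25/median/q75/max over the
    remainder (the boxplot convention).
    """
    docs = [run_compare(b, t) for b, t in pairs]
    out = {"package": "tricorr", "version": __version__, "n_pairs": len(pairs),
           "classes": []}
    for idx, cls in enumerate(MOTIF_CLASSES):
        values = [
            d["classes"][idx]["quotient"]
            for d in docs
            if not d["classes"][idx]["absent"]
        ]
        entry = {"label": cls.label, "n": len(values)}
        if values:
            q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0])
            entry.update(
                min=float(q[0]), q25=float(q[1]), median=float(q[2]),
                q75=float(q[3]), max=float(q[4]),
            )
        else:
            entry["absent"] = True
        out["classes"].append(entry)
    return out
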