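"""Null models for motif-class spectra.

Two nulls are provided.  The analytic Poisson null treats every channel
as a Bernoulli process with the observed rate p per bin:

    E[M_i | p, lambda] = NT * #(M_i | lambda) * p^{n_i}

with #(M_i | lambda) the number of lag pairs of class i in the window
and n_i the class order.  The constituent-controlled expectation E_c
additionally conditions on the observed contributions of the class's
second-order constituents: writing q_c = M_c / (NT * #(M_c | lambda))
for the empirical pair rate of constituent class c, and (c12, c23) for
the classes of the two temporally adjacent event pairs of the canonical
triplet,

    E_c[M_i] = NT * #(M_i | lambda) * q_c12 * q_c23 / p .

For classes 0, I, III and V, E_c = E.  Substituting M_c = E[M_c]
recovers E_c = E exactly, so the reported statistic M_i / E_c[M_i] - 1
fluctuates around zero on Poisson rasters and is positive where a class
contributes more than its rate and pairwise structure explain.

Surrogate ensembles estimate the same null empirically: global bin
shuffles (preserving total spike count), within-channel shuffles
(preserving each channel's count; appropriate for heterogeneous rates),
or rate-matched i.i.d. Bernoulli rasters.
"""

from __future__ import annotations

import numpy as np

from .correlation import class_contributions, compute_c3
from .lags import LagWindow
from .motifs import CLASS_ORDERS, MOTIF_CLASSES, N_CLASSES, class_by_label, motif_count_table
from .raster import SpikeRaster
from .spectra import (
    ComparisonResult,
    ExpectationSpectrum,
    MotifClassSpectrum,
    SurrogateEnsemble,
)

__all__ = [
    "expected_contributions",
    "constituent_controlled_expectation",
    "ratio_spectrum",
    "surrogate_raster",
    "make_surrogates",
    "compare_conditions",
    "SURROGATE_METHODS",
]

SURROGATE_METHODS = ("shuffle_all", "shuffle_within_channel", "bernoulli_matched")


def expected_contributions(
    p: float, window: LagWindow, n_channels: int, n_time_bins: int
) -> np.ndarray:
    """Poisson-null expectation E[M_i | p, lambda] for all 14 classes."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rate p must lie in [0, 1], got {p}")
    nt = n_channels * n_time_bins
    counts = motif_count_table(window)
    return nt * counts * p ** CLASS_ORDERS.astype(float)


def constituent_controlled_expectation(
    spectrum: MotifClassSpectrum, window: LagWindow | None = None
) -> np.ndarray:
    """E_c[M_i]: expectation controlling for constituent contributions.

    Uses the adjacent-pair chain rule described in the module docstring.
    With p = 0 every E_c is 0 (and any positive third-order contribution
    is inconsistent with an empty raster).
    """
    window = window or spectrum.window
    nt = spectrum.meta.size
    counts = motif_count_table(window).astype(float)
    p = spectrum.m[0] / nt
    e = expected_contributions(p, window, spectrum.meta.n_channels, spectrum.meta.n_time_bins)
    e_c = np.array(e)
    if p == 0.0:
        if (spectrum.m[1:] > 0).any():
            raise ValueError(
                "raster has no spikes yet non-zero higher-order contributions"
            )
        return e_c
    q = {}  # empirical pair rate per constituent class
    for label in ("I", "III", "V"):
        c = class_by_label(label)
        q[label] = spectrum.m[c.index] / (nt * counts[c.index])
    for cls in MOTIF_CLASSES:
        if cls.order == 3:
            c12, c23 = cls.adjacent_pairs
            e_c[cls.index] = nt * counts[cls.index] * q[c12] * q[c23] / p
    return e_c


def ratio_spectrum(
    spectrum: MotifClassSpectrum,
    window: LagWindow | None = None,
    control: str = "poisson",
) -> ExpectationSpectrum:
    """The reported statistic M_i / E_c[M_i] - 1 per motif class.

    Positive values mean a class contributes more than chance predicts;
    ratio_0 is identically 0.  A class with M_i > 0 but E_c = 0 is
    flagged (+inf), never silently dropped; M_i = E_c = 0 gives 0 (class
    absent, no evidence either way).

    ``control`` selects the denominator's anchoring.  ``"poisson"`` (the
    default) evaluates the constituent-controlled expectation at the
    rate-matched null's pair rates (q_c = p^2), where the chain rule
    reduces to E[M_i | p, lambda]; this is the statistic whose surrogate
    distribution centers on zero and which flags every form of structure,
    second- or third-order.  ``"observed"`` plugs in the analyzed
    raster's own pair rates, discounting third-order classes whose
    excess is already explained by their pairwise constituents (e.g. a
    fully synchronous raster then scores ratio_IV ~ 0).
    """
    window = window or spectrum.window
    p = spectrum.m[0] / spectrum.meta.size
    e = expected_contributions(
        p, window, spectrum.meta.n_channels, spectrum.meta.n_time_bins
    )
    if control == "poisson":
        e_c = np.array(e)
    elif control == "observed":
        e_c = constituent_controlled_expectation(spectrum, window)
    else:
        raise ValueError(f"control must be 'poisson' or 'observed', got {control!r}")
    ratio = np.zeros(N_CLASSES)
    pos = e_c > 0
    ratio[pos] = spectrum.m[pos] / e_c[pos] - 1.0
    bad = (~pos) & (spectrum.m > 0)
    ratio[bad] = np.inf
    ratio[0] = 0.0
    return ExpectationSpectrum(e=e, e_c=e_c, ratio=ratio)


def surrogate_raster(
    raster: SpikeRaster, method: str, rng: np.random.Generator
) -> SpikeRaster:
    """One randomized raster preserving what the method promises.

    ``shuffle_all`` permutes all bins (exact total spike count);
    ``shuffle_within_channel`` permutes each channel's bins (exact
    per-channel counts); ``bernoulli_matched`` draws i.i.d. Bernoulli
    bins at the observed rate (rate matched in expectation).
    """
    if method not in SURROGATE_METHODS:
        raise ValueError(f"method must be one of {SURROGATE_METHODS}, got {method!r}")
    if method == "shuffle_all":
        values = rng.permutation(raster.values.ravel()).reshape(raster.values.shape)
    elif method == "shuffle_within_channel":
        flat = raster.flat_values().copy()
        for row in flat:
            rng.shuffle(row)
        values = flat.reshape(raster.values.shape)
    else:
        values = (rng.random(raster.values.shape) < raster.rate).astype(np.uint8)
    return SpikeRaster(values, bin_width_s=raster.bin_width_s,
                       channel_labels=raster.channel_labels)


def make_surrogates(
    raster: SpikeRaster,
    window: LagWindow,
    method: str = "shuffle_all",
    n: int = 100,
    seed: int = 0,
    boundary: str = "zero_pad",
    control: str = "poisson",
) -> SurrogateEnsemble:
    """Surrogate ensemble: n randomized rasters and their ratio spectra.

    Each surrogate is scored with its *own* constituent-controlled
    expectation (mu_hat / mu_c - 1), so on structureless surrogates the
    per-class ratio distributions center on zero.  Bit-reproducible
    given (method, n, seed).
    """
    if n < 1:
        raise ValueError("need at least one surrogate")
    rng = np.random.default_rng(seed)
    spectra: list[MotifClassSpectrum] = []
    ratios = np.empty((n, N_CLASSES))
    for k in range(n):
        surrogate = surrogate_raster(raster, method, rng)
        spec = class_contributions(compute_c3(surrogate, window, boundary=boundary))
        spectra.append(spec)
        ratios[k] = ratio_spectrum(spec, control=control).ratio
    summary = {
        "min": ratios.min(axis=0),
        "q25": np.quantile(ratios, 0.25, axis=0),
        "median": np.median(ratios, axis=0),
        "q75": np.quantile(ratios, 0.75, axis=0),
        "max": ratios.max(axis=0),
        "mean": ratios.mean(axis=0),
    }
    return SurrogateEnsemble(
        method=method, n_surrogates=n, seed=seed,
        spectra=spectra, ratios=ratios, summary=summary,
    )


def compare_conditions(treatment, baseline) -> ComparisonResult:
    """Per-class quotient of treatment over baseline ratio spectra.

    Classes where the baseline ratio is zero (or either side is missing
    or undefined) are flagged absent rather than raising.
    """
    t = np.asarray(
        treatment.ratio if isinstance(treatment, ExpectationSpectrum) else treatment,
        dtype=float,
    )
    b = np.asarray(
        baseline.ratio if isinstance(baseline, ExpectationSpectrum) else baseline,
        dtype=float,
    )
    if t.shape != (N_CLASSES,) or b.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} ratios per condition")
    absent = (b == 0) | ~np.isfinite(b) | ~np.isfinite(t)
    quotient = np.full(N_CLASSES, np.nan)
    quotient[~absent] = t[~absent] / b[~absent]
    return ComparisonResult(quotient=quotient, absent=absent)
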