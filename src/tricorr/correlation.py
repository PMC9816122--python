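"""Triple correlation of a binary raster over a rectangular lag window.

The triple correlation is

    c3(n1, t1, n2, t2) = sum over anchors (n, t) of
                         r(n, t) * r(n + n1, t + t1) * r(n + n2, t + t2)

evaluated for every lag pair in the window (count normalization; the
average form divides by NT).  Out-of-range partners are treated as empty
under ``zero_pad`` and wrapped modulo the raster extent under
``periodic``; ``periodic_spatial`` wraps the spatial dimensions only
(the convention for closed electrode arrays, where time has a genuine
beginning and end).

The computation is event-driven: for each spike, the lags to all spikes
inside the window are collected once, and every ordered pair of present
lags increments one cell of the c3 table.  This is exact (integer
counts) and fast for the sparse rasters spike data produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .lags import LagPair, LagWindow
from .motifs import N_CLASSES, window_class_codes
from .raster import SpikeRaster
from .spectra import MotifClassSpectrum, RasterMeta

__all__ = ["TripleCorrelation", "compute_c3", "class_contributions", "BOUNDARIES"]

BOUNDARIES = ("zero_pad", "periodic", "periodic_spatial")


@njit(cache=False)
def _c3_kernel(flat, shape, strides, spikes, offsets, wrap):  # pragma: no cover
    n_spk = spikes.shape[0]
    n_off = offsets.shape[0]
    n_dim = shape.shape[0]
    out = np.zeros(n_off * n_off, np.int64)
    present = np.empty(n_off, np.int64)
    for s in range(n_spk):
        m = 0
        for w in range(n_off):
            idx = 0
            ok = True
            for d in range(n_dim):
                c = spikes[s, d] + offsets[w, d]
                if wrap[d]:
                    c = c % shape[d]
                elif c < 0 or c >= shape[d]:
                    ok = False
                    break
                idx += c * strides[d]
            if ok and flat[idx] != 0:
                present[m] = w
                m += 1
        for i in range(m):
            base = present[i] * n_off
            for j in range(m):
                out[base + present[j]] += 1
    return out


@dataclass
class TripleCorrelation:
    """c3 values over the lag window.

    ``values`` has shape ``(S, Tn, S, Tn)``: flattened spatial lag index
    (C-order over the window's spatial ranges) and temporal lag index,
    once per lag vector.  Count mode holds exact integer counts; average
    mode holds counts / NT.
    """

    values: np.ndarray
    window: LagWindow
    boundary: str
    normalization: str
    meta: RasterMeta
    n_spikes: int

    def value(self, lags: LagPair) -> float:
        """c3 at one lag pair."""
        w = self.window
        idx = (
            w.spatial_index(lags.n1),
            w.time_index(lags.t1),
            w.spatial_index(lags.n2),
            w.time_index(lags.t2),
        )
        return self.values[idx].item()

    def to_frame(self):
        """Export as a DataFrame with one row per lag pair."""
        import pandas as pd

        w = self.window
        sp = w.spatial_offsets()
        tv = w.time_offsets()
        n_s, n_t = sp.shape[0], tv.shape[0]
        i1, j1, i2, j2 = np.unravel_index(
            np.arange(self.values.size), self.values.shape
        )
        cols = {}
        for d in range(w.d_s):
            suffix = "" if w.d_s == 1 else f"_{'xy'[d] if d < 2 else d}"
            cols[f"n1{suffix}"] = sp[i1, d]
        cols["t1"] = tv[j1]
        for d in range(w.d_s):
            suffix = "" if w.d_s == 1 else f"_{'xy'[d] if d < 2 else d}"
            cols[f"n2{suffix}"] = sp[i2, d]
        cols["t2"] = tv[j2]
        cols["value"] = self.values.ravel()
        return pd.DataFrame(cols)


def _check_window(raster: SpikeRaster, window: LagWindow, boundary: str) -> None:
    extents = (*raster.spatial_shape, raster.n_time_bins)
    ranges = (*window.spatial, window.time)
    wrap_all = boundary == "periodic"
    wrap_spatial = boundary == "periodic_spatial"
    for d, ((lo, hi), extent) in enumerate(zip(ranges, extents)):
        span = hi - lo + 1
        wrapped = wrap_all or (wrap_spatial and d < raster.d_s)
        if wrapped and span > extent:
            raise ValueError(
                f"window span {span} in dim {d} exceeds the period {extent}"
            )
        if not wrapped and (hi >= extent or -lo >= extent):
            raise ValueError(
                f"window range [{lo}, {hi}] in dim {d} exceeds the raster "
                f"extent {extent}"
            )


def compute_c3(
    raster: SpikeRaster,
    window: LagWindow,
    boundary: str = "zero_pad",
    normalization: str = "count",
) -> TripleCorrelation:
    """Compute the triple correlation of a raster over a lag window."""
    if boundary not in BOUNDARIES:
        raise ValueError(f"boundary must be one of {BOUNDARIES}, got {boundary!r}")
    if normalization not in ("count", "average"):
        raise ValueError(f"normalization must be 'count' or 'average'")
    if window.d_s != raster.d_s:
        raise ValueError(
            f"window has {window.d_s} spatial dims but raster has {raster.d_s}"
        )
    _check_window(raster, window, boundary)

    values = np.ascontiguousarray(raster.values)
    shape = np.array(values.shape, dtype=np.int64)
    strides = np.array(
        [int(s) // values.itemsize for s in values.strides], dtype=np.int64
    )
    spikes = np.argwhere(values).astype(np.int64)
    offsets = window.offsets()
    n_dim = values.ndim
    if boundary == "periodic":
        wrap = np.ones(n_dim, dtype=np.bool_)
    elif boundary == "periodic_spatial":
        wrap = np.array([d < n_dim - 1 for d in range(n_dim)], dtype=np.bool_)
    else:
        wrap = np.zeros(n_dim, dtype=np.bool_)

    counts = _c3_kernel(values.ravel(), shape, strides, spikes, offsets, wrap)
    n_s = window.n_spatial_lags
    n_t = window.n_time_lags
    c3 = counts.reshape(n_s, n_t, n_s, n_t)
    meta = RasterMeta(raster.n_channels, raster.n_time_bins)
    if normalization == "average":
        c3 = c3 / meta.size
    return TripleCorrelation(
        values=c3,
        window=window,
        boundary=boundary,
        normalization=normalization,
        meta=meta,
        n_spikes=raster.n_spikes,
    )


def class_contributions(c3: TripleCorrelation) -> MotifClassSpectrum:
    """Sum c3 over the lag pairs of each motif class: M_i = sum c3(m).

    Requires count normalization, so that M_0 equals the raster's spike
    count and E[M_i] = NT * #(M_i | lambda) * p^{n_i} applies directly.
    The 14 contributions sum to the total of c3 over the window.
    """
    if c3.normalization != "count":
        raise ValueError(
            "class contributions require count normalization; recompute c3 "
            "with normalization='count'"
        )
    codes = window_class_codes(c3.window)
    m = np.bincount(
        codes.ravel(), weights=c3.values.ravel().astype(float), minlength=N_CLASSES
    )
    return MotifClassSpectrum(
        m=m, window=c3.window, meta=c3.meta, boundary=c3.boundary
    )
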