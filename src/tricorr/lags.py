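"""Lag vectors and rectangular lag windows.

A triplet motif is anchored at an event A and specified by two
spatiotemporal lag vectors: B = A + (n1, t1), C = A + (n2, t2), where
``n`` is an integer spatial lag vector (one entry per spatial dimension)
and ``t`` an integer time lag in bins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["LagPair", "LagWindow"]


def _as_spatial(n) -> tuple[int, ...]:
    if np.isscalar(n):
        return (int(n),)
    return tuple(int(v) for v in n)


@dataclass(frozen=True)
class LagPair:
    """The two lag vectors defining a triplet motif relative to its anchor."""

    n1: tuple[int, ...]
    t1: int
    n2: tuple[int, ...]
    t2: int

    def __init__(self, n1, t1, n2, t2):
        object.__setattr__(self, "n1", _as_spatial(n1))
        object.__setattr__(self, "t1", int(t1))
        object.__setattr__(self, "n2", _as_spatial(n2))
        object.__setattr__(self, "t2", int(t2))
        if len(self.n1) != len(self.n2):
            raise ValueError(
                f"spatial lag vectors differ in length: {self.n1} vs {self.n2}"
            )

    @property
    def d_s(self) -> int:
        """Number of spatial dimensions."""
        return len(self.n1)

    @property
    def lag1(self) -> tuple[tuple[int, ...], int]:
        return (self.n1, self.t1)

    @property
    def lag2(self) -> tuple[tuple[int, ...], int]:
        return (self.n2, self.t2)


@dataclass(frozen=True)
class LagWindow:
    """Rectangular lag window: an inclusive integer range per dimension.

    The same per-dimension ranges apply to both lag vectors of a pair
    (a rectangular product window).  Every range must contain zero; ranges
    may be asymmetric, e.g. spatial ``-1:2`` for a periodic 4-electrode
    dimension.

    Parameters
    ----------
    spatial
        One ``(lo, hi)`` pair per spatial dimension.
    time
        The ``(lo, hi)`` pair for the temporal lag.
    """

    spatial: tuple[tuple[int, int], ...]
    time: tuple[int, int]

    def __init__(self, spatial, time):
        spatial = tuple(
            (int(lo), int(hi)) for lo, hi in (spatial if spatial and not np.isscalar(spatial[0]) else [spatial])
        )
        time = (int(time[0]), int(time[1]))
        for lo, hi in (*spatial, time):
            if not (lo <= 0 <= hi):
                raise ValueError(f"lag range [{lo}, {hi}] must contain zero")
        object.__setattr__(self, "spatial", spatial)
        object.__setattr__(self, "time", time)

    @classmethod
    def symmetric(cls, max_time: int, max_space: int, d_s: int = 1) -> "LagWindow":
        """Window with lags ``-max:+max`` in time and in each spatial dim."""
        return cls(
            spatial=tuple((-max_space, max_space) for _ in range(d_s)),
            time=(-max_time, max_time),
        )

    @property
    def d_s(self) -> int:
        return len(self.spatial)

    @property
    def spatial_sizes(self) -> tuple[int, ...]:
        return tuple(hi - lo + 1 for lo, hi in self.spatial)

    @property
    def n_spatial_lags(self) -> int:
        return int(np.prod(self.spatial_sizes))

    @property
    def n_time_lags(self) -> int:
        lo, hi = self.time
        return hi - lo + 1

    @property
    def n_lags(self) -> int:
        """Number of single lag vectors in the window."""
        return self.n_spatial_lags * self.n_time_lags

    @property
    def n_lag_pairs(self) -> int:
        return self.n_lags**2

    def spatial_offsets(self) -> np.ndarray:
        """All spatial lag vectors, shape ``(n_spatial_lags, d_s)``, C-order."""
        ranges = [np.arange(lo, hi + 1) for lo, hi in self.spatial]
        grids = np.meshgrid(*ranges, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)

    def time_offsets(self) -> np.ndarray:
        lo, hi = self.time
        return np.arange(lo, hi + 1, dtype=np.int64)

    def offsets(self) -> np.ndarray:
        """All lag vectors ``(spatial..., time)``, shape ``(n_lags, d_s+1)``.

        Ordered C-style with time fastest, matching a reshape to
        ``(*spatial_sizes, n_time_lags)``.
        """
        ranges = [np.arange(lo, hi + 1) for lo, hi in self.spatial]
        ranges.append(self.time_offsets())
        grids = np.meshgrid(*ranges, indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)

    def spatial_index(self, n: tuple[int, ...]) -> int:
        """Flat C-order index of a spatial lag vector within the window."""
        if len(n) != self.d_s:
            raise ValueError(f"expected {self.d_s} spatial components, got {len(n)}")
        idx = 0
        for (lo, hi), v, size in zip(self.spatial, n, self.spatial_sizes):
            if not (lo <= v <= hi):
                raise KeyError(f"spatial lag {n} outside window")
            idx = idx * size + (v - lo)
        return idx

    def time_index(self, t: int) -> int:
        lo, hi = self.time
        if not (lo <= t <= hi):
            raise KeyError(f"time lag {t} outside window")
        return t - lo

    def iter_lag_pairs(self):
        """Iterate over every :class:`LagPair` in the window (small windows)."""
        offs = self.offsets()
        for a, b in itertools.product(offs, repeat=2):
            yield LagPair(tuple(a[:-1]), int(a[-1]), tuple(b[:-1]), int(b[-1]))
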