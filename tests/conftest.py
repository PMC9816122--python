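"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results from first principles
(naive loops over anchors and lags, multiset reasoning over the three
events) so that the package's vectorized/event-driven implementations
are checked against structurally different code.
"""

from __future__ import annotations

import numpy as np
import pytest

from tricorr.lags import LagWindow


@pytest.fixture
def rng():
    return np.random.default_rng(20230105)


def oracle_c3(values: np.ndarray, window: LagWindow, boundary: str) -> np.ndarray:
    """Brute-force triple loop over anchors and both lags.

    Returns the (n_lags, n_lags) count table in window-offset order.
    """
    shape = values.shape
    offsets = [tuple(int(v) for v in o) for o in window.offsets()]
    n_off = len(offsets)
    out = np.zeros((n_off, n_off), dtype=np.int64)

    def at(point):
        coord = []
        for d, c in enumerate(point):
            if boundary == "periodic":
                c %= shape[d]
            elif not (0 <= c < shape[d]):
                return 0
            coord.append(c)
        return values[tuple(coord)]

    for anchor in np.ndindex(shape):
        if values[anchor] == 0:
            continue
        for i, off1 in enumerate(offsets):
            if at(tuple(a + o for a, o in zip(anchor, off1))) == 0:
                continue
            for j, off2 in enumerate(offsets):
                if at(tuple(a + o for a, o in zip(anchor, off2))):
                    out[i, j] += 1
    return out


def multiset_classify(n1: int, t1: int, n2: int, t2: int) -> str:
    """Independent event-multiset classifier (one spatial dimension).

    Works purely from the distinct-event count and the position/time
    coincidence structure of the three events, without the package's
    canonical-form code path.
    """
    events = {(0, 0), (n1, t1), (n2, t2)}
    positions = [e[0] for e in events]
    times = [e[1] for e in events]
    k = len(events)
    if k == 1:
        return "0"
    if k == 2:
        if len(set(positions)) == 1:
            return "I"
        if len(set(times)) == 1:
            return "III"
        return "V"
    n_times = len(set(times))
    if n_times == 1:
        return "IV"
    if n_times == 2:
        sync_time = next(t for t in times if times.count(t) == 2)
        lone = next(e for e in events if e[1] != sync_time)
        pair_positions = [e[0] for e in events if e[1] == sync_time]
        shared = lone[0] in pair_positions
        earlier = lone[1] < sync_time
        if shared:
            return "VI" if earlier else "VII"
        return "XI" if earlier else "XII"
    n_pos = len(set(positions))
    if n_pos == 1:
        return "II"
    if n_pos == 3:
        return "XIII"
    dup_pos = next(p for p in positions if positions.count(p) == 2)
    dup_times = sorted(e[1] for e in events if e[0] == dup_pos)
    ranks = sorted(sorted(times).index(t) for t in dup_times)
    return {(0, 1): "VIII", (0, 2): "IX", (1, 2): "X"}[tuple(ranks)]
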