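"""Triplet motif taxonomy: lag-sign motifs and the fourteen motif classes.

Three events A, B = A + (n1, t1), C = A + (n2, t2) form a triplet motif.
Grouping the four lags by zero/non-zero gives 16 groups; refining by the
signs of the lags and of the between-event lag differences gives 169
realizable lag-sign motifs (one spatial dimension); identifying motifs
that differ only by node-identity permutation and spatial reflection,
and collapsing spatial lags to intra- (zero) vs inter-neuronal
(non-zero), reduces them to fourteen motif classes.

Class 0 is the spike rate (one event).  The second-order classes are
I (autocorrelation: one neuron, two times), III (synchrony: two neurons,
one time) and V (propagation / cross-correlation: two neurons, two
times); they are the *constituents* out of which every third-order class
is built.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .lags import LagPair, LagWindow

__all__ = [
    "MotifClass",
    "MOTIF_CLASSES",
    "CLASS_LABELS",
    "class_by_label",
    "LagSignMotif",
    "zero_pattern_group",
    "enumerate_lag_sign_motifs",
    "classify",
    "classify_codes",
    "reduce_to_classes",
    "count_motifs",
    "motif_count_table",
    "window_class_codes",
    "class_table_frame",
    "EXEMPLAR_LAG_PAIRS",
]


@dataclass(frozen=True)
class MotifClass:
    """One of the fourteen motif classes.

    ``order`` is the number of distinct events (1, 2 or 3);
    ``constituents`` are the second-order classes embedded in the motif;
    ``adjacent_pairs`` gives, for third-order classes, the classes of the
    two temporally adjacent event pairs of the canonical triplet (used by
    the constituent-controlled expectation).
    """

    index: int
    label: str
    order: int
    constituents: frozenset[str]
    name: str
    adjacent_pairs: tuple[str, str] | None = None


def _mc(i, label, order, cons, name, adj=None):
    return MotifClass(i, label, order, frozenset(cons), name, adj)


# Numeral conventions that the taxonomy itself does not force (VI vs VII,
# VIII vs X, XI vs XII) are centralized here: VI/XI lone event earlier,
# VII/XII lone event later; VIII co-located pair earliest, X latest.
MOTIF_CLASSES: tuple[MotifClass, ...] = (
    _mc(0, "0", 1, (), "spike rate"),
    _mc(1, "I", 2, ("I",), "autocorrelation"),
    _mc(2, "II", 3, ("I",), "local dynamics", ("I", "I")),
    _mc(3, "III", 2, ("III",), "synchrony"),
    _mc(4, "IV", 3, ("III",), "third-order synchrony", ("III", "III")),
    _mc(5, "V", 2, ("V",), "propagation"),
    _mc(6, "VI", 3, ("I", "III", "V"), "co-located lead-in to synchrony", ("I", "III")),
    _mc(7, "VII", 3, ("I", "III", "V"), "synchrony with co-located echo", ("III", "I")),
    _mc(8, "VIII", 3, ("I", "V"), "local pair then propagation", ("I", "V")),
    _mc(9, "IX", 3, ("I", "V"), "feedback", ("V", "V")),
    _mc(10, "X", 3, ("I", "V"), "propagation then local pair", ("V", "I")),
    _mc(11, "XI", 3, ("III", "V"), "divergence", ("V", "III")),
    _mc(12, "XII", 3, ("III", "V"), "convergence", ("III", "V")),
    _mc(13, "XIII", 3, ("V",), "feedforward", ("V", "V")),
)

CLASS_LABELS: tuple[str, ...] = tuple(c.label for c in MOTIF_CLASSES)
_BY_LABEL = {c.label: c for c in MOTIF_CLASSES}
N_CLASSES = len(MOTIF_CLASSES)

# Class orders as an array, indexed by class code.
CLASS_ORDERS = np.array([c.order for c in MOTIF_CLASSES], dtype=np.int64)


def class_by_label(label: str) -> MotifClass:
    try:
        return _BY_LABEL[label]
    except KeyError:
        raise KeyError(f"unknown motif class {label!r}; valid: {CLASS_LABELS}") from None


def zero_pattern_group(lags: LagPair) -> tuple[bool, bool, bool, bool]:
    """Zero/non-zero pattern of the four lags: (n1!=0, t1!=0, n2!=0, t2!=0).

    A spatial lag vector counts as zero iff all its components are zero.
    Over all lag pairs there are 2**4 = 16 distinct patterns.
    """
    return (
        any(v != 0 for v in lags.n1),
        lags.t1 != 0,
        any(v != 0 for v in lags.n2),
        lags.t2 != 0,
    )


# ---------------------------------------------------------------------------
# Lag-sign motifs (one spatial dimension)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LagSignMotif:
    """Sign pattern of the lags and between-event differences, one per dim.

    ``space`` and ``time`` are triples (sgn(l1), sgn(l2), sgn(l2-l1)) with
    signs in {-1, 0, +1}; only mutually consistent triples (realizable by
    actual integer lags) are valid.
    """

    space: tuple[int, int, int]
    time: tuple[int, int, int]


@lru_cache(maxsize=1)
def _consistent_sign_triples() -> dict[tuple[int, int, int], tuple[int, int]]:
    """Realizable (sgn(l1), sgn(l2), sgn(l2-l1)) triples with a witness.

    Witness lags in {-2..2} suffice because the constraints are scale-free.
    """
    triples: dict[tuple[int, int, int], tuple[int, int]] = {}
    for l1, l2 in itertools.product(range(-2, 3), repeat=2):
        key = (int(np.sign(l1)), int(np.sign(l2)), int(np.sign(l2 - l1)))
        triples.setdefault(key, (l1, l2))
    return triples


def enumerate_lag_sign_motifs() -> frozenset[LagSignMotif]:
    """All realizable lag-sign motifs for one spatial + one temporal dim.

    There are 13 consistent sign triples per dimension, hence 13 x 13 = 169
    lag-sign motifs, partitioning into the 16 zero-pattern groups.
    """
    triples = _consistent_sign_triples()
    return frozenset(
        LagSignMotif(space=s, time=t)
        for s, t in itertools.product(triples, repeat=2)
    )


def lag_sign_motif_witness(motif: LagSignMotif) -> LagPair:
    """A lag pair realizing the given sign pattern."""
    triples = _consistent_sign_triples()
    n1, n2 = triples[motif.space]
    t1, t2 = triples[motif.time]
    return LagPair((n1,), t1, (n2,), t2)


def lag_sign_motif_of(lags: LagPair) -> LagSignMotif:
    """Sign pattern of a lag pair (requires one spatial dimension)."""
    if lags.d_s != 1:
        raise ValueError("lag-sign motifs are defined for one spatial dimension")
    n1, n2 = lags.n1[0], lags.n2[0]
    sgn = lambda v: int(np.sign(v))
    return LagSignMotif(
        space=(sgn(n1), sgn(n2), sgn(n2 - n1)),
        time=(sgn(lags.t1), sgn(lags.t2), sgn(lags.t2 - lags.t1)),
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify(lags: LagPair) -> MotifClass:
    """Classify a triplet lag pair into one of the fourteen motif classes.

    The classification works on the canonical event form: events
    A = (0, 0), B = (n1, t1), C = (n2, t2), deduplicated, then grouped by
    the time ordering and the spatial-position equality pattern.  It is a
    total function, invariant under permutation of the three events
    (re-anchoring) and under relabeling of spatial positions.
    """
    zero = tuple(0 for _ in lags.n1)
    events = {(zero, 0), (lags.n1, lags.t1), (lags.n2, lags.t2)}
    k = len(events)
    if k == 1:
        return _BY_LABEL["0"]
    if k == 2:
        (px, tx), (py, ty) = events
        if px == py:
            return _BY_LABEL["I"]
        if tx == ty:
            return _BY_LABEL["III"]
        return _BY_LABEL["V"]
    evs = sorted(events, key=lambda e: e[1])
    (p0, t0), (p1, t1), (p2, t2) = evs
    if t0 == t2:
        return _BY_LABEL["IV"]
    if t0 == t1 or t1 == t2:
        # exactly two synchronous events (necessarily on different positions)
        if t0 == t1:
            pair_pos, lone_pos, lone_earlier = (p0, p1), p2, False
        else:
            pair_pos, lone_pos, lone_earlier = (p1, p2), p0, True
        if lone_pos in pair_pos:
            return _BY_LABEL["VI" if lone_earlier else "VII"]
        return _BY_LABEL["XI" if lone_earlier else "XII"]
    # three distinct times
    if p0 == p1 == p2:
        return _BY_LABEL["II"]
    if p0 == p1:
        return _BY_LABEL["VIII"]
    if p0 == p2:
        return _BY_LABEL["IX"]
    if p1 == p2:
        return _BY_LABEL["X"]
    return _BY_LABEL["XIII"]


def classify_codes(b_zero, c_zero, bc_equal, t1, t2) -> np.ndarray:
    """Vectorized classification into class codes 0..13.

    The class of a lag pair depends on the spatial lags only through three
    booleans — n1 == 0, n2 == 0, n1 == n2 (full-vector equality) — and on
    the two time lags.  All five arguments broadcast together.
    """
    b_zero, c_zero, bc_equal, t1, t2 = np.broadcast_arrays(
        np.asarray(b_zero, bool),
        np.asarray(c_zero, bool),
        np.asarray(bc_equal, bool),
        np.asarray(t1),
        np.asarray(t2),
    )
    i = {c.label: c.index for c in MOTIF_CLASSES}

    t1z = t1 == 0
    t2z = t2 == 0
    t12 = t1 == t2
    eq_ab = b_zero & t1z
    eq_ac = c_zero & t2z
    eq_bc = bc_equal & t12
    k1 = eq_ab & eq_ac
    k2 = (eq_ab | eq_ac | eq_bc) & ~k1
    k3 = ~(eq_ab | eq_ac | eq_bc)

    # k = 2: class of the one distinct pair
    pair_same_pos = np.where(eq_ab, c_zero, b_zero)
    pair_same_time = np.where(eq_ab, t2z, t1z)
    cls2 = np.where(
        pair_same_pos, i["I"], np.where(pair_same_time, i["III"], i["V"])
    )

    # k = 3, exactly two synchronous events
    two_ab = t1z & ~t2z  # pair (A,B) at time 0, lone C
    two_ac = t2z & ~t1z  # pair (A,C) at time 0, lone B
    two_bc = t12 & ~t1z  # pair (B,C) at time t1, lone A
    shared = np.select(
        [two_ab, two_ac, two_bc],
        [c_zero | bc_equal, b_zero | bc_equal, b_zero | c_zero],
        default=False,
    )
    lone_earlier = np.select([two_ab, two_ac, two_bc], [t2 < 0, t1 < 0, t1 > 0], default=False)
    cls_sync = np.where(
        shared,
        np.where(lone_earlier, i["VI"], i["VII"]),
        np.where(lone_earlier, i["XI"], i["XII"]),
    )

    # k = 3, three distinct times: position-equality pattern + temporal ranks
    only_ab = b_zero & ~c_zero
    only_ac = c_zero & ~b_zero
    only_bc = bc_equal & ~b_zero & ~c_zero
    # temporal ranks of the co-located pair: {1,2} -> VIII, {1,3} -> IX, {2,3} -> X
    third_last = np.select(
        [only_ab, only_ac, only_bc],
        [t2 > np.maximum(0, t1), t1 > np.maximum(0, t2), (t1 < 0) & (t2 < 0)],
        default=False,
    )
    third_first = np.select(
        [only_ab, only_ac, only_bc],
        [t2 < np.minimum(0, t1), t1 < np.minimum(0, t2), (t1 > 0) & (t2 > 0)],
        default=False,
    )
    cls_dist = np.where(
        b_zero & c_zero,
        i["II"],
        np.where(
            only_ab | only_ac | only_bc,
            np.where(third_last, i["VIII"], np.where(third_first, i["X"], i["IX"])),
            i["XIII"],
        ),
    )

    all_sync = t1z & t2z
    two_any = (two_ab | two_ac | two_bc) & ~all_sync

    codes = np.select(
        [k1, k2, k3 & all_sync, k3 & two_any],
        [i["0"], cls2, i["IV"], cls_sync],
        default=cls_dist,
    )
    return codes.astype(np.int64)


def reduce_to_classes(
    motifs: frozenset[LagSignMotif] | set[LagSignMotif],
) -> dict[str, set[LagSignMotif]]:
    """Partition lag-sign motifs into motif classes via witness lag pairs.

    Applied to the full 169-member set the image has exactly 14 classes.
    """
    partition: dict[str, set[LagSignMotif]] = {}
    for motif in motifs:
        label = classify(lag_sign_motif_witness(motif)).label
        partition.setdefault(label, set()).add(motif)
    return partition


# ---------------------------------------------------------------------------
# Counting motifs per class within a window
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def window_class_codes(window: LagWindow) -> np.ndarray:
    """Class code of every lag pair in the window.

    Shape ``(S, Tn, S, Tn)`` with ``S`` the flattened spatial lag count and
    ``Tn`` the temporal lag count, matching the layout of
    :class:`~tricorr.correlation.TripleCorrelation` values.
    """
    sp = window.spatial_offsets()  # (S, d_s)
    tv = window.time_offsets()  # (Tn,)
    s_zero = np.all(sp == 0, axis=1)  # (S,)
    s_eq = np.all(sp[:, None, :] == sp[None, :, :], axis=2)  # (S, S)
    codes = classify_codes(
        s_zero[:, None, None, None],
        s_zero[None, None, :, None],
        s_eq[:, None, :, None],
        tv[None, :, None, None],
        tv[None, None, None, :],
    )
    codes.setflags(write=False)
    return codes


@lru_cache(maxsize=32)
def motif_count_table(window: LagWindow) -> np.ndarray:
    """Number of lag pairs per motif class, #(M_i | lambda), shape (14,).

    The counts sum to the total number of lag pairs in the window; the
    count for class 0 is always 1 (the all-zero lag pair).
    """
    codes = window_class_codes(window)
    counts = np.bincount(codes.ravel(), minlength=N_CLASSES)
    counts.setflags(write=False)
    return counts


def count_motifs(class_id: MotifClass | str, window: LagWindow) -> int:
    """Number of lag pairs in the window belonging to one motif class."""
    label = class_id.label if isinstance(class_id, MotifClass) else class_id
    return int(motif_count_table(window)[class_by_label(label).index])


def class_table_frame():
    """The class table as a :class:`pandas.DataFrame` (for export)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [c.label for c in MOTIF_CLASSES],
            "order": [c.order for c in MOTIF_CLASSES],
            "constituents": ["+".join(sorted(c.constituents)) for c in MOTIF_CLASSES],
            "adjacent_pairs": [
                ",".join(c.adjacent_pairs) if c.adjacent_pairs else ""
                for c in MOTIF_CLASSES
            ],
            "name": [c.name for c in MOTIF_CLASSES],
        }
    )


# Canonical exemplar lag pair per class (used by the single-triplet tiling
# simulator); chosen with the smallest convenient positive lags.
EXEMPLAR_LAG_PAIRS: dict[str, LagPair] = {
    "0": LagPair((0,), 0, (0,), 0),
    "I": LagPair((0,), 1, (0,), 1),
    "II": LagPair((0,), 1, (0,), 2),
    "III": LagPair((1,), 0, (1,), 0),
    "IV": LagPair((1,), 0, (2,), 0),
    "V": LagPair((1,), 1, (1,), 1),
    "VI": LagPair((0,), 1, (1,), 1),
    "VII": LagPair((1,), 0, (0,), 1),
    "VIII": LagPair((0,), 1, (1,), 2),
    "IX": LagPair((1,), 1, (0,), 2),
    "X": LagPair((1,), 1, (1,), 2),
    "XI": LagPair((1,), 1, (2,), 1),
    "XII": LagPair((1,), 0, (2,), 1),
    "XIII": LagPair((1,), 1, (2,), 2),
}
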