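"""Motif taxonomy: sign patterns, the 14 classes, and window counts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tricorr.lags import LagPair, LagWindow
from tricorr.motifs import (
    CLASS_LABELS,
    EXEMPLAR_LAG_PAIRS,
    MOTIF_CLASSES,
    class_by_label,
    classify,
    classify_codes,
    count_motifs,
    enumerate_lag_sign_motifs,
    lag_sign_motif_of,
    lag_sign_motif_witness,
    motif_count_table,
    reduce_to_classes,
    zero_pattern_group,
)

from .conftest import multiset_classify

lag = st.integers(-2, 2)


class TestTaxonomyCounts:
    def test_lag_sign_motifs_number_169(self):
        assert len(enumerate_lag_sign_motifs()) == 169

    def test_sixteen_zero_pattern_groups(self):
        groups = {
            zero_pattern_group(lag_sign_motif_witness(m))
            for m in enumerate_lag_sign_motifs()
        }
        assert len(groups) == 16

    def test_reduction_yields_fourteen_classes(self):
        partition = reduce_to_classes(enumerate_lag_sign_motifs())
        assert set(partition) == set(CLASS_LABELS)
        assert sum(len(v) for v in partition.values()) == 169

    def test_inconsistent_sign_triple_excluded(self):
        # t1 = t2 = 0 forces t2 - t1 = 0
        assert all(
            m.time != (0, 0, 1) and m.space != (0, 0, 1)
            for m in enumerate_lag_sign_motifs()
        )

    def test_witnesses_realize_their_pattern(self):
        for motif in enumerate_lag_sign_motifs():
            assert lag_sign_motif_of(lag_sign_motif_witness(motif)) == motif


class TestClassTable:
    def test_orders(self):
        orders = {c.label: c.order for c in MOTIF_CLASSES}
        assert orders["0"] == 1
        assert all(orders[l] == 2 for l in ("I", "III", "V"))
        assert all(
            orders[l] == 3
            for l in ("II", "IV", "VI", "VII", "VIII", "IX", "X", "XI", "XII", "XIII")
        )

    def test_constituents_drawn_from_second_order(self):
        for cls in MOTIF_CLASSES:
            if cls.order == 2:
                assert cls.constituents == {cls.label}
            if cls.order == 3:
                assert cls.constituents and cls.constituents <= {"I", "III", "V"}
        assert class_by_label("0").constituents == frozenset()

    def test_adjacent_pairs_subset_of_constituents(self):
        # the chain rule may only consume constituent observables
        for cls in MOTIF_CLASSES:
            if cls.adjacent_pairs:
                assert set(cls.adjacent_pairs) <= {"I", "III", "V"}


class TestClassify:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            (LagPair((0,), 0, (0,), 0), "0"),
            (LagPair((2,), 0, (0,), 0), "III"),
            (LagPair((1,), 1, (0,), 2), "IX"),
            (LagPair((1,), 1, (2,), 1), "XI"),
            (LagPair((1,), 1, (2,), 2), "XIII"),
            (LagPair((0,), 3, (0,), 0), "I"),
            (LagPair((1,), 2, (1,), 2), "V"),
        ],
    )
    def test_canonical_examples(self, pair, expected):
        assert classify(pair).label == expected

    def test_exemplars_classify_to_their_label(self):
        for label, pair in EXEMPLAR_LAG_PAIRS.items():
            assert classify(pair).label == label

    def test_matches_multiset_oracle_exhaustively(self):
        for n1, t1, n2, t2 in itertools.product(range(-2, 3), repeat=4):
            pair = LagPair((n1,), t1, (n2,), t2)
            assert classify(pair).label == multiset_classify(n1, t1, n2, t2), pair

    def test_vectorized_agrees_with_scalar(self):
        span = np.arange(-2, 3)
        n1, t1, n2, t2 = np.meshgrid(span, span, span, span, indexing="ij")
        codes = classify_codes(n1 == 0, n2 == 0, n1 == n2, t1, t2)
        for idx in np.ndindex(codes.shape):
            pair = LagPair((n1[idx],), t1[idx], (n2[idx],), t2[idx])
            assert classify(pair).index == codes[idx]

    @given(n1=lag, t1=lag, n2=lag, t2=lag)
    @settings(derandomize=True, max_examples=200)
    def test_invariant_under_reanchoring(self, n1, t1, n2, t2):
        # the three events are unordered: re-anchor at B or C
        base = classify(LagPair((n1,), t1, (n2,), t2)).label
        at_b = classify(LagPair((-n1,), -t1, (n2 - n1,), t2 - t1)).label
        at_c = classify(LagPair((-n2,), -t2, (n1 - n2,), t1 - t2)).label
        assert base == at_b == at_c

    @given(n1=lag, t1=lag, n2=lag, t2=lag)
    @settings(derandomize=True, max_examples=200)
    def test_invariant_under_spatial_reflection(self, n1, t1, n2, t2):
        base = classify(LagPair((n1,), t1, (n2,), t2)).label
        assert classify(LagPair((-n1,), t1, (-n2,), t2)).label == base

    @given(n1=lag, t1=lag, n2=lag, t2=lag, scale=st.integers(2, 5))
    @settings(derandomize=True, max_examples=200)
    def test_depends_only_on_position_equality(self, n1, t1, n2, t2, scale):
        # scaling spatial lags preserves the equality pattern, hence the class
        base = classify(LagPair((n1,), t1, (n2,), t2)).label
        assert classify(LagPair((n1 * scale,), t1, (n2 * scale,), t2)).label == base

    def test_multidimensional_spatial_lags(self):
        # "same neuron" means equality of the full coordinate vector
        assert classify(LagPair((1, 0), 0, (1, 0), 0)).label == "III"
        # co-located pair at the two latest times -> X; at the earliest -> VIII
        assert classify(LagPair((1, 0), 1, (1, 0), 2)).label == "X"
        assert classify(LagPair((0, 0), 1, (1, 1), 2)).label == "VIII"
        assert classify(LagPair((1, 0), 1, (0, 1), 2)).label == "XIII"

    def test_same_lag_sign_motif_classifies_identically(self):
        buckets = {}
        for n1, t1, n2, t2 in itertools.product(range(-3, 4), repeat=4):
            pair = LagPair((n1,), t1, (n2,), t2)
            buckets.setdefault(lag_sign_motif_of(pair), set()).add(
                classify(pair).label
            )
        assert all(len(labels) == 1 for labels in buckets.values())


class TestZeroPatternGroup:
    def test_examples(self):
        assert zero_pattern_group(LagPair((0,), 0, (0,), 0)) == (False,) * 4
        assert zero_pattern_group(LagPair((0,), 3, (2,), 0)) == (
            False, True, True, False,
        )

    def test_vector_spatial_lag_zero_means_all_components(self):
        assert zero_pattern_group(LagPair((0, 0), 1, (0, 1), 0)) == (
            False, True, True, False,
        )


class TestCountMotifs:
    def test_class_zero_always_one(self):
        for window in (LagWindow.symmetric(1, 1), LagWindow.symmetric(4, 2)):
            assert count_motifs("0", window) == 1

    def test_conservation(self):
        window = LagWindow.symmetric(3, 2)
        assert motif_count_table(window).sum() == window.n_lag_pairs

    def test_counts_match_enumeration_oracle(self):
        window = LagWindow.symmetric(1, 1)
        expected = {label: 0 for label in CLASS_LABELS}
        for pair in window.iter_lag_pairs():
            expected[multiset_classify(pair.n1[0], pair.t1, pair.n2[0], pair.t2)] += 1
        table = motif_count_table(window)
        assert {l: int(table[class_by_label(l).index]) for l in CLASS_LABELS} == expected

    def test_growth_orders(self):
        # I has one free lag, XIII four: doubling the window scales their
        # counts by ~2x and ~16x respectively
        small = motif_count_table(LagWindow.symmetric(10, 10))
        large = motif_count_table(LagWindow.symmetric(20, 20))
        i_idx = class_by_label("I").index
        xiii_idx = class_by_label("XIII").index
        assert large[i_idx] / small[i_idx] == pytest.approx(2.0, rel=0.05)
        assert large[xiii_idx] / small[xiii_idx] == pytest.approx(16.0, rel=0.15)

    def test_asymmetric_window(self):
        window = LagWindow(spatial=((-1, 2),), time=(-2, 2))
        table = motif_count_table(window)
        assert table.sum() == window.n_lag_pairs == (4 * 5) ** 2
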