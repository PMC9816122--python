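"""Poisson and constituent-controlled expectations, surrogates, comparisons."""

import numpy as np
import pytest

from tricorr.correlation import class_contributions, compute_c3
from tricorr.lags import LagWindow
from tricorr.motifs import CLASS_LABELS, class_by_label, motif_count_table
from tricorr.nulls import (
    compare_conditions,
    constituent_controlled_expectation,
    expected_contributions,
    make_surrogates,
    ratio_spectrum,
    surrogate_raster,
)
from tricorr.simulate import bernoulli_raster, periodic_raster, PeriodicRasterSpec
from tricorr.spectra import MotifClassSpectrum, RasterMeta

W3 = LagWindow.symmetric(3, 3)


def idx(label):
    return class_by_label(label).index


class TestExpectedContributions:
    def test_zero_rate(self):
        assert (expected_contributions(0.0, W3, 10, 50) == 0).all()

    def test_class_zero_is_nt_p(self):
        for p in (0.01, 0.3, 1.0):
            e = expected_contributions(p, W3, 10, 50)
            assert e[0] == pytest.approx(500 * p)

    def test_formula_per_class(self):
        p, n, t = 0.2, 10, 50
        counts = motif_count_table(W3)
        e = expected_contributions(p, W3, n, t)
        for label in CLASS_LABELS:
            cls = class_by_label(label)
            assert e[cls.index] == pytest.approx(
                n * t * counts[cls.index] * p**cls.order
            )

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            expected_contributions(1.2, W3, 10, 50)


class TestConstituentControl:
    def _spectrum(self, m):
        return MotifClassSpectrum(m=m, window=W3, meta=RasterMeta(10, 50))

    def test_consistency_contract(self):
        # plugging the Poisson expectations back in returns them exactly
        for p in (0.02, 0.1, 0.5):
            e = expected_contributions(p, W3, 10, 50)
            e_c = constituent_controlled_expectation(self._spectrum(e))
            assert np.allclose(e_c, e)

    def test_lower_order_classes_unchanged(self):
        m = expected_contributions(0.1, W3, 10, 50) * 1.7
        m[0] = 500 * 0.1
        e = expected_contributions(0.1, W3, 10, 50)
        e_c = constituent_controlled_expectation(self._spectrum(m))
        for label in ("0", "I", "III", "V"):
            assert e_c[idx(label)] == pytest.approx(e[idx(label)])

    def test_feedback_uses_propagation_pairs_squared(self):
        # class IX chain: q_V * q_V / p
        nt = 500.0
        counts = motif_count_table(W3)
        m = expected_contributions(0.1, W3, 10, 50)
        m[idx("V")] *= 3.0  # elevate propagation pairs
        e_c = constituent_controlled_expectation(self._spectrum(m))
        q_v = m[idx("V")] / (nt * counts[idx("V")])
        assert e_c[idx("IX")] == pytest.approx(
            nt * counts[idx("IX")] * q_v**2 / 0.1
        )
        # and 3x pairwise elevation raises the IX bar 9x
        base = expected_contributions(0.1, W3, 10, 50)
        assert e_c[idx("IX")] == pytest.approx(9 * base[idx("IX")])

    def test_elevated_synchrony_raises_third_order_bar(self):
        m = expected_contributions(0.1, W3, 10, 50)
        base = constituent_controlled_expectation(self._spectrum(m.copy()))
        m[idx("III")] *= 2.0
        raised = constituent_controlled_expectation(self._spectrum(m))
        assert raised[idx("IV")] == pytest.approx(4 * base[idx("IV")])
        assert raised[idx("XII")] == pytest.approx(2 * base[idx("XII")])

    def test_empty_raster_with_structure_is_inconsistent(self):
        m = np.zeros(14)
        m[idx("IX")] = 5.0
        with pytest.raises(ValueError, match="no spikes"):
            constituent_controlled_expectation(self._spectrum(m))


class TestRatioSpectrum:
    def _spectrum(self, m):
        return MotifClassSpectrum(m=m, window=W3, meta=RasterMeta(10, 50))

    def test_ratio_zero_for_class_zero_always(self):
        m = expected_contributions(0.3, W3, 10, 50) * 2.0
        m[0] = 500 * 0.3
        assert ratio_spectrum(self._spectrum(m)).ratio[0] == 0.0

    def test_poisson_control_equals_poisson_expectation(self):
        m = expected_contributions(0.1, W3, 10, 50)
        out = ratio_spectrum(self._spectrum(m), control="poisson")
        assert np.allclose(out.e_c, out.e)
        assert np.allclose(out.ratio, 0.0)

    def test_observed_control_discounts_pairwise_structure(self):
        # a fully synchronous raster's third-order synchrony is explained
        # by its pairwise synchrony under observed-constituent control
        raster = periodic_raster(PeriodicRasterSpec(n_channels=40, n_time_bins=100))
        spectrum = class_contributions(
            compute_c3(raster, W3, boundary="periodic")
        )
        observed = ratio_spectrum(spectrum, control="observed")
        poisson = ratio_spectrum(spectrum, control="poisson")
        assert poisson["IV"] > 1.0
        assert abs(observed["IV"]) < 0.1 * poisson["IV"]

    def test_unknown_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            ratio_spectrum(self._spectrum(np.zeros(14)), control="bootstrap")

    def test_absent_class_gives_zero_not_nan(self):
        out = ratio_spectrum(self._spectrum(np.zeros(14)))
        assert (out.ratio == 0).all()

    def test_undefined_inferred_from_infinite_ratio(self):
        from tricorr.spectra import ExpectationSpectrum

        ratio = np.zeros(14)
        ratio[idx("XI")] = np.inf
        out = ExpectationSpectrum(e=np.ones(14), e_c=np.ones(14), ratio=ratio)
        assert out.undefined[idx("XI")] and out.undefined.sum() == 1

    def test_positive_rate_never_undefined(self):
        m = expected_contributions(0.05, W3, 10, 50)
        assert not ratio_spectrum(self._spectrum(m)).undefined.any()


class TestSurrogates:
    def test_shuffle_all_preserves_total_count(self, rng):
        raster = bernoulli_raster(8, 40, 0.2, seed=1)
        surrogate = surrogate_raster(raster, "shuffle_all", rng)
        assert surrogate.n_spikes == raster.n_spikes

    def test_shuffle_within_channel_preserves_channel_counts(self, rng):
        raster = bernoulli_raster(8, 40, 0.2, seed=2)
        surrogate = surrogate_raster(raster, "shuffle_within_channel", rng)
        assert (
            surrogate.flat_values().sum(axis=1)
            == raster.flat_values().sum(axis=1)
        ).all()

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="method"):
            surrogate_raster(bernoulli_raster(4, 10, 0.2), "jitter", rng)

    def test_ensemble_reproducible_bit_exact(self):
        raster = bernoulli_raster(8, 40, 0.2, seed=3)
        window = LagWindow.symmetric(2, 2)
        a = make_surrogates(raster, window, n=5, seed=11)
        b = make_surrogates(raster, window, n=5, seed=11)
        assert (a.ratios == b.ratios).all()
        c = make_surrogates(raster, window, n=5, seed=12)
        assert (a.ratios != c.ratios).any()

    def test_ensemble_summary_shapes(self):
        raster = bernoulli_raster(8, 40, 0.2, seed=4)
        ensemble = make_surrogates(raster, LagWindow.symmetric(2, 2), n=4, seed=0)
        assert ensemble.ratios.shape == (4, 14)
        assert set(ensemble.summary) >= {"min", "median", "max"}
        assert len(ensemble.spectra) == 4

    def test_needs_at_least_one(self):
        raster = bernoulli_raster(4, 10, 0.2)
        with pytest.raises(ValueError, match="at least one"):
            make_surrogates(raster, LagWindow.symmetric(1, 1), n=0)


class TestCompareConditions:
    def test_equal_conditions_quotient_one(self):
        ratios = np.linspace(0.5, 2.0, 14)
        result = compare_conditions(ratios, ratios)
        assert np.allclose(result.quotient, 1.0)
        assert not result.absent.any()

    def test_zero_baseline_flagged_absent(self):
        treatment = np.ones(14)
        baseline = np.ones(14)
        baseline[idx("IV")] = 0.0
        result = compare_conditions(treatment, baseline)
        assert result.absent[idx("IV")]
        assert np.isnan(result.quotient[idx("IV")])
        assert result.quotient[idx("I")] == 1.0

    def test_undefined_treatment_flagged(self):
        treatment = np.ones(14)
        treatment[idx("XI")] = np.inf
        result = compare_conditions(treatment, np.ones(14))
        assert result.absent[idx("XI")]
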