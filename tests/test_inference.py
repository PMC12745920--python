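"""Composite likelihood, model selection, GOF pieces, time conversion
and the pre-LGM signed-rank machinery."""

import itertools

import numpy as np
import pytest

from refugia.inference import (ConversionConstants, FitResult, OptimSchedule,
                               akaike_weights, composite_loglik,
                               convert_time, pearson_chi2, select_models,
                               walsh_averages)
from refugia.inference import test_pre_lgm as pre_lgm_wilcoxon  # noqa: N813
# (aliased so pytest does not collect the library function as a test)
from refugia.spectrum import Spectrum2D


def two_entry_spectra(d, m):
    data = np.zeros((2, 3))
    model = np.zeros((2, 3))
    mask = np.ones((2, 3), dtype=bool)
    data[0, 1], data[0, 2] = d
    model[0, 1], model[0, 2] = m
    mask[0, 1] = mask[0, 2] = False
    return Spectrum2D(data, mask), Spectrum2D(model, mask)


class TestCompositeLoglik:
    def test_hand_computed_example(self):
        data, model = two_entry_spectra((4, 6), (1, 1))
        ll, theta = composite_loglik(data, model)
        assert theta == pytest.approx(5.0)
        assert ll == pytest.approx(10 * np.log(5) - 10 - np.log(24 * 720))

    def test_identity_scaling(self):
        rng = np.random.default_rng(0)
        m = Spectrum2D(rng.random((6, 6)) + 0.5)
        d = Spectrum2D(np.round(m.data), m.mask.copy())
        _, theta = composite_loglik(d, m)
        assert theta == pytest.approx(d.sum() / m.sum())

    def test_model_rescaling_leaves_loglik_unchanged(self):
        data, model = two_entry_spectra((4, 6), (1, 2))
        scaled = Spectrum2D(3.7 * model.data, model.mask.copy())
        assert composite_loglik(data, model)[0] == pytest.approx(
            composite_loglik(data, scaled)[0])

    def test_theta_hat_is_the_maximizer(self):
        rng = np.random.default_rng(1)
        m = Spectrum2D(rng.random((6, 6)) + 0.2)
        d = Spectrum2D(rng.poisson(40 * m.data).astype(float),
                       m.mask.copy())
        ll, theta = composite_loglik(d, m)

        def ll_at(t):
            lam = t * m.data[~m.mask]
            D = d.data[~d.mask]
            from scipy.special import gammaln
            return np.sum(D * np.log(lam) - lam - gammaln(D + 1))

        assert ll_at(theta * 1.01) < ll
        assert ll_at(theta * 0.99) < ll

    def test_zero_model_entry_with_data_is_minus_inf(self):
        data, model = two_entry_spectra((4, 6), (1, 0))
        with pytest.warns(UserWarning):
            ll, _ = composite_loglik(data, model)
        assert ll == -np.inf

    def test_mask_mismatch_rejected(self):
        data, model = two_entry_spectra((4, 6), (1, 1))
        other = Spectrum2D(model.data, np.ones_like(model.mask))
        with pytest.raises(ValueError):
            composite_loglik(data, other)


class TestChi2:
    def test_zero_when_equal(self):
        d, e = two_entry_spectra((5, 5), (5, 5))
        assert pearson_chi2(d, e) == 0.0

    def test_hand_example(self):
        d, e = two_entry_spectra((4, 6), (5, 5))
        assert pearson_chi2(d, e) == pytest.approx(0.4)


class TestSelection:
    def test_weights_example(self):
        w = akaike_weights([100, 102, 110])
        assert np.round(w, 4).tolist() == [0.7275, 0.2676, 0.0049]

    def test_single_model_weight_one(self):
        assert akaike_weights([123.4])[0] == pytest.approx(1.0)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        w = akaike_weights(rng.uniform(50, 500, size=12))
        assert w.sum() == pytest.approx(1.0)

    def test_parsimony_breaks_equal_loglik(self):
        f2 = FitResult("vic_no_mig", {"s": .5, "T": .1}, -50.0, 1.0, 2)
        f3 = FitResult("founder_nomig", {"s": .5, "nu2": 1, "T": .1},
                       -50.0, 1.0, 3)
        table = select_models([f3, f2])
        assert table.iloc[0]["model"] == "vic_no_mig"
        assert table.iloc[1]["delta_aic"] == pytest.approx(2.0)
        assert table["akaike_weight"].sum() == pytest.approx(1.0)


class TestSchedule:
    def test_default_matches_protocol(self):
        s = OptimSchedule()
        assert s.folds == (3, 2, 2, 1)
        assert s.reps == (60, 70, 70, 80)
        assert s.maxiters == (10, 10, 10, 15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            OptimSchedule(folds=(1, 2), reps=(5,), maxiters=(5, 5))


class TestConvertTime:
    def test_worked_example(self):
        cc = ConversionConstants(mu=7e-9, L=1e6, g=10)
        assert cc.n_ref(400) == pytest.approx(14285.714, rel=1e-6)
        assert convert_time(0.5, 400, cc) == pytest.approx(142857.14,
                                                           rel=1e-6)

    def test_zero_time(self):
        cc = ConversionConstants()
        assert convert_time(0.0, 100.0, cc) == 0.0

    def test_invalid_constants(self):
        with pytest.raises(ValueError):
            ConversionConstants(mu=0)


def brute_force_signed_rank(values, null):
    """Exact one-sided p by enumerating all sign assignments, and the
    pseudomedian by direct Walsh-average median."""
    d = np.asarray(values, dtype=float) - null
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs:
            count += 1
    return count / 2 ** n


class TestPreLgm:
    def test_spec_example(self):
        r = pre_lgm_wilcoxon([30, 25, 40], null_ka=20)
        assert r["p_one_sided"] == pytest.approx(0.125)
        assert r["pseudomedian"] == pytest.approx(31.25)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        x = np.round(rng.normal(25, 10, size=n), 2)
        r = pre_lgm_wilcoxon(x, null_ka=20)
        assert r["p_one_sided"] == pytest.approx(
            brute_force_signed_rank(x, 20), abs=1e-12)
        assert r["pseudomedian"] == pytest.approx(
            np.median(walsh_averages(x)))

    def test_all_equal_to_null(self):
        r = pre_lgm_wilcoxon([20.0, 20.0, 20.0], null_ka=20)
        assert r["p_one_sided"] == 1.0
        assert r["pseudomedian"] == 20.0

    def test_fraction_below_null_reported(self):
        r = pre_lgm_wilcoxon([15, 25, 30, 40], null_ka=20)
        assert r["fraction_below_null"] == pytest.approx(0.25)

    def test_large_sample_matches_r_reference(self):
        """Frozen reference from R's wilcox.test (exact, n=15):
        p=6.103516e-05, pseudomedian=36.985, 95% CI (32.275, 40.47)."""
        rng = np.random.default_rng(1)
        x = np.round(rng.normal(35, 12, 15), 2)
        r = pre_lgm_wilcoxon(x, null_ka=20)
        assert r["p_one_sided"] == pytest.approx(6.103515625e-05)
        assert r["pseudomedian"] == pytest.approx(36.985)
        assert r["ci"][0] == pytest.approx(32.275)
        assert r["ci"][1] == pytest.approx(40.47)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            pre_lgm_wilcoxon([25, 30], null_ka=20)
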