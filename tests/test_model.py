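"""Model/Results facade: fitting, orientation, summary, GOF plumbing."""

import numpy as np
import pytest

from refugia.engine import EngineConfig, expected_sfs
from refugia.inference import ConversionConstants, OptimSchedule
from refugia.model import DivergenceModel, fit_model_set
from refugia.spectrum import poisson_sample

TINY = OptimSchedule(folds=(2, 1), reps=(4, 4), maxiters=(5, 6))


@pytest.fixture(scope="module")
def vic_data(fit_engine):
    exp = expected_sfs("vic_no_mig", {"s": 0.3, "T": 0.4}, 8, 8,
                       fold=True, config=fit_engine)
    return poisson_sample(exp, 4000 / exp.sum(), seed=5)


class TestDivergenceModel:
    def test_fit_recovers_parameters(self, vic_data, fit_engine):
        dm = DivergenceModel(vic_data, "vic_no_mig", engine=fit_engine)
        res = dm.fit(schedule=TINY, seed=2)
        assert abs(res.params["s"] - 0.3) < 0.07
        assert abs(res.params["T"] - 0.4) < 0.1
        assert res.aic == pytest.approx(2 * 2 - 2 * res.loglik)

    def test_fit_never_worse_than_its_start(self, vic_data, fit_engine):
        dm = DivergenceModel(vic_data, "vic_no_mig", engine=fit_engine)
        start = {"s": 0.3, "T": 0.4}
        ll_start, _ = dm.loglik(start)
        res = dm.fit(start=start, schedule=TINY, seed=3)
        assert res.loglik >= ll_start - 1e-6  # monotone contract

    def test_summary_mentions_key_quantities(self, vic_data, fit_engine):
        dm = DivergenceModel(vic_data, "vic_no_mig", engine=fit_engine)
        res = dm.fit(schedule=TINY, seed=4)
        text = res.summary()
        for token in ("vic_no_mig", "log-likelihood", "AIC", "theta_hat"):
            assert token in text

    def test_swapped_orientation_transposes_expectation(self, fit_engine):
        params = {"s": 0.1, "nu2": 1.2, "T": 0.2}
        fwd = expected_sfs("founder_nomig", params, 6, 6,
                           config=fit_engine)
        data = poisson_sample(fwd, 100.0, seed=0)
        dm_swap = DivergenceModel(data, "founder_nomig",
                                  orientation="swapped", engine=fit_engine)
        m = dm_swap.expected(params)
        direct = expected_sfs("founder_nomig", params, 6, 6,
                              config=fit_engine).transpose()
        assert np.allclose(m.data, direct.data)

    def test_invalid_orientation_rejected(self, vic_data):
        with pytest.raises(ValueError):
            DivergenceModel(vic_data, "vic_no_mig", orientation="up")


class TestGofAndTimes:
    def test_gof_bands_cover_self_simulated_data(self, vic_data,
                                                 fit_engine):
        dm = DivergenceModel(vic_data, "vic_no_mig", engine=fit_engine)
        res = dm.fit(schedule=TINY, seed=6)
        g = res.gof(n_sims=60, seed=1)
        assert len(g.sim_logliks) == 60
        assert g.loglik_inside and g.chi2_inside
        assert np.all(g.sim_chi2 >= 0)

    def test_simulated_times_and_pre_lgm(self, vic_data, fit_engine):
        dm = DivergenceModel(vic_data, "vic_no_mig", engine=fit_engine)
        res = dm.fit(schedule=TINY, seed=7)
        res.gof(n_sims=30, seed=2)
        cc = ConversionConstants(mu=7e-9, L=5e5, g=10)
        times = res.simulated_times_years(cc)
        assert len(times) == 30 and np.all(times > 0)
        point = res.divergence_time_years(cc)
        assert np.isclose(np.median(times), point, rtol=0.2)
        lgm = res.pre_lgm_test(cc)
        assert 0 <= lgm["p_one_sided"] <= 1

    def test_times_require_gof_first(self, vic_data, fit_engine):
        dm = DivergenceModel(vic_data, "vic_no_mig", engine=fit_engine)
        res = dm.fit(schedule=TINY, seed=8)
        with pytest.raises(ValueError):
            res.simulated_times_years(ConversionConstants())


class TestModelSet:
    def test_competition_ranks_generating_model_first(self, vic_data,
                                                      fit_engine):
        results, table = fit_model_set(
            vic_data, models=["vic_no_mig", "founder_nomig"],
            orientations="as-is", schedule=TINY, engine=fit_engine,
            seed=1)
        assert set(table["model"]) == {"vic_no_mig", "founder_nomig"}
        assert table["akaike_weight"].sum() == pytest.approx(1.0)
        assert table.iloc[0]["model"] == "vic_no_mig"

    def test_both_orientations_for_founder_models(self, vic_data,
                                                  fit_engine):
        results, table = fit_model_set(
            vic_data, models=["founder_nomig"], orientations="both",
            schedule=TINY, engine=fit_engine, seed=2)
        assert sorted(table["orientation"]) == ["as-is", "swapped"]
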