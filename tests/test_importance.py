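"""Akaike-weight variable importance over the 8-model GLS set."""

import math

import numpy as np
import pandas as pd
import pytest

from stockdist.importance import (
    PREDICTORS,
    ModelFit,
    ModelSpec,
    akaike_weights,
    canonical_model_set,
    first_rank_proportions,
    fit_gls_ar1,
    importance_for_series,
    importance_pipeline,
    model_average,
    summed_importance,
)


def make_fits(ics, n=30):
    """ModelFit stubs over the canonical set with prescribed loglik -> IC."""
    fits = []
    for spec, ic in zip(canonical_model_set(), ics):
        k = len(spec.predictors) + 3
        fits.append(
            ModelFit(
                spec=spec,
                intercept=0.0,
                coefficients={p: 1.0 for p in spec.predictors},
                rho=0.0,
                loglik=-(ic - 2 * k) / 2.0,  # so AIC == ic
                k=k,
                n=n,
            )
        )
    return fits


class TestCanonicalSet:
    def test_eight_models(self):
        assert len(canonical_model_set()) == 8

    def test_each_predictor_in_four_models(self):
        specs = canonical_model_set()
        for p in PREDICTORS:
            assert sum(p in s for s in specs) == 4

    def test_intercept_only_present_and_first(self):
        specs = canonical_model_set()
        assert specs[0].predictors == ()
        assert specs[0].label == "(intercept only)"


class TestAkaikeWeights:
    def test_equal_ic_uniform_weights(self):
        fits = akaike_weights(make_fits([100.0] * 8))
        assert [f.weight for f in fits] == pytest.approx([0.125] * 8)
        assert sum(f.weight for f in fits) == pytest.approx(1.0, abs=1e-12)

    def test_dominant_model(self):
        ics = [150.0] * 8
        ics[3] = 100.0
        fits = akaike_weights(make_fits(ics))
        assert fits[3].weight > 0.999
        assert fits[3].delta == 0.0

    def test_toy_ic_hand_normalization(self):
        ics = [100.0, 102, 104, 106, 108, 110, 112, 114]
        fits = akaike_weights(make_fits(ics))
        rel = np.exp(-0.5 * (np.array(ics) - 100.0))
        assert [f.weight for f in fits] == pytest.approx(rel / rel.sum())

    def test_aicc_correction(self):
        fits = akaike_weights(make_fits([100.0] * 8, n=20), criterion="AICc")
        for f in fits:
            expected = 100.0 + 2 * f.k * (f.k + 1) / (20 - f.k - 1)
            assert f.ic == pytest.approx(expected)

    def test_mismatched_rows_rejected(self):
        fits = make_fits([100.0] * 8)
        fits[0].n = 99
        with pytest.raises(ValueError):
            akaike_weights(fits)


class TestSummedImportance:
    def test_uniform_weights_give_half_and_three_way_tie(self):
        res = summed_importance(akaike_weights(make_fits([100.0] * 8)))
        for p in PREDICTORS:
            assert res.summed_weight[p] == pytest.approx(0.5, abs=1e-12)
        assert res.ties
        assert set(res.first_ranked()) == set(PREDICTORS)
        # each predictor occurs in half the models: importances sum to 1.5
        assert sum(res.summed_weight.values()) == pytest.approx(1.5, abs=1e-12)

    def test_single_dominant_model(self):
        ics = [200.0] * 8
        ics[1] = 100.0  # the {log_biomass} model
        res = summed_importance(akaike_weights(make_fits(ics)))
        assert res.summed_weight["log_biomass"] > 0.999
        assert res.rank["log_biomass"] == 1
        assert res.first_ranked() == ["log_biomass"]


class TestModelAverage:
    def test_identical_coefficient_recovered(self):
        fits = akaike_weights(make_fits([100, 105, 103, 108, 101, 99, 104, 102]))
        cond, full = model_average(fits)
        for p in PREDICTORS:
            assert cond[p] == pytest.approx(1.0)

    def test_hand_conditional_average(self):
        # two containing models with weights 0.6, 0.2 and coefficients 1, 2
        # -> (0.6*1 + 0.2*2) / 0.8 = 1.25
        f1 = ModelFit(ModelSpec(("log_relF",)), 0, {"log_relF": 1.0}, 0, 0, 4, 30, weight=0.6)
        f2 = ModelFit(
            ModelSpec(("log_relF", "temperature")),
            0,
            {"log_relF": 2.0, "temperature": 0.0},
            0,
            0,
            5,
            30,
            weight=0.2,
        )
        cond, full = model_average([f1, f2])
        assert cond["log_relF"] == pytest.approx(1.25)
        assert full["log_relF"] == pytest.approx(1.0)


class TestGlsFits:
    def make_table(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "year": np.arange(1970, 1970 + n),
                "log_biomass": rng.normal(0, 1, n),
                "log_relF": rng.normal(0, 1, n),
                "temperature": rng.normal(8, 1, n),
            }
        )

    def test_noiseless_recovery_of_temperature_coefficient(self):
        tab = self.make_table()
        y = 3.0 + 2.5 * tab["temperature"].to_numpy()
        fit = fit_gls_ar1(tab["year"], y, tab, ModelSpec(("temperature",)))
        assert fit.coefficients["temperature"] == pytest.approx(2.5, abs=1e-6)

    def test_simulated_relf_coefficient_within_2se(self):
        rng = np.random.default_rng(1)
        tab = self.make_table(n=40, seed=1)
        e = np.zeros(40)
        for i in range(1, 40):
            e[i] = 0.5 * e[i - 1] + rng.normal(0, np.sqrt(1 - 0.25))
        y = 2.0 * tab["log_relF"].to_numpy() + e
        full = ModelSpec(("log_relF",))
        from stockdist.ar1 import fit_ar1_ml

        X = np.column_stack([np.ones(40), tab["log_relF"]])
        ref = fit_ar1_ml(tab["year"].to_numpy(float), y, X)
        assert abs(ref.beta[1] - 2.0) < 2 * ref.se[1]
        fit = fit_gls_ar1(tab["year"], y, tab, full)
        assert fit.coefficients["log_relF"] == pytest.approx(ref.beta[1])

    def test_intercept_only_white_noise_rho_near_zero(self):
        rng = np.random.default_rng(2)
        tab = self.make_table(n=60, seed=2)
        y = rng.normal(0, 1, 60)
        fit = fit_gls_ar1(tab["year"], y, tab, ModelSpec(()))
        assert abs(fit.rho) < 0.3

    def test_importance_invariant_to_response_shift_and_row_order(self):
        rng = np.random.default_rng(33)
        tab = self.make_table(n=35, seed=3)
        y = 1.5 * tab["log_biomass"].to_numpy() + rng.normal(0, 0.5, 35)
        a = importance_for_series(tab["year"], y, tab)
        b = importance_for_series(tab["year"], y + 1000.0, tab)
        for p in PREDICTORS:
            assert b.summed_weight[p] == pytest.approx(a.summed_weight[p], abs=1e-6)
        perm = rng.permutation(35)
        c = importance_for_series(
            tab["year"].to_numpy()[perm], y[perm], tab.iloc[perm].reset_index(drop=True)
        )
        for p in PREDICTORS:
            assert c.summed_weight[p] == pytest.approx(a.summed_weight[p], abs=1e-6)

    def test_noiseless_single_driver_ranks_first_with_high_weight(self):
        tab = self.make_table(n=25, seed=4)
        y = 4.0 - 3.0 * tab["log_biomass"].to_numpy()
        res = importance_for_series(tab["year"], y, tab)
        assert res.first_ranked() == ["log_biomass"]
        assert res.summed_weight["log_biomass"] > 0.9

    def test_constant_response_all_tie(self):
        tab = self.make_table(n=30, seed=5)
        y = np.full(30, 5.0)
        res = importance_for_series(tab["year"], y, tab)
        assert res.ties


class TestPipelineAndSummary:
    def test_pipeline_skips_short_series(self):
        ind = pd.DataFrame({"year": [2000, 2001, 2002], "xcg": [1.0, 2.0, 3.0]})
        pred = pd.DataFrame(
            {
                "year": [2000, 2001, 2002],
                "log_biomass": [0.1, 0.2, 0.3],
                "log_relF": [1, 2, 1],
                "temperature": [5, 6, 7],
            }
        )
        out = importance_pipeline(ind, pred, indicators=["xcg"])
        assert out == {}

    def test_single_stock_proportions_are_zero_or_one(self):
        rng = np.random.default_rng(6)
        tab = pd.DataFrame(
            {
                "year": np.arange(1980, 2010),
                "log_biomass": rng.normal(size=30),
                "log_relF": rng.normal(size=30),
                "temperature": rng.normal(8, 1, 30),
            }
        )
        y = 2.0 * tab["log_relF"].to_numpy() + rng.normal(0, 0.3, 30)
        res = importance_for_series(tab["year"], y, tab)
        summary = first_rank_proportions({"ONLY": {"xcg": res}})
        assert set(summary["proportion_first"]).issubset({0.0, 1.0})

    def test_tied_predictors_counted_for_each(self):
        fits = akaike_weights(make_fits([100.0] * 8))
        res = summed_importance(fits)
        summary = first_rank_proportions({"S1": {"xcg": res}})
        assert summary["proportion_first"].sum() == 3.0  # three-way tie, all counted
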