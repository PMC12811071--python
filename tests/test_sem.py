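import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, chi2

from herbnet import (
    PathModelSpec,
    ValidationError,
    default_path_model,
    dsep_test,
    fit_path_model,
    fit_paths,
    indirect_effect,
    pseudo_r2,
)
from herbnet.sem import _basis_set, encode_season, standardize


def gaussian_chain_data(seed=0, n=200, slope=2.0, noise=0.1):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = slope * x + noise * rng.standard_normal(n)
    z = 0.5 * y + noise * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "y": y, "z": z})


class TestFitPaths:
    def test_gaussian_slope_recovery(self):
        data = gaussian_chain_data()
        spec = PathModelSpec(edges=(("x", "y"),))
        res = fit_paths(spec, data)["y"]
        assert abs(res.params["x"] - 2.0) < 3 * res.bse["x"]

    def test_constant_predictor_is_singular(self):
        data = gaussian_chain_data()
        data["x"] = 1.0
        spec = PathModelSpec(edges=(("x", "y"),))
        with pytest.raises(ValidationError, match="y"):
            fit_paths(spec, data)

    def test_binomial_logit_sign_recovery(self):
        spec = PathModelSpec(edges=(("x", "p"),), families={"p": "binomial"})
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(80)
            eta = -2.5 + 1.0 * x
            trials = np.full(80, 50)
            succ = rng.binomial(trials, 1 / (1 + np.exp(-eta)))
            data = pd.DataFrame({"x": x, "p_successes": succ, "p_trials": trials})
            res = fit_paths(spec, data)["p"]
            hits += res.params["x"] > 0
        assert hits >= 0.95 * n_seeds

    def test_cyclic_spec_rejected(self):
        with pytest.raises(ValidationError):
            PathModelSpec(edges=(("a", "b"), ("b", "a")))


class TestStandardize:
    def test_unit_sd_identity(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4000)
        y = 0.6 * x + 0.8 * rng.standard_normal(4000)
        x, y = x / x.std(ddof=1), y / y.std(ddof=1)
        data = pd.DataFrame({"x": x, "y": y})
        spec = PathModelSpec(edges=(("x", "y"),))
        fits = fit_paths(spec, data)
        table = standardize(spec, fits, data)
        assert table["std_estimate"].iloc[0] == pytest.approx(
            fits["y"].params["x"], rel=1e-6
        )

    def test_invariant_to_predictor_rescaling(self):
        data = gaussian_chain_data(seed=2)
        spec = PathModelSpec(edges=(("x", "y"),))
        b1 = standardize(spec, fit_paths(spec, data), data)["std_estimate"].iloc[0]
        scaled = data.assign(x=10 * data["x"])
        b2 = standardize(spec, fit_paths(spec, scaled), scaled)["std_estimate"].iloc[0]
        assert b1 == pytest.approx(b2, rel=1e-9)


class TestIndirectEffect:
    def coefficients(self, entries):
        return pd.DataFrame(
            [
                {"response": b, "predictor": a, "std_estimate": v}
                for (a, b), v in entries.items()
            ]
        )

    def test_two_step_product(self):
        coef = self.coefficients({("s", "c"): 0.33, ("c", "p"): 0.14})
        effect = indirect_effect(coef, [("s", "c"), ("c", "p")])
        assert effect == pytest.approx(0.0462)

    def test_zero_annihilates(self):
        coef = self.coefficients({("s", "c"): 0.0, ("c", "p"): 0.9})
        assert indirect_effect(coef, [("s", "c"), ("c", "p")]) == 0.0

    def test_single_edge_identity(self):
        coef = self.coefficients({("s", "c"): -0.4})
        assert indirect_effect(coef, [("s", "c")]) == pytest.approx(-0.4)

    def test_non_chaining_edges_rejected(self):
        coef = self.coefficients({("s", "c"): 0.3, ("x", "y"): 0.5})
        with pytest.raises(ValidationError):
            indirect_effect(coef, [("s", "c"), ("x", "y")])


class TestBasisSet:
    def test_default_model_claims(self):
        claims = _basis_set(default_path_model())
        as_set = {(resp, other, cond) for resp, other, cond in claims}
        assert as_set == {
            ("structural_pd", "compositional_pd", ("season",)),
            ("herbivory", "season", ("compositional_pd", "structural_pd")),
            (
                "herbivory",
                "p_i",
                ("compositional_pd", "season", "structural_pd"),
            ),
        }

    def test_exogenous_pairs_excluded(self):
        spec = PathModelSpec(edges=(("a", "y"), ("b", "y")))
        assert _basis_set(spec) == []  # a-b both exogenous; everything else adjacent


class TestDsep:
    def test_saturated_model(self):
        data = gaussian_chain_data()
        spec = PathModelSpec(edges=(("x", "y"), ("y", "z"), ("x", "z")))
        out = dsep_test(spec, data)
        assert (out["fishers_C"], out["df"], out["p_value"]) == (0.0, 0, 1.0)

    def test_fisher_aggregation_consistent_with_claims(self):
        data = gaussian_chain_data(seed=3)
        spec = PathModelSpec(edges=(("x", "y"), ("y", "z")))
        out = dsep_test(spec, data)
        pvals = out["claims"]["p_value"].to_numpy()
        assert len(pvals) == 1  # single claim: z independent of x given y
        C_oracle = -2 * np.log(pvals).sum()
        assert out["fishers_C"] == pytest.approx(C_oracle)
        assert out["df"] == 2
        assert out["p_value"] == pytest.approx(chi2.sf(C_oracle, 2))

    def test_missing_path_is_detected(self):
        # data generated with a real x->z path the model omits
        rng = np.random.default_rng(8)
        x = rng.standard_normal(300)
        y = x + 0.3 * rng.standard_normal(300)
        z = 0.8 * x + 0.5 * y + 0.3 * rng.standard_normal(300)
        data = pd.DataFrame({"x": x, "y": y, "z": z})
        spec = PathModelSpec(edges=(("x", "y"), ("y", "z")))
        assert dsep_test(spec, data)["p_value"] < 0.01


class TestPseudoR2:
    @staticmethod
    def binomial_fit(seed=0, slope=1.5):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(60)
        trials = np.full(60, 40)
        succ = rng.binomial(trials, 1 / (1 + np.exp(-(-1.0 + slope * x))))
        data = pd.DataFrame({"x": x, "p_successes": succ, "p_trials": trials})
        spec = PathModelSpec(edges=(("x", "p"),), families={"p": "binomial"})
        return fit_paths(spec, data)["p"], data

    def test_null_model_zero(self):
        res, _ = self.binomial_fit(slope=0.0)
        spec = PathModelSpec(edges=(("x", "p"),), families={"p": "binomial"})
        # refit with the intercept alone: llf == llnull, both statistics 0
        data = pd.DataFrame(
            {
                "p_successes": [5, 6, 4, 5],
                "p_trials": [10, 10, 10, 10],
                "one": 1.0,
            }
        )
        from herbnet.sem import _fit_one

        null_res = _fit_one("p", (), "binomial", data)
        assert pseudo_r2(null_res) == pytest.approx(0.0, abs=1e-12)
        assert pseudo_r2(null_res, method="mcfadden") == pytest.approx(0.0, abs=1e-12)

    def test_strong_effect_approaches_one(self):
        res, _ = self.binomial_fit(slope=6.0)
        assert pseudo_r2(res) > 0.8

    def test_nagelkerke_matches_textbook_formula(self):
        res, data = self.binomial_fit(seed=4)
        succ = data["p_successes"].to_numpy()
        trials = data["p_trials"].to_numpy()
        # independent log-likelihoods from scipy
        ll1 = binom.logpmf(succ, trials, res.predict()).sum()
        p0 = succ.sum() / trials.sum()
        ll0 = binom.logpmf(succ, trials, p0).sum()
        n = len(succ)
        expected = (1 - math.exp((ll0 - ll1) * 2 / n)) / (1 - math.exp(ll0 * 2 / n))
        assert pseudo_r2(res) == pytest.approx(expected, rel=1e-6)


class TestFullModel:
    def test_full_model_fit_on_synthetic_study(self, default_study):
        from herbnet.pipeline import attach_interaction_stats

        data = attach_interaction_stats(default_study.covariates, default_study.networks)
        fit = fit_path_model(None, data)
        assert fit.df == 6 and len(fit.claims) == 3
        assert 0 <= fit.p_value <= 1
        assert set(fit.pseudo_r2) == {"p_i"}
        # generated signs: season raises compositional PD; structural PD lowers
        # p_i and herbivory; compositional PD raises p_i
        assert fit.std_estimate("season", "compositional_pd") > 0
        assert fit.std_estimate("compositional_pd", "p_i") > 0
        assert fit.std_estimate("structural_pd", "p_i") < 0
        assert fit.std_estimate("structural_pd", "herbivory") < 0
        indirect = fit.indirect_effect(
            [("season", "compositional_pd"), ("compositional_pd", "p_i")]
        )
        assert indirect > 0

    def test_season_encoding(self):
        df = pd.DataFrame({"season": ["rainy", "dry", "rainy"]})
        out = encode_season(df)
        assert out["season"].tolist() == [0.0, 1.0, 0.0]
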