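import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtconf import (FitSpec, count_free_parameters, fit_model, fit_models,
                    map_parameters, negative_log_likelihood)
from rtconf.fitting import (_Codec, _Design, _Objective, information_criteria,
                            initial_grid)
from rtconf.recovery import ParameterSampler, _simulated_table, sample_parameters

LEAN = {"grid_size": 64, "n_starts": 1, "n_restarts": 1, "max_evals": 200}


@pytest.fixture(scope="module")
def small_2dsd():
    row = sample_parameters(ParameterSampler(model="2DSD", L=2, K=3, seed=3),
                            1)[0]
    trials = _simulated_table(row, 40, 3, seed=21)
    return row, trials


class TestMapParameters:
    def test_ddm_negative_stimulus(self):
        m = map_parameters("dynaViTE", -1, 0.8)
        assert m == {"nu": -0.8, "muV": 0.8}

    def test_race(self):
        assert map_parameters("PCRMt", 1, 0.5) == {"mu1": 0.5, "mu2": -0.5}

    def test_mtlnr(self):
        assert map_parameters("MTLNR", -1, 1.2) == {"mu_v1": 0.0,
                                                    "mu_v2": 1.2}

    def test_bad_stimulus(self):
        with pytest.raises(ValueError):
            map_parameters("2DSD", 0, 1.0)


class TestCountFreeParameters:
    @pytest.mark.parametrize("model,expected", [
        ("dynaViTE", 18), ("IRMt", 13), ("PCRMt", 13), ("MTLNRfull", 17),
        ("dynWEV", 17), ("2DSD", 14), ("DDConf", 13), ("MTLNR", 14),
        ("IRM", 11), ("PCRM", 11)])
    def test_l3_k3(self, model, expected):
        assert count_free_parameters(model, 3, 3) == expected

    def test_sym_thetas_reduction(self):
        assert count_free_parameters("dynaViTE", 3, 3, sym_thetas=True) == 16

    def test_fixed_reduction(self):
        assert count_free_parameters("dynaViTE", 3, 3, fixed={"z": 0.5}) == 17

    def test_l5_k5(self):
        # fitted layer configurations at L=5, K=5
        assert count_free_parameters("dynaViTE", 5, 5) == 24
        assert count_free_parameters("IRMt", 5, 5) == 19
        assert count_free_parameters("MTLNR", 5, 5) == 20

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown model"):
            count_free_parameters("foo", 3, 3)

    def test_unknown_fixed_name(self):
        with pytest.raises(ValueError, match="does not belong"):
            count_free_parameters("IRMt", 3, 3, fixed={"tau": 1.0})


class TestNLL:
    def test_single_trial_minus_log_p(self, small_2dsd):
        row, trials = small_2dsd
        spec = FitSpec(model="2DSD", n_ratings=3)
        one = trials.df.iloc[[0]]
        from rtconf.trial_data import RatingScaleInfo, TrialTable
        tt = TrialTable(df=one.reset_index(drop=True),
                        scale=RatingScaleInfo(3, {1: {1, 2, 3},
                                                  -1: {1, 2, 3}}),
                        condition_levels=trials.condition_levels)
        nll1 = negative_log_likelihood(row, tt, spec)
        from rtconf.fitting import trial_densities
        dens = trial_densities(row, tt, spec)
        assert nll1 == pytest.approx(-math.log(dens[0]), rel=1e-9)

    def test_duplication_doubles(self, small_2dsd):
        row, trials = small_2dsd
        spec = FitSpec(model="2DSD", n_ratings=3)
        from rtconf.trial_data import TrialTable
        doubled = TrialTable(
            df=pd.concat([trials.df, trials.df], ignore_index=True),
            scale=trials.scale, condition_levels=trials.condition_levels)
        assert negative_log_likelihood(row, doubled, spec) == pytest.approx(
            2 * negative_log_likelihood(row, trials, spec), rel=1e-9)

    def test_generator_near_local_minimum(self, small_2dsd):
        """Perturbing the generating parameters mostly increases the NLL."""
        row, trials = small_2dsd
        spec = FitSpec(model="2DSD", n_ratings=3)
        base = negative_log_likelihood(row, trials, spec)
        worse = 0
        rng = np.random.default_rng(0)
        for _ in range(12):
            pert = dict(row)
            for k in ("a", "d_1", "d_2", "t0"):
                pert[k] = row[k] * rng.uniform(0.6, 1.6)
            if negative_log_likelihood(pert, trials, spec) > base:
                worse += 1
        assert worse >= 9

    def test_zero_density_penalized_finite(self, small_2dsd):
        row, trials = small_2dsd
        spec = FitSpec(model="2DSD", n_ratings=3)
        bad = dict(row)
        bad["t0"] = trials.df["rt"].min() * 2  # some trials impossible
        val = negative_log_likelihood(bad, trials, spec)
        assert np.isfinite(val)
        assert val > negative_log_likelihood(row, trials, spec)


class TestCodec:
    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        row = sample_parameters(
            ParameterSampler(model="dynaViTE", L=2, K=3,
                             seed=int(rng.integers(1 << 30))), 1)[0]
        trials = _simulated_table(row, 15, 3, seed=int(rng.integers(1 << 30)))
        spec = FitSpec(model="dynaViTE", n_ratings=3)
        obj = _Objective(trials, spec)
        params = {k: v for k, v in row.items()
                  if k in obj.codec.base + obj.codec.dnames}
        from rtconf.fitting import _free_from_full, _row_thresholds
        params["_thfree"] = _free_from_full(
            _row_thresholds(row, 3), obj.design, spec)
        x = obj.codec.encode(params)
        back = obj.codec.decode(x)
        for k in obj.codec.base + obj.codec.dnames:
            assert back[k] == pytest.approx(params[k], rel=1e-6, abs=1e-8)
        for s in (1, -1):
            np.testing.assert_allclose(back["_thfree"][s],
                                       params["_thfree"][s], rtol=1e-6)


class TestGrid:
    def test_ranked_and_anchored(self, small_2dsd):
        row, trials = small_2dsd
        spec = FitSpec(model="2DSD", n_ratings=3, opts=LEAN)
        cands = initial_grid(trials, spec, seed=1)
        nlls = [c[0] for c in cands]
        assert nlls[0] <= np.median(nlls)
        assert nlls == sorted(nlls)
        # data-driven anchors: t0 below min rt, drift signs positive since
        # accuracy is above chance in every condition
        for _, p in cands[:10]:
            assert p["t0"] < trials.df["rt"].min()
            assert p["d_1"] > 0

    def test_grid_adequacy(self):
        """Best grid candidate is not far above the generator's NLL."""
        hits = 0
        for i in range(6):
            row = sample_parameters(
                ParameterSampler(model="2DSD", L=2, K=3, seed=100 + i), 1)[0]
            trials = _simulated_table(row, 40, 3, seed=i)
            spec = FitSpec(model="2DSD", n_ratings=3,
                           opts={"grid_size": 256})
            cands = initial_grid(trials, spec, seed=i)
            gen_nll = negative_log_likelihood(row, trials, spec)
            if cands[0][0] <= 1.2 * gen_nll:
                hits += 1
        assert hits >= 5


class TestFitModel:
    def test_fixed_propagates(self, small_2dsd):
        _, trials = small_2dsd
        spec = FitSpec(model="2DSD", n_ratings=3, fixed={"z": 0.5},
                       opts=LEAN)
        fit = fit_model(trials, spec, seed=0)
        assert fit["z"] == 0.5
        assert fit["k"] == count_free_parameters("2DSD", 2, 3,
                                                 fixed={"z": 0.5})

    def test_sym_thetas_exact_equality(self, small_2dsd):
        _, trials = small_2dsd
        spec = FitSpec(model="2DSD", n_ratings=3,
                       fixed={"sym_thetas": True}, opts=LEAN)
        fit = fit_model(trials, spec, seed=0)
        assert fit["theta_plus_1"] == fit["theta_minus_1"]
        assert fit["theta_plus_2"] == fit["theta_minus_2"]

    def test_ic_identities(self, small_2dsd):
        _, trials = small_2dsd
        spec = FitSpec(model="IRM", n_ratings=3, opts=LEAN)
        fit = fit_model(trials, spec, seed=0)
        nll, k, n = fit["negLogLik"], fit["k"], fit["N"]
        assert fit["AIC"] == pytest.approx(2 * nll + 2 * k)
        assert fit["BIC"] == pytest.approx(2 * nll + k * math.log(n))
        assert fit["AICc"] == pytest.approx(
            fit["AIC"] + 2 * k * (k + 1) / (n - k - 1))

    def test_optimum_beats_grid_starts(self, small_2dsd):
        row, trials = small_2dsd
        spec = FitSpec(model="2DSD", n_ratings=3, opts=LEAN)
        cands = initial_grid(trials, spec, seed=0)
        fit = fit_model(trials, spec, seed=0)
        assert fit["negLogLik"] <= cands[0][0] + 1e-9

    def test_unused_extreme_category_gets_sentinel(self):
        row = sample_parameters(
            ParameterSampler(model="IRM", L=1, K=4, seed=9), 1)[0]
        trials = _simulated_table(row, 60, 4, seed=2)
        # remove every rating-4 trial to make the top category unused
        df = trials.df[trials.df["rating"] < 4].reset_index(drop=True)
        from rtconf.trial_data import RatingScaleInfo, TrialTable
        tt = TrialTable(df=df, scale=RatingScaleInfo(
            4, {s: set(df.loc[df["response"] == s, "rating"])
                for s in (1, -1)}), condition_levels=trials.condition_levels)
        spec = FitSpec(model="IRM", n_ratings=4, opts=LEAN)
        fit = fit_model(tt, spec, seed=0)
        assert fit["theta_plus_3"] == np.inf
        assert fit["theta_minus_3"] == np.inf
        # reported free-parameter count reflects the reduction
        assert fit["k"] == count_free_parameters("IRM", 1, 4) - 2


class TestFitModels:
    def test_cross_product_rows(self, small_2dsd):
        _, trials = small_2dsd
        df = trials.df.copy()
        df["subject"] = np.where(np.arange(len(df)) % 2 == 0, "s1", "s2")
        from rtconf.trial_data import TrialTable
        tt = TrialTable(df=df, scale=trials.scale,
                        condition_levels=trials.condition_levels)
        out = fit_models(tt, ["IRM", "PCRM"], n_ratings=3, opts=LEAN, seed=0)
        assert len(out) == 4
        assert set(out["model"]) == {"IRM", "PCRM"}

    def test_serial_parallel_identical(self, small_2dsd):
        _, trials = small_2dsd
        a = fit_models(trials, ["IRM"], n_ratings=3, opts=LEAN, n_jobs=1,
                       seed=5)
        b = fit_models(trials, ["IRM"], n_ratings=3, opts=LEAN, n_jobs=2,
                       seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_failure_isolated(self, small_2dsd):
        _, trials = small_2dsd
        out = fit_models(trials, ["IRM"], n_ratings=3,
                         fixed={"tau": 1.0},  # not an IRM parameter
                         opts=LEAN, seed=0)
        assert (out["status"] == "failed").all()
        assert "does not belong" in out["error"].iloc[0]


def test_information_criteria_function():
    aic, aicc, bic = information_criteria(100.0, 5, 200)
    assert aic == 210.0
    assert bic == pytest.approx(200 + 5 * math.log(200))
    assert aicc == pytest.approx(210 + 2 * 5 * 6 / 194)
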