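import numpy as np
import pandas as pd
import pytest

from rtconf import pdf_to_quantiles, predict_discrete, predict_rt, simulate_fit_row

ROW_2DSD = {"subject": 1, "model": "2DSD", "a": 1.6, "z": 0.5, "sz": 0.1,
            "snu": 0.4, "tau": 0.6, "t0": 0.3, "st0": 0.15,
            "d_1": 0.5, "d_2": 1.4,
            "theta_plus_1": 0.5, "theta_plus_2": 1.6,
            "theta_minus_1": 0.4, "theta_minus_2": 1.5}

ROW_IRMT = {"subject": 1, "model": "IRMt", "A": 1.4, "B": 1.3, "wX": 0.5,
            "wRT": 0.3, "t0": 0.25, "st0": 0.1, "d_1": 0.6, "d_2": 1.2,
            "theta_plus_1": 0.8, "theta_plus_2": 1.9,
            "theta_minus_1": 0.8, "theta_minus_2": 1.9}

ROW_MTLNR = {"subject": 1, "model": "MTLNR", "mu_d1": 0.5, "mu_d2": 0.5,
             "s1": 0.6, "s2": 0.6, "rho": 0.2, "t0": 0.3, "st0": 0.1,
             "d_1": 0.4, "d_2": 0.9,
             "theta_plus_1": 0.4, "theta_plus_2": 1.1,
             "theta_minus_1": 0.4, "theta_minus_2": 1.1}


@pytest.fixture(scope="module", params=["2DSD", "IRMt", "MTLNR"])
def fit_row(request):
    return {"2DSD": ROW_2DSD, "IRMt": ROW_IRMT, "MTLNR": ROW_MTLNR}[
        request.param]


class TestPredictDiscrete:
    def test_probabilities_sum_to_one(self, fit_row):
        tab = predict_discrete(fit_row, precision=4)
        sums = tab.groupby(["stimulus", "condition"])["p"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=2e-3)

    def test_matches_simulation(self, fit_row):
        tab = predict_discrete(fit_row, precision=4)
        sim = simulate_fit_row(fit_row, n=8000, seed=3)
        ok = sim[sim["response"] != 0]
        for _, r in tab.iterrows():
            sel = ok[(ok["stimulus"] == r["stimulus"])
                     & (ok["condition"] == r["condition"])]
            psim = ((sel["response"] == r["response"])
                    & (sel["rating"] == r["rating"])).mean()
            se = np.sqrt(max(psim * (1 - psim), 1e-5) / len(sel))
            assert r["p"] == pytest.approx(psim, abs=3 * se + 0.01)

    def test_accuracy_increases_with_discriminability(self):
        tab = predict_discrete(ROW_2DSD, precision=4)
        def p_correct(cond):
            sel = tab[(tab["condition"] == cond)
                      & (tab["stimulus"] == tab["response"])]
            return sel["p"].sum() / 2  # two stimuli, each sums to 1
        assert p_correct(2) > p_correct(1)


class TestPredictRT:
    def test_riemann_sum_matches_discrete(self):
        disc = predict_discrete(ROW_IRMT, precision=4)
        # the highest-confidence cells carry a slow tail (the losing
        # accumulator's gap grows with time), so the grid must reach far out
        dens = predict_rt(ROW_IRMT, rt_grid=(0, 30, 0.01), precision=4)
        merged = (dens.groupby(["stimulus", "condition", "response",
                                "rating"])["dens"].sum() * 0.01).reset_index()
        both = merged.merge(disc, on=["stimulus", "condition", "response",
                                      "rating"])
        np.testing.assert_allclose(both["dens"], both["p"], atol=3e-3)

    def test_scaled_densities_integrate_to_one(self):
        dens = predict_rt(ROW_MTLNR, rt_grid=(0, 20, 0.01), scaled=True,
                          precision=4)
        for _, grp in dens.groupby(["stimulus", "condition", "response",
                                    "rating"]):
            mass = grp["densscaled"].sum() * 0.01
            if np.isfinite(mass) and mass > 0:
                assert mass == pytest.approx(1.0, abs=0.03)

    def test_mismatched_discrete_table_fails(self):
        disc = predict_discrete(ROW_IRMT, precision=3)
        other = dict(ROW_IRMT, subject=99)
        with pytest.raises(ValueError, match="subject"):
            predict_rt(other, scaled=True, discrete_table=disc,
                       rt_grid=(0, 3, 0.05))

    def test_density_peak_matches_simulation(self):
        dens = predict_rt(ROW_2DSD, rt_grid=(0, 6, 0.02), precision=4)
        sel = dens[(dens["stimulus"] == 1) & (dens["condition"] == 2)
                   & (dens["response"] == 1)]
        marg = sel.groupby("rt")["dens"].sum()
        sim = simulate_fit_row(ROW_2DSD, n=20000, seed=5)
        ok = sim[(sim["stimulus"] == 1) & (sim["condition"] == 2)
                 & (sim["response"] == 1)]
        hist, edges = np.histogram(ok["rt"], bins=np.arange(0, 6, 0.02))
        peak_sim = edges[np.argmax(np.convolve(hist, np.ones(9) / 9,
                                               mode="same"))]
        peak_the = marg.idxmax()
        assert abs(peak_the - peak_sim) < 0.1


class TestPdfToQuantiles:
    def test_uniform_density(self):
        grid = np.arange(0, 1.0001, 0.001)
        df = pd.DataFrame({"rt": grid, "dens": np.ones_like(grid)})
        q = pdf_to_quantiles(df, probs=[0.1, 0.5, 0.9])
        np.testing.assert_allclose(q["quantile"], [0.1, 0.5, 0.9], atol=0.002)

    def test_nondecreasing(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"rt": np.linspace(0, 5, 200),
                           "dens": rng.random(200)})
        q = pdf_to_quantiles(df, probs=[0.1, 0.3, 0.5, 0.7, 0.9])
        assert (np.diff(q["quantile"]) >= 0).all()

    def test_all_zero_flagged(self):
        df = pd.DataFrame({"rt": [0, 1, 2], "dens": [0.0, 0.0, 0.0],
                           "g": ["a"] * 3})
        q = pdf_to_quantiles(df, probs=[0.5], group_columns=["g"])
        assert (q["flag"] == "all_zero").all()

    def test_matches_empirical_quantiles(self):
        dens = predict_rt(ROW_MTLNR, rt_grid=(0, 20, 0.02), precision=4)
        sel = dens[(dens["stimulus"] == 1) & (dens["condition"] == 1)]
        marg = sel.groupby("rt", as_index=False)["dens"].sum()
        q = pdf_to_quantiles(marg, probs=[0.1, 0.5, 0.9])
        sim = simulate_fit_row(ROW_MTLNR, n=50000, seed=9)
        ok = sim[(sim["stimulus"] == 1) & (sim["condition"] == 1)]
        emp = np.quantile(ok["rt"], [0.1, 0.5, 0.9])
        np.testing.assert_allclose(q["quantile"], emp, atol=0.04)

    def test_bad_probs(self):
        df = pd.DataFrame({"rt": [0, 1], "dens": [1.0, 1.0]})
        with pytest.raises(ValueError):
            pdf_to_quantiles(df, probs=[1.5])
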