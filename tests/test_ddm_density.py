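import math

import numpy as np
import pytest
from scipy.integrate import quad

from rtconf import (ConfidenceThresholds, DynaViTEParams, density_2dsd,
                    density_ddconf, density_dynavite, density_dynwev,
                    fpt_density_ddm)


def reference_fpt(t, response, a, z, nu, s=1.0, n_terms=120):
    """Independent oracle: long-truncation series in both representations
    (must agree), with the drift factored out analytically."""
    if t <= 0:
        return 0.0
    an = a / s
    vn = nu / s
    w = z if response < 0 else 1.0 - z
    v = vn if response < 0 else -vn
    tt = t / an ** 2
    small = sum((w + 2 * k) * math.exp(-(w + 2 * k) ** 2 / (2 * tt))
                for k in range(-n_terms, n_terms + 1))
    small /= math.sqrt(2 * math.pi * tt ** 3)
    large = math.pi * sum(
        k * math.exp(-k ** 2 * math.pi ** 2 * tt / 2) * math.sin(k * math.pi * w)
        for k in range(1, 5 * n_terms))
    assert small == pytest.approx(large, abs=1e-12)
    return math.exp(-v * an * w - v ** 2 * t / 2) * small / an ** 2


class TestFptDensity:
    def test_negative_time_is_zero(self):
        assert fpt_density_ddm(-0.1, 1, a=2, z=0.5) == 0.0

    @pytest.mark.parametrize("t", [0.05, 0.3, 1.0, 2.5])
    @pytest.mark.parametrize("response", [-1, 1])
    def test_matches_long_series_oracle(self, t, response):
        got = fpt_density_ddm(t, response, a=2.0, z=0.5, nu=1.0, snu=0.0,
                              sz=0.0, precision=8)
        want = reference_fpt(t, response, a=2.0, z=0.5, nu=1.0)
        assert got == pytest.approx(want, rel=1e-7, abs=1e-12)

    def test_zero_drift_symmetry(self):
        ts = np.linspace(0.05, 3.0, 25)
        up = fpt_density_ddm(ts, 1, a=2.0, z=0.5, nu=0.0)
        lo = fpt_density_ddm(ts, -1, a=2.0, z=0.5, nu=0.0)
        np.testing.assert_allclose(up, lo, rtol=1e-12)

    def test_defective_densities_integrate_to_one(self):
        total = sum(
            quad(lambda t: fpt_density_ddm(t, r, a=1.5, z=0.45, nu=0.8,
                                           snu=0.5, sz=0.2, precision=5),
                 0, 40, limit=200)[0]
            for r in (-1, 1))
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_invalid_parameters_named(self):
        with pytest.raises(ValueError, match="boundary separation"):
            fpt_density_ddm(1.0, 1, a=-1, z=0.5)
        with pytest.raises(ValueError, match="sz"):
            fpt_density_ddm(1.0, 1, a=1, z=0.1, sz=0.5)


class TestDynaViTE:
    def test_marginal_equals_fpt(self, dynavite_params):
        """Full-line confidence interval marginalizes confidence away."""
        p = dynavite_params
        for rt in (0.8, 1.5, 3.0):
            full = density_dynavite(rt, 1, -np.inf, np.inf, p, precision=5)
            # marginal: integrate fpt over the non-decision window
            marg = quad(lambda tnd: fpt_density_ddm(
                rt - p.t0 - tnd, 1, p.a, p.z, p.sz, p.nu, p.snu, p.s,
                precision=6) / p.st0, 0, p.st0, limit=100)[0]
            assert full == pytest.approx(marg, rel=2e-3)

    def test_zero_width_interval(self, dynavite_params):
        assert density_dynavite(1.0, 1, 0.7, 0.7, dynavite_params) == 0.0

    def test_th1_above_th2_fails(self, dynavite_params):
        with pytest.raises(ValueError, match="th1"):
            density_dynavite(1.0, 1, 1.0, 0.5, dynavite_params)

    def test_rt_below_minimum_is_zero(self, dynavite_params):
        assert density_dynavite(0.1, 1, -1, 1, dynavite_params) == 0.0
        assert density_dynavite(
            dynavite_params.t0 + dynavite_params.tau - 0.01, 1, -1, 1,
            dynavite_params, simult_conf=True) == 0.0

    def test_normalization_random_parameters(self):
        from rtconf.recovery import ParameterSampler, sample_parameters
        from rtconf.simulate import _dynavite_params_from_row, _theta_from_row
        from rtconf.models import map_parameters
        rows = sample_parameters(
            ParameterSampler(model="dynaViTE", L=1, K=3, seed=42), 1)
        row = rows[0]
        theta = _theta_from_row(row)
        mapped = map_parameters("dynaViTE", 1, row["d_1"])
        p = _dynavite_params_from_row(row, "dynaViTE", theta, mapped)
        total = 0.0
        for resp in (-1, 1):
            for rating in (1, 2, 3):
                lo, hi = theta.interval(resp, rating)
                total += quad(lambda t: density_dynavite(t, resp, lo, hi, p,
                                                         precision=4),
                              p.t0, 40, limit=200)[0]
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_bin_additivity(self, dynavite_params):
        p = dynavite_params
        rt = 1.3
        a = density_dynavite(rt, 1, -0.5, 0.6, p)
        b = density_dynavite(rt, 1, 0.6, 1.8, p)
        c = density_dynavite(rt, 1, -0.5, 1.8, p)
        assert a + b == pytest.approx(c, rel=1e-9)

    def test_precision_scaling_monotone(self, dynavite_params):
        p = dynavite_params
        rts = np.linspace(0.7, 3.0, 12)
        precisions = [3.0, 3.5, 4.0, 4.5, 5.0]
        vals = [density_dynavite(rts, 1, 0.3, 1.0, p, precision=q)
                for q in precisions]
        ref = density_dynavite(rts, 1, 0.3, 1.0, p, precision=6.5)
        errs = np.array([np.mean(np.abs(v - ref)) for v in vals])
        # errors shrink overall (allow tiny non-monotonic wiggles on a
        # single parameter set; the pattern is exact only on average)
        assert np.all(np.diff(np.log10(errs)) < 0.3)
        assert errs[-1] < errs[0] / 10


class TestSpecialCases:
    @pytest.mark.parametrize("seed", range(10))
    def test_dynwev_equals_dynavite_at_lambda_zero(self, seed):
        rng = np.random.default_rng(seed)
        p = DynaViTEParams(
            a=rng.uniform(1, 2.5), z=rng.uniform(0.4, 0.6),
            sz=rng.uniform(0, 0.3), nu=rng.uniform(-1, 2),
            snu=rng.uniform(0, 0.8), tau=rng.uniform(0.2, 1.5),
            muV=rng.uniform(0, 2), sV=rng.uniform(0.5, 1.5),
            sigmaV=rng.uniform(0, 0.8), w=rng.uniform(0.2, 0.9), lam=0.0,
            t0=0.2, st0=0.15)
        rts = np.linspace(0.4, 4.0, 10)
        for lohi in [(-np.inf, 0.5), (0.5, 1.5)]:
            for r in (-1, 1):
                a = density_dynwev(rts, r, *lohi, p, precision=4)
                b = density_dynavite(rts, r, *lohi, p, precision=4)
                np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_2dsd_ignores_visibility(self, dynavite_params):
        p = dynavite_params.replace(lam=0.0, w=1.0)
        q = p.replace(muV=5.0, sV=9.0, sigmaV=3.0)  # arbitrary visibility
        rts = np.linspace(0.5, 3.0, 8)
        a = density_2dsd(rts, 1, 0.2, 1.0, p)
        b = density_2dsd(rts, 1, 0.2, 1.0, q)
        c = density_dynavite(rts, 1, 0.2, 1.0, q.replace(lam=0.0, w=1.0))
        np.testing.assert_allclose(a, b, rtol=1e-12)
        np.testing.assert_allclose(a, c, rtol=1e-12)

    def test_ddconf_equals_constrained_dynavite(self, dynavite_params):
        p = dynavite_params.replace(w=1.0, tau=0.0, lam=0.5)
        rts = np.linspace(0.5, 3.0, 8)
        a = density_ddconf(rts, -1, 0.4, 1.2, dynavite_params)
        b = density_dynavite(rts, -1, 0.4, 1.2, p)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_ddconf_bins_are_decision_time_windows(self):
        # a=2, z=0.5: confidence = 1/sqrt(T_dec); interval [th1, th2] maps
        # to T_dec in [1/th2^2, 1/th1^2]
        p = DynaViTEParams(a=2.0, z=0.5, nu=0.6, t0=0.2, st0=0.0, w=1.0,
                           tau=0.0, lam=0.5)
        th1, th2 = 0.8, 1.4
        for rt in (0.5, 0.9, 1.5, 2.5):
            tdec = rt - p.t0
            inside = (1 / th2 ** 2 <= tdec <= 1 / th1 ** 2)
            got = density_ddconf(rt, 1, th1, th2, p)
            fpt = fpt_density_ddm(tdec, 1, p.a, p.z, nu=p.nu)
            assert got == pytest.approx(fpt if inside else 0.0, rel=1e-9)
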