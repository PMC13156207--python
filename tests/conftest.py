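import math

import numpy as np
import pandas as pd
import pytest

from rtconf.params import ConfidenceThresholds, DynaViTEParams, MTLNRParams, RaceParams


@pytest.fixture(scope="session")
def dynavite_params():
    return DynaViTEParams(
        a=1.8, z=0.55, sz=0.2, nu=0.9, snu=0.6, s=1.0, tau=1.0, muV=0.9,
        sV=1.2, sigmaV=0.5, w=0.6, lam=0.4, t0=0.25, st0=0.2,
        theta=ConfidenceThresholds(np.array([0.3, 1.0]),
                                   np.array([0.2, 0.9])))


@pytest.fixture(scope="session")
def race_params():
    return RaceParams(
        A=1.2, B=1.4, mu1=0.8, mu2=-0.3, s1=1.0, s2=1.2, rho=-0.5,
        wX=0.5, wRT=0.3, wInt=0.2, t0=0.3, st0=0.25,
        theta=ConfidenceThresholds(np.array([0.8, 2.0])))


@pytest.fixture(scope="session")
def mtlnr_params():
    return MTLNRParams(
        mu_d1=0.5, mu_d2=0.6, mu_v1=0.8, mu_v2=0.0, sigma_d1=0.3,
        sigma_d2=0.25, rho_d=0.2, sigma_v1=0.6, sigma_v2=0.7, rho_v=-0.3,
        t0=0.3, st0=0.25,
        theta=ConfidenceThresholds(np.array([0.4, 1.2])))


@pytest.fixture(scope="session")
def trial_frame():
    """Small raw trial table with aliased columns."""
    rng = np.random.default_rng(0)
    n = 60
    stim = rng.choice(["left", "right"], n)
    correct = rng.random(n) < 0.75
    resp = np.where(correct, stim, np.where(stim == "left", "right", "left"))
    return pd.DataFrame({
        "participant": rng.integers(1, 4, n),
        "stimulus": stim,
        "response": resp,
        "rt": rng.uniform(0.4, 2.5, n),
        "confidence": rng.integers(1, 5, n),
        "condition": rng.choice([0.1, 0.2, 0.4], n),
    })


def joint_cell_probs(density_fn, responses, theta, upper=40.0, t_lo=0.0,
                     clip_nonneg=False):
    """Integrate a joint density over rt for every response x rating cell."""
    from scipy.integrate import quad
    out = {}
    for resp in responses:
        sign = 1 if resp == 1 else -1
        K = theta.n_ratings
        for rating in range(1, K + 1):
            lo, hi = theta.interval(sign, rating)
            if clip_nonneg:
                lo, hi = max(lo, 0.0), max(hi, 0.0)
            val = quad(lambda t: density_fn(t, resp, lo, hi), t_lo, upper,
                       limit=200)[0]
            out[(resp, rating)] = val
    return out
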