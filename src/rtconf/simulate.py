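"""Trial-level stochastic simulation for all models.

Low-level simulators take explicit parameter objects and return a SimTrial
table; :func:`simulate_fit_row` reproduces a whole design (stimulus x
condition) from a fitted parameter row.  Diffusion and Wiener-race paths use
Euler-Maruyama discretization (step ``delta``); the log-normal race is
sampled exactly.  A response of 0 flags trials where no boundary was reached
before ``maxrt``; their rt/confidence are missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _kernels as _k
from .models import base_parameters, family, map_parameters, response_to_winner
from .params import ConfidenceThresholds, DynaViTEParams, MTLNRParams, RaceParams

__all__ = ["simulate_dynavite", "simulate_race", "simulate_mtlnr",
           "simulate_fit_row", "kruskal_gamma", "rate_ratings"]

DEFAULT_DELTA = 0.001
DEFAULT_MAXRT = 15.0


def rate_ratings(conf, response, theta: ConfidenceThresholds):
    """Discretize internal confidence values with response-specific
    thresholds: ``rating = sum_k 1(c > theta_{R,k}) + 1``."""
    conf = np.asarray(conf, dtype=float)
    response = np.asarray(response)
    rating = np.ones(len(conf), dtype=int)
    for sign in (1, -1):
        sel = response == sign
        th = theta[sign]
        for t in th:
            rating[sel] += (conf[sel] > t).astype(int)
    rating[~np.isfinite(conf)] = 0
    return rating


def _sim_frame(resp, rt, conf, theta):
    rating = rate_ratings(conf, resp, theta)
    df = pd.DataFrame({"response": resp, "rt": rt, "conf_value": conf,
                       "rating": rating})
    df.loc[df["response"] == 0, ["rt", "conf_value"]] = np.nan
    df.loc[df["response"] == 0, "rating"] = 0
    return df


def _check_sim_args(n, delta, maxrt, t0):
    if n <= 0:
        raise ValueError("trial count n must be positive")
    if delta <= 0:
        raise ValueError("step size delta must be positive")
    if maxrt <= t0:
        raise ValueError("maxrt must exceed t0")


def simulate_dynavite(params: DynaViTEParams, n, delta=DEFAULT_DELTA,
                      maxrt=DEFAULT_MAXRT, seed=0, simult_conf=False):
    """Simulate the diffusion-family process (decision + visibility).

    The visibility path is skipped when ``w = 1`` (it would not enter the
    confidence variable).  Responses are -1/+1 in the returned table.
    """
    params.validate()
    _check_sim_args(n, delta, maxrt, params.t0)
    p = params
    resp, rt, conf = _k.simulate_dynavite_k(
        int(n), p.a, p.z, p.sz, p.nu, p.snu, p.s, p.tau, p.muV, p.sV,
        p.sigmaV, p.w, p.lam, p.t0, p.st0, float(delta), float(maxrt),
        bool(simult_conf), int(seed))
    return _sim_frame(resp, rt, conf, p.theta)


def simulate_race(params: RaceParams, n, delta=DEFAULT_DELTA,
                  maxrt=DEFAULT_MAXRT, seed=0):
    """Simulate the two-accumulator Wiener race (increment correlation
    ``rho``).  Winner 1 is reported as response +1, winner 2 as -1."""
    params.validate()
    _check_sim_args(n, delta, maxrt, params.t0)
    p = params
    win, rt, conf = _k.simulate_race_k(
        int(n), p.A, p.B, p.mu1, p.mu2, p.s1, p.s2, p.rho, p.wX, p.wRT,
        p.wInt, p.t0, p.st0, float(delta), float(maxrt), int(seed))
    resp = np.where(win == 0, 0, np.where(win == 1, 1, -1))
    return _sim_frame(resp, rt, conf, p.theta)


def simulate_mtlnr(params: MTLNRParams, n, seed=0):
    """Exact sampling of the log-normal race (ballistic: no discretization,
    no step size, and a response is always produced)."""
    params.validate()
    if n <= 0:
        raise ValueError("trial count n must be positive")
    p = params
    rng = np.random.default_rng(seed)
    cov_d = np.array([[p.sigma_d1 ** 2, p.sigma_d1 * p.sigma_d2 * p.rho_d],
                      [p.sigma_d1 * p.sigma_d2 * p.rho_d, p.sigma_d2 ** 2]])
    cov_v = np.array([[p.sigma_v1 ** 2, p.sigma_v1 * p.sigma_v2 * p.rho_v],
                      [p.sigma_v1 * p.sigma_v2 * p.rho_v, p.sigma_v2 ** 2]])
    log_d = rng.multivariate_normal([p.mu_d1, p.mu_d2], cov_d, size=n,
                                    method="cholesky" if np.linalg.det(cov_d) > 1e-12 else "svd")
    log_v = rng.multivariate_normal([p.mu_v1, p.mu_v2], cov_v, size=n,
                                    method="cholesky" if np.linalg.det(cov_v) > 1e-12 else "svd")
    T = np.exp(log_d - log_v)
    win = np.where(T[:, 0] <= T[:, 1], 1, 2)
    tdec = T.min(axis=1)
    conf = np.abs(np.log(T[:, 1] / T[:, 0]))
    rt = tdec + p.t0 + p.st0 * rng.random(n)
    resp = np.where(win == 1, 1, -1)
    return _sim_frame(resp, rt, conf, p.theta)


def simulate_fit_row(fit_row, n, simult_conf=False, aggregate=False,
                     gamma=False, seed=0, delta=DEFAULT_DELTA,
                     maxrt=DEFAULT_MAXRT):
    """Simulate ``n`` trials per stimulus identity and difficulty condition
    from a fitted parameter row (dict / pandas Series with a ``model`` entry,
    structural parameters, ``d_1..d_L`` and thresholds ``theta...``).

    Returns a trial table; with ``aggregate`` the choice x rating counts;
    with ``gamma`` additionally Kruskal's gamma between confidence and
    accuracy per condition.
    """
    row = dict(fit_row) if not isinstance(fit_row, dict) else dict(fit_row)
    model = row["model"]
    fam = family(model)
    drifts = sorted((k for k in row if k.startswith("d_") and pd.notna(row[k])),
                    key=lambda s: int(s.split("_")[1]))
    if not drifts:
        raise ValueError("fit row contains no discriminability entries d_l")
    theta = _theta_from_row(row)
    frames = []
    idx = 0
    for cond, dname in enumerate(drifts, start=1):
        d = float(row[dname])
        for stim in (-1, 1):
            mapped = map_parameters(model, stim, d)
            sub_seed = int(seed) + 7919 * idx
            idx += 1
            if fam == "ddm":
                p = _dynavite_params_from_row(row, model, theta, mapped)
                sim = simulate_dynavite(p, n, delta=delta, maxrt=maxrt,
                                        seed=sub_seed, simult_conf=simult_conf)
            elif fam == "race":
                p = _race_params_from_row(row, model, theta, mapped)
                sim = simulate_race(p, n, delta=delta, maxrt=maxrt,
                                    seed=sub_seed)
            else:
                p = _mtlnr_params_from_row(row, model, theta, mapped)
                sim = simulate_mtlnr(p, n, seed=sub_seed)
            sim.insert(0, "condition", cond)
            sim.insert(0, "stimulus", stim)
            frames.append(sim)
    out = pd.concat(frames, ignore_index=True)
    out["correct"] = (out["stimulus"] == out["response"]).astype(int)
    out.loc[out["response"] == 0, "correct"] = np.nan
    if gamma:
        gammas = _gamma_tables(out)
        if aggregate:
            return _aggregate(out), gammas
        return out, gammas
    if aggregate:
        return _aggregate(out)
    return out


def _aggregate(sim):
    ok = sim[sim["response"] != 0]
    agg = (ok.groupby(["stimulus", "condition", "response", "rating"])
           .size().rename("n").reset_index())
    return agg


def _gamma_tables(sim):
    """Kruskal's gamma between confidence and accuracy / rt per condition;
    unterminated trials (response 0) are dropped and counted."""
    ok = sim[sim["response"] != 0]
    dropped = int((sim["response"] == 0).sum())
    rows = []
    for cond, grp in ok.groupby("condition"):
        rows.append({"condition": cond,
                     "gamma_accuracy": kruskal_gamma(grp["rating"], grp["correct"]),
                     "gamma_rt": kruskal_gamma(grp["rating"], -grp["rt"]),
                     "n": len(grp)})
    tab = pd.DataFrame(rows)
    tab.attrs["n_dropped"] = dropped
    return tab


def kruskal_gamma(x, y):
    """Goodman-Kruskal gamma: (C - D) / (C + D) over concordant and
    discordant pairs; tied pairs are excluded.  Returns NaN when every pair
    is tied."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    xs = pd.unique(np.sort(x))
    ys = pd.unique(np.sort(y))
    # contingency-table count: O(|x levels|^2 * |y levels|^2)
    table = np.zeros((len(xs), len(ys)))
    xi = np.searchsorted(xs, x)
    yi = np.searchsorted(ys, y)
    np.add.at(table, (xi, yi), 1)
    C = D = 0.0
    nr, nc = table.shape
    for i in range(nr):
        for j in range(nc):
            nij = table[i, j]
            if nij == 0:
                continue
            C += nij * table[i + 1:, j + 1:].sum()
            D += nij * table[i + 1:, :j].sum()
    if C + D == 0:
        return np.nan
    return (C - D) / (C + D)


# -- fit-row -> parameter-object helpers ------------------------------------

def _theta_from_row(row):
    up = sorted((k for k in row if k.startswith("theta_plus_")
                 and pd.notna(row[k])), key=lambda s: int(s.rsplit("_", 1)[1]))
    lo = sorted((k for k in row if k.startswith("theta_minus_")
                 and pd.notna(row[k])), key=lambda s: int(s.rsplit("_", 1)[1]))
    upper = np.array([float(row[k]) for k in up])
    lower = np.array([float(row[k]) for k in lo]) if lo else None
    return ConfidenceThresholds(upper, lower)


def _get(row, name, default=0.0):
    v = row.get(name, default)
    return default if pd.isna(v) else float(v)


def _dynavite_params_from_row(row, model, theta, mapped):
    base = set(base_parameters(model))
    return DynaViTEParams(
        a=_get(row, "a", 1.0), z=_get(row, "z", 0.5), sz=_get(row, "sz"),
        nu=mapped["nu"], snu=_get(row, "snu"), s=_get(row, "s", 1.0),
        tau=_get(row, "tau") if "tau" in base else 0.0,
        muV=mapped["muV"],
        sV=_get(row, "sV", 1.0) if "sV" in base else 1.0,
        sigmaV=_get(row, "sigmaV") if "sigmaV" in base else 0.0,
        w=_get(row, "w", 1.0) if "w" in base else 1.0,
        lam=(_get(row, "lam") if "lam" in base
             else (0.5 if model == "DDConf" else 0.0)),
        t0=_get(row, "t0"), st0=_get(row, "st0"), theta=theta)


def _race_params_from_row(row, model, theta, mapped):
    rho = -0.5 if model.startswith("PCRM") else 0.0
    if model.endswith("t"):
        wX = _get(row, "wX", 1.0)
        wRT = _get(row, "wRT", 0.0)
        wInt = max(0.0, 1.0 - wX - wRT)
    else:
        wX, wRT, wInt = 1.0, 0.0, 0.0
    return RaceParams(
        A=_get(row, "A", 1.0), B=_get(row, "B", 1.0),
        mu1=mapped["mu1"], mu2=mapped["mu2"],
        s1=_get(row, "s1", 1.0), s2=_get(row, "s2", 1.0), rho=rho,
        wX=wX, wRT=wRT, wInt=wInt,
        t0=_get(row, "t0"), st0=_get(row, "st0"), theta=theta)


def _mtlnr_params_from_row(row, model, theta, mapped):
    # fitted layer: variability of the crossing times is carried by the
    # rates (boundary-distance variability fixed to 0); labels s1/s2/rho
    if "sigma_d1" in row and pd.notna(row.get("sigma_d1")):
        sd1, sd2, rd = (_get(row, "sigma_d1"), _get(row, "sigma_d2"),
                        _get(row, "rho_d"))
    else:
        sd1 = sd2 = rd = 0.0
    return MTLNRParams(
        mu_d1=_get(row, "mu_d1"), mu_d2=_get(row, "mu_d2"),
        mu_v1=mapped["mu_v1"], mu_v2=mapped["mu_v2"],
        sigma_d1=sd1, sigma_d2=sd2, rho_d=rd,
        sigma_v1=_get(row, "s1", 1.0), sigma_v2=_get(row, "s2", 1.0),
        rho_v=_get(row, "rho"),
        t0=_get(row, "t0"), st0=_get(row, "st0"), theta=theta)
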