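"""Predicted outcome distributions and RT densities from fitted parameters.

``predict_discrete`` integrates each model's joint density over response
time for every stimulus x condition x response x rating cell;
``predict_rt`` evaluates the (defective, optionally scaled) density on an
equidistant rt grid; ``pdf_to_quantiles`` converts density vectors to
quantiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import quad

from ._precision import DEFAULT_PRECISION
from .ddm import density_2dsd, density_ddconf, density_dynavite, density_dynwev
from .models import family, map_parameters, response_to_winner
from .mtlnr import density_mtlnr
from .race import density_race
from .simulate import (_dynavite_params_from_row, _mtlnr_params_from_row,
                       _race_params_from_row, _theta_from_row)

__all__ = ["predict_discrete", "predict_rt", "pdf_to_quantiles"]

RT_UPPER = 60.0  # integration horizon; joint densities are negligible beyond


def _cells(row):
    model = row["model"]
    drifts = sorted((k for k in row if k.startswith("d_") and pd.notna(row[k])),
                    key=lambda s: int(s.split("_")[1]))
    theta = _theta_from_row(row)
    K = theta.n_ratings
    for cond, dname in enumerate(drifts, start=1):
        for stim in (-1, 1):
            mapped = map_parameters(model, stim, float(row[dname]))
            for resp in (-1, 1):
                for rating in range(1, K + 1):
                    yield cond, stim, resp, rating, mapped, theta


def _cell_density(row, model, mapped, theta, resp, rating, precision,
                  simult_conf):
    fam = family(model)
    lo, hi = theta.interval(resp, rating)
    if fam == "ddm":
        p = _dynavite_params_from_row(row, model, theta, mapped)
        fun = {"dynaViTE": density_dynavite, "dynWEV": density_dynwev,
               "2DSD": density_2dsd, "DDConf": density_ddconf}[model]
        return (lambda t: fun(t, resp, lo, hi, p, precision=precision,
                              simult_conf=simult_conf)), p
    if fam == "race":
        p = _race_params_from_row(row, model, theta, mapped)
        w = response_to_winner(resp)
        return (lambda t: density_race(t, w, max(lo, 0.0), max(hi, 0.0), p,
                                       precision=precision)), p
    p = _mtlnr_params_from_row(row, model, theta, mapped)
    w = response_to_winner(resp)
    return (lambda t: density_mtlnr(t, w, max(lo, 0.0), max(hi, 0.0), p,
                                    precision=precision)), p


def predict_discrete(fit_row, precision=DEFAULT_PRECISION, simult_conf=False,
                     subdivisions=80):
    """Discrete outcome probabilities for one fitted parameter row.

    Returns one row per stimulus x condition x response x rating with the
    probability ``p``, an integration status ``info`` and error estimate
    ``err``.  Probabilities sum to 1 within each stimulus x condition.
    """
    row = dict(fit_row)
    model = row["model"]
    out = []
    for cond, stim, resp, rating, mapped, theta in _cells(row):
        fun, p = _cell_density(row, model, mapped, theta, resp, rating,
                               precision, simult_conf)
        lo_t = p.t0
        with np.errstate(all="ignore"):
            val, err = quad(fun, lo_t, RT_UPPER, limit=subdivisions,
                            epsabs=1e-6, epsrel=1e-5)
        info = "OK" if err < max(1e-4, 1e-3 * abs(val)) else "maxiter"
        out.append({"subject": row.get("subject"), "model": model,
                    "stimulus": stim, "condition": cond, "response": resp,
                    "rating": rating, "p": max(val, 0.0), "info": info,
                    "err": err})
    return pd.DataFrame(out)


def predict_rt(fit_row, rt_grid=(0.0, 9.0, 0.01), scaled=False,
               discrete_table=None, precision=DEFAULT_PRECISION,
               simult_conf=False):
    """Defective RT densities on an equidistant grid for every outcome cell;
    with ``scaled`` the densities are divided by the cell probability
    (taken from ``discrete_table`` if supplied, else recomputed)."""
    row = dict(fit_row)
    model = row["model"]
    lo, hi, step = rt_grid
    if step <= 0:
        raise ValueError("rt grid step must be positive")
    grid = np.arange(lo, hi + step / 2, step)
    if scaled and discrete_table is None:
        discrete_table = predict_discrete(row, precision=precision,
                                          simult_conf=simult_conf)
    if discrete_table is not None:
        _check_discrete_match(discrete_table, row)
    out = []
    for cond, stim, resp, rating, mapped, theta in _cells(row):
        fun, _ = _cell_density(row, model, mapped, theta, resp, rating,
                               precision, simult_conf)
        dens = fun(grid)
        cell = pd.DataFrame({"subject": row.get("subject"), "model": model,
                             "stimulus": stim, "condition": cond,
                             "response": resp, "rating": rating, "rt": grid,
                             "dens": dens})
        if scaled:
            sel = discrete_table[(discrete_table["stimulus"] == stim)
                                 & (discrete_table["condition"] == cond)
                                 & (discrete_table["response"] == resp)
                                 & (discrete_table["rating"] == rating)]
            pcell = float(sel["p"].iloc[0]) if len(sel) else np.nan
            cell["densscaled"] = dens / pcell if pcell and pcell > 0 else 0.0
        out.append(cell)
    return pd.concat(out, ignore_index=True)


def _check_discrete_match(tab, row):
    need = {"stimulus", "condition", "response", "rating", "p"}
    if not need <= set(tab.columns):
        raise ValueError("discrete table lacks required columns")
    if "model" in tab.columns and not (tab["model"] == row["model"]).any():
        raise ValueError("discrete table does not cover this model")
    subj = row.get("subject")
    if subj is not None and "subject" in tab.columns:
        if not (tab["subject"] == subj).any():
            raise ValueError("discrete table does not cover this subject")


def pdf_to_quantiles(density_table, probs=(0.1, 0.5, 0.9), group_columns=(),
                     rt_column="rt", density_column="dens"):
    """Quantiles from gridded density values, per group: the smallest grid
    rt at which the normalized cumulative density reaches each probability
    (left-continuous inverse of the discretized CDF)."""
    probs = list(probs)
    if any(not 0 < q < 1 for q in probs):
        raise ValueError("probs must lie in (0, 1)")
    df = density_table
    group_columns = list(group_columns)
    groups = df.groupby(group_columns) if group_columns else [((), df)]
    rows = []
    for key, grp in groups:
        if len(grp) < 2:
            raise ValueError("need at least 2 grid points per group")
        dens = grp[density_column].to_numpy(float)
        rt = grp[rt_column].to_numpy(float)
        order = np.argsort(rt)
        rt, dens = rt[order], dens[order]
        tot = dens.sum()
        rec = dict(zip(group_columns, key if isinstance(key, tuple) else (key,)))
        if tot <= 0:
            rec.update({"prob": np.nan, "quantile": np.nan, "flag": "all_zero"})
            rows.append(rec)
            continue
        cdf = np.cumsum(dens) / tot
        for q in probs:
            idx = int(np.searchsorted(cdf, q, side="left"))
            idx = min(idx, len(rt) - 1)
            r = dict(rec)
            r.update({"prob": q, "quantile": rt[idx], "flag": "ok"})
            rows.append(r)
    return pd.DataFrame(rows)
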