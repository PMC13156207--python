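"""Synthetic parameter sampling, parameter/model recovery, and precision
benchmarking.

Parameters are drawn uniformly within configurable ranges, with structured
exceptions: discriminability is sampled as a first level plus non-negative
increments (so difficulty levels are ordered); the start-range fraction is
uniform on its admissible range given z; the race confidence weights are
drawn sequentially on the simplex; race boundaries are drawn as a sum and a
relative share.  Confidence thresholds are placed at quantiles of a
simulated sample of the internal confidence variable so that every rating
category receives mass.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import FitSpec, fit_model, trial_densities
from .models import base_parameters, family
from .simulate import simulate_fit_row
from .trial_data import RatingScaleInfo, TrialTable

__all__ = ["ParameterSampler", "sample_parameters", "run_parameter_recovery",
           "run_model_recovery", "run_precision_benchmark", "ccc",
           "DEFAULT_RANGES"]

#: default sampling ranges (versioned configuration; derived from typical
#: empirical fits of these model families, not hard constraints)
DEFAULT_RANGES = {
    "ddm": {
        "a": (1.0, 2.6), "z": (0.4, 0.6), "sz_frac": (0.05, 0.7),
        "snu": (0.1, 0.8), "tau": (0.4, 1.8), "sV": (0.5, 1.8),
        "sigmaV": (0.1, 0.8), "w": (0.3, 0.8), "lam": (0.0, 1.0),
        "t0": (0.2, 0.5), "st0": (0.05, 0.3),
        "d_first": (0.1, 0.8), "d_step": (0.1, 0.7),
    },
    "race": {
        "AB_sum": (2.0, 4.5), "AB_share": (0.4, 0.6),
        "wX": (0.2, 0.8), "t0": (0.2, 0.5), "st0": (0.05, 0.3),
        "d_first": (0.2, 1.0), "d_step": (0.1, 0.8),
    },
    "mtlnr": {
        "mu_d1": (0.0, 0.8), "mu_d2": (0.0, 0.8),
        "s1": (0.4, 1.0), "s2": (0.4, 1.0), "rho": (-0.5, 0.5),
        "sigma_d1": (0.1, 0.5), "sigma_d2": (0.1, 0.5), "rho_d": (-0.5, 0.5),
        "t0": (0.2, 0.5), "st0": (0.05, 0.3),
        "d_first": (0.2, 0.8), "d_step": (0.1, 0.6),
    },
}


@dataclass
class ParameterSampler:
    model: str
    L: int = 3
    K: int = 3
    ranges: dict = field(default_factory=dict)
    rating_concentration: float = 4.0
    min_rating_mass: float = 0.05
    seed: int = 0

    def __post_init__(self):
        fam = family(self.model)
        merged = dict(DEFAULT_RANGES[fam])
        merged.update(self.ranges)
        self.ranges = merged
        lo, hi = self.ranges.get("sz_frac", (0.0, 0.0))
        if not (0 <= lo <= hi <= 1):
            raise ValueError("sz_frac range must lie within [0, 1] "
                             "(admissible region would be empty)")


def _uniform(rng, rang):
    return rng.uniform(rang[0], rang[1])


def sample_parameters(sampler: ParameterSampler, n_sets):
    """Draw ``n_sets`` generating parameter rows (flat fit-row layout)."""
    rng = np.random.default_rng(sampler.seed)
    rows = []
    for _ in range(n_sets):
        rows.append(_sample_one(sampler, rng))
    return rows


def _sample_one(sampler, rng):
    model = sampler.model
    fam = family(model)
    r = sampler.ranges
    row = {"model": model}
    d = _uniform(rng, r["d_first"])
    for l in range(1, sampler.L + 1):
        row[f"d_{l}"] = d
        d += _uniform(rng, r["d_step"])
    base = base_parameters(model)
    if fam == "ddm":
        row["z"] = _uniform(rng, r["z"])
        width = 2 * min(row["z"], 1 - row["z"])
        row["sz"] = _uniform(rng, r["sz_frac"]) * width * 0.98
        for name in ("a", "snu", "tau", "sV", "sigmaV", "w", "lam"):
            if name in base:
                row[name] = _uniform(rng, r[name])
    elif fam == "race":
        tot = _uniform(rng, r["AB_sum"])
        share = _uniform(rng, r["AB_share"])
        row["A"] = tot * share
        row["B"] = tot * (1 - share)
        if model.endswith("t"):
            # sequential simplex draw
            row["wX"] = _uniform(rng, r["wX"])
            row["wRT"] = rng.uniform(0, 1 - row["wX"])
    else:
        for name in ("mu_d1", "mu_d2", "s1", "s2", "rho"):
            row[name] = _uniform(rng, r[name])
        if model == "MTLNRfull":
            for name in ("sigma_d1", "sigma_d2", "rho_d"):
                row[name] = _uniform(rng, r[name])
    row["t0"] = _uniform(rng, r["t0"])
    row["st0"] = _uniform(rng, r["st0"])
    _attach_thresholds(row, sampler, rng)
    return row


def _attach_thresholds(row, sampler, rng):
    """Thresholds at confidence-variable quantiles matching a sampled rating
    proportion simplex (every category keeps mass)."""
    K = sampler.K
    while True:
        props = rng.dirichlet(np.full(K, sampler.rating_concentration))
        if props.min() >= sampler.min_rating_mass:
            break
    tmp = dict(row)
    sim = simulate_fit_row(tmp, n=200, seed=int(rng.integers(1 << 31)),
                           delta=0.005)
    ok = sim[sim["response"] != 0]
    cum = np.cumsum(props)[:-1]
    for sign, tag in ((1, "theta_plus_"), (-1, "theta_minus_")):
        conf = ok.loc[ok["response"] == sign, "conf_value"].to_numpy()
        if len(conf) < 20:
            conf = ok["conf_value"].to_numpy()
        vals = np.quantile(conf, cum)
        vals = np.maximum.accumulate(vals + np.arange(K - 1) * 1e-6)
        for k, v in enumerate(vals, start=1):
            row[f"{tag}{k}"] = float(v)
    return row


def _simulated_table(row, trials_per_cell, K, seed, simult_conf=False):
    sim = simulate_fit_row(row, n=trials_per_cell, seed=seed,
                           simult_conf=simult_conf)
    ok = sim[sim["response"] != 0].reset_index(drop=True)
    df = ok[["stimulus", "condition", "response", "rt", "rating"]].copy()
    df["subject"] = 0
    df["correct"] = (df["stimulus"] == df["response"]).astype(int)
    used = {s: set(df.loc[df["response"] == s, "rating"]) for s in (1, -1)}
    levels = sorted(df["condition"].unique())
    return TrialTable(df=df, scale=RatingScaleInfo(K, used),
                      condition_levels=levels)


def ccc(x, y):
    """Lin's concordance correlation coefficient (population moments):
    ``2 cov(x, y) / (var x + var y + (mean x - mean y)^2)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must have equal length >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return np.nan
    return 2.0 * cov / denom


@dataclass
class RecoveryReport:
    ccc: pd.DataFrame | None = None
    generated: pd.DataFrame | None = None
    recovered: pd.DataFrame | None = None
    misclassification: pd.DataFrame | None = None
    classification: pd.DataFrame | None = None
    precision_errors: pd.DataFrame | None = None
    runtimes: pd.DataFrame | None = None


def run_parameter_recovery(model, n_sets=10, trials_per_cell=100, L=3, K=3,
                           fit_opts=None, seed=0, simult_conf=False,
                           ranges=None):
    """Simulate -> refit -> per-parameter CCC between generating and
    recovered values across sets."""
    sampler = ParameterSampler(model=model, L=L, K=K, seed=seed,
                               ranges=ranges or {})
    rows = sample_parameters(sampler, n_sets)
    gen, rec, times = [], [], []
    for i, row in enumerate(rows):
        trials = _simulated_table(row, trials_per_cell, K, seed=seed + 31 * i,
                                  simult_conf=simult_conf)
        spec = FitSpec(model=model, n_ratings=K, simult_conf=simult_conf,
                       opts=dict(fit_opts or {}))
        t1 = time.time()
        fit = fit_model(trials, spec, seed=seed + 17 * i, subject=i)
        times.append(time.time() - t1)
        gen.append(row)
        rec.append(fit)
    gen_df = pd.DataFrame(gen)
    rec_df = pd.DataFrame(rec)
    names = [c for c in gen_df.columns
             if c != "model" and c in rec_df.columns
             and np.isfinite(gen_df[c]).all() and np.isfinite(rec_df[c]).all()]
    ccc_rows = [{"parameter": c, "ccc": ccc(gen_df[c], rec_df[c])}
                for c in names]
    return RecoveryReport(
        ccc=pd.DataFrame(ccc_rows), generated=gen_df, recovered=rec_df,
        runtimes=pd.DataFrame({"set": range(n_sets), "seconds": times}))


def run_model_recovery(generators, candidates=None, n_sets=10,
                       trials_per_cell=100, L=3, K=3, fit_opts=None, seed=0):
    """Simulate from each generator, fit all candidate models, classify each
    dataset by minimum BIC / AIC / AICc; returns the misclassification
    matrix (rows: generators; columns: classified models)."""
    candidates = list(candidates or generators)
    cls_rows = []
    times = []
    for gi, gmodel in enumerate(generators):
        sampler = ParameterSampler(model=gmodel, L=L, K=K, seed=seed + 101 * gi)
        rows = sample_parameters(sampler, n_sets)
        for i, row in enumerate(rows):
            trials = _simulated_table(row, trials_per_cell, K,
                                      seed=seed + 977 * gi + 31 * i)
            ics = {}
            for model in candidates:
                spec = FitSpec(model=model, n_ratings=K,
                               opts=dict(fit_opts or {}))
                t1 = time.time()
                fit = fit_model(trials, spec, seed=seed + 13 * i + gi,
                                subject=i)
                times.append({"generator": gmodel, "model": model,
                              "seconds": time.time() - t1})
                ics[model] = fit
            rec = {"generator": gmodel, "set": i}
            for crit in ("BIC", "AIC", "AICc"):
                rec[f"best_{crit}"] = min(candidates,
                                          key=lambda m: ics[m][crit])
            cls_rows.append(rec)
    cls = pd.DataFrame(cls_rows)
    mis = (cls.groupby("generator")["best_BIC"].value_counts().unstack()
           .reindex(index=generators, columns=candidates).fillna(0).astype(int))
    return RecoveryReport(classification=cls, misclassification=mis,
                          runtimes=pd.DataFrame(times))


def run_precision_benchmark(model, n_sets=10, trials_per_set=600,
                            precision_values=(2, 3, 4, 5, 6),
                            reference_precision=9.0, L=3, K=3, seed=0,
                            ranges=None):
    """Mean absolute difference of per-trial densities against a
    reference-precision computation, plus consecutive-precision differences
    and timings."""
    sampler = ParameterSampler(model=model, L=L, K=K, seed=seed,
                               ranges=ranges or {})
    rows = sample_parameters(sampler, n_sets)
    n_cell = max(1, trials_per_set // (2 * L))
    recs = []
    for i, row in enumerate(rows):
        trials = _simulated_table(row, n_cell, K, seed=seed + 31 * i)
        dens = {}
        for p in list(precision_values) + [reference_precision]:
            spec = FitSpec(model=model, n_ratings=K,
                           opts={"precision": float(p)})
            t1 = time.time()
            dens[p] = trial_densities(row, trials, spec)
            dt = time.time() - t1
            recs.append({"set": i, "precision": float(p), "seconds": dt,
                         "mean_abs_error": np.nan, "mean_abs_step": np.nan})
        ref = dens[reference_precision]
        for j, p in enumerate(precision_values):
            err = float(np.mean(np.abs(dens[p] - ref)))
            step = (float(np.mean(np.abs(dens[p] - dens[precision_values[j + 1]])))
                    if j + 1 < len(precision_values) else np.nan)
            for r in recs:
                if r["set"] == i and r["precision"] == float(p):
                    r["mean_abs_error"] = err
                    r["mean_abs_step"] = step
    tab = pd.DataFrame(recs)
    return RecoveryReport(precision_errors=tab)
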