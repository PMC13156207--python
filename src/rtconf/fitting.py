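"""Maximum-likelihood fitting of all models to per-subject trial data.

Workflow per subject x model: a data-anchored coarse search over parameter
space (thresholds set by quantile-matching the observed rating proportions
on a small simulated sample of the internal confidence variable), followed
by restarted bounded simplex optimization in a transformed, unconstrained
space.  Output rows carry the fitted parameters, trial count, number of
free parameters, the negative log-likelihood, and AIC / AICc / BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.optimize import minimize
from scipy.stats import norm, qmc

from . import _kernels as _k
from ._precision import FIT_PRECISION
from .ddm import nll_dynavite
from .mtlnr import nll_mtlnr
from .models import (MODELS, base_parameters, count_free_parameters, family,
                     map_parameters, response_to_winner)
from .params import ConfidenceThresholds, DynaViTEParams, MTLNRParams, RaceParams
from .race import nll_race
from .simulate import rate_ratings
from .trial_data import TrialTable, split_by_subject

__all__ = ["FitSpec", "fit_model", "fit_models", "negative_log_likelihood",
           "initial_grid", "count_free_parameters", "map_parameters",
           "information_criteria"]

ZERO_DENSITY_PENALTY = math.log(1e300)
MIN_THRESH_STEP = 1e-6


@dataclass
class FitSpec:
    """Configuration of one fitting problem."""

    model: str
    fixed: dict = field(default_factory=dict)
    n_ratings: int | None = None
    simult_conf: bool = False
    restr_tau: object = None  # None | "simult_conf" | float bound
    opts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in MODELS and self.model != "MTLNRfull":
            raise ValueError(
                f"unknown model {self.model!r}; supported: {', '.join(MODELS)}")
        # defaults: ~12k-candidate coarse search, 5 starts x 5 restarts of
        # the simplex with 5000 evaluations per call, precision 3
        o = dict(grid_size=12000, n_starts=5, n_restarts=5, max_evals=5000,
                 precision=FIT_PRECISION)
        o.update(self.opts)
        self.opts = o
        if o["n_starts"] < 1 or o["n_restarts"] < 1:
            raise ValueError("n_starts and n_restarts must be >= 1")
        base = set(base_parameters(self.model))
        for name in self.fixed:
            if name == "sym_thetas":
                continue
            if name not in base and not name.startswith("d_"):
                raise ValueError(
                    f"fixed parameter {name!r} does not belong to "
                    f"model {self.model}")

    @property
    def sym_thetas(self):
        return bool(self.fixed.get("sym_thetas", False))


# ---------------------------------------------------------------------------
# design: per-trial arrays prepared once
# ---------------------------------------------------------------------------

class _Design:
    def __init__(self, trials: TrialTable, spec: FitSpec):
        df = trials.df
        self.rt = df["rt"].to_numpy(float)
        self.resp = df["response"].to_numpy(int)
        self.stim = df["stimulus"].to_numpy(int)
        self.rating = df["rating"].to_numpy(int)
        self.cond = df["condition"].to_numpy(int)
        self.L = trials.n_conditions
        self.K = int(spec.n_ratings or trials.n_ratings)
        if self.K < 2:
            raise ValueError("need at least 2 rating categories")
        if self.rating.max() > self.K:
            raise ValueError("observed ratings exceed n_ratings")
        self.n = len(self.rt)
        self.min_rt = float(self.rt.min())
        self.used = {s: sorted(set(self.rating[self.resp == s]) or {1})
                     for s in (1, -1)}
        if spec.sym_thetas:
            both = sorted(set(self.used[1]) | set(self.used[-1]))
            self.used = {1: both, -1: both}
        # accuracy per condition for drift anchors
        self.acc = np.array([
            (self.stim[self.cond == l] == self.resp[self.cond == l]).mean()
            if (self.cond == l).any() else 0.5
            for l in range(1, self.L + 1)])
        self.rating_props = {
            s: np.bincount(self.rating[self.resp == s], minlength=self.K + 1)[1:]
            for s in (1, -1)}


# ---------------------------------------------------------------------------
# parameter codec: dict <-> unconstrained vector
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = min(max(p, 1e-12), 1 - 1e-12)
    return math.log(p / (1 - p))


class _Codec:
    """Bijective map between the free parameters of a fit configuration and
    an unconstrained real vector.

    log for strictly positive parameters, logistic for (0,1) parameters
    (the start range is a logistic fraction of its admissible width given
    z), stick-breaking for the confidence weights, tanh for correlations,
    and first-value + log-increments for the ordered thresholds.
    """

    def __init__(self, spec: FitSpec, design: _Design):
        self.spec = spec
        self.d = design
        self.model = spec.model
        self.fam = family(self.model)
        base = [p for p in base_parameters(self.model) if p not in spec.fixed]
        if spec.restr_tau is not None and "tau" in base:
            self.tau_bound = (max(design.min_rt, 1e-3)
                              if spec.restr_tau == "simult_conf"
                              else float(spec.restr_tau))
        else:
            self.tau_bound = None
        self.base = base
        self.dnames = [f"d_{l}" for l in range(1, design.L + 1)
                       if f"d_{l}" not in spec.fixed]
        # free thresholds: one per boundary between consecutive used
        # categories, per response sign (shared when symmetric)
        signs = (1,) if spec.sym_thetas else (1, -1)
        self.th_free = {s: max(0, len(design.used[s]) - 1) for s in signs}
        self.names = (list(base) + self.dnames
                      + [f"_th{s}_{i}" for s in signs
                         for i in range(self.th_free[s])])

    # -- scalar transforms ---------------------------------------------------

    def _fwd(self, name, value, partial):
        d = self.d
        if name in ("a", "A", "B", "sV", "sigmaV", "snu", "st0", "lam",
                    "s1", "s2", "sigma_d1", "sigma_d2"):
            return math.log(max(value, 1e-10))
        if name == "tau":
            if self.tau_bound is not None:
                return _logit(value / self.tau_bound)
            return math.log(max(value, 1e-10))
        if name == "t0":
            return _logit(value / (d.min_rt * 0.999 + 1e-12))
        if name in ("z", "w", "wX"):
            return _logit(value)
        if name == "wRT":
            rest = 1.0 - partial.get("wX", 0.0)
            return _logit(value / max(rest, 1e-12))
        if name == "sz":
            z = partial.get("z", 0.5)
            width = 2 * min(z, 1 - z) * (1 - 1e-9)
            return _logit(value / max(width, 1e-12))
        if name in ("rho", "rho_d"):
            return math.atanh(min(max(value, -1 + 1e-9), 1 - 1e-9))
        return float(value)  # identity: mu_d*, d_l

    def _bwd(self, name, x, partial):
        d = self.d
        if name in ("a", "A", "B", "sV", "sigmaV", "snu", "st0", "lam",
                    "s1", "s2", "sigma_d1", "sigma_d2"):
            return math.exp(min(x, 50.0))
        if name == "tau":
            if self.tau_bound is not None:
                return _sigmoid(x) * self.tau_bound
            return math.exp(min(x, 50.0))
        if name == "t0":
            return _sigmoid(x) * d.min_rt * 0.999
        if name in ("z", "w", "wX"):
            return _sigmoid(x)
        if name == "wRT":
            rest = 1.0 - partial.get("wX", 0.0)
            return _sigmoid(x) * rest
        if name == "sz":
            z = partial.get("z", 0.5)
            return _sigmoid(x) * 2 * min(z, 1 - z) * (1 - 1e-9)
        if name in ("rho", "rho_d"):
            return math.tanh(x)
        return float(x)

    # -- vector <-> dict -----------------------------------------------------

    def encode(self, params: dict):
        x = []
        partial = {}
        for name in self.base + self.dnames:
            partial[name] = params[name]
            x.append(self._fwd(name, params[name], partial))
        signs = (1,) if self.spec.sym_thetas else (1, -1)
        for s in signs:
            th = np.asarray(params["_thfree"][s], dtype=float)
            for i, v in enumerate(th):
                if i == 0:
                    x.append(math.log(max(v, 1e-10)) if self.fam != "ddm"
                             else v)
                else:
                    x.append(math.log(
                        max(v - th[i - 1] - MIN_THRESH_STEP, 1e-12)))
        return np.array(x)

    def decode(self, x):
        params = {}
        i = 0
        for name in self.base + self.dnames:
            params[name] = self._bwd(name, x[i], params)
            i += 1
        for name, v in self.spec.fixed.items():
            if name != "sym_thetas":
                params[name] = float(v)
        thfree = {}
        signs = (1,) if self.spec.sym_thetas else (1, -1)
        for s in signs:
            m = self.th_free[s]
            vals = np.empty(m)
            for j in range(m):
                if j == 0:
                    vals[0] = (math.exp(min(x[i], 50.0))
                               if self.fam != "ddm" else x[i])
                else:
                    vals[j] = vals[j - 1] + MIN_THRESH_STEP + math.exp(min(x[i], 50.0))
                i += 1
            thfree[s] = vals
        if self.spec.sym_thetas:
            thfree[-1] = thfree[1]
        params["_thfree"] = thfree
        return params

    # -- expansion to full sentinel thresholds -------------------------------

    def full_thresholds(self, thfree):
        """Expand free threshold values to the K-1 per-sign vectors, placing
        sentinels for unused extreme categories and coincident thresholds
        for unused interior categories."""
        d = self.d
        out = {}
        for s in (1, -1):
            used = d.used[s]
            vals = thfree[s if not self.spec.sym_thetas else 1]
            th = np.empty(d.K - 1)
            th[:] = np.nan
            for k in range(1, used[0]):
                th[k - 1] = -np.inf
            for k in range(used[-1], d.K):
                th[k - 1] = np.inf
            for i in range(len(used) - 1):
                for k in range(used[i], used[i + 1]):
                    th[k - 1] = vals[i]
            out[s] = th
        return out


# ---------------------------------------------------------------------------
# negative log-likelihood
# ---------------------------------------------------------------------------

def _structural(params, model, fixed):
    """Parameter objects for each family from a flat fitted-parameter dict."""
    get = lambda n, dflt=0.0: float(params.get(n, dflt))
    fam = family(model)
    if fam == "ddm":
        lam = get("lam") if model == "dynaViTE" else (
            0.5 if model == "DDConf" else 0.0)
        w = get("w", 1.0) if model in ("dynaViTE", "dynWEV") else 1.0
        return DynaViTEParams(
            a=get("a", 1.0), z=get("z", 0.5), sz=get("sz"), snu=get("snu"),
            s=get("s", 1.0), tau=get("tau") if model != "DDConf" else 0.0,
            sV=get("sV", 1.0), sigmaV=get("sigmaV"), w=w, lam=lam,
            t0=get("t0"), st0=get("st0"))
    if fam == "race":
        rho = -0.5 if model.startswith("PCRM") else 0.0
        if model.endswith("t"):
            wX, wRT = get("wX", 1.0), get("wRT", 0.0)
            wInt = max(0.0, 1.0 - wX - wRT)
        else:
            wX, wRT, wInt = 1.0, 0.0, 0.0
        return RaceParams(A=get("A", 1.0), B=get("B", 1.0),
                          s1=get("s1", 1.0), s2=get("s2", 1.0), rho=rho,
                          wX=wX, wRT=wRT, wInt=wInt,
                          t0=get("t0"), st0=get("st0"))
    return MTLNRParams(
        mu_d1=get("mu_d1"), mu_d2=get("mu_d2"),
        sigma_d1=get("sigma_d1"), sigma_d2=get("sigma_d2"),
        rho_d=get("rho_d"),
        sigma_v1=get("s1", 1.0), sigma_v2=get("s2", 1.0), rho_v=get("rho"),
        t0=get("t0"), st0=get("st0"))


def _trial_arrays(design, params, model, thresholds):
    """Per-trial drift arrays and threshold intervals."""
    d = design
    dvec = np.array([float(params.get(f"d_{l}", 0.0))
                     for l in range(1, d.L + 1)])
    dd = dvec[d.cond - 1]
    full = {s: np.concatenate(([-np.inf], thresholds[s], [np.inf]))
            for s in (1, -1)}
    th1 = np.where(d.resp == 1, full[1][d.rating - 1], full[-1][d.rating - 1])
    th2 = np.where(d.resp == 1, full[1][d.rating], full[-1][d.rating])
    fam = family(model)
    if fam == "ddm":
        return dd * d.stim, np.abs(dd), th1, th2
    if fam == "race":
        mu1 = dd * d.stim
        return mu1, -mu1, np.clip(th1, 0, None), np.clip(th2, 0, None)
    mu_v1 = np.where(d.stim == 1, dd, 0.0)
    mu_v2 = np.where(d.stim == 1, 0.0, dd)
    return mu_v1, mu_v2, np.clip(th1, 0, None), np.clip(th2, 0, None)


class _Objective:
    def __init__(self, trials, spec):
        self.spec = spec
        self.design = _Design(trials, spec)
        self.codec = _Codec(spec, self.design)
        self.n_zero_last = 0

    def nll_params(self, params):
        d = self.design
        spec = self.spec
        thr = self.codec.full_thresholds(params["_thfree"])
        try:
            struct = _structural(params, spec.model, spec.fixed).validate()
        except ValueError:
            return ZERO_DENSITY_PENALTY * d.n
        a1, a2, th1, th2 = _trial_arrays(d, params, spec.model, thr)
        fam = family(spec.model)
        prec = spec.opts["precision"]
        if fam == "ddm":
            nll, nz = nll_dynavite(d.rt, d.resp, th1, th2, a1, a2, struct,
                                   prec, spec.simult_conf)
        elif fam == "race":
            winner = np.where(d.resp == 1, 1, 2)
            nll, nz = nll_race(d.rt, winner, th1, th2, a1, a2, struct, prec,
                               time_dependent=spec.model.endswith("t"))
        else:
            winner = np.where(d.resp == 1, 1, 2)
            nll, nz = nll_mtlnr(d.rt, winner, th1, th2, a1, a2, struct, prec)
        self.n_zero_last = nz
        if not np.isfinite(nll):
            return ZERO_DENSITY_PENALTY * d.n
        return nll

    def nll_vector(self, x):
        return self.nll_params(self.codec.decode(x))


def negative_log_likelihood(params, trials: TrialTable, spec: FitSpec):
    """Negative log-likelihood of a flat parameter dict (structural
    parameters, ``d_l`` entries, and thresholds ``theta_plus_k`` /
    ``theta_minus_k``) for a trial table.  The thresholds are used exactly
    as given; zero-density trials contribute a large finite penalty."""
    dens = trial_densities(params, trials, spec)
    zero = dens <= 0.0
    return float(-np.log(dens[~zero]).sum()
                 + ZERO_DENSITY_PENALTY * zero.sum())


def trial_densities(params, trials: TrialTable, spec: FitSpec):
    """Per-trial joint density values for a flat parameter dict (same layout
    as a fitted row) at the configuration's precision."""
    obj = _Objective(trials, spec)
    d = obj.design
    p = dict(params)
    thr = _row_thresholds(p, d.K)
    a1, a2, th1, th2 = _trial_arrays(d, p, spec.model, thr)
    struct = _structural(p, spec.model, spec.fixed).validate()
    fam = family(spec.model)
    prec = spec.opts["precision"]
    out = np.empty(d.n)
    from ._precision import (KAPPA_DDM_T0, KAPPA_DDM_Z, KAPPA_MTLNR_T0,
                             KAPPA_RACE_T0, n_steps, series_eps)
    if fam == "ddm":
        nz = n_steps(struct.sz, prec, KAPPA_DDM_Z)
        nt = n_steps(struct.st0, prec, KAPPA_DDM_T0)
        _k.dynavite_density_batch(
            d.rt, d.resp.astype(np.int64), th1, th2, a1, a2,
            struct.a, struct.z, struct.sz, struct.snu, struct.s, struct.tau,
            struct.sV, struct.sigmaV, struct.w, struct.lam, struct.t0,
            struct.st0, spec.simult_conf, nz, nt, series_eps(prec), out)
    elif fam == "race":
        winner = np.where(d.resp == 1, 1, 2).astype(np.int64)
        nt = n_steps(struct.st0, prec, KAPPA_RACE_T0)
        _k.race_density_batch(
            d.rt, winner, th1, th2, a1, a2, struct.A, struct.B, struct.s1,
            struct.s2, struct.rho, struct.wX, struct.wRT, struct.wInt,
            struct.t0, struct.st0, spec.model.endswith("t"), nt, out)
    else:
        winner = np.where(d.resp == 1, 1, 2).astype(np.int64)
        nt = n_steps(struct.st0, prec, KAPPA_MTLNR_T0)
        _k.mtlnr_density_batch(
            d.rt, winner, th1, th2, a1, a2, struct.mu_d1, struct.mu_d2,
            struct.sigma_d1, struct.sigma_d2, struct.rho_d, struct.sigma_v1,
            struct.sigma_v2, struct.rho_v, struct.t0, struct.st0, nt, out)
    return out


def _row_thresholds(params, K):
    out = {}
    for s, tag in ((1, "theta_plus_"), (-1, "theta_minus_")):
        th = np.array([float(params.get(f"{tag}{k}", np.nan))
                       for k in range(1, K)])
        if np.isnan(th).all() and s == -1:
            th = out[1]
        out[s] = th
    return out


def _free_from_full(thr, design, spec):
    thfree = {}
    for s in ((1,) if spec.sym_thetas else (1, -1)):
        used = design.used[s]
        vals = [thr[s][k - 1] for k in used[:-1]]
        thfree[s] = np.array(vals, dtype=float)
    if spec.sym_thetas:
        thfree[-1] = thfree[1]
    return thfree


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def _anchor_thresholds(obj: _Objective, params, seed):
    """Thresholds from quantile-matching the observed rating proportions on
    a small simulated sample of the internal confidence variable."""
    d = obj.design
    spec = obj.spec
    fam = family(spec.model)
    struct = _structural(params, spec.model, spec.fixed)
    nsim = 240
    dmid = float(np.median([params.get(f"d_{l}", 0.5)
                            for l in range(1, d.L + 1)]))
    if fam == "ddm":
        mapped = map_parameters(spec.model, 1, dmid)
        p = struct.replace(nu=mapped["nu"], muV=mapped["muV"])
        resp, rt, conf = _k.simulate_dynavite_k(
            nsim, p.a, p.z, p.sz, p.nu, p.snu, p.s, p.tau, p.muV, p.sV,
            p.sigmaV, p.w, p.lam, p.t0, p.st0, 0.005, 12.0,
            spec.simult_conf, seed)
    elif fam == "race":
        mapped = map_parameters(spec.model, 1, dmid)
        p = struct.replace(mu1=mapped["mu1"], mu2=mapped["mu2"])
        resp, rt, conf = _k.simulate_race_k(
            nsim, p.A, p.B, p.mu1, p.mu2, p.s1, p.s2, p.rho, p.wX, p.wRT,
            p.wInt, p.t0, p.st0, 0.005, 12.0, seed)
    else:
        mapped = map_parameters(spec.model, 1, dmid)
        p = struct.replace(mu_v1=mapped["mu_v1"], mu_v2=mapped["mu_v2"])
        rng = np.random.default_rng(seed)
        l1 = rng.normal(p.mu_d1 - p.mu_v1, math.sqrt(p.sigma_d1 ** 2 + p.sigma_v1 ** 2), nsim)
        l2 = rng.normal(p.mu_d2 - p.mu_v2, math.sqrt(p.sigma_d2 ** 2 + p.sigma_v2 ** 2), nsim)
        conf = np.abs(l2 - l1)
    conf = conf[np.isfinite(conf)]
    if len(conf) < 10:
        conf = np.linspace(0.1, 2.0, 20)
    thfree = {}
    for s in ((1,) if spec.sym_thetas else (1, -1)):
        props = d.rating_props[s].astype(float)
        if spec.sym_thetas:
            props = props + d.rating_props[-1]
        if props.sum() == 0:
            props = np.ones(d.K)
        props = props / props.sum()
        used = d.used[s]
        cum = np.cumsum([props[k - 1] for k in used[:-1]])
        # cumulative proportion within used categories
        tot = sum(props[k - 1] for k in used)
        cum = np.clip(cum / max(tot, 1e-9), 0.02, 0.98)
        vals = np.quantile(conf, cum)
        vals = np.maximum.accumulate(vals + np.arange(len(vals)) * MIN_THRESH_STEP)
        thfree[s] = vals
    if spec.sym_thetas:
        thfree[-1] = thfree[1]
    return thfree


def _structural_ranges(spec, design):
    """Broad data-anchored ranges of the structural parameters, sampled by a
    scrambled low-discrepancy sequence in the coarse search."""
    mr = design.min_rt
    fam = family(spec.model)
    r = {}
    if fam == "ddm":
        r = {"a": (0.6, 3.2), "z": (0.35, 0.65), "sz": (0.0, 0.5),
             "snu": (0.05, 1.2), "tau": (0.1, 2.2), "sV": (0.3, 2.5),
             "sigmaV": (0.05, 1.2), "w": (0.2, 0.9), "lam": (0.0, 1.5)}
        if spec.restr_tau is not None:
            bound = (mr if spec.restr_tau == "simult_conf"
                     else float(spec.restr_tau))
            r["tau"] = (0.05 * bound, 0.9 * bound)
    elif fam == "race":
        r = {"A": (0.5, 3.0), "B": (0.5, 3.0), "wX": (0.1, 0.9),
             "wRT": (0.05, 0.8)}
    else:
        r = {"mu_d1": (-0.8, 1.2), "mu_d2": (-0.8, 1.2),
             "s1": (0.2, 1.5), "s2": (0.2, 1.5), "rho": (-0.6, 0.6),
             "sigma_d1": (0.05, 0.8), "sigma_d2": (0.05, 0.8),
             "rho_d": (-0.6, 0.6)}
    r["t0"] = (0.15 * mr, 0.9 * mr)
    r["st0"] = (0.01, max(0.02, 0.8 * mr))
    return r


def initial_grid(trials: TrialTable, spec: FitSpec, seed=0):
    """Coarse search: evaluate the likelihood for a broad, deterministic
    (seeded low-discrepancy) set of parameter combinations with data-driven
    anchors; returns (nll, params) candidates ranked by negative
    log-likelihood."""
    obj = _Objective(trials, spec)
    return _initial_grid(obj, seed)


def _initial_grid(obj: _Objective, seed):
    spec = obj.spec
    design = obj.design
    ranges = _structural_ranges(spec, design)
    names = [p for p in obj.codec.base if p in ranges]
    ndim = max(1, len(names) + 1)  # +1 drift scale
    n_cand = int(spec.opts["grid_size"])
    sampler = qmc.Sobol(d=ndim, scramble=True, seed=seed)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        u = sampler.random(n_cand)
    # drift anchors from accuracy per condition
    zanchor = norm.ppf(np.clip(design.acc, 0.55, 0.995))
    cands = []
    for i in range(n_cand):
        params = {}
        for j, name in enumerate(names):
            lo, hi = ranges[name]
            params[name] = lo + (hi - lo) * u[i, j]
        if "sz" in params:
            z = params.get("z", spec.fixed.get("z", 0.5))
            params["sz"] = min(params["sz"], 1.8 * min(z, 1 - z))
        if "wRT" in params:
            wx = params.get("wX", spec.fixed.get("wX", 0.5))
            params["wRT"] = min(params["wRT"], 0.95 * (1 - wx))
        scale = 0.25 + 2.75 * u[i, -1]
        for l in range(1, design.L + 1):
            params[f"d_{l}"] = scale * zanchor[l - 1]
        for nm, v in spec.fixed.items():
            if nm != "sym_thetas":
                params[nm] = float(v)
        params["_thfree"] = _anchor_thresholds(obj, params, seed + i)
        nll = obj.nll_params(params)
        cands.append((nll, params))
    cands.sort(key=lambda t: t[0])
    return cands


# ---------------------------------------------------------------------------
# fitting driver
# ---------------------------------------------------------------------------

def information_criteria(nll, k, n):
    aic = 2.0 * nll + 2.0 * k
    bic = 2.0 * nll + k * math.log(n)
    aicc = aic + (2.0 * k * (k + 1) / (n - k - 1) if n > k + 1 else np.inf)
    return aic, aicc, bic


def fit_model(trials: TrialTable, spec: FitSpec, seed=0, subject=None):
    """Fit one model to one subject's trials; returns a flat result dict."""
    obj = _Objective(trials, spec)
    cands = _initial_grid(obj, seed)
    n_starts = min(spec.opts["n_starts"], len(cands))
    best_nll, best_x = cands[0][0], obj.codec.encode(cands[0][1])
    improved = False
    for s in range(n_starts):
        x = obj.codec.encode(cands[s][1])
        fx = cands[s][0]
        for _ in range(spec.opts["n_restarts"]):
            res = minimize(obj.nll_vector, x, method="Nelder-Mead",
                           options={"maxfev": spec.opts["max_evals"],
                                    "xatol": 1e-4, "fatol": 1e-6})
            if res.fun < fx - 1e-12:
                improved = True
            if res.fun < fx:
                fx, x = res.fun, res.x
        if fx < best_nll:
            best_nll, best_x = fx, x
    params = obj.codec.decode(best_x)
    return _result_row(obj, params, best_nll, subject=subject,
                       warn_no_improvement=not improved)


def _result_row(obj, params, nll, subject=None, warn_no_improvement=False):
    spec = obj.spec
    d = obj.design
    thr = obj.codec.full_thresholds(params["_thfree"])
    row = {"subject": subject, "model": spec.model}
    for name in base_parameters(spec.model):
        row[name] = float(params.get(name, spec.fixed.get(name, np.nan)))
    for l in range(1, d.L + 1):
        row[f"d_{l}"] = float(params.get(f"d_{l}",
                                         spec.fixed.get(f"d_{l}", np.nan)))
    for k in range(1, d.K):
        row[f"theta_plus_{k}"] = thr[1][k - 1]
        row[f"theta_minus_{k}"] = thr[-1][k - 1]
    # free-parameter count: nominal formula minus rating categories the
    # subject never used (their thresholds are set post hoc, not optimized)
    k_nominal = count_free_parameters(
        spec.model, d.L, d.K, fixed=spec.fixed, sym_thetas=spec.sym_thetas)
    signs = (1,) if spec.sym_thetas else (1, -1)
    n_th_nominal = (d.K - 1) * len(signs)
    n_th_free = sum(obj.codec.th_free[s] for s in signs)
    k_free = k_nominal - (n_th_nominal - n_th_free)
    obj.nll_params(params)  # refresh zero-density count at the optimum
    aic, aicc, bic = information_criteria(nll, k_free, d.n)
    row.update({"N": d.n, "k": k_free, "negLogLik": float(nll),
                "AIC": aic, "AICc": aicc, "BIC": bic,
                "fixed": ";".join(f"{k}={v}" for k, v in spec.fixed.items()),
                "n_zero_density": obj.n_zero_last,
                "status": ("no_improvement" if warn_no_improvement else "ok")})
    return row


def fit_models(trials: TrialTable, models, fixed=None, n_ratings=None,
               simult_conf=False, restr_tau=None, opts=None, n_jobs=1,
               seed=0):
    """Fit every model to every subject; one output row per combination.

    Parallelization over subject x model cells does not change results: each
    cell's seed is derived from its position.  Failed cells are recorded
    with a failure status and do not affect others.
    """
    groups = split_by_subject(trials)
    cells = []
    for si, (sid, sub) in enumerate(groups):
        for mi, model in enumerate(models):
            cells.append((sid, sub, model, seed + 1000003 * si + 7919 * mi))

    def run(cell):
        sid, sub, model, s = cell
        try:
            spec = FitSpec(model=model, fixed=dict(fixed or {}),
                           n_ratings=n_ratings, simult_conf=simult_conf,
                           restr_tau=restr_tau, opts=dict(opts or {}))
            return fit_model(sub, spec, seed=s, subject=sid)
        except Exception as exc:  # noqa: BLE001 - per-cell isolation
            return {"subject": sid, "model": model, "status": "failed",
                    "error": str(exc)}

    if n_jobs == 1:
        rows = [run(c) for c in cells]
    else:
        rows = Parallel(n_jobs=n_jobs)(delayed(run)(c) for c in cells)
    return pd.DataFrame(rows)
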