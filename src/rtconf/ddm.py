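"""Joint densities for the diffusion-based confidence family.

All densities return ``P(rt, response, c in [th1, th2])`` — the joint density
of response time and choice together with the probability that the internal
confidence variable falls in the given interval.  The special cases fix
parameters of the general model:

========  =======================================
dynWEV    ``lam = 0``
2DSD      ``lam = 0, w = 1`` (visibility ignored)
DDConf    ``w = 1, tau = 0, lam = 0.5``
========  =======================================
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels as _k
from ._precision import (DEFAULT_PRECISION, KAPPA_DDM_T0, KAPPA_DDM_Z,
                         check_precision, n_steps, series_eps)
from .params import DynaViTEParams

__all__ = [
    "fpt_density_ddm",
    "density_dynavite",
    "density_dynwev",
    "density_2dsd",
    "density_ddconf",
]


def fpt_density_ddm(t, response, a, z, sz=0.0, nu=0.0, snu=0.0, s=1.0,
                    precision=DEFAULT_PRECISION):
    """Defective first-passage density of the decision process at the boundary
    selected by ``response`` (+1 upper, -1 lower), marginal over the normal
    drift distribution and the uniform start range.

    ``t`` may be scalar or array; non-positive times yield 0.
    """
    precision = check_precision(precision)
    DynaViTEParams(a=a, z=z, sz=sz, nu=nu, snu=snu, s=s).validate()
    if response not in (-1, 1):
        raise ValueError("response must be -1 or +1")
    nz = n_steps(sz, precision, KAPPA_DDM_Z)
    eps = series_eps(precision)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        out[i] = _k.fpt_density_ddm_k(ti, response, a, z, sz, nu, snu, s,
                                      nz, eps)
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def _density(rt, response, th1, th2, p: DynaViTEParams, precision,
             simult_conf):
    precision = check_precision(precision)
    p.validate()
    if not (th1 <= th2):
        raise ValueError("th1 must not exceed th2")
    if response not in (-1, 1):
        raise ValueError("response must be -1 or +1")
    nz = n_steps(p.sz, precision, KAPPA_DDM_Z)
    nt = n_steps(p.st0, precision, KAPPA_DDM_T0)
    eps = series_eps(precision)
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    out = np.empty_like(rt_arr)
    for i, ri in enumerate(rt_arr):
        out[i] = _k.dynavite_density_point(
            ri, response, th1, th2, p.a, p.z, p.sz, p.nu, p.snu, p.s, p.tau,
            p.muV, p.sV, p.sigmaV, p.w, p.lam, p.t0, p.st0, simult_conf,
            nz, nt, eps)
    return out[0] if np.isscalar(rt) or np.asarray(rt).ndim == 0 else out


def density_dynavite(rt, response, th1, th2, params: DynaViTEParams,
                     precision=DEFAULT_PRECISION, simult_conf=False):
    """Joint density of the full model (post-decisional accumulation,
    visibility process, accumulation-time penalty).

    With ``simult_conf`` the observed response time includes the
    post-decisional accumulation period (``rt = T_dec + tau + T_nd``),
    otherwise ``rt = T_dec + T_nd``.
    """
    return _density(rt, response, th1, th2, params, precision, simult_conf)


def density_dynwev(rt, response, th1, th2, params: DynaViTEParams,
                   precision=DEFAULT_PRECISION, simult_conf=False):
    """Special case without the accumulation-time penalty (``lam = 0``)."""
    if params.lam != 0.0:
        params = params.replace(lam=0.0)
    return _density(rt, response, th1, th2, params, precision, simult_conf)


def density_2dsd(rt, response, th1, th2, params: DynaViTEParams,
                 precision=DEFAULT_PRECISION, simult_conf=False):
    """Special case with confidence driven by post-decisional decision
    evidence only (``lam = 0, w = 1``); visibility parameters are ignored."""
    if params.lam != 0.0 or params.w != 1.0:
        params = params.replace(lam=0.0, w=1.0)
    return _density(rt, response, th1, th2, params, precision, simult_conf)


def density_ddconf(rt, response, th1, th2, params: DynaViTEParams,
                   precision=DEFAULT_PRECISION, simult_conf=False):
    """Special case with confidence a decreasing function of decision time
    (``w = 1, tau = 0, lam = 0.5``).

    The confidence variable is ``R (X(T_dec) - a z) / sqrt(T_dec)``; because
    the process sits at a boundary at decision time this is a deterministic,
    strictly decreasing function of decision time, so the threshold interval
    maps to a decision-time window.
    """
    if params.tau != 0.0 or params.w != 1.0 or params.lam != 0.5:
        params = params.replace(tau=0.0, w=1.0, lam=0.5)
    return _density(rt, response, th1, th2, params, precision, simult_conf)


def nll_dynavite(rt, response, th1, th2, nu, muV, params: DynaViTEParams,
                 precision, simult_conf, penalty=math.log(1e300)):
    """Vectorized negative log-likelihood helper: per-trial drifts and
    threshold intervals, shared structural parameters.  Zero-density trials
    contribute ``penalty`` each; returns (nll, n_zero)."""
    p = params
    nz = n_steps(p.sz, precision, KAPPA_DDM_Z)
    nt = n_steps(p.st0, precision, KAPPA_DDM_T0)
    eps = series_eps(precision)
    out = np.empty(len(rt))
    _k.dynavite_density_batch(
        np.asarray(rt, float), np.asarray(response, np.int64),
        np.asarray(th1, float), np.asarray(th2, float),
        np.asarray(nu, float), np.asarray(muV, float),
        p.a, p.z, p.sz, p.snu, p.s, p.tau, p.sV, p.sigmaV, p.w, p.lam,
        p.t0, p.st0, simult_conf, nz, nt, eps, out)
    zero = out <= 0.0
    nll = -np.log(out[~zero]).sum() + penalty * zero.sum()
    return nll, int(zero.sum())
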