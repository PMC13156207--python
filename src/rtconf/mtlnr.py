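"""Joint density for the multiple-threshold log-normal race model.

Accumulation is ballistic: boundary-crossing times are ``T_i = D_i / V_i``
with log-normal boundary distances and rates, so ``(log T1, log T2)`` is
bivariate normal.  The internal confidence variable is the log of the ratio
of the losing to the winning crossing time (always positive).
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels as _k
from ._precision import (DEFAULT_PRECISION, KAPPA_MTLNR_T0, check_precision,
                         n_steps)
from .params import MTLNRParams

__all__ = ["density_mtlnr"]


def density_mtlnr(rt, response, th1, th2, params: MTLNRParams,
                  precision=DEFAULT_PRECISION):
    """Joint density P(rt, response, log(T_lose / T_win) in [th1, th2]);
    ``response`` is the winning accumulator (1 or 2), ``th1 >= 0``."""
    precision = check_precision(precision)
    params.validate()
    if th1 < 0:
        raise ValueError("th1 must be >= 0 (log time ratio is positive)")
    if not (th1 <= th2):
        raise ValueError("th1 must not exceed th2")
    if response not in (1, 2):
        raise ValueError("response must be 1 or 2")
    nt = n_steps(params.st0, precision, KAPPA_MTLNR_T0)
    p = params
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    out = np.empty_like(rt_arr)
    for i, ri in enumerate(rt_arr):
        out[i] = _k.mtlnr_density_point(
            ri, response, th1, th2, p.mu_d1, p.mu_d2, p.mu_v1, p.mu_v2,
            p.sigma_d1, p.sigma_d2, p.rho_d, p.sigma_v1, p.sigma_v2, p.rho_v,
            p.t0, p.st0, nt)
    return out[0] if np.isscalar(rt) or np.asarray(rt).ndim == 0 else out


def nll_mtlnr(rt, winner, th1, th2, mu_v1, mu_v2, params: MTLNRParams,
              precision, penalty=math.log(1e300)):
    """Vectorized negative log-likelihood helper with per-trial rate means."""
    p = params
    nt = n_steps(p.st0, precision, KAPPA_MTLNR_T0)
    out = np.empty(len(rt))
    _k.mtlnr_density_batch(
        np.asarray(rt, float), np.asarray(winner, np.int64),
        np.asarray(th1, float), np.asarray(th2, float),
        np.asarray(mu_v1, float), np.asarray(mu_v2, float),
        p.mu_d1, p.mu_d2, p.sigma_d1, p.sigma_d2, p.rho_d,
        p.sigma_v1, p.sigma_v2, p.rho_v, p.t0, p.st0, nt, out)
    zero = out <= 0.0
    nll = -np.log(out[~zero]).sum() + penalty * zero.sum()
    return nll, int(zero.sum())
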