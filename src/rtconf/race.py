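"""Joint densities for the two-accumulator Wiener race models.

Closed-form first-passage solutions exist for increment correlation 0
(independent race) and -0.5 (partially anti-correlated race); both are
obtained by the method of images.  The time-dependent confidence variable is
``c = wX * b + wRT / sqrt(t) + wInt * b / sqrt(t)`` with ``b`` the losing
accumulator's distance to its own threshold; the time-independent variants
use ``c = b`` (weights (1, 0, 0)).
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels as _k
from ._precision import (DEFAULT_PRECISION, KAPPA_RACE_T0, check_precision,
                         n_steps)
from .params import RaceParams

__all__ = ["fpt_density_race", "density_race"]


def fpt_density_race(t, winner, loser_gap, params: RaceParams):
    """Closed-form joint density of (decision time, winner, losing gap).

    ``winner`` is 1 or 2; ``loser_gap`` is the distance of the losing
    accumulator to its own threshold at decision time (>= 0).
    """
    params.validate()
    if winner not in (1, 2):
        raise ValueError("winner must be 1 or 2")
    if loser_gap < 0:
        raise ValueError("loser_gap must be >= 0")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        out[i] = _k.race_gap_density(ti, winner, loser_gap, params.A, params.B,
                                     params.mu1, params.mu2, params.s1,
                                     params.s2, params.rho)
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def density_race(rt, response, th1, th2, params: RaceParams,
                 time_dependent=None, precision=DEFAULT_PRECISION):
    """Joint density P(rt, response, c in [th1, th2]); ``response`` is the
    winning accumulator (1 or 2).

    The confidence interval maps to a gap interval in closed form (the
    confidence variable is increasing in the gap at fixed decision time;
    negative lower limits are clipped to 0), so only the non-decision window
    is integrated numerically.
    """
    precision = check_precision(precision)
    params.validate()
    if not (th1 <= th2):
        raise ValueError("th1 must not exceed th2")
    if response not in (1, 2):
        raise ValueError("response must be 1 or 2")
    if time_dependent is None:
        time_dependent = params.time_dependent
    nt = n_steps(params.st0, precision, KAPPA_RACE_T0)
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    out = np.empty_like(rt_arr)
    for i, ri in enumerate(rt_arr):
        out[i] = _k.race_density_point(
            ri, response, th1, th2, params.A, params.B, params.mu1, params.mu2,
            params.s1, params.s2, params.rho, params.wX, params.wRT,
            params.wInt, params.t0, params.st0, time_dependent, nt)
    return out[0] if np.isscalar(rt) or np.asarray(rt).ndim == 0 else out


def nll_race(rt, winner, th1, th2, mu1, mu2, params: RaceParams, precision,
             time_dependent=None, penalty=math.log(1e300)):
    """Vectorized negative log-likelihood helper with per-trial drifts."""
    p = params
    if time_dependent is None:
        time_dependent = p.time_dependent
    nt = n_steps(p.st0, precision, KAPPA_RACE_T0)
    out = np.empty(len(rt))
    _k.race_density_batch(
        np.asarray(rt, float), np.asarray(winner, np.int64),
        np.asarray(th1, float), np.asarray(th2, float),
        np.asarray(mu1, float), np.asarray(mu2, float),
        p.A, p.B, p.s1, p.s2, p.rho, p.wX, p.wRT, p.wInt, p.t0, p.st0,
        time_dependent, nt, out)
    zero = out <= 0.0
    nll = -np.log(out[~zero]).sum() + penalty * zero.sum()
    return nll, int(zero.sum())
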