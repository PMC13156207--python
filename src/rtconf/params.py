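"""Parameter containers for the three model families."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConfidenceThresholds",
    "DynaViTEParams",
    "RaceParams",
    "MTLNRParams",
]


class ConfidenceThresholds:
    """Response-conditional confidence thresholds.

    Holds one ascending vector of K-1 finite (or sentinel) thresholds per
    response sign.  ``interval(response, rating)`` returns the half-open
    interval for a rating, with -inf / +inf sentinels at the extremes.
    """

    def __init__(self, upper, lower=None):
        upper = np.asarray(upper, dtype=float)
        if lower is None:
            lower = upper
        lower = np.asarray(lower, dtype=float)
        if upper.ndim != 1 or lower.ndim != 1 or len(upper) != len(lower):
            raise ValueError("threshold vectors must be 1-d and equally long")
        for name, th in (("upper", upper), ("lower", lower)):
            if np.any(np.diff(th) < 0):
                raise ValueError(f"{name}-response thresholds must be non-decreasing")
        self._th = {1: upper, -1: lower}

    @property
    def n_ratings(self):
        return len(self._th[1]) + 1

    def __getitem__(self, response):
        return self._th[1 if response > 0 else -1]

    def interval(self, response, rating):
        th = self[response]
        k = int(rating)
        if not 1 <= k <= len(th) + 1:
            raise ValueError(f"rating {rating} outside 1..{len(th) + 1}")
        lo = -math.inf if k == 1 else th[k - 2]
        hi = math.inf if k == len(th) + 1 else th[k - 1]
        return lo, hi

    @property
    def symmetric(self):
        return np.array_equal(self._th[1], self._th[-1])

    def __repr__(self):
        return f"ConfidenceThresholds(upper={self._th[1]!r}, lower={self._th[-1]!r})"


def _check(cond, msg):
    if not cond:
        raise ValueError(msg)


@dataclass
class DynaViTEParams:
    """Parameters of the diffusion-based confidence family.

    ``w = 1`` disables the visibility process; ``lam = 0`` removes the
    accumulation-time penalty; ``tau = 0`` removes post-decisional
    accumulation.
    """

    a: float
    z: float = 0.5
    sz: float = 0.0
    nu: float = 0.0
    snu: float = 0.0
    s: float = 1.0
    tau: float = 0.0
    muV: float = 0.0
    sV: float = 1.0
    sigmaV: float = 0.0
    w: float = 1.0
    lam: float = 0.0
    t0: float = 0.0
    st0: float = 0.0
    theta: ConfidenceThresholds = field(
        default_factory=lambda: ConfidenceThresholds(np.array([])))

    def validate(self):
        _check(self.a > 0, "boundary separation a must be > 0")
        _check(0 < self.z < 1, "relative start z must lie in (0, 1)")
        _check(self.sz >= 0, "start range sz must be >= 0")
        _check(self.z - self.sz / 2 > 0 and self.z + self.sz / 2 < 1,
               "start distribution must stay inside the boundaries "
               "(z - sz/2 > 0 and z + sz/2 < 1)")
        _check(self.s > 0, "diffusion constant s must be > 0")
        _check(self.snu >= 0, "drift SD snu must be >= 0")
        _check(self.tau >= 0, "post-decisional time tau must be >= 0")
        _check(self.sV > 0, "visibility diffusion sV must be > 0")
        _check(self.sigmaV >= 0, "visibility drift SD sigmaV must be >= 0")
        _check(0 <= self.w <= 1, "evidence weight w must lie in [0, 1]")
        _check(self.lam >= 0, "time-penalty exponent lam must be >= 0")
        _check(self.t0 >= 0, "minimal non-decision time t0 must be >= 0")
        _check(self.st0 >= 0, "non-decision range st0 must be >= 0")
        return self

    def replace(self, **kw):
        return replace(self, **kw)


@dataclass
class RaceParams:
    """Parameters of the two-accumulator Wiener race models."""

    A: float
    B: float
    mu1: float = 0.0
    mu2: float = 0.0
    s1: float = 1.0
    s2: float = 1.0
    rho: float = 0.0
    wX: float = 1.0
    wRT: float = 0.0
    wInt: float = 0.0
    t0: float = 0.0
    st0: float = 0.0
    theta: ConfidenceThresholds = field(
        default_factory=lambda: ConfidenceThresholds(np.array([])))

    def validate(self):
        _check(self.A > 0 and self.B > 0, "thresholds A and B must be > 0")
        _check(self.s1 > 0 and self.s2 > 0, "diffusion constants must be > 0")
        _check(self.rho in (0.0, -0.5),
               "correlation rho restricted to 0 or -0.5")
        _check(self.wX >= 0 and self.wRT >= 0 and self.wInt >= 0,
               "confidence weights must be non-negative")
        _check(abs(self.wX + self.wRT + self.wInt - 1.0) < 1e-9,
               "confidence weights must sum to 1")
        _check(self.t0 >= 0 and self.st0 >= 0,
               "non-decision parameters must be >= 0")
        return self

    @property
    def time_dependent(self):
        return not (self.wX == 1.0 and self.wRT == 0.0 and self.wInt == 0.0)

    def replace(self, **kw):
        return replace(self, **kw)


@dataclass
class MTLNRParams:
    """Parameters of the multiple-threshold log-normal race model.

    Boundary distances and accumulation rates of the two accumulators are
    log-normal; boundary-crossing log-times are bivariate normal.
    """

    mu_d1: float = 0.0
    mu_d2: float = 0.0
    mu_v1: float = 0.0
    mu_v2: float = 0.0
    sigma_d1: float = 0.0
    sigma_d2: float = 0.0
    rho_d: float = 0.0
    sigma_v1: float = 1.0
    sigma_v2: float = 1.0
    rho_v: float = 0.0
    t0: float = 0.0
    st0: float = 0.0
    theta: ConfidenceThresholds = field(
        default_factory=lambda: ConfidenceThresholds(np.array([])))

    def validate(self):
        _check(self.sigma_d1 >= 0 and self.sigma_d2 >= 0,
               "boundary-distance SDs must be >= 0")
        _check(self.sigma_v1 >= 0 and self.sigma_v2 >= 0,
               "rate SDs must be >= 0")
        _check(-1 <= self.rho_d <= 1 and -1 <= self.rho_v <= 1,
               "correlations must lie in [-1, 1]")
        _check(self.t0 >= 0 and self.st0 >= 0,
               "non-decision parameters must be >= 0")
        v1 = self.sigma_d1 ** 2 + self.sigma_v1 ** 2
        _check(v1 > 0, "total variance of accumulator 1 log-time must be > 0")
        v2 = self.sigma_d2 ** 2 + self.sigma_v2 ** 2
        _check(v2 > 0, "total variance of accumulator 2 log-time must be > 0")
        cv = (self.sigma_d1 * self.sigma_d2 * self.rho_d
              + self.sigma_v1 * self.sigma_v2 * self.rho_v)
        _check(cv * cv <= v1 * v2 + 1e-12,
               "log-time covariance matrix must be positive semidefinite")
        return self

    def log_time_moments(self):
        """Mean vector and covariance matrix of (log T1, log T2)."""
        m = np.array([self.mu_d1 - self.mu_v1, self.mu_d2 - self.mu_v2])
        v1 = self.sigma_d1 ** 2 + self.sigma_v1 ** 2
        v2 = self.sigma_d2 ** 2 + self.sigma_v2 ** 2
        cv = (self.sigma_d1 * self.sigma_d2 * self.rho_d
              + self.sigma_v1 * self.sigma_v2 * self.rho_v)
        return m, np.array([[v1, cv], [cv, v2]])

    def replace(self, **kw):
        return replace(self, **kw)
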