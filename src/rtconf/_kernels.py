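"""Low-level numba kernels for the model densities.

Everything in here works on plain floats/arrays and is wrapped by the
user-facing modules (`ddm`, `race`, `mtlnr`), which handle validation and
the precision -> step-size mapping.
"""

import math

import numpy as np
from numba import njit

SQRT_2PI = math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Wiener first-passage time density (two absorbing boundaries)
# ---------------------------------------------------------------------------

@njit(cache=True)
def wfpt_series(tt, w, eps):
    """Normalized zero-drift density of first passage through the lower of two
    unit-separated boundaries at normalized time ``tt``, relative start ``w``.

    Switches between the small-time and large-time series representation,
    picking whichever needs fewer terms for truncation error <= ``eps``.
    """
    if tt <= 0.0:
        return 0.0
    # terms needed by the large-time representation
    if math.pi * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * eps) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    # terms needed by the small-time representation
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    f = 0.0
    if ks < kl:
        kmax = int(math.ceil(ks))
        lo = -((kmax - 1) // 2)
        hi = (kmax - 1) // 2 + (kmax - 1) % 2
        for k in range(lo, hi + 1):
            x = w + 2.0 * k
            f += x * math.exp(-x * x / (2.0 * tt))
        f /= math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:
        kmax = int(math.ceil(kl))
        for k in range(1, kmax + 1):
            f += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
        f *= math.pi
    if f < 0.0:
        f = 0.0
    return f


@njit(cache=True)
def fpt0(t, boundary, a, w, s, eps):
    """Zero-drift first-passage density at time ``t`` through the boundary
    selected by ``boundary`` (+1 upper, -1 lower); separation ``a``, relative
    start ``w``, diffusion constant ``s``."""
    if t <= 0.0:
        return 0.0
    an = a / s
    tt = t / (an * an)
    if boundary > 0:
        return wfpt_series(tt, 1.0 - w, eps) / (an * an)
    return wfpt_series(tt, w, eps) / (an * an)


@njit(cache=True)
def drift_marginal(t, boundary, a, w, s, nu, snu):
    """Marginalize the drift (Normal(nu, snu)) out of the first-passage event.

    Returns ``(factor, m, v2)``: the multiplicative correction to the
    zero-drift density, and the Gaussian posterior mean/variance of the drift
    given absorption at ``(t, boundary)``.  Uses the exponential change of
    measure: the drift enters the first-passage density only through
    ``exp(delta*mu/s^2 - mu^2 t/(2 s^2))`` with ``delta`` the signed distance
    from start to the absorbing boundary.
    """
    s2 = s * s
    if boundary > 0:
        delta = a * (1.0 - w)
    else:
        delta = -a * w
    A = t / (2.0 * s2)
    B = delta / s2
    if snu <= 0.0:
        return math.exp(B * nu - A * nu * nu), nu, 0.0
    eta2 = snu * snu
    P = A + 1.0 / (2.0 * eta2)
    Q = B + nu / eta2
    factor = math.exp(Q * Q / (4.0 * P) - nu * nu / (2.0 * eta2)) / math.sqrt(1.0 + 2.0 * A * eta2)
    m = Q / (2.0 * P)
    v2 = 1.0 / (2.0 * P)
    return factor, m, v2


@njit(cache=True)
def fpt_density_ddm_k(t, boundary, a, z, sz, nu, snu, s, nz, eps):
    """Defective first-passage density, marginal over drift and uniform start
    (midpoint rule with ``nz`` steps over the start range)."""
    if t <= 0.0:
        return 0.0
    if sz <= 0.0:
        f0 = fpt0(t, boundary, a, z, s, eps)
        fac, _, _ = drift_marginal(t, boundary, a, z, s, nu, snu)
        return f0 * fac
    acc = 0.0
    for i in range(nz):
        z0 = z - sz / 2.0 + sz * (i + 0.5) / nz
        f0 = fpt0(t, boundary, a, z0, s, eps)
        fac, _, _ = drift_marginal(t, boundary, a, z0, s, nu, snu)
        acc += f0 * fac
    return acc / nz


@njit(cache=True)
def norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _conf_prob_dynavite(tdec, boundary, m, v2, a, z, s, tau, muV, sV, sigmaV,
                        w, lam, th1, th2):
    """P(confidence variable in [th1, th2] | decision time, response).

    Conditional on the decision time and response the post-decisional decision
    evidence and the visibility evidence are Gaussian; the drift posterior
    (m, v2) inflates the evidence variance.
    """
    if boundary > 0:
        bnd = a
        R = 1.0
    else:
        bnd = 0.0
        R = -1.0
    ttot = tdec + tau
    mean_e = R * (bnd - a * z) + R * m * tau
    var_e = s * s * tau + v2 * tau * tau
    mean_c = w * mean_e
    var_c = w * w * var_e
    if w < 1.0:
        mean_v = muV * ttot
        var_v = sV * sV * ttot + sigmaV * sigmaV * ttot * ttot
        mean_c += (1.0 - w) * mean_v
        var_c += (1.0 - w) * (1.0 - w) * var_v
    denom = ttot ** lam if lam != 0.0 else 1.0
    mean_c /= denom
    sd_c = math.sqrt(var_c) / denom
    if sd_c <= 0.0:
        return 1.0 if (th1 <= mean_c <= th2) else 0.0
    p = norm_cdf((th2 - mean_c) / sd_c) - norm_cdf((th1 - mean_c) / sd_c)
    if p < 0.0:
        p = 0.0
    return p


@njit(cache=True)
def dynavite_density_point(rt, response, th1, th2, a, z, sz, nu, snu, s, tau,
                           muV, sV, sigmaV, w, lam, t0, st0, simult_conf,
                           nz, nt, eps):
    """Joint density P(rt, response, c in [th1, th2]) for the diffusion family.

    Midpoint rule over the uniform non-decision window (``nt`` steps) and the
    uniform start range (``nz`` steps).
    """
    boundary = 1 if response > 0 else -1
    shift = t0 + (tau if simult_conf else 0.0)
    acc = 0.0
    ntt = nt if st0 > 0.0 else 1
    nzz = nz if sz > 0.0 else 1
    for it in range(ntt):
        if st0 > 0.0:
            tnd = st0 * (it + 0.5) / ntt
        else:
            tnd = 0.0
        tdec = rt - shift - tnd
        if tdec <= 0.0:
            continue
        for iz in range(nzz):
            if sz > 0.0:
                z0 = z - sz / 2.0 + sz * (iz + 0.5) / nzz
            else:
                z0 = z
            f0 = fpt0(tdec, boundary, a, z0, s, eps)
            if f0 <= 0.0:
                continue
            fac, m, v2 = drift_marginal(tdec, boundary, a, z0, s, nu, snu)
            p = _conf_prob_dynavite(tdec, boundary, m, v2, a, z, s, tau,
                                    muV, sV, sigmaV, w, lam, th1, th2)
            acc += f0 * fac * p
    return acc / (ntt * nzz)


@njit(cache=True)
def dynavite_density_batch(rt, response, th1, th2, nu, muV, a, z, sz, snu, s,
                           tau, sV, sigmaV, w, lam, t0, st0, simult_conf,
                           nz, nt, eps, out):
    for i in range(rt.shape[0]):
        out[i] = dynavite_density_point(
            rt[i], response[i], th1[i], th2[i], a, z, sz, nu[i], snu, s, tau,
            muV[i], sV, sigmaV, w, lam, t0, st0, simult_conf, nz, nt, eps)


# ---------------------------------------------------------------------------
# Wiener race models (rho = 0 or rho = -0.5), method of images
# ---------------------------------------------------------------------------

@njit(cache=True)
def _race_images(Ap, Bp, rho):
    """Image points of the origin under the reflection group of the wedge
    ``{y1 < Ap, y2 < Bp}`` for a unit-variance pair with correlation ``rho``.

    Reflections preserving the process law, expressed in scaled coordinates:
    ``R1(y) = y - 2 (y1 - Ap) (1, rho)``, ``R2(y) = y - 2 (y2 - Bp) (rho, 1)``.
    The group is finite for rho in {0, -0.5}: order 4 resp. 6.  Returns
    (points[ng, 2], signs[ng]).
    """
    ng = 4 if rho == 0.0 else 6
    pts = np.empty((ng, 2))
    sgn = np.empty(ng)
    # identity
    pts[0, 0] = 0.0
    pts[0, 1] = 0.0
    sgn[0] = 1.0
    # group words over {R1, R2} (0 = padding), applied right-to-left:
    # R1, R2, R1R2, R2R1, R1R2R1 (== R2R1R2 for rho = -0.5)
    words = np.array([[1, 0, 0],
                      [2, 0, 0],
                      [1, 2, 0],
                      [2, 1, 0],
                      [1, 2, 1]], dtype=np.int64)
    nw = 3 if rho == 0.0 else 5
    for iw in range(nw):
        x0 = 0.0
        x1 = 0.0
        length = 0
        for j in range(3):
            if words[iw, j] > 0:
                length += 1
        for j in range(length - 1, -1, -1):
            r = words[iw, j]
            if r == 1:
                d = x0 - Ap
                x0 -= 2.0 * d
                x1 -= 2.0 * d * rho
            else:
                d = x1 - Bp
                x0 -= 2.0 * d * rho
                x1 -= 2.0 * d
        pts[iw + 1, 0] = x0
        pts[iw + 1, 1] = x1
        sgn[iw + 1] = -1.0 if (length % 2 == 1) else 1.0
    return pts, sgn


@njit(cache=True)
def race_gap_density(t, winner, b, A, B, mu1, mu2, s1, s2, rho):
    """Closed-form joint density of (decision time ``t``, ``winner``, losing
    accumulator's gap ``b`` to its own threshold)."""
    if t <= 0.0 or b < 0.0:
        return 0.0
    if winner == 2:
        # exchange accumulators
        A, B = B, A
        mu1, mu2 = mu2, mu1
        s1, s2 = s2, s1
    Ap = A / s1
    Bp = B / s2
    pts, sgn = _race_images(Ap, Bp, rho)
    omr2 = 1.0 - rho * rho
    # absorption point in scaled coordinates
    y0 = Ap
    y1 = Bp - b / s2
    acc = 0.0
    for g in range(pts.shape[0]):
        u0 = y0 - pts[g, 0]
        u1 = y1 - pts[g, 1]
        d2 = (u0 * u0 - 2.0 * rho * u0 * u1 + u1 * u1) / omr2
        acc += sgn[g] * (Ap - pts[g, 0]) * math.exp(-d2 / (2.0 * t))
    q0 = acc / (4.0 * math.pi * t * t * s2 * math.sqrt(omr2))
    # Girsanov drift correction at the absorption point (original coords)
    det = s1 * s1 * s2 * s2 * omr2
    i11 = s2 * s2 / det
    i12 = -rho * s1 * s2 / det
    i22 = s1 * s1 / det
    xa = A
    xb = B - b
    expo = (mu1 * (i11 * xa + i12 * xb) + mu2 * (i12 * xa + i22 * xb)
            - 0.5 * t * (mu1 * mu1 * i11 + 2.0 * mu1 * mu2 * i12 + mu2 * mu2 * i22))
    return q0 * math.exp(expo)


@njit(cache=True)
def race_gap_interval(t, winner, b1, b2, A, B, mu1, mu2, s1, s2, rho):
    """Integral of :func:`race_gap_density` over ``b in [b1, b2]`` (analytic:
    each image term is Gaussian in the gap)."""
    if t <= 0.0:
        return 0.0
    if b2 <= b1:
        return 0.0
    if b1 < 0.0:
        b1 = 0.0
    if b2 <= b1:
        return 0.0
    if winner == 2:
        A, B = B, A
        mu1, mu2 = mu2, mu1
        s1, s2 = s2, s1
    Ap = A / s1
    Bp = B / s2
    pts, sgn = _race_images(Ap, Bp, rho)
    omr2 = 1.0 - rho * rho
    det = s1 * s1 * s2 * s2 * omr2
    i11 = s2 * s2 / det
    i12 = -rho * s1 * s2 / det
    i22 = s1 * s1 / det
    # Girsanov at b=0 absorption corner + quadratic-in-b assembly per image
    g_const = (mu1 * (i11 * A + i12 * B) + mu2 * (i12 * A + i22 * B)
               - 0.5 * t * (mu1 * mu1 * i11 + 2.0 * mu1 * mu2 * i12 + mu2 * mu2 * i22))
    g_lin = -(i12 * mu1 + i22 * mu2)  # coefficient of b in the exponent
    alpha = 1.0 / (2.0 * t * s2 * s2 * omr2)
    pref = 1.0 / (4.0 * math.pi * t * t * s2 * math.sqrt(omr2))
    gauss_norm = math.sqrt(math.pi / alpha)
    acc = 0.0
    for g in range(pts.shape[0]):
        u0 = Ap - pts[g, 0]
        u1 = Bp - pts[g, 1]
        d20 = (u0 * u0 - 2.0 * rho * u0 * u1 + u1 * u1) / omr2
        # (Sigma_rho^{-1} u)_2 / (t*s2): linear coefficient from the kernel
        mu_b = (-rho * u0 + u1) / (omr2 * t * s2)
        beta = mu_b + g_lin
        expo = -d20 / (2.0 * t) + g_const + beta * beta / (4.0 * alpha)
        mean = beta / (2.0 * alpha)
        sd = 1.0 / math.sqrt(2.0 * alpha)
        cdfd = norm_cdf((b2 - mean) / sd) - norm_cdf((b1 - mean) / sd)
        acc += sgn[g] * u0 * math.exp(expo) * cdfd
    val = pref * gauss_norm * acc
    if val < 0.0:
        val = 0.0
    return val


@njit(cache=True)
def race_density_point(rt, winner, th1, th2, A, B, mu1, mu2, s1, s2, rho,
                       wX, wRT, wInt, t0, st0, time_dependent, nt):
    """Joint density P(rt, winner, c in [th1, th2]) for the Wiener race
    models; midpoint rule over the non-decision window."""
    acc = 0.0
    ntt = nt if st0 > 0.0 else 1
    big = 1.0e10
    for it in range(ntt):
        tnd = st0 * (it + 0.5) / ntt if st0 > 0.0 else 0.0
        tdec = rt - t0 - tnd
        if tdec <= 0.0:
            continue
        if time_dependent:
            coef = wX + wInt / math.sqrt(tdec)
            off = wRT / math.sqrt(tdec)
            if coef > 0.0:
                b1 = (th1 - off) / coef
                b2 = (th2 - off) / coef
                acc += race_gap_interval(tdec, winner, b1, b2, A, B,
                                         mu1, mu2, s1, s2, rho)
            else:
                # confidence depends on decision time only
                if th1 <= off <= th2:
                    acc += race_gap_interval(tdec, winner, 0.0, big, A, B,
                                             mu1, mu2, s1, s2, rho)
        else:
            acc += race_gap_interval(tdec, winner, th1, th2, A, B,
                                     mu1, mu2, s1, s2, rho)
    return acc / ntt


@njit(cache=True)
def race_density_batch(rt, winner, th1, th2, mu1, mu2, A, B, s1, s2, rho,
                       wX, wRT, wInt, t0, st0, time_dependent, nt, out):
    for i in range(rt.shape[0]):
        out[i] = race_density_point(
            rt[i], winner[i], th1[i], th2[i], A, B, mu1[i], mu2[i], s1, s2,
            rho, wX, wRT, wInt, t0, st0, time_dependent, nt)


# ---------------------------------------------------------------------------
# Multiple-threshold log-normal race
# ---------------------------------------------------------------------------

@njit(cache=True)
def mtlnr_density_point(rt, winner, th1, th2, mu_d1, mu_d2, mu_v1, mu_v2,
                        sigma_d1, sigma_d2, rho_d, sigma_v1, sigma_v2, rho_v,
                        t0, st0, nt):
    """Joint density P(rt, winner, log-time-ratio in [th1, th2]).

    Boundary-crossing log-times are bivariate normal: ``log T_i`` has mean
    ``mu_di - mu_vi``, variance ``sigma_di^2 + sigma_vi^2`` and covariance
    ``sigma_d1 sigma_d2 rho_d + sigma_v1 sigma_v2 rho_v``.
    """
    m1 = mu_d1 - mu_v1
    m2 = mu_d2 - mu_v2
    v1 = sigma_d1 * sigma_d1 + sigma_v1 * sigma_v1
    v2 = sigma_d2 * sigma_d2 + sigma_v2 * sigma_v2
    cv = sigma_d1 * sigma_d2 * rho_d + sigma_v1 * sigma_v2 * rho_v
    if winner == 2:
        m1, m2 = m2, m1
        v1, v2 = v2, v1
    if v1 <= 0.0:
        return 0.0
    # conditional law of the loser's log time given the winner's
    cm_slope = cv / v1
    cvar = v2 - cv * cv / v1
    if cvar < 0.0:
        cvar = 0.0
    csd = math.sqrt(cvar)
    acc = 0.0
    ntt = nt if st0 > 0.0 else 1
    for it in range(ntt):
        tnd = st0 * (it + 0.5) / ntt if st0 > 0.0 else 0.0
        tdec = rt - t0 - tnd
        if tdec <= 0.0:
            continue
        lt = math.log(tdec)
        f1 = math.exp(-(lt - m1) * (lt - m1) / (2.0 * v1)) / (math.sqrt(v1) * SQRT_2PI * tdec)
        cmean = m2 + cm_slope * (lt - m1)
        lo = lt + th1
        hi = lt + th2
        if csd > 0.0:
            p = norm_cdf((hi - cmean) / csd) - norm_cdf((lo - cmean) / csd)
        else:
            p = 1.0 if (lo <= cmean <= hi) else 0.0
        acc += f1 * p
    return acc / ntt


@njit(cache=True)
def mtlnr_density_batch(rt, winner, th1, th2, mu_v1, mu_v2, mu_d1, mu_d2,
                        sigma_d1, sigma_d2, rho_d, sigma_v1, sigma_v2, rho_v,
                        t0, st0, nt, out):
    for i in range(rt.shape[0]):
        out[i] = mtlnr_density_point(
            rt[i], winner[i], th1[i], th2[i], mu_d1, mu_d2, mu_v1[i], mu_v2[i],
            sigma_d1, sigma_d2, rho_d, sigma_v1, sigma_v2, rho_v, t0, st0, nt)


# ---------------------------------------------------------------------------
# Euler-Maruyama simulators
# ---------------------------------------------------------------------------

@njit(cache=True)
def simulate_dynavite_k(n, a, z, sz, nu, snu, s, tau, muV, sV, sigmaV, w, lam,
                        t0, st0, delta, maxrt, simult_conf, seed):
    """Trial-level simulation of the diffusion-family process.

    Returns (response, rt, conf) arrays; response 0 flags no boundary hit
    before ``maxrt`` (rt and conf are NaN there).
    """
    np.random.seed(seed)
    resp = np.zeros(n, dtype=np.int64)
    rt = np.empty(n)
    conf = np.empty(n)
    sq = s * math.sqrt(delta)
    sqv = sV * math.sqrt(delta)
    nmax = int(maxrt / delta) + 1
    for i in range(n):
        mu = nu + snu * np.random.randn() if snu > 0.0 else nu
        muv = muV + sigmaV * np.random.randn() if sigmaV > 0.0 else muV
        z0 = z + sz * (np.random.rand() - 0.5) if sz > 0.0 else z
        x = a * z0
        v = 0.0
        hit = 0
        tdec = 0.0
        for k in range(nmax):
            x += mu * delta + sq * np.random.randn()
            if w < 1.0:
                v += muv * delta + sqv * np.random.randn()
            if x >= a:
                hit = 1
                tdec = (k + 1) * delta
                break
            if x <= 0.0:
                hit = -1
                tdec = (k + 1) * delta
                break
        if hit == 0:
            resp[i] = 0
            rt[i] = np.nan
            conf[i] = np.nan
            continue
        # post-decisional accumulation
        ntau = int(round(tau / delta))
        for k in range(ntau):
            x += mu * delta + sq * np.random.randn()
            if w < 1.0:
                v += muv * delta + sqv * np.random.randn()
        ttot = tdec + ntau * delta
        e = hit * (x - a * z)
        c = (w * e + (1.0 - w) * v) / (ttot ** lam if lam != 0.0 else 1.0)
        tnd = t0 + st0 * np.random.rand()
        resp[i] = hit
        rt[i] = (tdec + tau + tnd) if simult_conf else (tdec + tnd)
        conf[i] = c
    return resp, rt, conf


@njit(cache=True)
def simulate_race_k(n, A, B, mu1, mu2, s1, s2, rho, wX, wRT, wInt,
                    t0, st0, delta, maxrt, seed):
    """Simulation of the two-accumulator Wiener race with increment
    correlation ``rho``; confidence from the losing accumulator's gap and
    decision time."""
    np.random.seed(seed)
    resp = np.zeros(n, dtype=np.int64)
    rt = np.empty(n)
    conf = np.empty(n)
    sq = math.sqrt(delta)
    cfac = math.sqrt(1.0 - rho * rho)
    nmax = int(maxrt / delta) + 1
    for i in range(n):
        x1 = 0.0
        x2 = 0.0
        hit = 0
        tdec = 0.0
        for k in range(nmax):
            e1 = np.random.randn()
            e2 = rho * e1 + cfac * np.random.randn()
            x1 += mu1 * delta + s1 * sq * e1
            x2 += mu2 * delta + s2 * sq * e2
            if x1 >= A or x2 >= B:
                hit = 1 if x1 >= A else 2
                if x1 >= A and x2 >= B:
                    hit = 1 if (x1 - A) / s1 >= (x2 - B) / s2 else 2
                tdec = (k + 1) * delta
                break
        if hit == 0:
            resp[i] = 0
            rt[i] = np.nan
            conf[i] = np.nan
            continue
        b = (B - x2) if hit == 1 else (A - x1)
        if b < 0.0:
            b = 0.0
        c = wX * b + wRT / math.sqrt(tdec) + wInt * b / math.sqrt(tdec)
        tnd = t0 + st0 * np.random.rand()
        resp[i] = hit
        rt[i] = tdec + tnd
        conf[i] = c
    return resp, rt, conf
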