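"""Subject-level information-criterion weights and group-level random-effects
Bayesian model selection.

The group analysis treats ``-IC/2`` as log model evidence, fits a Dirichlet
over population model frequencies by variational Bayes, and reports
exceedance probabilities (EP), the Bayesian omnibus risk (BOR) of the
random-effects model against the equal-frequency null, and protected
exceedance probabilities ``PEP = (1 - BOR) * EP + BOR / M``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc, digamma, gammaln
from scipy.stats import dirichlet

__all__ = ["subject_model_weights", "group_bms", "BMSResult"]


@dataclass
class BMSResult:
    models: list
    alpha: np.ndarray
    model_probs: np.ndarray
    ep: np.ndarray
    pep: np.ndarray
    bor: float
    fixed_effect_probs: np.ndarray
    free_energy: float
    iterations: int

    def summary(self):
        return pd.DataFrame({"model": self.models, "alpha": self.alpha,
                             "model_prob": self.model_probs, "ep": self.ep,
                             "pep": self.pep,
                             "fixed_effect_prob": self.fixed_effect_probs})


def _evidence_matrix(fits: pd.DataFrame, measure):
    if measure not in ("BIC", "AIC", "AICc"):
        raise ValueError("measure must be one of BIC, AIC, AICc")
    if measure not in fits.columns:
        raise ValueError(f"fits table has no {measure!r} column")
    subjects = list(pd.unique(fits["subject"]))
    models = list(pd.unique(fits["model"]))
    ic = np.full((len(subjects), len(models)), np.nan)
    for i, s in enumerate(subjects):
        for j, m in enumerate(models):
            sel = fits[(fits["subject"] == s) & (fits["model"] == m)]
            if len(sel) != 1 or not np.isfinite(sel[measure].iloc[0]):
                raise ValueError(
                    f"missing or invalid {measure} for subject {s!r}, "
                    f"model {m!r}")
            ic[i, j] = sel[measure].iloc[0]
    return subjects, models, ic


def subject_model_weights(fits: pd.DataFrame, measure="BIC"):
    """Per-subject model weights ``exp(-delta/2)`` normalized within subject,
    with ``delta`` the IC difference to the subject's best model."""
    subjects, models, ic = _evidence_matrix(fits, measure)
    delta = ic - ic.min(axis=1, keepdims=True)
    w = np.exp(-delta / 2.0)
    w /= w.sum(axis=1, keepdims=True)
    out = pd.DataFrame(w, columns=models)
    out.insert(0, "subject", subjects)
    return out


def group_bms(fits: pd.DataFrame, measure="BIC", mc_samples=1_000_000,
              seed=0, alpha0=1.0, tol=1e-8, max_iter=10_000):
    """Random-effects group-level model selection.

    Variational update of the Dirichlet concentration (free energy is
    non-decreasing and checked); EP by Dirichlet Monte Carlo (analytic Beta
    comparison when two models); BOR from the free-energy comparison with
    the equal-frequency null; fixed-effects probabilities from summed ICs.
    """
    _, models, ic = _evidence_matrix(fits, measure)
    log_ev = -ic / 2.0
    n_sub, n_mod = log_ev.shape
    a0 = np.full(n_mod, float(alpha0))

    alpha = a0.copy()
    f_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        lw = log_ev + (digamma(alpha) - digamma(alpha.sum()))
        lw -= lw.max(axis=1, keepdims=True)
        z = np.exp(lw)
        z /= z.sum(axis=1, keepdims=True)
        alpha_new = a0 + z.sum(axis=0)
        f = _free_energy(log_ev, z, alpha_new, a0)
        if f < f_prev - 1e-9:
            raise RuntimeError("variational free energy decreased")
        converged = np.max(np.abs(alpha_new - alpha)) < tol
        alpha = alpha_new
        f_prev = f
        if converged:
            break
    else:
        raise RuntimeError(
            f"variational update did not converge in {max_iter} iterations")

    model_probs = alpha / alpha.sum()
    ep = _exceedance(alpha, mc_samples, seed)
    f0 = _null_free_energy(log_ev)
    bor = 1.0 / (1.0 + np.exp(f_prev - f0))
    pep = (1.0 - bor) * ep + bor / n_mod
    sums = ic.sum(axis=0)
    d = sums - sums.min()
    fixed = np.exp(-d / 2.0)
    fixed /= fixed.sum()
    return BMSResult(models=models, alpha=alpha, model_probs=model_probs,
                     ep=ep, pep=pep, bor=float(bor),
                     fixed_effect_probs=fixed, free_energy=f_prev,
                     iterations=it)


def _free_energy(log_ev, z, alpha, a0):
    """Variational free energy of the random-effects model."""
    psi = digamma(alpha) - digamma(alpha.sum())
    zs = z[z > 0]
    e_like = float((z * log_ev).sum())
    e_prior_z = float((z * psi).sum())
    h_z = -float((zs * np.log(zs)).sum())
    ln_c0 = gammaln(a0.sum()) - gammaln(a0).sum()
    ln_c = gammaln(alpha.sum()) - gammaln(alpha).sum()
    e_prior_r = ln_c0 + float(((a0 - 1) * psi).sum())
    h_r = -ln_c - float(((alpha - 1) * psi).sum())
    return e_like + e_prior_z + h_z + e_prior_r + h_r


def _null_free_energy(log_ev):
    """Log evidence of the equal-frequency null: each subject's data is a
    uniform mixture over models."""
    m = log_ev.shape[1]
    mx = log_ev.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.exp(log_ev - mx).sum(axis=1))
    return float((lse - np.log(m)).sum())


def _exceedance(alpha, mc_samples, seed):
    m = len(alpha)
    if m == 2:
        # P(x1 > 1/2), x1 ~ Beta(a1, a2)
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    draws = dirichlet.rvs(alpha, size=int(mc_samples), random_state=rng)
    win = np.argmax(draws, axis=1)
    return np.bincount(win, minlength=m) / len(win)
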