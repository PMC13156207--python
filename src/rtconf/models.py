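"""Model registry, condition-to-drift mapping, and parameter counting.

The fitting layer estimates one discriminability parameter ``d_l`` per
difficulty level; the stimulus-dependent drifts of each model family are
derived from it:

* diffusion family: ``nu = S * d_l``, visibility drift ``muV = d_l``
* Wiener race: ``(mu1, mu2) = (S * d_l, -S * d_l)``
* log-normal race: rate means ``(d_l, 0)`` for ``S = +1``, ``(0, d_l)`` for
  ``S = -1``
"""

from __future__ import annotations

__all__ = ["MODELS", "family", "base_parameters", "map_parameters",
           "count_free_parameters", "response_to_winner"]

#: models accepted by the fitting layer
MODELS = ("dynaViTE", "dynWEV", "2DSD", "DDConf",
          "IRM", "IRMt", "PCRM", "PCRMt", "MTLNR")

_FAMILY = {
    "dynaViTE": "ddm", "dynWEV": "ddm", "2DSD": "ddm", "DDConf": "ddm",
    "IRM": "race", "IRMt": "race", "PCRM": "race", "PCRMt": "race",
    "MTLNR": "mtlnr", "MTLNRfull": "mtlnr",
}

#: structural (condition-independent) parameters fitted per model; the
#: diffusion constants are fixed to 1 and the constrained entries of the
#: special cases are dropped
_BASE = {
    "dynaViTE": ("a", "z", "sz", "snu", "tau", "sV", "sigmaV", "w", "lam",
                 "t0", "st0"),
    "dynWEV": ("a", "z", "sz", "snu", "tau", "sV", "sigmaV", "w", "t0", "st0"),
    "2DSD": ("a", "z", "sz", "snu", "tau", "t0", "st0"),
    "DDConf": ("a", "z", "sz", "snu", "t0", "st0"),
    "IRMt": ("A", "B", "wX", "wRT", "t0", "st0"),
    "PCRMt": ("A", "B", "wX", "wRT", "t0", "st0"),
    "IRM": ("A", "B", "t0", "st0"),
    "PCRM": ("A", "B", "t0", "st0"),
    # restricted configuration: boundary-distance variability fixed to 0;
    # the free variance/correlation parameters of the crossing times are
    # exposed as s1, s2, rho
    "MTLNR": ("mu_d1", "mu_d2", "s1", "s2", "rho", "t0", "st0"),
    # unrestricted parameterization (used by the precision benchmark)
    "MTLNRfull": ("mu_d1", "mu_d2", "sigma_d1", "sigma_d2", "rho_d",
                  "s1", "s2", "rho", "t0", "st0"),
}


def family(model):
    try:
        return _FAMILY[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; supported models: {', '.join(MODELS)}"
        ) from None


def base_parameters(model):
    family(model)
    return _BASE[model]


def map_parameters(model, stimulus, d):
    """Per-trial drift configuration for stimulus sign ``stimulus`` and
    discriminability ``d`` (the fitted ``d_l`` of the trial's condition)."""
    fam = family(model)
    if stimulus not in (-1, 1):
        raise ValueError("stimulus must be -1 or +1")
    if fam == "ddm":
        return {"nu": stimulus * d, "muV": d}
    if fam == "race":
        return {"mu1": stimulus * d, "mu2": -stimulus * d}
    if stimulus == 1:
        return {"mu_v1": d, "mu_v2": 0.0}
    return {"mu_v1": 0.0, "mu_v2": d}


def response_to_winner(response):
    """Signed response (+1/-1) to accumulator index (1/2) for the race
    families: accumulator 1 collects evidence for the +1 category."""
    return 1 if response > 0 else 2


def count_free_parameters(model, L, K, fixed=None, sym_thetas=False):
    """Number of free parameters of a fitting configuration.

    Base count + L discriminability parameters + 2(K-1) confidence
    thresholds; symmetric thresholds remove K-1; every user-fixed parameter
    removes one.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if K < 2:
        raise ValueError("K must be >= 2")
    base = base_parameters(model)
    fixed = dict(fixed or {})
    sym_thetas = bool(fixed.pop("sym_thetas", sym_thetas))
    n = len(base) + L + 2 * (K - 1)
    if sym_thetas:
        n -= K - 1
    for name in fixed:
        valid = set(base) | {f"d_{i}" for i in range(1, L + 1)}
        if name not in valid:
            raise ValueError(
                f"fixed parameter {name!r} does not belong to model {model}")
        n -= 1
    return n
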