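"""Trial-level data model: ingestion, encoding, and bookkeeping.

One row per trial with columns (canonical names): ``subject``, ``stimulus``
(-1/+1), ``condition`` (factor, encoded 1..L), ``response`` (-1/+1), ``rt``
(seconds), ``rating`` (1..K), ``correct`` (0/1).  Alternative column names
can be supplied as an alias map, e.g. ``{"rating": "confidence"}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrialTable", "RatingScaleInfo", "ingest_trials",
           "split_by_subject", "filter_rt_outliers", "write_trials"]

SUBJECT_ALIASES = ("subject", "participant", "sbj")


@dataclass
class RatingScaleInfo:
    """Number of rating categories and the categories actually used per
    response sign (subjects do not always use the full scale)."""

    n_ratings: int
    used: dict = field(default_factory=dict)  # {+1: set, -1: set}

    def __post_init__(self):
        if self.n_ratings < 2:
            raise ValueError("number of rating categories K must be >= 2")
        for sign in (1, -1):
            self.used.setdefault(sign, set())

    def unused(self, sign):
        return set(range(1, self.n_ratings + 1)) - self.used[1 if sign > 0 else -1]


@dataclass
class TrialTable:
    """Encoded per-trial table plus rating-scale metadata."""

    df: pd.DataFrame
    scale: RatingScaleInfo
    condition_levels: list = field(default_factory=list)

    @property
    def n_conditions(self):
        return max(1, len(self.condition_levels))

    @property
    def n_ratings(self):
        return self.scale.n_ratings

    def __len__(self):
        return len(self.df)


def _find_column(df, canonical, aliases):
    requested = aliases.get(canonical)
    if requested is not None:
        if requested not in df.columns:
            raise ValueError(
                f"column {requested!r} (alias for {canonical!r}) not found")
        return requested
    if canonical in df.columns:
        return canonical
    if canonical == "subject":
        for cand in SUBJECT_ALIASES:
            if cand in df.columns:
                return cand
    return None


def _encode_signed(values, what):
    """Map a two-level column to -1/+1.  Already-signed numeric values pass
    through; otherwise the two levels are assigned by sorted order."""
    vals = pd.Series(values)
    uniq = pd.unique(vals.dropna())
    as_num = pd.to_numeric(vals, errors="coerce")
    if not as_num.isna().any() and set(np.unique(as_num)) <= {-1.0, 1.0}:
        return as_num.astype(int).to_numpy()
    if len(uniq) > 2:
        raise ValueError(f"{what} column has {len(uniq)} levels; expected 2")
    levels = sorted(uniq, key=lambda v: str(v))
    mapping = {levels[0]: -1}
    if len(levels) == 2:
        mapping[levels[1]] = 1
    return vals.map(mapping).astype(int).to_numpy()


def ingest_trials(raw, column_aliases=None, n_ratings=None) -> TrialTable:
    """Read and encode a trial table.

    ``raw`` may be a delimited-text path (delimiter auto-detected) or a
    DataFrame.  Requires ``rt``, ``rating`` and two of
    {``stimulus``, ``response``, ``correct``}; the missing one of
    stimulus/response is reconstructed from ``correct = 1(S == R)``.
    """
    aliases = dict(column_aliases or {})
    if isinstance(raw, (str, Path)):
        raw = pd.read_csv(raw, sep=None, engine="python")
    df = raw.copy()

    cols = {}
    for canonical in ("subject", "stimulus", "condition", "response", "rt",
                      "rating", "correct"):
        cols[canonical] = _find_column(df, canonical, aliases)

    for mandatory in ("rt", "rating"):
        if cols[mandatory] is None:
            raise ValueError(f"mandatory column {mandatory!r} is missing")

    have_s = cols["stimulus"] is not None
    have_r = cols["response"] is not None
    have_c = cols["correct"] is not None
    if not have_s and not have_r:
        raise ValueError("need at least one of 'stimulus' or 'response'")
    if (not have_s or not have_r) and not have_c:
        missing = "stimulus" if not have_s else "response"
        raise ValueError(
            f"column {missing!r} is missing and cannot be reconstructed "
            "without a 'correct' column")

    out = pd.DataFrame(index=df.index)
    out["subject"] = (df[cols["subject"]].to_numpy()
                      if cols["subject"] is not None else 0)

    rt = pd.to_numeric(df[cols["rt"]], errors="coerce").to_numpy(float)
    bad = ~(np.isfinite(rt) & (rt > 0))
    if bad.any():
        rows = [int(i) for i in np.flatnonzero(bad)[:20]]
        raise ValueError(
            f"rt must be strictly positive and finite; offending rows: {rows}"
            + (" ..." if bad.sum() > 20 else ""))
    out["rt"] = rt

    if have_s:
        out["stimulus"] = _encode_signed(df[cols["stimulus"]], "stimulus")
    if have_r:
        out["response"] = _encode_signed(df[cols["response"]], "response")
    if have_c:
        correct = pd.to_numeric(df[cols["correct"]], errors="coerce").to_numpy()
        if not set(np.unique(correct[~np.isnan(correct)])) <= {0.0, 1.0}:
            raise ValueError("correct column must be 0/1")
        if have_s and have_r:
            implied = (out["stimulus"] == out["response"]).astype(int)
            if not np.array_equal(implied.to_numpy(), correct.astype(int)):
                raise ValueError(
                    "response and correct columns are inconsistent with "
                    "stimulus; refusing to silently prefer one")
        elif have_s:
            out["response"] = (out["stimulus"]
                               * (2 * correct.astype(int) - 1)).astype(int)
        else:
            out["stimulus"] = (out["response"]
                               * (2 * correct.astype(int) - 1)).astype(int)
    out["correct"] = (out["stimulus"] == out["response"]).astype(int)

    if cols["condition"] is not None:
        cond = pd.Categorical(df[cols["condition"]])
        levels = list(cond.categories)
        out["condition"] = cond.codes + 1
    else:
        levels = [1]
        out["condition"] = 1

    rating_raw = df[cols["rating"]]
    if isinstance(rating_raw.dtype, pd.CategoricalDtype):
        codes = rating_raw.cat.codes.to_numpy() + 1
        k_obs = len(rating_raw.cat.categories)
    else:
        rnum = pd.to_numeric(rating_raw, errors="coerce")
        if rnum.isna().any():
            cat = pd.Categorical(rating_raw)
            codes = cat.codes + 1
            k_obs = len(cat.categories)
        else:
            codes = rnum.astype(int).to_numpy()
            if (codes < 1).any():
                raise ValueError("numeric ratings must be >= 1")
            k_obs = int(codes.max())
    K = int(n_ratings) if n_ratings is not None else max(k_obs, 2)
    if (codes > K).any() or (codes < 1).any():
        raise ValueError(
            f"rating values outside 1..{K} (n_ratings={n_ratings})")
    out["rating"] = codes

    used = {1: set(), -1: set()}
    for sign in (1, -1):
        used[sign] = set(out.loc[out["response"] == sign, "rating"].unique())
    scale = RatingScaleInfo(n_ratings=K, used=used)
    return TrialTable(df=out.reset_index(drop=True), scale=scale,
                      condition_levels=levels)


def split_by_subject(trials: TrialTable):
    """Partition into per-subject tables (row order preserved).  Falls back
    to a single group with a warning when no subject column was present."""
    df = trials.df
    if "subject" not in df.columns or df["subject"].nunique() <= 1:
        if "subject" not in df.columns:
            warnings.warn("no subject column; treating data as one group")
        return [(df["subject"].iloc[0] if len(df) else 0, trials)] if len(df) else []
    out = []
    for sid, grp in df.groupby("subject", sort=True):
        sub = TrialTable(df=grp.reset_index(drop=True),
                         scale=RatingScaleInfo(
                             trials.scale.n_ratings,
                             {s: set(grp.loc[grp["response"] == s, "rating"])
                              for s in (1, -1)}),
                         condition_levels=trials.condition_levels)
        out.append((sid, sub))
    return out


def filter_rt_outliers(trials: TrialTable, lower=0.3, upper_sd=2.0):
    """Per-subject response-time filter: drop trials below ``lower`` seconds
    or above mean + ``upper_sd`` standard deviations.  Exclusion rules are a
    user decision; nothing is filtered automatically elsewhere."""
    df = trials.df
    keep = np.ones(len(df), dtype=bool)
    for _, grp in df.groupby("subject"):
        hi = grp["rt"].mean() + upper_sd * grp["rt"].std(ddof=1)
        bad = (grp["rt"] < lower) | (grp["rt"] > hi)
        keep[grp.index[bad]] = False
    return TrialTable(df=df[keep].reset_index(drop=True), scale=trials.scale,
                      condition_levels=trials.condition_levels)


def write_trials(trials: TrialTable, path, sep=","):
    trials.df.to_csv(path, sep=sep, index=False)
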