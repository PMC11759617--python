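"""Propensity-score subclassification matching on projected PCs.

Cohort membership (reference cohort = 1) is regressed on the projected
principal components plus affection status — optionally age and sex — by
logistic regression.  The propensity-score range is partitioned into
subclasses at quantiles of the *reference* scores (the estimand treats the
reference cohort as the target of matching, so every reference participant
keeps weight 1), target samples are weighted by the within-subclass
reference/target count ratio rescaled to mean 1, and "matched" target
samples are those with weight >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._glm import SeparationError, firth_logistic, logistic_irls

__all__ = [
    "PropensityFit", "MatchResult", "fit_propensity", "subclassify",
    "compute_weights", "select_matched", "balance_report", "run_matching",
    "SeparationError",
]


@dataclass
class PropensityFit:
    coef: np.ndarray
    columns: list
    scores: np.ndarray              # strictly in (0, 1)
    converged: bool
    n_iter: int
    penalized: bool = False


@dataclass
class MatchResult:
    subclass: np.ndarray            # 1-based subclass index per sample
    weights: np.ndarray             # per sample; reference samples exactly 1
    matched: np.ndarray             # boolean over all samples; subset of target
    is_reference: np.ndarray
    n_subclasses: int


def _design(pc_scores: np.ndarray, sheet: pd.DataFrame, include_age_sex: bool):
    cols = ["intercept"] + [f"PC{j + 1}" for j in range(pc_scores.shape[1])]
    parts = [np.ones((len(sheet), 1)), pc_scores]
    parts.append(sheet["status"].to_numpy(dtype=float)[:, None])
    cols.append("status")
    if include_age_sex:
        parts.append(sheet["age"].to_numpy(dtype=float)[:, None])
        parts.append(sheet["sex"].to_numpy(dtype=float)[:, None])
        cols += ["age", "sex"]
    X = np.hstack(parts)
    if np.isnan(X).any():
        raise ValueError("missing covariate values in the propensity design")
    return X, cols


def fit_propensity(pc_scores: np.ndarray, sheet: pd.DataFrame,
                   reference_cohort: str, include_age_sex: bool = False,
                   penalize: bool = False) -> PropensityFit:
    """Logistic model of cohort membership on PCs (+ status, age, sex).

    Raises :class:`SeparationError` with advice to use ``penalize=True``
    (a Firth-penalized fit) when the cohorts are separable.
    """
    y = (sheet["cohort"] == reference_cohort).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both cohorts must be present")
    X, cols = _design(pc_scores, sheet, include_age_sex)
    if penalize:
        beta, _, _, it, conv = firth_logistic(X, y)
    else:
        beta, _, it, conv = logistic_irls(X, y, max_iter=100, tol=1e-8)
    scores = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    return PropensityFit(beta, cols, scores, conv, it, penalized=penalize)


def subclassify(scores: np.ndarray, is_reference: np.ndarray,
                n_subclasses: int = 500) -> np.ndarray:
    """Assign every sample to a propensity subclass (1-based).

    Boundaries are the score quantiles of the reference cohort; subclasses
    that end up without any reference member are merged downward (with the
    nearest lower subclass, upward only from the bottom edge).
    """
    if n_subclasses < 2:
        raise ValueError("need at least 2 subclasses")
    scores = np.asarray(scores, dtype=float)
    is_reference = np.asarray(is_reference, dtype=bool)
    n_ref = int(is_reference.sum())
    S = min(n_subclasses, n_ref)
    qs = np.quantile(scores[is_reference], np.linspace(0, 1, S + 1)[1:-1])
    sub = np.searchsorted(qs, scores, side="left") + 1
    # merge subclasses with no reference member
    ref_counts = np.bincount(sub[is_reference], minlength=S + 1)
    mapping = np.arange(S + 1)
    last_nonempty = 0
    for s in range(1, S + 1):
        if ref_counts[s] > 0:
            last_nonempty = s
        else:
            mapping[s] = last_nonempty      # 0 = pending, fixed below
    if np.any(mapping[1:] == 0):
        first_nonempty = int(np.flatnonzero(ref_counts[1:] > 0)[0]) + 1
        mapping[mapping == 0] = first_nonempty
    sub = mapping[sub]
    # relabel to consecutive 1..S'
    uniq = np.unique(sub)
    relab = np.zeros(S + 1, dtype=int)
    relab[uniq] = np.arange(1, len(uniq) + 1)
    return relab[sub]


def compute_weights(subclass: np.ndarray, is_reference: np.ndarray) -> np.ndarray:
    """Subclassification weights with the reference cohort as estimand.

    Reference samples have weight exactly 1.  A target sample in subclass
    ``s`` receives the raw weight ``n_ref,s / n_target,s``; target weights
    are then rescaled so that their mean over all weighted target samples
    is 1.
    """
    subclass = np.asarray(subclass)
    is_reference = np.asarray(is_reference, dtype=bool)
    S = subclass.max()
    n_ref = np.bincount(subclass[is_reference], minlength=S + 1)
    n_tgt = np.bincount(subclass[~is_reference], minlength=S + 1)
    if np.any((n_ref[1:] == 0) & (np.bincount(subclass, minlength=S + 1)[1:] > 0)):
        raise ValueError("every subclass must contain a reference sample")
    w = np.zeros(len(subclass))
    w[is_reference] = 1.0
    tgt = ~is_reference
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(n_tgt > 0, n_ref / np.maximum(n_tgt, 1), 0.0)
    w[tgt] = raw[subclass[tgt]]
    total = w[tgt].sum()
    n_weighted = int(tgt.sum())
    if total > 0:
        w[tgt] *= n_weighted / total
    return w


def select_matched(weights: np.ndarray, is_reference: np.ndarray,
                   threshold: float = 1.0) -> np.ndarray:
    """Target samples whose weight matches or exceeds the reference weight."""
    return (~np.asarray(is_reference, dtype=bool)) & (weights >= threshold)


def balance_report(pc_scores: np.ndarray, sheet: pd.DataFrame,
                   is_reference: np.ndarray, matched: np.ndarray) -> pd.DataFrame:
    """Standardized mean differences reference vs (matched, unmatched) target."""
    is_reference = np.asarray(is_reference, dtype=bool)
    covars = {f"PC{j + 1}": pc_scores[:, j] for j in range(pc_scores.shape[1])}
    covars["age"] = sheet["age"].to_numpy(dtype=float)
    covars["sex"] = sheet["sex"].to_numpy(dtype=float)
    covars["status"] = sheet["status"].to_numpy(dtype=float)

    def smd(x, grp):
        a, b = x[is_reference], x[grp]
        if len(b) == 0:
            return np.nan
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        if pooled == 0:
            return 0.0
        return (a.mean() - b.mean()) / pooled

    target = ~is_reference
    rows = [
        {"covariate": name,
         "smd_matched": smd(x, matched),
         "smd_unmatched": smd(x, target)}
        for name, x in covars.items()
    ]
    return pd.DataFrame(rows)


def run_matching(pc_scores: np.ndarray, sheet: pd.DataFrame,
                 reference_cohort: str, include_age_sex: bool = False,
                 n_subclasses: int = 500, weight_threshold: float = 1.0,
                 penalize: bool = False) -> MatchResult:
    """Full matching pass: propensity fit -> subclasses -> weights -> mask."""
    fit = fit_propensity(pc_scores, sheet, reference_cohort,
                         include_age_sex=include_age_sex, penalize=penalize)
    is_ref = (sheet["cohort"] == reference_cohort).to_numpy()
    sub = subclassify(fit.scores, is_ref, n_subclasses)
    w = compute_weights(sub, is_ref)
    matched = select_matched(w, is_ref, weight_threshold)
    return MatchResult(sub, w, matched, is_ref, int(sub.max()))
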