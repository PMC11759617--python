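"""Analytic case-control power for an additive disease model.

The model is the classic genotype-relative-risk formulation: a biallelic
variant with risk-allele frequency ``q`` in Hardy-Weinberg proportions,
penetrances additive on the risk scale,

    f1 = GRR * f0,   f2 = (2 * GRR - 1) * f0,

with ``f0`` pinned down by the population prevalence
``K = g0 f0 + g1 f1 + g2 f2``.  Case and control genotype frequencies follow
from Bayes' rule and collapse to risk-allele frequencies ``p_case`` and
``p_ctrl``; the association test is the 1-df comparison of those two allele
proportions.

Three power conventions are provided (see ``docs/methods.md`` for the
calibration that fixed the default):

``calculator`` (default)
    Normal ogive in the expected Wald allele statistic
    ``t = |p_case - p_ctrl| / SE_alt`` (alternative-hypothesis variance),
    anchored so that its 80% point sits where ``t`` equals the one-sided
    normal critical value ``z_{1-alpha}``.  This reproduces the published
    thresholds of the University of Michigan genetic-association power
    calculator to the printed two decimals.
``cats``
    Textbook two-proportion power: pooled-variance critical value, spread
    under the alternative-hypothesis variance (the CaTS one-stage formula).
``trend``
    Cochran-Armitage trend test on genotype frequencies, same
    null/alternative variance treatment as ``cats``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

CONVENTIONS = ("calculator", "cats", "trend")

#: the anchored operating point of the ``calculator`` convention
_ANCHOR_POWER = 0.80


class InfeasibleModelError(ValueError):
    pass


@dataclass
class PowerSpec:
    maf: float
    grr: float
    n_cases: int
    n_controls: int
    prevalence: float = 0.111
    alpha: float = 5e-8
    model: str = "additive"

    def validate(self):
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.grr < 1:
            raise ValueError("grr must be >= 1")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.model != "additive":
            raise ValueError("only the additive model is supported")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("case and control counts must be positive")


def genotype_freqs(maf: float) -> np.ndarray:
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def penetrances(spec: PowerSpec) -> tuple[float, float, float]:
    """(f0, f1, f2) under the additive model, conserving the prevalence."""
    spec.validate()
    g = genotype_freqs(spec.maf)
    f0 = spec.prevalence / (g[0] + g[1] * spec.grr + g[2] * (2 * spec.grr - 1))
    f1 = spec.grr * f0
    f2 = (2 * spec.grr - 1) * f0
    if f2 > 1:
        raise InfeasibleModelError(
            f"homozygote penetrance {f2:.3f} exceeds 1; reduce grr or prevalence")
    return f0, f1, f2


def case_control_allele_freqs(spec: PowerSpec) -> tuple[float, float]:
    """Risk-allele frequency among cases and among controls."""
    g = genotype_freqs(spec.maf)
    f = np.array(penetrances(spec))
    K = spec.prevalence
    p_case_g = g * f / K
    p_ctrl_g = g * (1 - f) / (1 - K)
    p_case = p_case_g[2] + p_case_g[1] / 2
    p_ctrl = p_ctrl_g[2] + p_ctrl_g[1] / 2
    return float(p_case), float(p_ctrl)


def _allele_test_terms(spec: PowerSpec):
    p1, p0 = case_control_allele_freqs(spec)
    n1, n0 = 2 * spec.n_cases, 2 * spec.n_controls
    d = abs(p1 - p0)
    pbar = (n1 * p1 + n0 * p0) / (n1 + n0)
    se_null = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
    se_alt = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    return d, se_null, se_alt


def power_additive(spec: PowerSpec, convention: str = "calculator") -> float:
    """Probability of genome-wide rejection under the additive model."""
    spec.validate()
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if convention == "trend":
        return _power_trend(spec)
    d, se_null, se_alt = _allele_test_terms(spec)
    if convention == "calculator":
        # ogive in the expected Wald statistic, anchored at the one-sided
        # critical value as its 80% operating point
        z_crit = stats.norm.isf(spec.alpha)
        shift = z_crit - stats.norm.ppf(_ANCHOR_POWER)
        t = d / se_alt
        return float(stats.norm.cdf(t - shift) + stats.norm.cdf(-t - shift))
    # "cats": two-sided test, null-variance critical value, alternative spread
    z_half = stats.norm.isf(spec.alpha / 2)
    return float(
        stats.norm.sf((z_half * se_null - d) / se_alt)
        + stats.norm.cdf((-z_half * se_null - d) / se_alt)
    )


def _power_trend(spec: PowerSpec) -> float:
    g = genotype_freqs(spec.maf)
    f = np.array(penetrances(spec))
    K = spec.prevalence
    pc = g * f / K
    p0 = g * (1 - f) / (1 - K)
    x = np.array([0.0, 1.0, 2.0])
    d = abs(x @ pc - x @ p0)
    n1, n0 = spec.n_cases, spec.n_controls
    n = n1 + n0
    phi = n1 / n
    pbar = phi * pc + (1 - phi) * p0
    var_null = ((x ** 2) @ pbar - (x @ pbar) ** 2) * (1 / n1 + 1 / n0)
    var_alt = ((x ** 2) @ pc - (x @ pc) ** 2) / n1 \
        + ((x ** 2) @ p0 - (x @ p0) ** 2) / n0
    z_half = stats.norm.isf(spec.alpha / 2)
    se0, se1 = np.sqrt(var_null), np.sqrt(var_alt)
    return float(stats.norm.sf((z_half * se0 - d) / se1)
                 + stats.norm.cdf((-z_half * se0 - d) / se1))


def min_grr_for_power(maf: float, n_cases: int, n_controls: int,
                      prevalence: float = 0.111, alpha: float = 5e-8,
                      target: float = 0.80, convention: str = "calculator",
                      bracket=(1.0, 50.0), tol: float = 1e-4) -> float:
    """Smallest GRR attaining ``target`` power, reported to two decimals."""
    if not (0 < target < 1):
        raise ValueError("target power must lie in (0, 1)")

    def gap(grr):
        spec = PowerSpec(maf=maf, grr=grr, n_cases=n_cases,
                         n_controls=n_controls, prevalence=prevalence,
                         alpha=alpha)
        return power_additive(spec, convention=convention) - target

    lo, hi = bracket
    lo = max(lo, 1.0) + 1e-9
    # clip the bracket to the penetrance-feasible region (f2 <= 1)
    def infeasibility(grr):
        g = genotype_freqs(maf)
        f0 = prevalence / (g[0] + g[1] * grr + g[2] * (2 * grr - 1))
        return (2 * grr - 1) * f0 - 1.0

    if infeasibility(hi) > 0:
        hi = brentq(infeasibility, lo, hi, xtol=1e-9) - 1e-9
    if gap(hi) < 0:
        raise ValueError(f"target power {target} unreachable with grr <= {hi:.3g}")
    if gap(lo) >= 0:
        return round(lo, 2)
    grr = brentq(gap, lo, hi, xtol=tol)
    # smallest two-decimal GRR that still attains the target
    return float(np.ceil(grr * 100 - 1e-7) / 100)
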