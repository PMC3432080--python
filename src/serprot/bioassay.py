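"""Probit dose-mortality regression and LC50 with Fieller confidence limits.

The model is the classical insecticide bioassay probit: for dose d > 0,
P(death) = Phi(alpha + beta * log10 d), fitted by maximum likelihood on
grouped binomial data via Fisher scoring (with step halving, so the
log-likelihood never decreases).  LC50 = 10^(-alpha/beta); its interval is
the Fieller solution for the ratio -alpha/beta back-transformed from log10.
Probits are modern (no archaic +5 offset).  A zero-dose control group is
excluded from the fit rather than Abbott-corrected, the appropriate choice
when control mortality is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class DoseGroup:
    dose: float  # concentration, e.g. ug/ml
    n: int
    dead: int

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if not 0 <= self.dead <= self.n:
            raise ValueError("dead count outside [0, n]")


@dataclass(frozen=True)
class ProbitFit:
    intercept: float  # probit units at log10(dose) = 0
    slope: float  # probit units per log10(dose)
    lc50: float
    ci_low: float
    ci_high: float
    ci_unbounded: bool
    g: float  # Fieller criterion z^2 Var(beta) / beta^2
    vcov: np.ndarray
    converged: bool
    iterations: int
    log_likelihood: float


class SeparationError(ValueError):
    """No finite MLE: the dose groups carry no partial response."""


def _loglik(a: float, b: float, x: np.ndarray, n: np.ndarray, dead: np.ndarray) -> float:
    eta = a + b * x
    p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(dead * np.log(p) + (n - dead) * np.log1p(-p)))


def fit_probit(
    groups: Sequence[DoseGroup],
    *,
    max_iter: int = 200,
    grad_tol: float = 1e-8,
    ci_level: float = 0.95,
) -> ProbitFit:
    """Maximum-likelihood probit fit on log10(dose); controls (dose 0) excluded."""
    pos = [g for g in groups if g.dose > 0]
    if len(pos) < 2:
        raise ValueError("need at least 2 groups with dose > 0")
    x = np.log10([g.dose for g in pos])
    n = np.array([g.n for g in pos], dtype=float)
    dead = np.array([g.dead for g in pos], dtype=float)
    if dead.sum() == 0 or (n - dead).sum() == 0:
        raise SeparationError("all-or-none mortality across every dose: no finite MLE")

    # starting values: least squares on empirical probits (counts shrunk off 0/1)
    p_emp = (dead + 0.5) / (n + 1.0)
    probits = stats.norm.ppf(p_emp)
    b = np.polyfit(x, probits, 1)
    a, b = float(b[1]), float(b[0])

    ll = _loglik(a, b, x, n, dead)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        eta = a + b * x
        p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
        phi = stats.norm.pdf(eta)
        w = n * phi**2 / (p * (1 - p))
        score_common = (dead - n * p) * phi / (p * (1 - p))
        grad = np.array([score_common.sum(), (score_common * x).sum()])
        if np.linalg.norm(grad) < grad_tol:
            converged = True
            break
        info = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(40):
            ll_new = _loglik(a + scale * step[0], b + scale * step[1], x, n, dead)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        a += scale * step[0]
        b += scale * step[1]
        assert ll_new >= ll - 1e-9, "log-likelihood decreased during Fisher scoring"
        ll = ll_new

    eta = a + b * x
    p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
    phi = stats.norm.pdf(eta)
    w = n * phi**2 / (p * (1 - p))
    info = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
    vcov = np.linalg.inv(info)
    if b == 0:
        raise SeparationError("zero slope: LC50 undefined")
    lc50 = 10.0 ** (-a / b)
    lo, hi, unbounded, g = _fieller(a, b, vcov, ci_level)
    return ProbitFit(
        intercept=a,
        slope=b,
        lc50=lc50,
        ci_low=lo,
        ci_high=hi,
        ci_unbounded=unbounded,
        g=g,
        vcov=vcov,
        converged=converged,
        iterations=it,
        log_likelihood=ll,
    )


def _fieller(a: float, b: float, vcov: np.ndarray, level: float) -> tuple[float, float, bool, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    vaa, vab, vbb = vcov[0, 0], vcov[0, 1], vcov[1, 1]
    g = z**2 * vbb / b**2
    # roots of (a + b m)^2 = z^2 (vaa + 2 m vab + m^2 vbb) in m = log10 LC50
    qa = b**2 - z**2 * vbb
    qb = 2.0 * (a * b - z**2 * vab)
    qc = a**2 - z**2 * vaa
    disc = qb**2 - 4.0 * qa * qc
    if g >= 1.0 or qa <= 0 or disc < 0:
        return 0.0, math.inf, True, g
    r1 = (-qb - math.sqrt(disc)) / (2.0 * qa)
    r2 = (-qb + math.sqrt(disc)) / (2.0 * qa)
    lo, hi = sorted((r1, r2))
    return 10.0**lo, 10.0**hi, False, g


def lc50_ci(fit: ProbitFit, level: float = 0.95) -> tuple[float, float]:
    """Fieller confidence limits for LC50 at another level, from a stored fit."""
    if not fit.converged:
        raise ValueError("confidence limits require a converged fit")
    lo, hi, _, _ = _fieller(fit.intercept, fit.slope, fit.vcov, level)
    return lo, hi


def fit_report(fit: ProbitFit, *, unit: str = "ug/ml") -> str:
    """Human-readable summary of a probit fit."""
    ci = "unbounded (Fieller g >= 1)" if fit.ci_unbounded else f"{fit.ci_low:.3g}-{fit.ci_high:.3g} {unit}"
    return (
        f"probit regression on log10(dose)\n"
        f"  intercept {fit.intercept:.4f}, slope {fit.slope:.4f} probit/log10\n"
        f"  LC50 {fit.lc50:.3g} {unit} (95% CI {ci})\n"
        f"  converged={fit.converged} after {fit.iterations} iterations, logL={fit.log_likelihood:.3f}"
    )
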