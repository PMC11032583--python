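"""Class-conditional density fitting by maximum likelihood.

Two families are supported, matching the modelling choices made for the
plasma biomarkers: the Abeta42/40 ratio is well approximated by a normal
distribution within each CSF A/T class, while p-tau181 concentrations are
right-skewed and better approximated by a gamma distribution.

Normal MLE is closed form (sigma uses the MLE divisor n, not n-1, for
likelihood consistency; published per-group SDs are sample SDs, so the two
differ by the usual factor sqrt((n-1)/n)). Gamma MLE profiles the
likelihood on the shape: with the scale concentrated out
(scale = xbar / shape), the shape solves

    log(shape) - digamma(shape) = log(xbar) - mean(log x),

which is solved by bracketed root-finding from a moment-matched start. If
the root-finder fails the fit falls back to moment matching and flags it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .errors import FitError

__all__ = [
    "DensityFit",
    "GoFReport",
    "fit_normal",
    "fit_gamma",
    "fit_family",
    "evaluate_density",
    "goodness_of_fit",
]

_GRAD_TOL = 1e-8


@dataclass
class DensityFit:
    """A fitted class-conditional density.

    params is (mu, sigma) for the normal family and (shape, scale) for the
    gamma family. loglik is the natural-log likelihood at the MLE and
    aic = 2k - 2*loglik with k = 2 parameters for both families.
    """

    family: str  # "normal" | "gamma"
    params: tuple[float, float]
    n: int
    loglik: float
    aic: float
    converged: bool = True
    moment_fallback: bool = False

    def pdf(self, x):
        return evaluate_density(self, x)

    def cdf(self, x):
        if self.family == "normal":
            mu, sigma = self.params
            return stats.norm.cdf(x, mu, sigma)
        shape, scale = self.params
        return stats.gamma.cdf(x, shape, scale=scale)

    def ppf(self, q):
        if self.family == "normal":
            mu, sigma = self.params
            return stats.norm.ppf(q, mu, sigma)
        shape, scale = self.params
        return stats.gamma.ppf(q, shape, scale=scale)

    @property
    def mean(self) -> float:
        if self.family == "normal":
            return self.params[0]
        return self.params[0] * self.params[1]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": list(self.params),
            "n": self.n,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "moment_fallback": self.moment_fallback,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "DensityFit":
        return cls(family=d["family"], params=tuple(d["params"]), n=d["n"],
                   loglik=d["loglik"], aic=d["aic"],
                   converged=d.get("converged", True),
                   moment_fallback=d.get("moment_fallback", False))

    @classmethod
    def from_json(cls, text: str) -> "DensityFit":
        return cls.from_dict(json.loads(text))


@dataclass
class GoFReport:
    """Goodness-of-fit diagnostics: KS distance plus Q-Q / P-P coordinates."""

    ks_stat: float
    qq_points: np.ndarray  # (n, 2): theoretical vs empirical quantiles
    pp_points: np.ndarray  # (n, 2): empirical vs fitted CDF
    cdf_table: np.ndarray  # (m, 3): x, empirical CDF, fitted CDF


def _as_values(values, min_n: int = 2) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_n:
        raise FitError(f"need at least {min_n} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise FitError("values must be finite")
    return x


def fit_normal(values) -> DensityFit:
    """Fit a normal density by maximum likelihood."""
    x = _as_values(values)
    mu = float(np.mean(x))
    sigma = float(np.std(x))  # MLE: divisor n
    if sigma <= 0.0:
        raise FitError("zero variance: normal MLE undefined")
    n = x.size
    loglik = float(np.sum(stats.norm.logpdf(x, mu, sigma)))
    return DensityFit("normal", (mu, sigma), n, loglik, 4.0 - 2.0 * loglik)


def fit_gamma(values) -> DensityFit:
    """Fit a gamma density (shape/scale) by profile-likelihood MLE."""
    x = _as_values(values)
    if np.any(x <= 0.0):
        raise FitError("gamma fit requires strictly positive values")
    xbar = float(np.mean(x))
    s = math.log(xbar) - float(np.mean(np.log(x)))
    if s <= 0.0:
        raise FitError("degenerate sample: log-moment gap non-positive")
    shape0 = float((xbar / np.std(x)) ** 2) if np.std(x) > 0 else 1.0

    def grad(a):  # d/da of profile log-likelihood, up to factor n
        return math.log(a) - special.digamma(a) - s

    converged = True
    fallback = False
    try:
        lo, hi = shape0, shape0
        while grad(lo) < 0:
            lo /= 2.0
            if lo < 1e-12:
                raise FitError("gamma shape bracket collapsed")
        while grad(hi) > 0:
            hi *= 2.0
            if hi > 1e12:
                raise FitError("gamma shape bracket diverged")
        shape = float(optimize.brentq(grad, lo, hi, xtol=1e-14, rtol=8.9e-16))
        if abs(grad(shape)) > _GRAD_TOL:
            converged = False
    except (FitError, ValueError):
        # Moment-matched fallback, flagged on the fit.
        shape, converged, fallback = shape0, False, True
    scale = xbar / shape
    n = x.size
    loglik = float(np.sum(stats.gamma.logpdf(x, shape, scale=scale)))
    return DensityFit("gamma", (shape, scale), n, loglik, 4.0 - 2.0 * loglik,
                      converged=converged, moment_fallback=fallback)


def fit_family(values, family: str) -> DensityFit:
    """Dispatch to :func:`fit_normal` or :func:`fit_gamma` by name."""
    if family == "normal":
        return fit_normal(values)
    if family == "gamma":
        return fit_gamma(values)
    raise FitError(f"unknown family {family!r}; expected 'normal' or 'gamma'")


def evaluate_density(fit: DensityFit, x):
    """Probability density of the fit at x (0 outside the gamma support)."""
    x = np.asarray(x, dtype=float)
    if fit.family == "normal":
        mu, sigma = fit.params
        out = stats.norm.pdf(x, mu, sigma)
    else:
        shape, scale = fit.params
        out = np.where(x > 0.0, stats.gamma.pdf(np.maximum(x, 1e-300), shape,
                                                scale=scale), 0.0)
    return float(out) if out.ndim == 0 else out


def goodness_of_fit(fit: DensityFit, values, cdf_grid: int = 100) -> GoFReport:
    """KS statistic plus Q-Q, P-P and CDF-comparison coordinates.

    Q-Q points use plotting positions (i - 0.5)/n; P-P points pair the
    empirical CDF at each order statistic with the fitted CDF there.
    """
    x = np.sort(_as_values(values, min_n=10))
    n = x.size
    pp_emp = (np.arange(1, n + 1) - 0.5) / n
    fitted_cdf = fit.cdf(x)
    # KS: sup over both one-sided gaps at the jumps of the empirical CDF
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    ks = float(max(np.max(ecdf_hi - fitted_cdf), np.max(fitted_cdf - ecdf_lo)))
    qq = np.column_stack([fit.ppf(pp_emp), x])
    pp = np.column_stack([pp_emp, fitted_cdf])
    grid = np.linspace(x[0], x[-1], cdf_grid)
    emp_at_grid = np.searchsorted(x, grid, side="right") / n
    table = np.column_stack([grid, emp_at_grid, fit.cdf(grid)])
    return GoFReport(ks_stat=ks, qq_points=qq, pp_points=pp, cdf_table=table)
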