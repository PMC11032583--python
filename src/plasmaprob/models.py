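"""Probability-based classifiers for CSF A/T status from plasma biomarkers.

The central construction: fit a class-conditional density to a biomarker in
the positive class and in the negative class, then convert a measured value
x to the two-class posterior

    p(x) = pi_pos * f_pos(x) / (pi_pos * f_pos(x) + pi_neg * f_neg(x)),

with equal class priors by default. The biomarker value where p(x) crosses
a probability level (0.5 for the working cutoff; 0.1/0.3/0.7/0.9 for the
reported probability bands) is found by bracketed root-finding on the
monotone branch of the posterior between the two class means. With unequal
variances the posterior has a second, extraneous crossing far in the tail
of the wider class; bracketing between the means selects the clinically
meaningful root and the extraneous one is ignored.

Two contrasts are modelled: A+ versus A- (driven by the Abeta42/40 ratio)
and A+/T+ versus not A+/T+ (driven by p-tau181). A bivariate classifier
mixes the two univariate posteriors as k*p_ratio + (1-k)*p_ptau, with k
chosen by grid search maximizing mean held-out accuracy under stratified
100-fold cross-validation. Serial application of the two bivariate models
yields the trinomial A+/T+ / A+/T- / A-/T+- profile call.

Estimators follow the scikit-learn protocol (fit / predict /
predict_proba, fitted attributes with trailing underscores) and compose
with sklearn model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .densities import DensityFit, fit_family
from .errors import ClassificationError, TrainingError

__all__ = [
    "CONTRASTS",
    "Contrast",
    "CutoffTable",
    "ClassificationResult",
    "TrinomialResult",
    "DensityPosteriorClassifier",
    "WeightedPosteriorClassifier",
    "SerialTrinomialClassifier",
    "combine_bivariate",
    "train_univariate",
    "train_bivariate",
    "posterior_probability",
    "solve_cutoffs",
    "classify_binomial",
    "classify_trinomial",
    "isoprobability_curve",
]

DEFAULT_EXCLUSION_ZONE = (0.3, 0.7)
#: k grid at the resolution of the published mixing constants (3 decimals).
DEFAULT_K_GRID = np.round(np.arange(0.0, 1.0005, 0.001), 3)

#: Default density family per (biomarker, side); the ratio is modelled as
#: normal and p-tau181 as gamma in BOTH classes of BOTH contrasts.
DEFAULT_FAMILIES = {"ratio": ("normal", "normal"), "ptau181": ("gamma", "gamma")}


@dataclass(frozen=True)
class Contrast:
    """A binary contrast over CSF A/T status."""

    name: str
    positive: Callable[[pd.DataFrame], pd.Series]
    description: str

    def labels(self, df: pd.DataFrame) -> np.ndarray:
        """0/1 labels (1 = positive class) for records with known status."""
        return self.positive(df).to_numpy().astype(int)


CONTRASTS = {
    "A+vsA-": Contrast(
        "A+vsA-",
        lambda df: df["a_status"] == "A+",
        "amyloid-positive versus amyloid-negative",
    ),
    "A+T+vsRest": Contrast(
        "A+T+vsRest",
        lambda df: (df["a_status"] == "A+") & (df["t_status"] == "T+"),
        "A+/T+ versus every other A/T profile",
    ),
}


@dataclass
class ClassificationResult:
    probability: float
    label: str  # "positive" | "negative"
    uncertain: bool


@dataclass
class TrinomialResult:
    p_at: float
    p_a: float | None  # evaluated only when the A+/T+ stage is negative
    label: str  # "A+/T+" | "A+/T-" | "A-/T±"
    uncertain: bool


@dataclass
class CutoffTable:
    """Biomarker thresholds at fixed classification-probability levels."""

    biomarker: str
    contrast: str
    orientation: str
    levels: dict[float, float | None]  # None = level unattained

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "level": list(self.levels),
            "threshold": [self.levels[l] for l in self.levels],
            "orientation": self.orientation,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def combine_bivariate(p_ratio, p_ptau, k: float):
    """Weighted average of the two univariate posteriors."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("k must lie in [0, 1]")
    return k * np.asarray(p_ratio) + (1.0 - k) * np.asarray(p_ptau)


def _column(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2:
        if x.shape[1] != 1:
            raise ValueError("univariate classifier expects a single column")
        x = x[:, 0]
    return x


class DensityPosteriorClassifier(ClassifierMixin, BaseEstimator):
    """Univariate classifier from class-conditional densities.

    Parameters
    ----------
    family_pos, family_neg : {"normal", "gamma"}
        Density family fitted to the positive / negative class.
    priors : (float, float)
        (pi_pos, pi_neg); must sum to 1. Equal priors by default — the
        published p = 0.5 cutoffs correspond to the equal-prior density
        crossing, not the prevalence-weighted one.
    min_class_size : int
        Minimum records per class required to fit.

    Fitted attributes: ``pos_fit_``, ``neg_fit_`` (DensityFit),
    ``orientation_`` ("positive_low" if the positive-class mean is below
    the negative-class mean, else "positive_high"), ``classes_``.
    """

    def __init__(self, family_pos: str = "normal", family_neg: str = "normal",
                 priors: tuple[float, float] = (0.5, 0.5),
                 min_class_size: int = 10):
        self.family_pos = family_pos
        self.family_neg = family_neg
        self.priors = priors
        self.min_class_size = min_class_size

    def fit(self, X, y):
        x = _column(X)
        y = np.asarray(y).astype(int)
        if x.shape[0] != y.shape[0]:
            raise TrainingError("X and y length mismatch")
        if abs(self.priors[0] + self.priors[1] - 1.0) > 1e-9:
            raise TrainingError("priors must sum to 1")
        pos, neg = x[y == 1], x[y == 0]
        if len(pos) < self.min_class_size or len(neg) < self.min_class_size:
            raise TrainingError(
                f"each class needs >= {self.min_class_size} records "
                f"(got {len(pos)} positive, {len(neg)} negative)"
            )
        self.pos_fit_ = fit_family(pos, self.family_pos)
        self.neg_fit_ = fit_family(neg, self.family_neg)
        self.orientation_ = ("positive_low"
                             if self.pos_fit_.mean < self.neg_fit_.mean
                             else "positive_high")
        self.classes_ = np.array([0, 1])
        return self

    def posterior(self, x):
        """Posterior probability of the positive class at biomarker value x."""
        check_is_fitted(self, "pos_fit_")
        x = np.asarray(x, dtype=float)
        pi_pos, pi_neg = self.priors
        num = pi_pos * self.pos_fit_.pdf(x)
        den = num + pi_neg * self.neg_fit_.pdf(x)
        with np.errstate(invalid="ignore"):
            p = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), np.nan)
        if np.any(np.isnan(p)):
            raise ClassificationError(
                "both class densities vanish at the requested value; "
                "posterior undefined"
            )
        return float(p) if p.ndim == 0 else p

    def predict_proba(self, X):
        p = np.atleast_1d(self.posterior(_column(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # -- probability-level cutoffs ------------------------------------

    def _posterior_scalar(self, x: float) -> float:
        return self.posterior(np.array(x))

    def solve_cutoff(self, level: float) -> float | None:
        """Biomarker value where the posterior equals ``level``.

        The p = 0.5 root is bracketed between the two class means; other
        levels are reached by extending the bracket monotonically outward
        from that root. Returns None when the level is not attained on the
        monotone branch (e.g. beyond the gamma support boundary).
        """
        check_is_fitted(self, "pos_fit_")
        if not 0.0 < level < 1.0:
            raise ValueError("level must lie strictly inside (0, 1)")
        m_pos, m_neg = self.pos_fit_.mean, self.neg_fit_.mean
        lo, hi = sorted((m_pos, m_neg))
        g = self._posterior_scalar

        def root(a: float, b: float, lvl: float) -> float:
            return float(optimize.brentq(lambda t: g(t) - lvl, a, b,
                                         xtol=1e-300, rtol=1e-12, maxiter=300))

        if not (g(lo) - 0.5) * (g(hi) - 0.5) < 0:
            raise TrainingError(
                "posterior does not cross 0.5 between the class means; "
                "classes too similar for a probability cutoff"
            )
        x05 = root(lo, hi, 0.5)
        if level == 0.5:
            return x05

        increasing = self.orientation_ == "positive_high"
        # step toward the positive side for levels above 0.5, negative below
        toward_pos = (level > 0.5)
        step_right = toward_pos == increasing
        step = max(hi - lo, 1e-6 * max(abs(hi), 1.0))
        a = x05
        support_lo = 0.0 if "gamma" in (self.family_pos, self.family_neg) else -np.inf
        for _ in range(60):
            b = a + step if step_right else a - step
            if b <= support_lo:
                b = support_lo + 1e-12 * max(step, 1.0)
                if b >= a:
                    return None
            try:
                ga, gb = g(a), g(b)
            except ClassificationError:
                return None
            if (ga - level) * (gb - level) <= 0:
                return root(*sorted((a, b)), level)
            a, step = b, step * 2.0
            if not step_right and a <= support_lo + 1e-12:
                return None
        return None

    def cutoff_table(self, levels: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
                     biomarker: str = "", contrast: str = "") -> CutoffTable:
        cuts = {float(l): self.solve_cutoff(float(l)) for l in levels}
        return CutoffTable(biomarker=biomarker, contrast=contrast,
                           orientation=self.orientation_, levels=cuts)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "pos_fit_")
        return {
            "kind": "univariate",
            "family_pos": self.family_pos, "family_neg": self.family_neg,
            "priors": list(self.priors), "min_class_size": self.min_class_size,
            "pos_fit": self.pos_fit_.to_dict(), "neg_fit": self.neg_fit_.to_dict(),
            "orientation": self.orientation_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DensityPosteriorClassifier":
        m = cls(family_pos=d["family_pos"], family_neg=d["family_neg"],
                priors=tuple(d["priors"]), min_class_size=d["min_class_size"])
        m.pos_fit_ = DensityFit.from_dict(d["pos_fit"])
        m.neg_fit_ = DensityFit.from_dict(d["neg_fit"])
        m.orientation_ = d["orientation"]
        m.classes_ = np.array([0, 1])
        return m


class WeightedPosteriorClassifier(ClassifierMixin, BaseEstimator):
    """Bivariate classifier mixing the ratio and p-tau181 posteriors.

    Expects X with two columns, ``[ratio, ptau181]``. The mixing constant k
    weights the Abeta42/40 posterior: p = k*p_ratio + (1-k)*p_ptau. When
    ``k`` is None it is selected by grid search maximizing mean held-out
    accuracy over ``n_folds`` stratified folds (densities refit on each
    fold's training part; ties broken toward the smallest k).
    """

    def __init__(self, k: float | None = None,
                 k_grid: np.ndarray | None = None, n_folds: int = 100,
                 priors: tuple[float, float] = (0.5, 0.5),
                 ratio_families: tuple[str, str] = ("normal", "normal"),
                 ptau_families: tuple[str, str] = ("gamma", "gamma"),
                 min_class_size: int = 10, random_state: int | None = None):
        self.k = k
        self.k_grid = k_grid
        self.n_folds = n_folds
        self.priors = priors
        self.ratio_families = ratio_families
        self.ptau_families = ptau_families
        self.min_class_size = min_class_size
        self.random_state = random_state

    def _fit_submodels(self, X, y) -> tuple[DensityPosteriorClassifier,
                                            DensityPosteriorClassifier]:
        ratio = DensityPosteriorClassifier(*self.ratio_families,
                                           priors=self.priors,
                                           min_class_size=self.min_class_size)
        ptau = DensityPosteriorClassifier(*self.ptau_families,
                                          priors=self.priors,
                                          min_class_size=self.min_class_size)
        ratio.fit(X[:, 0], y)
        ptau.fit(X[:, 1], y)
        return ratio, ptau

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise TrainingError("expected X with two columns [ratio, ptau181]")
        y = np.asarray(y).astype(int)
        grid = DEFAULT_K_GRID if self.k_grid is None else np.asarray(self.k_grid)

        if self.k is None:
            self.k_, self.cv_accuracy_ = self._grid_search(X, y, grid)
        else:
            if not 0.0 <= self.k <= 1.0:
                raise TrainingError("k must lie in [0, 1]")
            self.k_, self.cv_accuracy_ = float(self.k), None
        self.ratio_model_, self.ptau_model_ = self._fit_submodels(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def _grid_search(self, X, y, grid) -> tuple[float, np.ndarray]:
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.random_state)
        try:
            folds = list(skf.split(X, y))
        except ValueError as e:
            raise TrainingError(
                f"cannot form {self.n_folds} stratified folds: {e}; "
                "reduce n_folds"
            ) from e
        fold_acc = np.zeros((len(folds), len(grid)))
        for i, (tr, te) in enumerate(folds):
            ytr = y[tr]
            if np.bincount(ytr, minlength=2).min() < self.min_class_size:
                raise TrainingError(
                    "a fold's training part has fewer than "
                    f"{self.min_class_size} records in one class; reduce n_folds"
                )
            ratio, ptau = self._fit_submodels(X[tr], ytr)
            p_r = ratio.posterior(X[te, 0])
            p_p = ptau.posterior(X[te, 1])
            # accuracy for every k at once: (n_te, nk) mixed probabilities
            mixed = np.outer(p_r, grid) + np.outer(p_p, 1.0 - grid)
            pred = mixed >= 0.5
            fold_acc[i] = (pred == y[te][:, None]).mean(axis=0)
        mean_acc = fold_acc.mean(axis=0)
        best = int(np.argmax(mean_acc))  # first argmax -> smallest k on ties
        return float(grid[best]), mean_acc

    def posterior(self, X):
        check_is_fitted(self, "ratio_model_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != 2:
            raise ClassificationError("expected columns [ratio, ptau181]")
        if np.any(~np.isfinite(X)):
            raise ClassificationError("missing biomarker value in input")
        p_r = self.ratio_model_.posterior(X[:, 0])
        p_p = self.ptau_model_.posterior(X[:, 1])
        return combine_bivariate(p_r, p_p, self.k_)

    def predict_proba(self, X):
        p = np.atleast_1d(self.posterior(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def to_dict(self) -> dict:
        check_is_fitted(self, "ratio_model_")
        return {
            "kind": "bivariate",
            "k": self.k_,
            "n_folds": self.n_folds,
            "priors": list(self.priors),
            "ratio_model": self.ratio_model_.to_dict(),
            "ptau_model": self.ptau_model_.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightedPosteriorClassifier":
        m = cls(k=d["k"], n_folds=d.get("n_folds", 100), priors=tuple(d["priors"]))
        m.k_ = float(d["k"])
        m.cv_accuracy_ = None
        m.ratio_model_ = DensityPosteriorClassifier.from_dict(d["ratio_model"])
        m.ptau_model_ = DensityPosteriorClassifier.from_dict(d["ptau_model"])
        m.classes_ = np.array([0, 1])
        return m


class SerialTrinomialClassifier(ClassifierMixin, BaseEstimator):
    """Trinomial A/T-profile caller from two bivariate models in series.

    Stage 1 applies the A+/T+ versus rest model; a positive call stops
    there ("A+/T+"). Otherwise stage 2 applies the A+ versus A- model to
    separate "A+/T-" from "A-/T±". A result is flagged uncertain when any
    evaluated stage's probability falls inside the exclusion zone.
    """

    LABELS = ("A+/T+", "A+/T-", "A-/T±")

    def __init__(self, model_at: WeightedPosteriorClassifier | None = None,
                 model_a: WeightedPosteriorClassifier | None = None,
                 exclusion_zone: tuple[float, float] = DEFAULT_EXCLUSION_ZONE,
                 n_folds: int = 100, random_state: int | None = None):
        self.model_at = model_at
        self.model_a = model_a
        self.exclusion_zone = exclusion_zone
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, X, y=None, *, a_status=None, t_status=None):
        """Fit both stage models.

        Either pass ``y`` as stratum-style labels ("A+/T+", "A+/T-", ...)
        or pass ``a_status``/``t_status`` arrays of "A+"/"A-", "T+"/"T-".
        Pre-fitted stage models given at construction are used as-is.
        """
        X = np.asarray(X, dtype=float)
        if a_status is None or t_status is None:
            if y is None:
                raise TrainingError("need y stratum labels or a_status/t_status")
            y = np.asarray(y)
            a_status = np.where(np.char.startswith(y.astype(str), "A+"), "A+", "A-")
            t_status = np.where(np.char.endswith(y.astype(str), "T+"), "T+", "T-")
        a_status = np.asarray(a_status)
        t_status = np.asarray(t_status)
        y_at = ((a_status == "A+") & (t_status == "T+")).astype(int)
        y_a = (a_status == "A+").astype(int)
        if self.model_at is None:
            self.model_at_ = WeightedPosteriorClassifier(
                n_folds=self.n_folds, random_state=self.random_state).fit(X, y_at)
        else:
            self.model_at_ = self.model_at
        if self.model_a is None:
            self.model_a_ = WeightedPosteriorClassifier(
                n_folds=self.n_folds, random_state=self.random_state).fit(X, y_a)
        else:
            self.model_a_ = self.model_a
        self.classes_ = np.array(self.LABELS)
        return self

    def predict_detail(self, X) -> list[TrinomialResult]:
        check_is_fitted(self, "model_at_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        lo, hi = self.exclusion_zone
        out = []
        p_at_all = np.atleast_1d(self.model_at_.posterior(X))
        for i, p_at in enumerate(p_at_all):
            p_at = float(p_at)
            uncertain = lo <= p_at <= hi
            if p_at >= 0.5:
                out.append(TrinomialResult(p_at, None, "A+/T+", uncertain))
                continue
            p_a = float(np.atleast_1d(self.model_a_.posterior(X[i]))[0])
            uncertain = uncertain or (lo <= p_a <= hi)
            label = "A+/T-" if p_a >= 0.5 else "A-/T±"
            out.append(TrinomialResult(p_at, p_a, label, uncertain))
        return out

    def predict(self, X):
        return np.array([r.label for r in self.predict_detail(X)])


# ---------------------------------------------------------------------------
# Functional wrappers over the estimators (spec-shaped operation surface)

def train_univariate(cohort: pd.DataFrame, contrast: str | Contrast,
                     biomarker: str, family_pos: str | None = None,
                     family_neg: str | None = None,
                     priors: tuple[float, float] = (0.5, 0.5),
                     ) -> DensityPosteriorClassifier:
    """Fit a univariate posterior classifier from a tidy cohort table.

    Records with unknown A/T status are dropped. Default families are
    normal/normal for the ratio and gamma/gamma for p-tau181.
    """
    c = CONTRASTS[contrast] if isinstance(contrast, str) else contrast
    fams = DEFAULT_FAMILIES.get(biomarker, ("normal", "normal"))
    family_pos = family_pos or fams[0]
    family_neg = family_neg or fams[1]
    df = _known_status(cohort)
    model = DensityPosteriorClassifier(family_pos, family_neg, priors=priors)
    return model.fit(df[biomarker].to_numpy(), c.labels(df))


def train_bivariate(cohort: pd.DataFrame, contrast: str | Contrast,
                    k_grid: np.ndarray | None = None, n_folds: int = 100,
                    seed: int | None = None,
                    priors: tuple[float, float] = (0.5, 0.5),
                    ) -> WeightedPosteriorClassifier:
    """Fit the bivariate (ratio + p-tau181) classifier with CV-selected k."""
    c = CONTRASTS[contrast] if isinstance(contrast, str) else contrast
    df = _known_status(cohort)
    X = df[["ratio", "ptau181"]].to_numpy()
    model = WeightedPosteriorClassifier(k_grid=k_grid, n_folds=n_folds,
                                        priors=priors, random_state=seed)
    return model.fit(X, c.labels(df))


def _known_status(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[(cohort["a_status"] != "unknown")
                  & (cohort["t_status"] != "unknown")]


def posterior_probability(model: DensityPosteriorClassifier, x):
    """Posterior probability of the positive class at biomarker value x."""
    return model.posterior(x)


def solve_cutoffs(model: DensityPosteriorClassifier,
                  levels: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
                  biomarker: str = "", contrast: str = "") -> CutoffTable:
    """Biomarker thresholds where the posterior equals each level."""
    return model.cutoff_table(levels, biomarker=biomarker, contrast=contrast)


def classify_binomial(model, x,
                      exclusion_zone: tuple[float, float] = DEFAULT_EXCLUSION_ZONE,
                      ) -> ClassificationResult:
    """Classify one record; ties at p = 0.5 go to the positive class."""
    p = float(np.atleast_1d(model.posterior(x))[0])
    lo, hi = exclusion_zone
    return ClassificationResult(
        probability=p,
        label="positive" if p >= 0.5 else "negative",
        uncertain=lo <= p <= hi,
    )


def classify_trinomial(model_at: WeightedPosteriorClassifier,
                       model_a: WeightedPosteriorClassifier, x,
                       exclusion_zone: tuple[float, float] = DEFAULT_EXCLUSION_ZONE,
                       ) -> TrinomialResult:
    """Serial two-stage A/T-profile call for one record."""
    clf = SerialTrinomialClassifier(model_at=model_at, model_a=model_a,
                                    exclusion_zone=exclusion_zone)
    clf.model_at_, clf.model_a_ = model_at, model_a
    clf.classes_ = np.array(SerialTrinomialClassifier.LABELS)
    return clf.predict_detail(np.atleast_2d(np.asarray(x, dtype=float)))[0]


def isoprobability_curve(model: WeightedPosteriorClassifier, level: float,
                         ratio_range: tuple[float, float],
                         ptau_range: tuple[float, float],
                         grid_n: int = 100) -> np.ndarray:
    """(ratio, ptau181) points where the bivariate probability equals level.

    Solved along one axis per grid line: for k > 0 the ratio is solved for
    each p-tau grid value (the required univariate ratio-posterior level is
    (level - (1-k)*p_ptau)/k); for k = 0 the p-tau value is solved on ratio
    grid lines instead. Returns an (m, 2) array ordered along the grid;
    empty when the level is attained nowhere in the box.
    """
    check_is_fitted(model, "ratio_model_")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    k = model.k_
    pts: list[tuple[float, float]] = []
    if k > 0.0:
        grid = np.linspace(ptau_range[0], ptau_range[1], grid_n)
        for ptau in grid:
            p_p = float(np.atleast_1d(model.ptau_model_.posterior(ptau))[0])
            needed = (level - (1.0 - k) * p_p) / k
            if not 0.0 < needed < 1.0:
                continue
            r = _solve_on_interval(model.ratio_model_, needed, ratio_range)
            if r is not None:
                pts.append((r, float(ptau)))
    else:
        grid = np.linspace(ratio_range[0], ratio_range[1], grid_n)
        t = _solve_on_interval(model.ptau_model_, level, ptau_range)
        if t is not None:
            pts = [(float(r), t) for r in grid]
    return np.array(pts).reshape(-1, 2)


def _solve_on_interval(model: DensityPosteriorClassifier, level: float,
                       rng: tuple[float, float]) -> float | None:
    """Root of posterior(x) = level restricted to [rng[0], rng[1]]."""
    x = model.solve_cutoff(level)
    if x is None or not rng[0] <= x <= rng[1]:
        return None
    return x


# ---------------------------------------------------------------------------
# Model JSON round-trip

def model_to_json(model, **provenance) -> str:
    d = model.to_dict()
    d["version"] = 1
    d.update(provenance)
    return json.dumps(d, indent=2, sort_keys=True)


def model_from_json(text: str):
    d = json.loads(text)
    if d["kind"] == "univariate":
        return DensityPosteriorClassifier.from_dict(d)
    if d["kind"] == "bivariate":
        return WeightedPosteriorClassifier.from_dict(d)
    raise ValueError(f"unknown model kind {d.get('kind')!r}")
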