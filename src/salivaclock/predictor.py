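"""Marker-based age regression, leave-one-out evaluation, lasso screening.

A small panel of CpG markers — beta values, optionally with a squared term —
predicts chronological age by ordinary least squares.  Predictive accuracy is
estimated by leave-one-out cross-validation (refit on n−1, predict the held
out sample; mean absolute error in years).  Candidate markers are screened by
lasso-penalized regression over a decreasing λ path and pruned to the terms
that contribute significantly to the joint model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import lasso_path
from sklearn.utils.validation import check_is_fitted

from .io import BetaMatrix, ValidationError

__all__ = [
    "MarkerSpec",
    "AgeModel",
    "LooResult",
    "MarkerAgeRegressor",
    "fit_age_model",
    "loo_evaluate",
    "lasso_screen",
    "significance_prune",
]


@dataclass(frozen=True)
class MarkerSpec:
    """Ordered marker panel; ``include_square`` adds a beta² term for a marker."""

    markers: tuple[tuple[str, bool], ...]

    def __post_init__(self):
        if len(self.markers) == 0:
            raise ValidationError("marker spec needs >= 1 marker")
        ids = [m for m, _ in self.markers]
        if len(set(ids)) != len(ids):
            raise ValidationError("marker probes must be distinct")

    @classmethod
    def from_strings(cls, items: list[str]) -> "MarkerSpec":
        """Parse ``probe`` / ``probe^2`` strings ("^2" = add the squared term)."""
        return cls(tuple((s[:-2], True) if s.endswith("^2") else (s, False)
                         for s in items))

    @property
    def probe_ids(self) -> list[str]:
        return [m for m, _ in self.markers]

    @property
    def term_names(self) -> list[str]:
        names = []
        for m, sq in self.markers:
            names.append(m)
            if sq:
                names.append(f"{m}^2")
        return names

    def expand(self, X: np.ndarray) -> np.ndarray:
        """Expand a samples × markers array into the design (beta, beta² terms)."""
        cols = []
        for j, (_, sq) in enumerate(self.markers):
            cols.append(X[:, j])
            if sq:
                cols.append(X[:, j] ** 2)  # raw beta squared, not centered
        return np.column_stack(cols)


@dataclass
class AgeModel:
    """Fitted OLS age model: years = intercept + Σ coef · term."""

    intercept: float
    coefficients: dict[str, float]
    coefficient_pvalues: dict[str, float]
    n: int
    r_squared: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class LooResult:
    sample_ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    mae: float
    r: float
    p: float
    estimable: bool

    def to_dict(self) -> dict:
        return {
            "mae_years": self.mae,
            "r": self.r if self.estimable else None,
            "p": self.p if self.estimable else None,
            "n": len(self.sample_ids),
        }


class MarkerAgeRegressor(RegressorMixin, BaseEstimator):
    """OLS age regressor over marker betas with optional squared terms.

    ``include_square`` is a boolean per input column; ``fit`` takes X of
    shape (n_samples, n_markers) and y = ages in years.
    """

    def __init__(self, include_square: tuple[bool, ...] | None = None):
        self.include_square = include_square

    def _spec_for(self, n_cols: int) -> MarkerSpec:
        flags = self.include_square or tuple([False] * n_cols)
        if len(flags) != n_cols:
            raise ValidationError("include_square length must match marker count")
        return MarkerSpec(tuple((f"x{j}", bool(flags[j])) for j in range(n_cols)))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-d (samples × markers)")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValidationError("non-finite values in the design or response")
        spec = self._spec_for(X.shape[1])
        D = spec.expand(X)
        if X.shape[0] <= D.shape[1] + 1:
            raise ValidationError("need n > number of expanded terms + 1")
        design = sm.add_constant(D, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError(
                f"rank-deficient design; collinear terms among {spec.term_names}"
            )
        res = sm.OLS(y, design).fit()
        self.spec_ = spec
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.pvalues_ = np.asarray(res.pvalues[1:], dtype=float)
        self.r_squared_ = float(res.rsquared)
        self.n_ = int(X.shape[0])
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        D = self.spec_.expand(np.asarray(X, dtype=float))
        return self.intercept_ + D @ self.coef_


def _marker_matrix(bm: BetaMatrix, spec: MarkerSpec) -> np.ndarray:
    missing = [p for p in spec.probe_ids if p not in set(bm.probe_ids)]
    if missing:
        raise ValidationError(f"markers absent from the beta matrix: {missing}")
    return bm.data.loc[spec.probe_ids].to_numpy(float).T  # samples × markers


def fit_age_model(bm: BetaMatrix, ages, spec: MarkerSpec) -> AgeModel:
    """Fit age ~ marker betas (+ squared terms) by OLS."""
    X = _marker_matrix(bm, spec)
    reg = MarkerAgeRegressor(tuple(sq for _, sq in spec.markers)).fit(X, np.asarray(ages, float))
    return AgeModel(
        intercept=reg.intercept_,
        coefficients=dict(zip(spec.term_names, reg.coef_)),
        coefficient_pvalues=dict(zip(spec.term_names, reg.pvalues_)),
        n=reg.n_,
        r_squared=reg.r_squared_,
    )


def loo_evaluate(bm: BetaMatrix, ages, spec: MarkerSpec) -> LooResult:
    """Leave-one-out evaluation: refit on n−1 samples, predict the held-out one."""
    X = _marker_matrix(bm, spec)
    y = np.asarray(ages, dtype=float)
    D = spec.expand(X)
    n, k = D.shape
    if n < k + 3:
        raise ValidationError("need n >= number of expanded terms + 3")
    design = np.column_stack([np.ones(n), D])
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        A, b = design[keep], y[keep]
        if np.linalg.matrix_rank(A) < A.shape[1]:
            raise ValidationError(f"rank-deficient design in fold {i} (held-out sample "
                                  f"{bm.sample_ids[i]!r})")
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        preds[i] = design[i] @ coef
    mae = float(np.mean(np.abs(preds - y)))
    if np.std(preds) == 0 or np.std(y) == 0:
        return LooResult(bm.sample_ids, y, preds, mae, np.nan, np.nan, estimable=False)
    from scipy.stats import pearsonr

    r, p = pearsonr(preds, y)
    return LooResult(bm.sample_ids, y, preds, mae, float(r), float(p), estimable=True)


def lasso_screen(
    bm: BetaMatrix,
    ages,
    lambda_path: np.ndarray | None = None,
    top_k: int = 5,
) -> pd.DataFrame:
    """Rank probes by the λ at which they first enter the lasso solution.

    The objective is (1/(2n))·RSS + λ·Σ|coef| on internally standardized
    predictors and a centered response.  Probes entering at larger λ are
    stronger marginal predictors of age; the top ``top_k`` are returned
    (fewer if fewer ever enter the path).
    """
    X = bm.values.T  # samples × probes
    y = np.asarray(ages, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in predictors or ages")
    if X.shape[0] < 5:
        raise ValidationError("lasso screening needs n >= 5")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if (sd == 0).any():
        bad = bm.probe_ids[int(np.argmax(sd == 0))]
        raise ValidationError(f"constant probe {bad!r}; filter first")
    Xs = (X - mu) / sd
    yc = y - y.mean()
    n = len(y)
    lam_max = np.max(np.abs(Xs.T @ yc)) / n
    if lambda_path is None:
        lambda_path = lam_max * np.logspace(0, -3, 100)
    lambda_path = np.sort(np.asarray(lambda_path, float))[::-1]
    alphas, coefs, _ = lasso_path(Xs, yc, alphas=lambda_path)
    nonzero = np.abs(coefs) > 0
    entry = np.full(coefs.shape[0], -np.inf)
    for j in range(coefs.shape[0]):
        hits = np.flatnonzero(nonzero[j])
        if hits.size:
            entry[j] = alphas[hits[0]]  # alphas are decreasing; first hit = largest λ
    order = np.argsort(-entry, kind="stable")
    ranked = pd.DataFrame({
        "probe_id": np.asarray(bm.probe_ids)[order],
        "entry_lambda": entry[order],
    })
    ranked = ranked[np.isfinite(ranked["entry_lambda"])].head(top_k)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked.reset_index(drop=True)


def significance_prune(
    bm: BetaMatrix, ages, candidates: list[str], alpha: float = 0.05
) -> tuple[MarkerSpec | None, AgeModel | None]:
    """Keep candidate markers whose joint-OLS coefficient has p < alpha.

    Fits age on all candidates jointly, drops non-significant terms, and
    refits on the retained set.  Returns (None, None) with a warning when
    every candidate is pruned.
    """
    if not candidates:
        raise ValidationError("no candidate markers supplied")
    joint = MarkerSpec(tuple((c, False) for c in candidates))
    model = fit_age_model(bm, ages, joint)
    retained = [c for c in candidates if model.coefficient_pvalues[c] < alpha]
    if not retained:
        warnings.warn("all candidate markers pruned at alpha=%g" % alpha)
        return None, None
    spec = MarkerSpec(tuple((c, False) for c in retained))
    return spec, fit_age_model(bm, ages, spec)
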