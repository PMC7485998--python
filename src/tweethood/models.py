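"""Survey-weighted association models.

Two fitters, both authored here on top of plain linear algebra:

* weighted least squares for continuous BMI, with an HC0 sandwich
  (heteroskedasticity-robust) covariance that incorporates the weights;
* modified Poisson regression for binary outcomes — log-link Poisson
  estimating equations solved by IRLS — whose exponentiated coefficients
  are prevalence ratios.  The sandwich variance is mandatory here: the
  model-based Poisson variance is misspecified for 0/1 outcomes.

Weights act as sampling (survey) weights in the estimating equations, so
the sandwich is A^{-1} B A^{-1} with A the weighted information and B the
outer product of *weighted* scores.  Confidence intervals use the normal
1.96 quantile: additive for linear coefficients, multiplicative on the log
scale for prevalence ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "FitResult",
    "build_design",
    "fit_weighted_linear",
    "fit_modified_poisson",
]

Z95 = 1.959963984540054  # standard normal 97.5% quantile

INDIVIDUAL_COVARIATES = ("age", "sex", "race_ethnicity", "income_band")
ZONE_COVARIATES = (
    "pct_nonhispanic_white_masked",
    "median_income_masked",
    "population_density_masked",
    "median_age_masked",
)


class ModelError(RuntimeError):
    """Raised for rank-deficient designs, empty samples, or non-convergence."""


@dataclass(frozen=True)
class ModelSpec:
    """One Table-4-style model: an outcome against one characteristic's tertiles."""

    outcome: str
    characteristic: str
    individual_covariates: tuple[str, ...] = INDIVIDUAL_COVARIATES
    zone_covariates: tuple[str, ...] = ZONE_COVARIATES
    weight_column: str = "exam_weight"

    @property
    def tertile_column(self) -> str:
        return f"tertile_{self.characteristic}"


@dataclass(frozen=True)
class FitResult:
    """One model term: estimate with robust SE and 95% CI.

    ``scale`` is "linear" (coefficient, additive CI) or "pr" (prevalence
    ratio = exp(coefficient), CI multiplicative on the log scale).
    """

    term: str
    estimate: float
    robust_se: float
    ci_low: float
    ci_high: float
    n: int
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale == "pr" and self.estimate <= 0:
            raise ValueError("prevalence ratio must be positive")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must contain the estimate")


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Assemble design matrix, outcome vector, and weights for one model.

    Tertiles are dummy-coded against tertile 1; categorical covariates are
    dummy-coded against their first-seen sorted level; an intercept is
    included.  Records missing any model variable are dropped (listwise
    deletion).  Raises :class:`ModelError` for an empty sample or a
    constant column.
    """
    cols = (
        [spec.outcome, spec.tertile_column, spec.weight_column]
        + list(spec.individual_covariates)
        + list(spec.zone_covariates)
    )
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ModelError(f"model variables absent from data: {missing_cols}")
    df = data[cols].dropna()
    if df.empty:
        raise ModelError("no records remain after listwise deletion")
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    tert = df[spec.tertile_column].astype(int)
    X[f"{spec.characteristic}_t2"] = (tert == 2).astype(float)
    X[f"{spec.characteristic}_t3"] = (tert == 3).astype(float)
    for cov in spec.individual_covariates + spec.zone_covariates:
        col = df[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # first sorted level is the reference
                X[f"{cov}_{lev}"] = (col.astype(str) == lev).astype(float)
        else:
            X[cov] = col.astype(float)
    nunique = X.nunique()
    constant = [c for c in X.columns if c != "intercept" and nunique[c] <= 1]
    if constant:
        raise ModelError(f"constant model columns after deletion: {constant}")
    y = df[spec.outcome].to_numpy(dtype=float)
    w = df[spec.weight_column].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ModelError("non-positive sampling weights")
    return X, y, w


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the Gram matrix
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ModelError(f"rank-deficient design; collinear columns: {bad or 'unknown'}")


def _sandwich(X: np.ndarray, w: np.ndarray, score_resid: np.ndarray, a_weights: np.ndarray) -> np.ndarray:
    """A^{-1} B A^{-1} with A = X' diag(a_weights) X, B from weighted scores."""
    A = X.T @ (a_weights[:, None] * X)
    B = X.T @ (((w * score_resid) ** 2)[:, None] * X)
    A_inv = np.linalg.inv(A)
    return A_inv @ B @ A_inv


def fit_weighted_linear(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    terms: Sequence[str] | None = None,
) -> list[FitResult]:
    """Weighted least squares with HC0 robust standard errors.

    Returns one :class:`FitResult` per column (or per requested term),
    with additive 95% CIs.  Estimates are invariant to rescaling all
    weights by a constant.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    _check_rank(X, names)
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    resid = y - X @ beta
    V = _sandwich(X, w, resid, a_weights=w)
    se = np.sqrt(np.diag(V))
    n = len(y)
    results = []
    for j, name in enumerate(names):
        if terms is not None and name not in terms:
            continue
        results.append(
            FitResult(
                term=name,
                estimate=float(beta[j]),
                robust_se=float(se[j]),
                ci_low=float(beta[j] - Z95 * se[j]),
                ci_high=float(beta[j] + Z95 * se[j]),
                n=n,
                scale="linear",
            )
        )
    return results


def fit_modified_poisson(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    terms: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> list[FitResult]:
    """Modified Poisson regression: log-link IRLS plus sandwich variance.

    The outcome must be 0/1.  Exponentiated coefficients are prevalence
    ratios; CIs are exp(coef -/+ 1.96 * robust SE).  Raises
    :class:`ModelError` with the iteration trace on non-convergence.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("modified Poisson requires a binary 0/1 outcome")
    _check_rank(X, names)
    beta = np.zeros(X.shape[1])
    if "intercept" in names:
        mean_y = float(np.average(y, weights=w))
        beta[names.index("intercept")] = np.log(max(mean_y, 1e-8))
    trace = []
    for it in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        wk = w * mu  # IRLS working weights for the log link
        XtW = X.T * wk
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        step = float(np.max(np.abs(beta_new - beta)))
        trace.append(step)
        beta = beta_new
        if step < tol:
            break
    else:
        raise ModelError(f"modified Poisson IRLS did not converge; step trace: {trace}")
    mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
    V = _sandwich(X, w, y - mu, a_weights=w * mu)
    se = np.sqrt(np.diag(V))
    n = len(y)
    results = []
    for j, name in enumerate(names):
        if terms is not None and name not in terms:
            continue
        results.append(
            FitResult(
                term=name,
                estimate=float(np.exp(beta[j])),
                robust_se=float(se[j]),
                ci_low=float(np.exp(beta[j] - Z95 * se[j])),
                ci_high=float(np.exp(beta[j] + Z95 * se[j])),
                n=n,
                scale="pr",
            )
        )
    return results
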