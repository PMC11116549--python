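"""Outcome model and plug-in g-formula standardization.

The outcome model is a logistic regression of five-year survival on the
confounders L, three treatment indicators (no-drug reference) and, by
default, all treatment-by-confounder interactions:

    logit P(Y=1 | A, L) = alpha1' L + alpha2' A + alpha3' (A x L)

``predict_b`` evaluates the fitted success probability b_i(L) with the
treatment *set* to strategy i for every row regardless of the treatment
actually received; ``standardized_means`` averages b_i(L) over the
empirical confounder distribution — the plug-in g-formula estimator of the
counterfactual mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._newton import EstimationError, fit_logistic_newton
from .encoding import AnalysisMatrix, EncodingError

__all__ = ["OutcomeFit", "fit_outcome", "predict_b", "standardized_means"]


@dataclass
class OutcomeFit:
    alpha1: np.ndarray          # confounder block, intercept first (p,)
    alpha2: np.ndarray          # treatment indicators (3,)
    alpha3: np.ndarray          # treatment x confounder interactions (3, p-1)
    loglik: float
    converged: bool
    n_iter: int
    columns: list[str]
    interactions: bool

    def __post_init__(self):
        self.alpha1 = np.asarray(self.alpha1, dtype=float)
        self.alpha2 = np.asarray(self.alpha2, dtype=float)
        self.alpha3 = np.asarray(self.alpha3, dtype=float)


def outcome_design(L: np.ndarray, A: np.ndarray, interactions: bool = True) -> np.ndarray:
    """Stack [L | A-dummies | A-dummy x non-intercept-L] for fitting."""
    n, p = L.shape
    dummies = np.zeros((n, 3))
    for i in range(1, 4):
        dummies[:, i - 1] = A == i
    blocks = [L, dummies]
    if interactions:
        for i in range(3):
            blocks.append(dummies[:, i][:, None] * L[:, 1:])
    return np.concatenate(blocks, axis=1)


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset.

    Greedy in column order (earlier columns win), so confounder and
    treatment main effects are always preferred over the interaction
    columns that can duplicate them.  Works on the Gram matrix with
    Schur-complement pivots, O(n p^2 + p^3).
    """
    G = X.T @ X
    p = G.shape[0]
    tol = np.diag(G).max() * 1e-10
    S = G.copy()
    keep = []
    for j in range(p):
        d = S[j, j]
        if d > tol:
            keep.append(j)
            col = S[:, j] / d
            S = S - np.outer(col, S[j, :])
    return np.asarray(keep, dtype=int)


def fit_outcome(
    matrix: AnalysisMatrix,
    interactions: bool = True,
    ridge: float = 0.0,
    max_iter: int = 100,
    start: np.ndarray | None = None,
    drop_collinear: bool = True,
) -> OutcomeFit:
    """ML logistic fit; Newton-Raphson with the same tolerances as the
    treatment model.  Interactions are on by default.

    With a full interaction block, treatment-by-level cells that are empty
    in the sample produce all-zero (or collinear) columns; by default those
    columns are dropped and their coefficients fixed at 0 — the
    corresponding interactions are simply not estimable from the data.  Set
    ``drop_collinear=False`` to error on a rank-deficient design instead.
    """
    X = outcome_design(matrix.L, matrix.A, interactions)
    keep = _independent_columns(X)
    if keep.size < X.shape[1]:
        if not drop_collinear:
            raise EstimationError(
                f"outcome design is rank-deficient (rank {keep.size} < "
                f"{X.shape[1]} columns) after adding treatment blocks"
            )
        if not np.isin(np.arange(matrix.L.shape[1] + 3), keep).all():
            raise EstimationError(
                "outcome design is rank-deficient in the confounder or "
                "treatment main-effect block; only interaction columns may "
                "be dropped automatically"
            )
        X = X[:, keep]
    sub_start = None if start is None else np.asarray(start, dtype=float)[keep]
    beta_kept, ll, converged, it = fit_logistic_newton(
        X, matrix.Y, ridge=ridge, max_iter=max_iter, start=sub_start
    )
    beta = np.zeros(outcome_design(matrix.L[:1], matrix.A[:1], interactions).shape[1])
    beta[keep] = beta_kept
    p = matrix.L.shape[1]
    alpha1 = beta[:p]
    alpha2 = beta[p:p + 3]
    if interactions:
        alpha3 = beta[p + 3:].reshape(3, p - 1)
    else:
        alpha3 = np.zeros((3, p - 1))
    return OutcomeFit(
        alpha1, alpha2, alpha3, ll, converged, it,
        list(matrix.columns), interactions,
    )


def predict_b(fit: OutcomeFit, L_rows: np.ndarray, treatment: int) -> np.ndarray:
    """Counterfactual success probabilities b_i(L) with A set to ``treatment``."""
    if treatment not in (0, 1, 2, 3):
        raise ValueError(f"treatment must be one of 0..3, got {treatment!r}")
    L_rows = np.asarray(L_rows, dtype=float)
    if L_rows.ndim != 2 or L_rows.shape[1] != fit.alpha1.shape[0]:
        raise EncodingError(
            f"L has {L_rows.shape[-1] if L_rows.ndim == 2 else '?'} columns "
            f"but the fit encodes {fit.alpha1.shape[0]}"
        )
    eta = L_rows @ fit.alpha1
    if treatment > 0:
        eta = eta + fit.alpha2[treatment - 1] + L_rows[:, 1:] @ fit.alpha3[treatment - 1]
    return 1.0 / (1.0 + np.exp(-eta))


def predict_b_all(fit: OutcomeFit, L_rows: np.ndarray) -> np.ndarray:
    """(n, 4) matrix of b_i(L) for all four strategies."""
    return np.column_stack([predict_b(fit, L_rows, i) for i in range(4)])


def standardized_means(fit: OutcomeFit, L_rows: np.ndarray) -> np.ndarray:
    """Plug-in g-formula counterfactual means: mean of b_i(L) per strategy."""
    L_rows = np.asarray(L_rows, dtype=float)
    if L_rows.shape[0] < 1:
        raise ValueError("standardization needs at least one row")
    return predict_b_all(fit, L_rows).mean(axis=0)
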