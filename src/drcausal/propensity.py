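"""Treatment model: multinomial logit, IP weights, HT means, SMD balance.

The assignment model is a baseline-category multinomial logit
log[P(A=i|L)/P(A=0|L)] = beta_i' L for the three active strategies against
the no-drug reference.  Fitted probabilities feed unstabilized inverse
probability weights 1/pi_i(L); the Horvitz-Thompson estimator of the
counterfactual mean under strategy i averages I{A=i} Y / pi_i(L) over the
whole cohort.  HT is unnormalized, so finite-sample values can leave [0,1];
they are reported as-is.  ``smd_balance`` checks covariate balance in the
weighted pseudo-population via standardized mean differences for all six
treatment pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._newton import (
    EstimationError,
    SeparationError,
    fit_multinomial_newton,
    softmax_rows,
)
from .encoding import AnalysisMatrix, EncodingError

__all__ = [
    "PropensityFit",
    "PositivityError",
    "fit_multinomial",
    "predict_probs",
    "ht_means",
    "smd_balance",
    "EstimationError",
    "SeparationError",
]

POSITIVITY_FLOOR = 1e-3


class PositivityError(RuntimeError):
    """A subject has zero estimated probability of their own treatment."""


@dataclass
class PropensityFit:
    betas: np.ndarray  # (3, p), arm 0 is reference
    loglik: float
    converged: bool
    n_iter: int
    columns: list[str]

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)


def fit_multinomial(
    matrix: AnalysisMatrix,
    ridge: float = 0.0,
    max_iter: int = 100,
    start: np.ndarray | None = None,
) -> PropensityFit:
    """ML fit of the treatment model by Newton-Raphson with step-halving.

    Requires at least one observation per arm and a full-rank design;
    rank deficiency surfaces as an estimation error.  ``ridge`` enables the
    optional L2 fallback for separated data (default off).
    """
    rank = np.linalg.matrix_rank(matrix.L)
    if rank < matrix.L.shape[1]:
        raise EstimationError(
            f"covariate design is rank-deficient (rank {rank} < "
            f"{matrix.L.shape[1]} columns); drop collinear columns"
        )
    betas, ll, converged, it = fit_multinomial_newton(
        matrix.L, matrix.A, n_classes=4, ridge=ridge, max_iter=max_iter, start=start
    )
    fit = PropensityFit(betas, ll, converged, it, list(matrix.columns))
    probs = predict_probs(fit, matrix.L)
    assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-10
    return fit


def predict_probs(fit: PropensityFit, L_rows: np.ndarray) -> np.ndarray:
    """(n, 4) assignment probabilities pi_i(L); rows sum to one."""
    L_rows = np.asarray(L_rows, dtype=float)
    if L_rows.ndim != 2 or L_rows.shape[1] != fit.betas.shape[1]:
        raise EncodingError(
            f"L has {L_rows.shape[-1] if L_rows.ndim == 2 else '?'} columns "
            f"but the fit encodes {fit.betas.shape[1]}"
        )
    return softmax_rows(L_rows @ fit.betas.T)


def ht_means(
    matrix: AnalysisMatrix,
    probs: np.ndarray,
    positivity_floor: float = POSITIVITY_FLOOR,
) -> np.ndarray:
    """Horvitz-Thompson IP-weighted counterfactual means, one per strategy."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (matrix.n, 4):
        raise EncodingError("probability table must be n x 4 and row-aligned")
    own = probs[np.arange(matrix.n), matrix.A]
    zero = np.flatnonzero(own == 0.0)
    if zero.size:
        raise PositivityError(
            f"zero estimated probability of the received treatment at rows "
            f"{zero[:10].tolist()}{'...' if zero.size > 10 else ''}"
        )
    n_low = int((own < positivity_floor).sum())
    if n_low:
        warnings.warn(
            f"{n_low} subject(s) have fitted own-arm probability below "
            f"{positivity_floor}; HT means may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.empty(4)
    for i in range(4):
        ind = (matrix.A == i).astype(float)
        out[i] = float(np.mean(ind * matrix.Y / probs[:, i]))
    return out


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    m = float((w * x).sum() / wsum)
    v = float((w * (x - m) ** 2).sum() / wsum)
    return m, v


def smd_balance(
    matrix: AnalysisMatrix,
    probs: np.ndarray | None,
    pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Standardized mean differences per covariate and treatment pair.

    In the IP-weighted pseudo-population each subject in arm i carries
    weight 1/pi_i(L); passing ``probs=None`` gives the unweighted
    comparison.  SMD = (m_i - m_j) / sqrt((v_i + v_j)/2); a multi-level
    categorical is summarized by the maximum-|SMD| indicator column (the
    reference-coded indicators), so the table has one row per covariate
    field.  Zero pooled variance yields 0 when the means agree and NaN
    otherwise.
    """
    if pairs is None:
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    if probs is None:
        weights = np.ones(matrix.n)
    else:
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (matrix.n, 4):
            raise EncodingError("probability table must be n x 4 and row-aligned")
        weights = 1.0 / probs[np.arange(matrix.n), matrix.A]

    groups = matrix.schema.column_groups()
    arm_masks = [matrix.A == i for i in range(4)]
    rows = {}
    for fname, cols in groups.items():
        per_pair = []
        for (i, j) in pairs:
            best = 0.0
            for c in cols:
                x = matrix.L[:, c]
                mi, vi = _weighted_moments(x[arm_masks[i]], weights[arm_masks[i]])
                mj, vj = _weighted_moments(x[arm_masks[j]], weights[arm_masks[j]])
                pooled = np.sqrt((vi + vj) / 2.0)
                if pooled == 0.0:
                    smd = 0.0 if mi == mj else float("nan")
                else:
                    smd = (mi - mj) / pooled
                if np.isnan(smd) or abs(smd) > abs(best):
                    best = smd
                    if np.isnan(smd):
                        break
            per_pair.append(best)
        rows[fname] = per_pair
    colnames = [f"{i}_vs_{j}" for i, j in pairs]
    return pd.DataFrame.from_dict(rows, orient="index", columns=colnames)
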