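"""Doubly robust (AIPW) counterfactual means and derived causal effects.

The doubly robust estimator augments the g-formula prediction with an
IP-weighted residual correction:

    E_DR(Y^{a=i}) = (1/n) sum_k [ b_i(L_k) + I{A_k=i}/pi_i(L_k) (Y_k - b_i(L_k)) ]

It reduces exactly to the standardized mean when the residuals vanish and
to the Horvitz-Thompson mean when b_i is identically zero, and it is
consistent when *either* the treatment model or the outcome model is
correctly specified.  Effects derived from four counterfactual means: risk
differences of the combined strategy against each comparator, relative
percent changes, risk ratios, and the additive drug-drug interaction

    DDI = E(Y^{a=3}) - E(Y^{a=2}) - E(Y^{a=1}) + E(Y^{a=0}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoding import AnalysisMatrix, EncodingError
from .outcome import fit_outcome, predict_b_all
from .propensity import fit_multinomial, ht_means, predict_probs

__all__ = [
    "CounterfactualSet",
    "EffectSet",
    "dr_means",
    "effects",
    "estimate_all",
]


@dataclass
class CounterfactualSet:
    """Counterfactual means under all three estimators."""

    means_ip: np.ndarray
    means_st: np.ndarray
    means_dr: np.ndarray
    n: int

    def __post_init__(self):
        for name in ("means_ip", "means_st", "means_dr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass
class EffectSet:
    """Causal contrasts of the combined strategy vs each comparator s=0,1,2."""

    rds: np.ndarray       # E(Y^{a=3}) - E(Y^{a=s})
    rel_pct: np.ndarray   # 100 * rds / E(Y^{a=s})
    ddi: float
    rrs: np.ndarray       # E(Y^{a=3}) / E(Y^{a=s})

    def __post_init__(self):
        self.rds = np.asarray(self.rds, dtype=float)
        self.rel_pct = np.asarray(self.rel_pct, dtype=float)
        self.rrs = np.asarray(self.rrs, dtype=float)


def dr_means(
    matrix: AnalysisMatrix,
    propensity_probs: np.ndarray,
    outcome_predictions: np.ndarray,
) -> np.ndarray:
    """Doubly robust counterfactual means for all four strategies.

    ``outcome_predictions`` is the (n, 4) matrix of b_i(L).  Values are not
    clipped to [0, 1]: out-of-range results are finite-sample IP artifacts
    and clipping would break the estimator's algebra; a warning is issued
    instead.
    """
    probs = np.asarray(propensity_probs, dtype=float)
    bhat = np.asarray(outcome_predictions, dtype=float)
    if probs.shape != (matrix.n, 4) or bhat.shape != (matrix.n, 4):
        raise EncodingError(
            "propensity and outcome predictions must both be n x 4 and "
            "row-aligned with the analysis matrix"
        )
    out = np.empty(4)
    for i in range(4):
        ind = (matrix.A == i).astype(float)
        out[i] = float(
            np.mean(bhat[:, i] + ind / probs[:, i] * (matrix.Y - bhat[:, i]))
        )
    if ((out < 0) | (out > 1)).any():
        warnings.warn(
            "doubly robust mean outside [0, 1] (finite-sample IP artifact); "
            "values reported unclipped",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def effects(means: np.ndarray) -> EffectSet:
    """Risk differences, relative %, risk ratios and DDI from four means.

    A zero comparator mean yields NaN ("undefined") for the relative
    percent and risk ratio of that contrast.
    """
    means = np.asarray(means, dtype=float)
    if means.shape != (4,) or not np.isfinite(means).all():
        raise ValueError("effects() needs four finite counterfactual means")
    rds = means[3] - means[:3]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(means[:3] != 0, 100.0 * rds / means[:3], np.nan)
        rrs = np.where(means[:3] != 0, means[3] / means[:3], np.nan)
    ddi = float(means[3] - means[2] - means[1] + means[0])
    return EffectSet(rds=rds, rel_pct=rel, ddi=ddi, rrs=rrs)


def estimate_all(
    matrix: AnalysisMatrix,
    interactions: bool = True,
    ridge: float = 0.0,
) -> tuple[CounterfactualSet, EffectSet]:
    """Fit both nuisance models and return all three estimator families.

    The reported EffectSet uses the doubly robust means.
    """
    pfit = fit_multinomial(matrix, ridge=ridge)
    probs = predict_probs(pfit, matrix.L)
    ofit = fit_outcome(matrix, interactions=interactions, ridge=ridge)
    bhat = predict_b_all(ofit, matrix.L)
    cf = CounterfactualSet(
        means_ip=ht_means(matrix, probs),
        means_st=bhat.mean(axis=0),
        means_dr=dr_means(matrix, probs, bhat),
        n=matrix.n,
    )
    return cf, effects(cf.means_dr)
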