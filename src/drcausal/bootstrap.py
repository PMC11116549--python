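"""Nonparametric bootstrap of the full doubly robust pipeline.

Patients (rows) are resampled with replacement to the original cohort size;
both nuisance models are refitted on every replicate and the eight
statistics of interest recorded: the four DR counterfactual means, the
three risk differences against the combined strategy, and the additive
drug-drug interaction.  Confidence intervals are empirical percentiles
(linear interpolation between order statistics, the numpy default rule).
Bonferroni adjustment divides the two-sided error rate by the family size:
4 for the means family — levels (0.00625, 0.99375) — and 3 for the
differences family; the DDI keeps its naive 95% interval (family size 1).

Replicates where an arm empties out or a fit fails are recorded and
excluded from the percentiles, never silently redrawn (redrawing biases
the bootstrap distribution); more than 10% failures aborts with advice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._newton import EstimationError
from .encoding import AnalysisMatrix
from .estimators import dr_means, effects
from .outcome import fit_outcome, outcome_design, predict_b_all
from .propensity import PositivityError, fit_multinomial, predict_probs

__all__ = [
    "BootstrapResult",
    "InferenceError",
    "bootstrap",
    "percentile_ci",
    "bonferroni_levels",
]

STATISTIC_NAMES = (
    "mean_0", "mean_1", "mean_2", "mean_3",
    "rd_0", "rd_1", "rd_2",
    "ddi",
)

# family sizes for Bonferroni adjustment of the 95% intervals
FAMILY_SIZE = {
    "mean_0": 4, "mean_1": 4, "mean_2": 4, "mean_3": 4,
    "rd_0": 3, "rd_1": 3, "rd_2": 3,
    "ddi": 1,
}


class InferenceError(RuntimeError):
    """Too many failed bootstrap replicates for trustworthy percentiles."""


def percentile_ci(samples, level_lo: float, level_hi: float) -> tuple[float, float]:
    """Empirical percentile interval, linear interpolation between order stats."""
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size < 2:
        raise ValueError("percentile interval needs at least two finite samples")
    if not (0.0 <= level_lo < level_hi <= 1.0):
        raise ValueError("levels must satisfy 0 <= lo < hi <= 1")
    lo, hi = np.quantile(samples, [level_lo, level_hi], method="linear")
    return float(lo), float(hi)


def bonferroni_levels(alpha: float, k: int) -> tuple[float, float]:
    """Two-sided percentile levels at family-wise error ``alpha`` over k tests."""
    a = alpha / k
    return a / 2.0, 1.0 - a / 2.0


@dataclass
class BootstrapResult:
    n_reps: int
    replicates: np.ndarray               # (B_ok, 8)
    naive_ci: dict[str, tuple[float, float]]
    bonferroni_ci: dict[str, tuple[float, float]]
    failed_reps: list[tuple[int, str]] = field(default_factory=list)
    seed: int = 0
    statistic_names: tuple[str, ...] = STATISTIC_NAMES


def _pipeline_statistics(matrix, L, Y, A, idx, p_start, o_start, interactions):
    sub = AnalysisMatrix(
        Y=Y[idx], A=A[idx], L=L[idx], schema=matrix.schema, columns=matrix.columns
    )
    pfit = fit_multinomial(sub, start=p_start)
    probs = predict_probs(pfit, sub.L)
    ofit = fit_outcome(sub, interactions=interactions, start=o_start)
    bhat = predict_b_all(ofit, sub.L)
    means = dr_means(sub, probs, bhat)
    eff = effects(means)
    return np.concatenate([means, eff.rds, [eff.ddi]])


def bootstrap(
    matrix: AnalysisMatrix,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    interactions: bool = True,
    max_failed_frac: float = 0.10,
) -> BootstrapResult:
    """Bootstrap the DR pipeline; reproducible from ``seed``.

    Fits on the original data first (also providing warm starts for the
    replicate fits), then resamples ``B`` times.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2")
    rng = np.random.default_rng(seed)
    n = matrix.n
    L, Y, A = matrix.L, matrix.Y, matrix.A

    # original-data fits: the pipeline must fit once, and the coefficients
    # warm-start every replicate
    pfit0 = fit_multinomial(matrix)
    ofit0 = fit_outcome(matrix, interactions=interactions)
    p_start = pfit0.betas
    p = L.shape[1]
    o_start = np.concatenate(
        [ofit0.alpha1, ofit0.alpha2]
        + ([ofit0.alpha3.ravel()] if interactions else [])
    )
    # sanity: warm start must match the replicate design width
    assert o_start.size == outcome_design(L[:1], A[:1], interactions).shape[1]

    rows = []
    failed: list[tuple[int, str]] = []
    with np.errstate(over="ignore"):
        for j in range(B):
            idx = rng.integers(0, n, size=n)
            try:
                rows.append(
                    _pipeline_statistics(
                        matrix, L, Y, A, idx, p_start, o_start, interactions
                    )
                )
            except (EstimationError, PositivityError) as exc:
                failed.append((j, str(exc)))
    if len(failed) > max_failed_frac * B:
        raise InferenceError(
            f"{len(failed)} of {B} bootstrap replicates failed "
            f"({100 * len(failed) / B:.1f}%); consider a larger cohort or "
            "fewer covariate strata"
        )
    reps = np.asarray(rows)

    naive: dict[str, tuple[float, float]] = {}
    bonf: dict[str, tuple[float, float]] = {}
    for k, name in enumerate(STATISTIC_NAMES):
        naive[name] = percentile_ci(reps[:, k], alpha / 2.0, 1.0 - alpha / 2.0)
        lo, hi = bonferroni_levels(alpha, FAMILY_SIZE[name])
        bonf[name] = percentile_ci(reps[:, k], lo, hi)
    return BootstrapResult(
        n_reps=B,
        replicates=reps,
        naive_ci=naive,
        bonferroni_ci=bonf,
        failed_reps=failed,
        seed=seed,
    )
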