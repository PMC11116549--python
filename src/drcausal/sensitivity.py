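"""E-value sensitivity analysis and population-level extrapolation.

The E-value is the minimum strength of association, on the risk-ratio
scale, that an unmeasured confounder would need with both treatment and
outcome to explain away an observed risk ratio:

    E-value = RR + sqrt(RR (RR - 1))        for RR >= 1,

with RR < 1 handled by inverting RR (and the CI) first — the standard
convention.  The CI E-value applies the same transform to the confidence
bound closer to the null, and is 1 when the interval crosses 1.

Population extrapolation converts risk differences into counts of lives
extended beyond five years: population x group share x RD, rounded to the
nearest thousand per group before summing; projections to a future
population scale the *unrounded* total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvalueResult",
    "ExtrapolationInput",
    "evalue",
    "risk_ratios_from_means",
    "population_extrapolation",
]


@dataclass
class EvalueResult:
    rr: float
    rr_ci: tuple[float, float] | None
    evalue_point: float
    evalue_ci: float | None


def _transform(rr: float) -> float:
    # defined for rr >= 1; strictly increasing, continuous at rr = 1
    return rr + np.sqrt(rr * (rr - 1.0))


def evalue(rr: float, ci: tuple[float, float] | None = None) -> EvalueResult:
    """E-value for a risk ratio and, optionally, its confidence interval."""
    if not np.isfinite(rr) or rr <= 0:
        raise ValueError(f"risk ratio must be a positive finite number, got {rr!r}")
    if ci is not None:
        lo, hi = float(ci[0]), float(ci[1])
        if not (0 < lo <= hi):
            raise ValueError(f"invalid confidence interval {ci!r}")
        if not (lo <= rr <= hi):
            raise ValueError("risk ratio must lie inside its confidence interval")

    if rr >= 1.0:
        ev_point = _transform(rr)
        if ci is None:
            ev_ci = None
        elif ci[0] <= 1.0:
            ev_ci = 1.0
        else:
            ev_ci = _transform(float(ci[0]))
    else:
        # protective estimate: invert before transforming
        ev_point = _transform(1.0 / rr)
        if ci is None:
            ev_ci = None
        elif ci[1] >= 1.0:
            ev_ci = 1.0
        else:
            ev_ci = _transform(1.0 / float(ci[1]))
    return EvalueResult(rr=float(rr), rr_ci=ci, evalue_point=float(ev_point),
                        evalue_ci=None if ev_ci is None else float(ev_ci))


def risk_ratios_from_means(means: np.ndarray) -> np.ndarray:
    """RR_s = E(Y^{a=3}) / E(Y^{a=s}) for s = 0, 1, 2 (NaN on zero denominator)."""
    means = np.asarray(means, dtype=float)
    if means.shape != (4,):
        raise ValueError("need four counterfactual means")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(means[:3] != 0, means[3] / means[:3], np.nan)


@dataclass
class ExtrapolationInput:
    """Inputs for the lives-extended extrapolation.

    ``group_proportions`` are the shares of the prevalent patient
    population on each comparator strategy, paired positionally with the
    risk differences ``rds`` of the combined strategy against them.
    """

    population_size: float
    group_proportions: tuple[float, float, float]
    rds: tuple[float, float, float]
    rounding: int = 1000

    def __post_init__(self):
        props = np.asarray(self.group_proportions, dtype=float)
        if (props < 0).any() or (props > 1).any() or props.sum() > 1 + 1e-12:
            raise ValueError("group proportions must lie in [0,1] and sum to <= 1")
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")


def _round_to(x: float, unit: int) -> float:
    return float(np.rint(x / unit) * unit)


def population_extrapolation(
    inp: ExtrapolationInput,
    projected_population: float | None = None,
) -> dict:
    """Counts of lives extended beyond five years, per group and total.

    Negative risk differences produce negative counts (a harm scenario);
    they are reported, not clipped.
    """
    props = np.asarray(inp.group_proportions, dtype=float)
    rds = np.asarray(inp.rds, dtype=float)
    if (rds < 0).any():
        warnings.warn(
            "negative risk difference: the corresponding count is negative "
            "(lives shortened, not extended)",
            RuntimeWarning,
            stacklevel=2,
        )
    raw = inp.population_size * props * rds
    rounded = [_round_to(x, inp.rounding) for x in raw]
    out = {
        "per_group": rounded,
        "per_group_unrounded": raw.tolist(),
        "total": float(sum(rounded)),
        "total_unrounded": float(raw.sum()),
    }
    if projected_population is not None:
        scaled = raw.sum() * projected_population / inp.population_size
        out["projection"] = _round_to(scaled, inp.rounding)
        out["projection_unrounded"] = float(scaled)
    return out
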