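"""Synthetic EHR-like cohort generator with known counterfactual truth.

Emulates the structure of a retrospective Alzheimer's-disease cohort: four
categorical demographics (age group at diagnosis, sex, race, marital
status), six binary comorbidity flags, a four-level treatment strategy
(0 = no drug, 1 = Memantine, 2 = Donepezil, 3 = combined) assigned by a
multinomial-logit law, and a binary five-year-survival outcome drawn from a
logistic law.  Covariates are mutually independent with configurable
marginals; the default marginals match the published cohort's summary
tables, the default treatment shares are calibrated to
(48.30, 11.35, 30.70, 9.66)% and the default counterfactual survival
probabilities to (0.780, 0.781, 0.765, 0.830).

Because the generating law is known, the true counterfactual means
E(Y^{a=i}) = E[b_i(L)] are computable exactly by enumerating the finite
covariate support (or by Monte Carlo for large supports), giving every
downstream estimator an oracle.

Model misspecification scenarios add a hidden transform — the product of
two comorbidity flags — to the true assignment and/or outcome mechanism.
The transform is a function of *observed* fields, but analyst models never
include flag-flag interactions, so the corresponding analyst model is
misspecified while the other remains correct: the setting in which double
robustness is supposed to rescue the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import yaml

from .encoding import CovariateSchema

__all__ = [
    "CohortSpec",
    "TrueEffects",
    "CohortConfigError",
    "generate_cohort",
    "true_counterfactuals",
    "published_cohort_spec",
    "dr_benchmark_spec",
    "small_confounded_spec",
    "write_cohort_csv",
    "read_cohort_csv",
    "spec_to_yaml",
    "spec_from_yaml",
    "TREATMENT_LABELS",
]

MISSPEC_SCENARIOS = ("none", "propensity_wrong", "outcome_wrong", "both_wrong")

TREATMENT_LABELS = ("none", "memantine", "donepezil", "memantine+donepezil")

# cohort-table marginals (counts over 12,744 patients)
_AGE_LEVELS = ("<46", "46-65", "66-75", "76-85")
_AGE_COUNTS = (39, 607, 1834, 10264)
_SEX_LEVELS = ("Female", "Male", "Unknown")
_SEX_COUNTS = (7967, 4772, 5)
_RACE_LEVELS = (
    "Caucasian",
    "African American",
    "American Indian or Alaska Native",
    "Asian",
    "Hispanic",
    "Pacific Islander",
    "Unknown",
)
_RACE_COUNTS = (10341, 808, 42, 279, 44, 20, 1210)
_MARITAL_LEVELS = ("Single", "Divorced", "Married", "Unknown")
_MARITAL_COUNTS = (6258, 867, 4531, 1088)
_COMORBIDITY_PREV = {
    "cerebral_infarction": 1841 / 12744,
    "diabetes": 1477 / 12744,
    "overweight_obesity": 213 / 12744,
    "hypertensive_disease": 1622 / 12744,
    "other_heart_disease": 3022 / 12744,
    "kidney_disease": 3507 / 12744,
}

# observed arm shares in taxonomy order 0=none, 1=Memantine, 2=Donepezil, 3=both
ARM_SHARE_TARGETS = (6155 / 12744, 1446 / 12744, 3912 / 12744, 1231 / 12744)
# counterfactual five-year survival targets per arm
SURVIVAL_TARGETS = (0.780, 0.781, 0.765, 0.830)


class CohortConfigError(ValueError):
    """A cohort specification is internally inconsistent."""


@dataclass
class CohortSpec:
    """Full generating law for a synthetic cohort.

    ``treatment_coefs`` is a (3, p) array of multinomial-logit coefficients
    over the encoded covariate columns (arm 0 is the reference).
    ``alpha1`` (length p, intercept first), ``alpha2`` (length 3) and
    ``alpha3`` (3 x (p-1), treatment-by-covariate interactions, no
    intercept column) define the outcome logit.  ``hidden_pair`` names the
    two binary flags whose product is the hidden transform; ``gamma_treat``
    / ``gamma_out`` are its coefficients in the assignment / outcome
    mechanism when the misspecification scenario switches them on.
    """

    n_patients: int
    covariate_marginals: dict[str, tuple[tuple, tuple]]  # name -> (levels, probs)
    treatment_coefs: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    alpha3: np.ndarray
    misspec_scenario: str = "none"
    hidden_pair: tuple[str, str] | None = None
    gamma_treat: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gamma_out: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise CohortConfigError("n_patients must be >= 1")
        if self.misspec_scenario not in MISSPEC_SCENARIOS:
            raise CohortConfigError(
                f"unknown misspec_scenario {self.misspec_scenario!r}; "
                f"choose one of {MISSPEC_SCENARIOS}"
            )
        for name, (levels, probs) in self.covariate_marginals.items():
            probs = np.asarray(probs, dtype=float)
            if len(levels) != probs.size:
                raise CohortConfigError(
                    f"covariate {name!r}: {len(levels)} levels but "
                    f"{probs.size} probabilities"
                )
            if (probs < 0).any():
                raise CohortConfigError(f"covariate {name!r}: negative probability")
            if abs(probs.sum() - 1.0) > 1e-12:
                raise CohortConfigError(
                    f"covariate {name!r}: marginal sums to {probs.sum()!r}, not 1"
                )
        p = self.schema.n_columns
        self.treatment_coefs = np.asarray(self.treatment_coefs, dtype=float)
        self.alpha1 = np.asarray(self.alpha1, dtype=float)
        self.alpha2 = np.asarray(self.alpha2, dtype=float)
        self.alpha3 = np.asarray(self.alpha3, dtype=float)
        self.gamma_treat = np.asarray(self.gamma_treat, dtype=float)
        if self.treatment_coefs.shape != (3, p):
            raise CohortConfigError(
                f"treatment_coefs has shape {self.treatment_coefs.shape}, "
                f"expected (3, {p}) for the encoded covariate dimension"
            )
        if self.alpha1.shape != (p,):
            raise CohortConfigError(
                f"outcome_coefs block alpha1 has shape {self.alpha1.shape}, "
                f"expected ({p},)"
            )
        if self.alpha2.shape != (3,):
            raise CohortConfigError(
                f"outcome_coefs block alpha2 has shape {self.alpha2.shape}, "
                "expected (3,)"
            )
        if self.alpha3.shape != (3, p - 1):
            raise CohortConfigError(
                f"outcome_coefs block alpha3 has shape {self.alpha3.shape}, "
                f"expected (3, {p - 1})"
            )
        if self.gamma_treat.shape != (3,):
            raise CohortConfigError("gamma_treat must have length 3")
        if self.hidden_pair is not None:
            for f_ in self.hidden_pair:
                levels = self.covariate_marginals.get(f_, ((), ()))[0]
                if tuple(levels) != (0, 1):
                    raise CohortConfigError(
                        f"hidden_pair field {f_!r} must be a binary 0/1 flag"
                    )

    @property
    def schema(self) -> CovariateSchema:
        return CovariateSchema(
            {name: tuple(lv) for name, (lv, _) in self.covariate_marginals.items()}
        )

    # -- true mechanisms -------------------------------------------------
    @property
    def _hidden_in_treatment(self) -> bool:
        return self.misspec_scenario in ("propensity_wrong", "both_wrong")

    @property
    def _hidden_in_outcome(self) -> bool:
        return self.misspec_scenario in ("outcome_wrong", "both_wrong")

    def _hidden_term(self, df: pd.DataFrame) -> np.ndarray:
        if self.hidden_pair is None:
            return np.zeros(len(df))
        a, b = self.hidden_pair
        return (df[a].to_numpy() * df[b].to_numpy()).astype(float)

    def treatment_probs(self, L: np.ndarray, h: np.ndarray) -> np.ndarray:
        """True (n, 4) assignment probabilities for encoded rows L."""
        from ._newton import softmax_rows

        eta = L @ self.treatment_coefs.T
        if self._hidden_in_treatment:
            eta = eta + h[:, None] * self.gamma_treat[None, :]
        return softmax_rows(eta)

    def outcome_prob(self, L: np.ndarray, h: np.ndarray, arm: int) -> np.ndarray:
        """True P(Y=1 | A=arm, L) for encoded rows L."""
        eta = L @ self.alpha1
        if arm > 0:
            eta = eta + self.alpha2[arm - 1] + L[:, 1:] @ self.alpha3[arm - 1]
        if self._hidden_in_outcome:
            eta = eta + self.gamma_out * h
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class TrueEffects:
    """Oracle counterfactual quantities implied by a CohortSpec."""

    true_means: np.ndarray
    true_rds: np.ndarray
    true_ddi: float
    method: str
    mc_error: float = 0.0

    def __post_init__(self):
        self.true_means = np.asarray(self.true_means, dtype=float)
        self.true_rds = np.asarray(self.true_rds, dtype=float)
        if ((self.true_means < 0) | (self.true_means > 1)).any():
            raise CohortConfigError("true means must lie in [0, 1]")
        m = self.true_means
        implied = m[3] - m[2] - m[1] + m[0]
        if abs(implied - self.true_ddi) > 1e-12:
            raise CohortConfigError("true_ddi inconsistent with true_means")


# ---------------------------------------------------------------------------
# generation


def _draw_covariates(spec: CohortSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    data = {}
    for name, (levels, probs) in spec.covariate_marginals.items():
        idx = rng.choice(len(levels), size=n, p=np.asarray(probs, dtype=float))
        arr = np.asarray(levels, dtype=object)[idx]
        if tuple(levels) == (0, 1):
            arr = arr.astype(int)
        data[name] = arr
    return pd.DataFrame(data)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a full synthetic cohort table, reproducible from the seed.

    One explicit RNG stream drives every draw; ``seed`` overrides
    ``spec.seed`` when given.  Survivors get exactly 5.0 follow-up years;
    deaths get a uniform(0, 5] death time (synthetic plumbing: only the
    five-year indicator is modelled, the death-time law exists to exercise
    person-year rate computations).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_patients
    df = _draw_covariates(spec, n, rng)
    L = spec.schema.encode(df)
    h = spec._hidden_term(df)

    probs = spec.treatment_probs(L, h)
    u = rng.random(n)
    treatment = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    p_surv = np.empty(n)
    for arm in range(4):
        mask = treatment == arm
        if mask.any():
            p_surv[mask] = spec.outcome_prob(L[mask], h[mask], arm)
    y = (rng.random(n) < p_surv).astype(int)

    followup = np.full(n, 5.0)
    deaths = y == 0
    followup[deaths] = 5.0 - rng.random(deaths.sum()) * 5.0  # uniform (0, 5]

    dx_offset = rng.integers(0, 365, size=n)
    first_dx = pd.Timestamp("2016-01-01") + pd.to_timedelta(dx_offset, unit="D")

    out = pd.DataFrame({"patient_id": [f"P{i:06d}" for i in range(n)]})
    out["first_dx_date"] = first_dx.strftime("%Y-%m-%d")
    for c in df.columns:
        out[c] = df[c].to_numpy()
    out["med_history"] = [TREATMENT_LABELS[a] for a in treatment]
    out["treatment"] = treatment
    out["y5_survival"] = y
    out["followup_years"] = followup
    return out


# ---------------------------------------------------------------------------
# oracle counterfactuals


def _enumerate_support(spec: CohortSpec):
    """All covariate cells, their probabilities, encoded rows and hidden term."""
    names = list(spec.covariate_marginals)
    level_lists = [spec.covariate_marginals[n][0] for n in names]
    prob_lists = [np.asarray(spec.covariate_marginals[n][1], float) for n in names]
    cells = list(product(*[range(len(lv)) for lv in level_lists]))
    rows = {
        name: np.asarray(
            [level_lists[j][c[j]] for c in cells],
            dtype=object if tuple(level_lists[j]) != (0, 1) else int,
        )
        for j, name in enumerate(names)
    }
    df = pd.DataFrame(rows)
    w = np.ones(len(cells))
    for j in range(len(names)):
        w *= prob_lists[j][[c[j] for c in cells]]
    return df, w


def support_size(spec: CohortSpec) -> int:
    out = 1
    for levels, _ in spec.covariate_marginals.values():
        out *= len(levels)
    return out


def true_counterfactuals(
    spec: CohortSpec,
    n_mc: int | None = None,
    method: str = "auto",
    max_cells: int = 200_000,
    seed: int = 0,
) -> TrueEffects:
    """Oracle E(Y^{a=i}) by averaging the true b_i(L) over the covariate law.

    ``closed_form_average`` enumerates the finite covariate support exactly;
    ``monte_carlo`` averages over ``n_mc`` fresh covariate draws and reports
    the largest per-arm standard error as ``mc_error``.
    """
    if method == "auto":
        method = (
            "closed_form_average" if support_size(spec) <= max_cells else "monte_carlo"
        )
    if method == "closed_form_average":
        df, w = _enumerate_support(spec)
        L = spec.schema.encode(df)
        h = spec._hidden_term(df)
        means = np.array(
            [float(w @ spec.outcome_prob(L, h, arm)) for arm in range(4)]
        )
        mc_error = 0.0
    elif method == "monte_carlo":
        if n_mc is None or n_mc < 1:
            raise ValueError("monte_carlo requires n_mc >= 1")
        rng = np.random.default_rng(seed)
        df = _draw_covariates(spec, n_mc, rng)
        L = spec.schema.encode(df)
        h = spec._hidden_term(df)
        means = np.empty(4)
        ses = np.empty(4)
        for arm in range(4):
            b = spec.outcome_prob(L, h, arm)
            means[arm] = b.mean()
            ses[arm] = b.std(ddof=1) / np.sqrt(n_mc)
        mc_error = float(ses.max())
    else:
        raise ValueError(f"unknown method {method!r}")
    rds = means[3] - means[:3]
    ddi = float(means[3] - means[2] - means[1] + means[0])
    return TrueEffects(means, rds, ddi, method=method, mc_error=mc_error)


# ---------------------------------------------------------------------------
# default specs


def _calibrate_treatment_intercepts(spec: CohortSpec, targets) -> None:
    """Set per-arm intercepts so marginal arm shares hit ``targets`` exactly
    (over the enumerated covariate law)."""
    df, w = _enumerate_support(spec)
    L = spec.schema.encode(df)
    h = spec._hidden_term(df)
    targets = np.asarray(targets, dtype=float)
    for _ in range(200):
        probs = spec.treatment_probs(L, h)
        marg = w @ probs
        if np.abs(marg - targets).max() < 1e-12:
            break
        spec.treatment_coefs[:, 0] += np.log(targets[1:] / marg[1:]) - np.log(
            targets[0] / marg[0]
        )


def _calibrate_outcome_offsets(spec: CohortSpec, targets) -> None:
    """Set the outcome intercept and per-arm shifts so the true
    counterfactual means hit ``targets`` (requires alpha3 = 0)."""
    df, w = _enumerate_support(spec)
    L = spec.schema.encode(df)
    h = spec._hidden_term(df)
    base = L[:, 1:] @ spec.alpha1[1:]
    if spec._hidden_in_outcome:
        base = base + spec.gamma_out * h

    def solve(target):
        d = 0.0
        for _ in range(100):
            p = 1.0 / (1.0 + np.exp(-(base + d)))
            m = float(w @ p)
            g = float(w @ (p * (1 - p)))
            step = (target - m) / max(g, 1e-12)
            d += step
            if abs(step) < 1e-13:
                break
        return d

    offsets = np.array([solve(t) for t in targets])
    spec.alpha1[0] = offsets[0]
    spec.alpha2[:] = offsets[1:] - offsets[0]


def _default_marginals() -> dict:
    marg = {
        "age_group": (_AGE_LEVELS, tuple(c / 12744 for c in _AGE_COUNTS)),
        "sex": (_SEX_LEVELS, tuple(c / 12744 for c in _SEX_COUNTS)),
        "race": (_RACE_LEVELS, tuple(c / 12744 for c in _RACE_COUNTS)),
        "marital_status": (_MARITAL_LEVELS, tuple(c / 12744 for c in _MARITAL_COUNTS)),
    }
    for name, prev in _COMORBIDITY_PREV.items():
        marg[name] = ((0, 1), (1.0 - prev, prev))
    return marg


def published_cohort_spec(
    n_patients: int = 12_744,
    misspec_scenario: str = "none",
    seed: int = 0,
) -> CohortSpec:
    """Default cohort spec with published-table marginals.

    Covariate effects on assignment follow a single latent severity
    direction with arm-specific loadings (0.5, -0.4, 0.8); the same
    direction (scaled to 1.0) drives survival, producing genuine
    confounding.  Intercepts are calibrated so arm shares and counterfactual
    survival match the published cohort exactly in expectation.
    """
    marg = _default_marginals()
    schema = CovariateSchema({k: tuple(v[0]) for k, v in marg.items()})
    p = schema.n_columns
    # fixed severity direction over the non-intercept columns
    pat_rng = np.random.default_rng(20160101)
    severity = pat_rng.uniform(-0.5, 0.5, size=p - 1)
    loadings = np.array([0.5, -0.4, 0.8])
    treatment_coefs = np.zeros((3, p))
    treatment_coefs[:, 1:] = loadings[:, None] * severity[None, :]
    alpha1 = np.zeros(p)
    alpha1[1:] = severity
    spec = CohortSpec(
        n_patients=n_patients,
        covariate_marginals=marg,
        treatment_coefs=treatment_coefs,
        alpha1=alpha1,
        alpha2=np.zeros(3),
        alpha3=np.zeros((3, p - 1)),
        misspec_scenario=misspec_scenario,
        hidden_pair=("other_heart_disease", "kidney_disease"),
        gamma_treat=np.array([1.5, -1.0, 1.8]),
        gamma_out=1.2,
        seed=seed,
    )
    _calibrate_treatment_intercepts(spec, ARM_SHARE_TARGETS)
    _calibrate_outcome_offsets(spec, SURVIVAL_TARGETS)
    return spec


def dr_benchmark_spec(
    n_patients: int = 50_000,
    misspec_scenario: str = "none",
    seed: int = 0,
) -> CohortSpec:
    """Reduced-dimension benchmark for double-robustness Monte Carlo runs.

    Age and sex keep cohort-like marginals; the two comorbidity flags are
    given high prevalence (0.45, 0.55) so their product — the hidden
    transform — is common enough (~25%) that omitting it produces clearly
    detectable bias in the singly robust estimator matching the broken
    model, while arm shares and survival stay at cohort levels.
    """
    marg = {
        "age_group": (_AGE_LEVELS, tuple(c / 12744 for c in _AGE_COUNTS)),
        "sex": (("Female", "Male"), (7967 / 12739, 4772 / 12739)),
        "other_heart_disease": ((0, 1), (0.55, 0.45)),
        "kidney_disease": ((0, 1), (0.45, 0.55)),
    }
    schema = CovariateSchema({k: tuple(v[0]) for k, v in marg.items()})
    p = schema.n_columns
    severity = np.array([-0.8, -0.5, -0.2, 0.3, 1.0, 0.8])  # p - 1 = 6
    loadings = np.array([0.6, -0.5, 0.9])
    treatment_coefs = np.zeros((3, p))
    treatment_coefs[:, 1:] = loadings[:, None] * severity[None, :]
    alpha1 = np.zeros(p)
    alpha1[1:] = severity
    spec = CohortSpec(
        n_patients=n_patients,
        covariate_marginals=marg,
        treatment_coefs=treatment_coefs,
        alpha1=alpha1,
        alpha2=np.zeros(3),
        alpha3=np.zeros((3, p - 1)),
        misspec_scenario=misspec_scenario,
        hidden_pair=("other_heart_disease", "kidney_disease"),
        gamma_treat=np.array([0.8, -0.6, 1.0]),
        gamma_out=1.6,
        seed=seed,
    )
    _calibrate_treatment_intercepts(spec, ARM_SHARE_TARGETS)
    _calibrate_outcome_offsets(spec, SURVIVAL_TARGETS)
    return spec


def small_confounded_spec(n_patients: int = 600, seed: int = 0) -> CohortSpec:
    """Tiny two-confounder design for coverage simulations and fast fixtures."""
    marg = {
        "hypertensive_disease": ((0, 1), (0.6, 0.4)),
        "kidney_disease": ((0, 1), (0.5, 0.5)),
    }
    schema = CovariateSchema({k: tuple(v[0]) for k, v in marg.items()})
    p = schema.n_columns
    severity = np.array([0.9, -0.7])
    loadings = np.array([0.8, -0.6, 1.0])
    treatment_coefs = np.zeros((3, p))
    treatment_coefs[:, 1:] = loadings[:, None] * severity[None, :]
    alpha1 = np.zeros(p)
    alpha1[1:] = severity
    spec = CohortSpec(
        n_patients=n_patients,
        covariate_marginals=marg,
        treatment_coefs=treatment_coefs,
        alpha1=alpha1,
        alpha2=np.zeros(3),
        alpha3=np.zeros((3, p - 1)),
        seed=seed,
    )
    _calibrate_treatment_intercepts(spec, ARM_SHARE_TARGETS)
    _calibrate_outcome_offsets(spec, SURVIVAL_TARGETS)
    return spec


# ---------------------------------------------------------------------------
# plain-text I/O


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def spec_to_yaml(spec: CohortSpec, path) -> None:
    doc = {
        "n_patients": int(spec.n_patients),
        "covariates": {
            name: {"levels": list(levels), "probs": [float(x) for x in probs]}
            for name, (levels, probs) in spec.covariate_marginals.items()
        },
        "treatment_coefs": spec.treatment_coefs.tolist(),
        "outcome_coefs": {
            "alpha1": spec.alpha1.tolist(),
            "alpha2": spec.alpha2.tolist(),
            "alpha3": spec.alpha3.tolist(),
        },
        "misspec": {
            "scenario": spec.misspec_scenario,
            "hidden_pair": list(spec.hidden_pair) if spec.hidden_pair else None,
            "gamma_treat": spec.gamma_treat.tolist(),
            "gamma_out": float(spec.gamma_out),
        },
        "seed": int(spec.seed),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> CohortSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    marg = {
        name: (tuple(v["levels"]), tuple(v["probs"]))
        for name, v in doc["covariates"].items()
    }
    mis = doc.get("misspec", {})
    return CohortSpec(
        n_patients=doc["n_patients"],
        covariate_marginals=marg,
        treatment_coefs=np.asarray(doc["treatment_coefs"], dtype=float),
        alpha1=np.asarray(doc["outcome_coefs"]["alpha1"], dtype=float),
        alpha2=np.asarray(doc["outcome_coefs"]["alpha2"], dtype=float),
        alpha3=np.asarray(doc["outcome_coefs"]["alpha3"], dtype=float),
        misspec_scenario=mis.get("scenario", "none"),
        hidden_pair=tuple(mis["hidden_pair"]) if mis.get("hidden_pair") else None,
        gamma_treat=np.asarray(mis.get("gamma_treat", [0, 0, 0]), dtype=float),
        gamma_out=float(mis.get("gamma_out", 0.0)),
        seed=int(doc.get("seed", 0)),
    )
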