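"""Shared fixtures: one cohort-scale synthetic cohort and its fitted models.

The expensive objects (12,744-patient cohort, multinomial and logistic
fits) are session-scoped so the whole suite pays for them once.
"""

import warnings

import numpy as np
import pytest

import drcausal as dc


@pytest.fixture(scope="session")
def study_spec():
    return dc.published_cohort_spec(n_patients=12_744, seed=1)


@pytest.fixture(scope="session")
def study_cohort(study_spec):
    return dc.generate_cohort(study_spec)


@pytest.fixture(scope="session")
def study_matrix(study_spec, study_cohort):
    return dc.build_analysis_matrix(study_cohort, study_spec.schema)


@pytest.fixture(scope="session")
def study_propensity(study_matrix):
    fit = dc.fit_multinomial(study_matrix)
    probs = dc.predict_probs(fit, study_matrix.L)
    return fit, probs


@pytest.fixture(scope="session")
def study_outcome(study_matrix):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return dc.fit_outcome(study_matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def intercept_only_matrix(A, Y):
    """AnalysisMatrix with no covariates (design = intercept column)."""
    A = np.asarray(A)
    schema = dc.CovariateSchema({})
    return dc.AnalysisMatrix(
        Y=np.asarray(Y, dtype=float),
        A=A,
        L=np.ones((A.size, 1)),
        schema=schema,
        columns=["intercept"],
    )
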