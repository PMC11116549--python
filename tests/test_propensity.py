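"""Multinomial treatment model, IP weighting and balance diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

import drcausal as dc
from drcausal._newton import EstimationError
from drcausal.encoding import EncodingError
from drcausal.propensity import PositivityError
from tests.conftest import intercept_only_matrix

ARM_COUNTS = (6155, 1446, 3912, 1231)  # published cohort arm sizes


def counts_matrix(counts, y=None):
    A = np.repeat(np.arange(len(counts)), counts)
    Y = np.zeros(A.size) if y is None else np.asarray(y, dtype=float)
    return intercept_only_matrix(A, Y)


class TestFitMultinomial:
    def test_intercept_only_recovers_sample_shares(self):
        m = counts_matrix(ARM_COUNTS)
        fit = dc.fit_multinomial(m)
        probs = dc.predict_probs(fit, m.L[:1])
        shares = np.asarray(ARM_COUNTS) / sum(ARM_COUNTS)
        # closed form for the saturated intercept model: fitted probabilities
        # equal the sample shares (0.48297, 0.11346, 0.30697, 0.09659)
        assert np.abs(probs[0] - shares).max() < 1e-9
        assert fit.converged

    def test_equal_arms_give_quarter_probabilities(self):
        m = counts_matrix((50, 50, 50, 50))
        probs = dc.predict_probs(dc.fit_multinomial(m), m.L[:1])
        assert np.abs(probs[0] - 0.25).max() < 1e-10

    def test_saturated_binary_covariate_matches_stratum_shares(self):
        # 40-row toy: within each stratum of x the fitted probabilities must
        # equal the empirical arm shares of that stratum
        x = np.array([0] * 24 + [1] * 16)
        A = np.array([0] * 12 + [1] * 6 + [2] * 4 + [3] * 2
                     + [0] * 4 + [1] * 2 + [2] * 6 + [3] * 4)
        schema = dc.CovariateSchema({"x": (0, 1)})
        m = dc.AnalysisMatrix(
            Y=np.zeros(40), A=A, L=schema.encode(pd.DataFrame({"x": x})),
            schema=schema, columns=schema.column_names(),
        )
        fit = dc.fit_multinomial(m)
        probs = dc.predict_probs(fit, m.L)
        for stratum, nsub in ((0, 24), (1, 16)):
            mask = x == stratum
            empirical = np.bincount(A[mask], minlength=4) / nsub
            assert np.abs(probs[mask][0] - empirical).max() < 1e-7

    def test_empty_arm_raises_naming_arm(self):
        m = counts_matrix((10, 0, 10, 10))
        with pytest.raises(EstimationError, match=r"\[1\]"):
            dc.fit_multinomial(m)

    def test_rank_deficient_design_detected(self):
        schema = dc.CovariateSchema({"x": (0, 1)})
        L = np.column_stack([np.ones(40), np.zeros(40)])  # constant dummy
        m = dc.AnalysisMatrix(
            Y=np.zeros(40), A=np.tile(np.arange(4), 10), L=L,
            schema=schema, columns=schema.column_names(),
        )
        with pytest.raises(EstimationError, match="rank"):
            dc.fit_multinomial(m)

    def test_row_permutation_leaves_coefficients(self, study_matrix):
        rng = np.random.default_rng(12)
        perm = rng.permutation(study_matrix.n)
        m2 = dc.AnalysisMatrix(
            Y=study_matrix.Y[perm], A=study_matrix.A[perm], L=study_matrix.L[perm],
            schema=study_matrix.schema, columns=study_matrix.columns,
        )
        f1 = dc.fit_multinomial(study_matrix)
        f2 = dc.fit_multinomial(m2)
        assert np.abs(f1.betas - f2.betas).max() < 1e-8

    def test_cross_check_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        spec = dc.small_confounded_spec(n_patients=2000)
        df = dc.generate_cohort(spec, seed=21)
        m = dc.build_analysis_matrix(df, spec.schema)
        ours = dc.fit_multinomial(m)
        ref = sm.MNLogit(m.A, m.L).fit(disp=0, method="newton", maxiter=200)
        assert np.abs(ours.betas - ref.params.T).max() < 1e-6


class TestPredictProbs:
    def test_zero_betas_uniform(self):
        fit = dc.PropensityFit(np.zeros((3, 1)), 0.0, True, 0, ["intercept"])
        probs = dc.predict_probs(fit, np.ones((5, 1)))
        assert np.abs(probs - 0.25).max() < 1e-15

    def test_hand_row_log2(self):
        # betas (ln 2, 0, 0): denominators 1 + 2 + 1 + 1 = 5
        fit = dc.PropensityFit(
            np.array([[math.log(2)], [0.0], [0.0]]), 0.0, True, 0, ["intercept"]
        )
        probs = dc.predict_probs(fit, np.ones((1, 1)))
        assert probs[0] == pytest.approx([0.2, 0.4, 0.2, 0.2], abs=1e-12)

    def test_large_coefficient_limit(self):
        rows = []
        for scale in (5.0, 15.0, 40.0, 400.0):
            fit = dc.PropensityFit(
                np.array([[scale], [0.0], [0.0]]), 0.0, True, 0, ["intercept"]
            )
            rows.append(dc.predict_probs(fit, np.ones((1, 1)))[0])
        p1 = [r[1] for r in rows]
        assert all(a < b or b == 1.0 for a, b in zip(p1, p1[1:]))
        assert rows[-1] == pytest.approx([0, 1, 0, 0], abs=1e-12)
        assert np.isfinite(rows[-1]).all()  # overflow-safe softmax

    def test_rows_sum_to_one_everywhere(self, study_matrix, study_propensity):
        _, probs = study_propensity
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-12

    def test_misaligned_columns_raise(self, study_propensity):
        fit, _ = study_propensity
        with pytest.raises(EncodingError, match="columns"):
            dc.predict_probs(fit, np.ones((3, 2)))


class TestHTMeans:
    def test_randomized_known_quarter_weights(self):
        rng = np.random.default_rng(7)
        A = rng.integers(0, 4, size=2000)
        m = intercept_only_matrix(A, np.ones(2000))
        probs = np.full((2000, 4), 0.25)
        means = dc.ht_means(m, probs)
        counts = np.bincount(A, minlength=4)
        assert means == pytest.approx(counts / (0.25 * 2000), abs=1e-12)

    def test_saturated_propensity_reduces_to_stratified_means(self):
        # with the saturated treatment model HT equals per-stratum arm means
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, size=4000)
        A = rng.integers(0, 4, size=4000)
        Y = rng.random(4000) < 0.3 + 0.2 * x + 0.05 * A
        schema = dc.CovariateSchema({"x": (0, 1)})
        m = dc.AnalysisMatrix(
            Y=Y.astype(float), A=A, L=schema.encode(pd.DataFrame({"x": x})),
            schema=schema, columns=schema.column_names(),
        )
        probs = dc.predict_probs(dc.fit_multinomial(m), m.L)
        means = dc.ht_means(m, probs)
        # oracle: stratum-weighted arm means computed with pandas
        df = pd.DataFrame({"x": x, "A": A, "Y": Y.astype(float)})
        strat = df.groupby(["x", "A"])["Y"].mean().unstack()
        wx = df["x"].value_counts(normalize=True).sort_index()
        oracle = (strat.mul(wx, axis=0)).sum(axis=0)
        assert means == pytest.approx(oracle.to_numpy(), abs=1e-6)

    def test_zero_outcome_gives_zero_means(self):
        m = counts_matrix((10, 10, 10, 10))
        probs = np.full((40, 4), 0.25)
        assert dc.ht_means(m, probs) == pytest.approx([0, 0, 0, 0], abs=0)

    def test_zero_probability_on_own_arm_raises(self):
        m = counts_matrix((2, 2, 2, 2), y=np.ones(8))
        probs = np.full((8, 4), 0.25)
        probs[0, 0] = 0.0
        with pytest.raises(PositivityError):
            dc.ht_means(m, probs)

    def test_low_probability_warns(self):
        m = counts_matrix((2, 2, 2, 2), y=np.ones(8))
        probs = np.full((8, 4), 0.25)
        probs[0, 0] = 1e-5
        with pytest.warns(RuntimeWarning, match="positivity|probability"):
            dc.ht_means(m, probs)


class TestSMDBalance:
    def test_identical_distributions_all_zero(self):
        # same covariate rows replicated in every arm -> exact balance
        x = np.tile(np.array([0, 1, 1, 0, 1]), 4)
        A = np.repeat(np.arange(4), 5)
        schema = dc.CovariateSchema({"x": (0, 1)})
        m = dc.AnalysisMatrix(
            Y=np.zeros(20), A=A, L=schema.encode(pd.DataFrame({"x": x})),
            schema=schema, columns=schema.column_names(),
        )
        bal = dc.smd_balance(m, None)
        assert np.abs(bal.to_numpy()).max() == 0.0

    def test_hand_computed_unweighted_smd(self):
        # arms 0/1, three subjects each; x means 1/3 vs 1, variances 2/9 and 0
        x = np.array([0, 1, 0, 1, 1, 1])
        A = np.array([0, 0, 0, 1, 1, 1])
        schema = dc.CovariateSchema({"x": (0, 1)})
        m = dc.AnalysisMatrix(
            Y=np.zeros(6), A=A, L=schema.encode(pd.DataFrame({"x": x})),
            schema=schema, columns=schema.column_names(),
        )
        bal = dc.smd_balance(m, None, pairs=[(0, 1)])
        expected = (1 / 3 - 1.0) / math.sqrt((2 / 9 + 0.0) / 2)
        assert bal.loc["x", "0_vs_1"] == pytest.approx(expected, abs=1e-12)

    def test_zero_pooled_sd_conventions(self):
        x = np.array([1, 1, 1, 0, 0, 0])
        A = np.array([0, 0, 1, 2, 2, 3])
        schema = dc.CovariateSchema({"x": (0, 1)})
        m = dc.AnalysisMatrix(
            Y=np.zeros(6), A=A, L=schema.encode(pd.DataFrame({"x": x})),
            schema=schema, columns=schema.column_names(),
        )
        bal = dc.smd_balance(m, None)
        assert bal.loc["x", "0_vs_1"] == 0.0          # equal means, zero SD
        assert np.isnan(bal.loc["x", "0_vs_2"])       # different means, zero SD

    def test_weighting_removes_confounded_imbalance(self, study_matrix, study_propensity):
        _, probs = study_propensity
        raw = dc.smd_balance(study_matrix, None).to_numpy()
        weighted = dc.smd_balance(study_matrix, probs).to_numpy()
        assert np.abs(raw).max() > 0.1          # generator confounds by design
        assert np.abs(weighted).max() < np.abs(raw).max()

    def test_table_shape_is_10_covariates_by_6_pairs(self, study_matrix, study_propensity):
        _, probs = study_propensity
        bal = dc.smd_balance(study_matrix, probs)
        assert bal.shape == (10, 6)
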