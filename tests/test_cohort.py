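"""Synthetic cohort generator: generating law, oracle counterfactuals, I/O."""

import math

import numpy as np
import pytest

import drcausal as dc
from drcausal.cohort import (
    ARM_SHARE_TARGETS,
    CohortConfigError,
    CohortSpec,
    SURVIVAL_TARGETS,
)


def two_flag_spec(
    treatment_coefs=None,
    alpha1=(0.2, 0.8, -0.5),
    alpha2=(0.3, -0.2, 0.6),
    alpha3=((0.1, -0.3), (0.0, 0.2), (-0.4, 0.5)),
    n=1000,
):
    """Tiny fully-enumerable spec: two independent binary flags."""
    marg = {"flag_a": ((0, 1), (0.7, 0.3)), "flag_b": ((0, 1), (0.4, 0.6))}
    if treatment_coefs is None:
        treatment_coefs = [[0.1, 0.5, -0.2], [-0.3, 0.2, 0.4], [0.0, -0.6, 0.3]]
    return CohortSpec(
        n_patients=n,
        covariate_marginals=marg,
        treatment_coefs=np.asarray(treatment_coefs, dtype=float),
        alpha1=np.asarray(alpha1, dtype=float),
        alpha2=np.asarray(alpha2, dtype=float),
        alpha3=np.asarray(alpha3, dtype=float),
        seed=0,
    )


class TestSpecValidation:
    def test_marginal_must_sum_to_one(self):
        with pytest.raises(CohortConfigError, match="flag_a"):
            CohortSpec(
                n_patients=10,
                covariate_marginals={"flag_a": ((0, 1), (0.5, 0.6))},
                treatment_coefs=np.zeros((3, 2)),
                alpha1=np.zeros(2),
                alpha2=np.zeros(3),
                alpha3=np.zeros((3, 1)),
            )

    @pytest.mark.parametrize(
        "field,shape",
        [("treatment_coefs", (3, 5)), ("alpha1", (7,)), ("alpha3", (3, 5))],
    )
    def test_dimension_mismatch_names_offending_block(self, field, shape):
        kwargs = dict(
            n_patients=10,
            covariate_marginals={"flag_a": ((0, 1), (0.5, 0.5))},
            treatment_coefs=np.zeros((3, 2)),
            alpha1=np.zeros(2),
            alpha2=np.zeros(3),
            alpha3=np.zeros((3, 1)),
        )
        kwargs[field] = np.zeros(shape)
        with pytest.raises(CohortConfigError, match=field.split("_")[-1]):
            CohortSpec(**kwargs)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(CohortConfigError, match="scenario"):
            CohortSpec(
                n_patients=10,
                covariate_marginals={"flag_a": ((0, 1), (0.5, 0.5))},
                treatment_coefs=np.zeros((3, 2)),
                alpha1=np.zeros(2),
                alpha2=np.zeros(3),
                alpha3=np.zeros((3, 1)),
                misspec_scenario="typo",
            )


class TestGenerateCohort:
    def test_zero_treatment_coefs_give_uniform_arms(self):
        spec = two_flag_spec(treatment_coefs=np.zeros((3, 3)), n=20_000)
        df = dc.generate_cohort(spec, seed=4)
        shares = df["treatment"].value_counts(normalize=True)
        se = math.sqrt(0.25 * 0.75 / 20_000)
        for arm in range(4):
            assert abs(shares[arm] - 0.25) < 3 * se

    def test_zero_outcome_coefs_give_half_survival(self):
        spec = two_flag_spec(
            alpha1=(0.0, 0.0, 0.0),
            alpha2=(0.0, 0.0, 0.0),
            alpha3=np.zeros((3, 2)),
            n=20_000,
        )
        df = dc.generate_cohort(spec, seed=5)
        se = math.sqrt(0.25 / 20_000)
        assert abs(df["y5_survival"].mean() - 0.5) < 3 * se

    def test_arm_shares_near_published(self, study_cohort):
        shares = study_cohort["treatment"].value_counts(normalize=True)
        for arm, target in enumerate(ARM_SHARE_TARGETS):
            assert abs(shares[arm] - target) < 0.02

    def test_followup_consistent_with_survival(self, study_cohort):
        surv = study_cohort[study_cohort["y5_survival"] == 1]
        dead = study_cohort[study_cohort["y5_survival"] == 0]
        assert (surv["followup_years"] == 5.0).all()
        assert ((dead["followup_years"] > 0) & (dead["followup_years"] <= 5)).all()

    def test_reproducible_byte_identical(self):
        spec = two_flag_spec(n=500)
        a = dc.generate_cohort(spec, seed=9).to_csv(index=False)
        b = dc.generate_cohort(spec, seed=9).to_csv(index=False)
        assert a == b
        c = dc.generate_cohort(spec, seed=10).to_csv(index=False)
        assert a != c

    def test_med_history_matches_treatment(self):
        df = dc.generate_cohort(two_flag_spec(n=200), seed=2)
        for _, row in df.iterrows():
            assert row["med_history"] == dc.TREATMENT_LABELS[row["treatment"]]


class TestTrueCounterfactuals:
    def test_no_treatment_effect_means_equal(self):
        spec = two_flag_spec(alpha2=(0, 0, 0), alpha3=np.zeros((3, 2)))
        eff = dc.true_counterfactuals(spec)
        assert np.ptp(eff.true_means) < 1e-12
        assert abs(eff.true_ddi) < 1e-12

    def test_enumeration_matches_hand_computation(self):
        spec = two_flag_spec()
        eff = dc.true_counterfactuals(spec, method="closed_form_average")
        # independent oracle: loop over the four covariate cells by hand
        pa, pb = 0.3, 0.6
        a1 = (0.2, 0.8, -0.5)
        a2 = (0.3, -0.2, 0.6)
        a3 = ((0.1, -0.3), (0.0, 0.2), (-0.4, 0.5))
        for arm in range(4):
            total = 0.0
            for fa in (0, 1):
                for fb in (0, 1):
                    w = (pa if fa else 1 - pa) * (pb if fb else 1 - pb)
                    eta = a1[0] + a1[1] * fa + a1[2] * fb
                    if arm > 0:
                        eta += a2[arm - 1] + a3[arm - 1][0] * fa + a3[arm - 1][1] * fb
                    total += w / (1.0 + math.exp(-eta))
            assert eff.true_means[arm] == pytest.approx(total, abs=1e-12)

    def test_monte_carlo_agrees_with_closed_form(self):
        spec = two_flag_spec()
        exact = dc.true_counterfactuals(spec, method="closed_form_average")
        mc = dc.true_counterfactuals(spec, method="monte_carlo", n_mc=40_000, seed=3)
        assert mc.mc_error > 0
        assert np.abs(mc.true_means - exact.true_means).max() < 4 * mc.mc_error

    def test_default_truth_is_calibrated_to_published_means(self, study_spec):
        eff = dc.true_counterfactuals(study_spec)
        assert np.abs(eff.true_means - SURVIVAL_TARGETS).max() < 1e-9
        assert eff.true_ddi == pytest.approx(0.064, abs=1e-9)

    def test_monte_carlo_requires_n(self):
        with pytest.raises(ValueError, match="n_mc"):
            dc.true_counterfactuals(two_flag_spec(), method="monte_carlo", n_mc=0)


class TestIO:
    def test_yaml_round_trip_preserves_generating_law(self, tmp_path):
        spec = two_flag_spec(n=300)
        path = tmp_path / "spec.yaml"
        dc.spec_to_yaml(spec, path)
        spec2 = dc.spec_from_yaml(path)
        a = dc.generate_cohort(spec, seed=7).to_csv(index=False)
        b = dc.generate_cohort(spec2, seed=7).to_csv(index=False)
        assert a == b

    def test_cohort_csv_round_trip(self, tmp_path):
        df = dc.generate_cohort(two_flag_spec(n=120), seed=1)
        path = tmp_path / "cohort.csv"
        dc.write_cohort_csv(df, path)
        back = dc.read_cohort_csv(path)
        assert list(back.columns) == list(df.columns)
        assert (back["treatment"] == df["treatment"]).all()
        assert np.allclose(back["followup_years"], df["followup_years"])
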