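import numpy as np
import pandas as pd
import pytest

from isosub.composition import BehaviourComposition, build_ilr_basis, default_basis
from isosub.models import (
    DesignError,
    ModelFit,
    behaviours_to_hours,
    build_covariate_design,
    cism_reallocation,
    delta_z_for_reallocation,
    fit_cism,
    fit_ism,
    ism_reallocation,
    solve_gamma_from_estimates,
)
from isosub.risk import standardize
from isosub.simulate import default_params, generate_cohort

ALT_SBP = np.array([[1, 1], [1, -1], [-1, 0]], dtype=float)
SIT_LAST_SBP = np.array([[-1, -1], [1, -1], [-1, 1]], dtype=float)


def manual_ism_fit(beta_stand, beta_step, se_stand=0.02, se_step=0.02):
    names = ["const", "wear_h", "stand_h", "step_h"]
    params = pd.Series([0.0, 0.0, beta_stand, beta_step], index=names)
    cov = pd.DataFrame(np.diag([0.0, 0.0, se_stand**2, se_step**2]), index=names, columns=names)
    return ModelFit(method="ISM", outcome="zbmi", params=params, cov=cov, n=1524, resid_df=1510)


def manual_cism_fit(gamma, cov=None, basis=None):
    basis = basis or default_basis()
    names = ["const", "z1", "z2"]
    params = pd.Series([0.0, gamma[0], gamma[1]], index=names)
    c = np.zeros((3, 3))
    if cov is not None:
        c[1:, 1:] = cov
    cov_df = pd.DataFrame(c, index=names, columns=names)
    return ModelFit(
        method="CISM", outcome="zbmi", params=params, cov=cov_df, n=1524, resid_df=1515, basis=basis
    )


class TestFitIsm:
    def test_matches_normal_equations_on_small_dataset(self, rng):
        n = 12
        df = pd.DataFrame(
            {
                "sit_min": rng.uniform(400, 700, n),
                "stand_min": rng.uniform(200, 350, n),
                "step_min": rng.uniform(60, 150, n),
                "age": rng.uniform(30, 75, n),
            }
        )
        df["wear_min"] = df[["sit_min", "stand_min", "step_min"]].sum(axis=1)
        df["y"] = rng.normal(size=n)
        fit = fit_ism(df, "y", covariates=("age",))
        X = np.column_stack(
            [np.ones(n), df["wear_min"] / 60, df["stand_min"] / 60, df["step_min"] / 60, df["age"]]
        )
        beta_hand = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta_hand, atol=1e-9)

    def test_recovers_generator_truth_within_3se(self, cohort_beta):
        df = cohort_beta.copy()
        df["z_bmi"] = standardize(df["bmi"])
        fit = fit_ism(df, "z_bmi")
        truth = dict(default_params().outcomes)["bmi"].beta  # (stand, step) per hour
        for name, true_val in zip(("stand_h", "step_h"), truth):
            se = np.sqrt(fit.cov.loc[name, name])
            assert abs(fit.params[name] - true_val) < 3 * se

    def test_zero_outcome_gives_zero_coefficients(self, cohort_gamma):
        df = cohort_gamma.copy()
        df["zero"] = 0.0
        fit = fit_ism(df, "zero")
        np.testing.assert_allclose(fit.params.to_numpy(), 0.0, atol=1e-10)

    def test_rank_deficiency_names_collinear_columns(self, cohort_gamma):
        df = cohort_gamma.copy()
        df["imd"] = 2.0 * df["age"] + 1.0
        df["z_bmi"] = standardize(df["bmi"])
        with pytest.raises(DesignError, match="age|imd"):
            fit_ism(df, "z_bmi")

    def test_missing_column_reported(self, cohort_gamma):
        with pytest.raises(DesignError, match="nope"):
            fit_ism(cohort_gamma, "nope")


class TestIsmReallocation:
    def test_printed_half_hour_scaling(self):
        # a -0.365/h stepping coefficient gives -0.1825 for 30 min
        fit = manual_ism_fit(-0.07, -0.365)
        est = ism_reallocation(fit, "step", 30)
        assert est.estimate == pytest.approx(-0.1825, abs=1e-12)
        est60 = ism_reallocation(fit, "step", 60)
        assert est60.estimate == pytest.approx(-0.365, abs=1e-12)
        assert est.se == pytest.approx(est60.se / 2, abs=1e-12)

    def test_perfect_symmetry(self, cohort_gamma):
        df = cohort_gamma.copy()
        df["z_bmi"] = standardize(df["bmi"])
        fit = fit_ism(df, "z_bmi")
        for t in (5, 17.5, 30, 60):
            fwd = ism_reallocation(fit, "step", t).estimate
            rev = ism_reallocation(fit, "sit", t, from_part="step").estimate
            assert fwd + rev == 0.0  # exact, not approximate

    def test_zero_minutes(self):
        est = ism_reallocation(manual_ism_fit(-0.1, -0.4), "stand", 0)
        assert (est.estimate, est.ci_low, est.ci_high) == (0.0, 0.0, 0.0)

    def test_non_sitting_swap_rejected(self):
        with pytest.raises(ValueError, match="sit"):
            ism_reallocation(manual_ism_fit(-0.1, -0.4), "step", 30, from_part="stand")


class TestFitCism:
    def test_recovers_generator_truth_within_3se(self, cohort_gamma):
        df = cohort_gamma.copy()
        df["z_bmi"] = standardize(df["bmi"])
        fit = fit_cism(df, "z_bmi")
        truth = dict(default_params().outcomes)["bmi"].gamma
        se = np.sqrt(np.diag(fit.gamma_cov))
        np.testing.assert_array_less(np.abs(fit.gamma - truth), 3 * se)

    def test_null_outcome_rarely_flags(self):
        # outcome independent of composition: each |gamma_i| < 3 SE nearly always
        from dataclasses import replace

        hits = np.zeros(2)
        n_rep = 200
        params = default_params(n=250)
        for rep in range(n_rep):
            df = generate_cohort(replace(params, seed=1000 + rep))
            df["z_hba1c"] = standardize(df["hba1c"])
            fit = fit_cism(df, "z_hba1c")
            se = np.sqrt(np.diag(fit.gamma_cov))
            hits += np.abs(fit.gamma) < 3 * se
        assert np.all(hits / n_rep >= 0.95)

    def test_different_sbp_same_predictions(self, cohort_gamma, table1_base):
        df = cohort_gamma.copy()
        df["z_bmi"] = standardize(df["bmi"])
        fit1 = fit_cism(df, "z_bmi", default_basis())
        fit2 = fit_cism(df, "z_bmi", build_ilr_basis(ALT_SBP))
        assert not np.allclose(fit1.gamma, fit2.gamma)  # coordinates rotate
        for t in (15, 60):
            e1 = cism_reallocation(fit1, table1_base, "sit", "step", t)
            e2 = cism_reallocation(fit2, table1_base, "sit", "step", t)
            assert e1.estimate == pytest.approx(e2.estimate, abs=1e-9)
            assert e1.se == pytest.approx(e2.se, abs=1e-9)


class TestCismReallocation:
    def test_reconstruction_from_printed_estimates(self, table1_base):
        # solve gamma from the two published 60-min standardised-BMI effects,
        # then predict the 30-min effects
        gamma = solve_gamma_from_estimates(
            table1_base,
            [("sit", "step", 60.0), ("step", "sit", 60.0)],
            [-0.230, 0.315],
        )
        fit = manual_cism_fit(gamma)
        half_fwd = cism_reallocation(fit, table1_base, "sit", "step", 30).estimate
        half_rev = cism_reallocation(fit, table1_base, "step", "sit", 30).estimate
        assert half_fwd == pytest.approx(-0.122, abs=0.01)
        assert half_rev == pytest.approx(0.142, abs=0.01)
        # asymmetry: forward and reverse 60-min effects differ in magnitude
        fwd = cism_reallocation(fit, table1_base, "sit", "step", 60).estimate
        rev = cism_reallocation(fit, table1_base, "step", "sit", 60).estimate
        assert abs(abs(fwd) - abs(rev)) > 0.05

    def test_delta_method_se_and_ci(self, table1_base):
        cov = np.array([[0.004, 0.001], [0.001, 0.003]])
        fit = manual_cism_fit((1.2, -0.34), cov=cov)
        est = cism_reallocation(fit, table1_base, "sit", "step", 60)
        dz = delta_z_for_reallocation(table1_base, "sit", "step", 60)
        assert est.se == pytest.approx(np.sqrt(dz @ cov @ dz), abs=1e-12)
        assert est.ci_low == pytest.approx(est.estimate - 1.96 * est.se, abs=1e-12)
        assert est.ci_low <= est.estimate <= est.ci_high

    def test_zero_minutes_zero_estimate(self, table1_base):
        est = cism_reallocation(manual_cism_fit((1.2, -0.34)), table1_base, "sit", "step", 0)
        assert est.estimate == 0.0 and est.se == 0.0

    def test_infeasible_reallocation_propagates(self, table1_base):
        from isosub.composition import CompositionError

        with pytest.raises(CompositionError):
            cism_reallocation(manual_cism_fit((1.2, -0.34)), table1_base, "step", "sit", 107)


class TestSolveGamma:
    def test_overdetermined_consistent_system(self, table1_base):
        gamma_true = np.array([0.9, -0.2])
        fit = manual_cism_fit(gamma_true)
        reallocs = [("sit", "step", 60.0), ("step", "sit", 60.0), ("sit", "stand", 45.0)]
        ests = [cism_reallocation(fit, table1_base, f, t, m).estimate for f, t, m in reallocs]
        recovered = solve_gamma_from_estimates(table1_base, reallocs, ests)
        np.testing.assert_allclose(recovered, gamma_true, atol=1e-10)


class TestHelpers:
    @pytest.mark.parametrize(
        "comp,expected",
        [
            ((548, 286, 107), (9.1333, 4.7667, 1.7833)),
            ((60, 60, 60), (1, 1, 1)),
            ((0, 0, 0), (0, 0, 0)),
        ],
    )
    def test_behaviours_to_hours(self, comp, expected):
        np.testing.assert_allclose(behaviours_to_hours(np.array(comp)), expected, atol=1e-4)

    def test_covariate_design_reference_coding(self, cohort_gamma):
        X = build_covariate_design(cohort_gamma)
        assert "ethnicity_south_asian" in X and "ethnicity_other" in X
        assert "ethnicity_white_european" not in X
        with pytest.raises(DesignError, match="unknown ethnicity"):
            bad = cohort_gamma.copy()
            bad.loc[bad.index[0], "ethnicity"] = "martian"
            build_covariate_design(bad)
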