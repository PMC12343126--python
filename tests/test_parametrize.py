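import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from srdrive._genotypes import GENOTYPE_TOKENS
from srdrive.parametrize import (
    DoseResponseCurve,
    FecundityParams,
    MixedFit,
    SeparationError,
    build_dose_response,
    build_fecundity_params,
    fit_fecundity_mixed,
    fit_mortality_glm,
    genotype_contrasts,
    lrt_drop,
)
from srdrive.synthetic_data import (
    TrueFecundityParams,
    TrueMortalityParams,
    generate_fecundity_dataset,
    generate_mortality_dataset,
)

ALL = list(GENOTYPE_TOKENS)


class TestMortalityGlm:
    def test_parameter_recovery_within_3_se(self):
        truth = TrueMortalityParams(
            intercepts={t: -2.0 for t in ALL}, slopes={t: 2.5 for t in ALL}
        )
        df = generate_mortality_dataset(truth, n_vials_per_genotype=500, seed=101)
        fit = fit_mortality_glm(df, formula="per_class")
        se = np.sqrt(np.diag(fit.cov))
        for i, name in enumerate(fit.terms):
            expected = 2.5 if name.endswith(":dose") else -2.0
            assert abs(fit.params[i] - expected) < 3 * se[i], name

    def test_refit_is_deterministic(self, mortality_df):
        a = fit_mortality_glm(mortality_df)
        b = fit_mortality_glm(mortality_df)
        assert a.llf == b.llf
        np.testing.assert_array_equal(a.params, b.params)

    def test_symmetric_data_gives_equal_genotype_effects(self):
        # two genotypes, one dose, every vial exactly half dead
        rows = []
        for i, tok in enumerate(["SR", "ST"] * 10):
            rows.append({"vial_id": f"V{i}", "genotype": tok, "sex": "male",
                         "dose_ml": 0.5, "n_exposed": 10, "n_dead": 5})
        df = pd.DataFrame(rows)
        fit = fit_mortality_glm(df, formula="per_class_intercept")
        assert abs(fit.params[0] - fit.params[1]) < 1e-8
        assert abs(fit.params[0]) < 1e-8  # logit(1/2) = 0

    def test_deviance_improves_on_intercept_only(self, mortality_df):
        full = fit_mortality_glm(mortality_df, formula="per_class")
        null = fit_mortality_glm(mortality_df, formula="per_class_intercept")
        assert full.llf > null.llf

    def test_complete_separation_flagged(self):
        rows = []
        for i in range(40):
            tok = ["SR", "ST"][i % 2]
            dose = [0.0, 0.6, 1.2, 1.8][i % 4]
            dead = 10 if tok == "SR" else 5
            rows.append({"vial_id": f"V{i}", "genotype": tok, "sex": "male",
                         "dose_ml": dose, "n_exposed": 10, "n_dead": dead})
        with pytest.raises(SeparationError):
            fit_mortality_glm(pd.DataFrame(rows), formula="per_class")

    def test_empty_and_degenerate_tables_rejected(self, mortality_df):
        with pytest.raises(ValueError):
            fit_mortality_glm(mortality_df.iloc[:0])
        single = mortality_df[mortality_df["genotype"] == "SR"]
        with pytest.raises(ValueError):
            fit_mortality_glm(single)
        one_dose = mortality_df.assign(dose_ml=1.0)
        with pytest.raises(ValueError):
            fit_mortality_glm(one_dose)


class TestLrt:
    def test_identical_models_give_zero_statistic(self, glm_fit):
        res = lrt_drop(glm_fit, glm_fit)
        assert res.chi2 == 0.0
        assert res.pvalue == 1.0

    def test_df_bookkeeping(self, mortality_df):
        full = fit_mortality_glm(mortality_df, formula="per_class")          # 10 params
        red = fit_mortality_glm(mortality_df, formula="per_class_additive_dose")  # 6
        res = lrt_drop(full, red, assume_nested=True)
        assert res.df == 4
        assert res.chi2 >= 0
        assert 0 <= res.pvalue <= 1

    def test_non_nested_rejected_by_default(self, mortality_df):
        full = fit_mortality_glm(mortality_df, formula="per_class")
        red = fit_mortality_glm(mortality_df, formula="per_class_treatment_additive_dose")
        with pytest.raises(ValueError, match="nested"):
            lrt_drop(full, red)

    def test_statistic_invariant_to_factor_coding(self, mortality_df):
        # cell-means and treatment codings span the same model spaces
        full_a = fit_mortality_glm(mortality_df, formula="per_class")
        red_a = fit_mortality_glm(mortality_df, formula="per_class_additive_dose")
        full_b = fit_mortality_glm(mortality_df, formula="per_class_treatment")
        red_b = fit_mortality_glm(mortality_df, formula="per_class_treatment_additive_dose")
        res_a = lrt_drop(full_a, red_a, assume_nested=True)
        res_b = lrt_drop(full_b, red_b, assume_nested=True)
        assert res_a.df == res_b.df
        assert res_a.chi2 == pytest.approx(res_b.chi2, abs=1e-6)

    def test_null_rejection_rate_is_calibrated(self):
        # 300 null replicates, df=1: dose:genotype absent in truth
        truth = TrueMortalityParams(
            intercepts={t: -1.0 for t in ALL}, slopes={t: 1.5 for t in ALL}
        )
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            df = generate_mortality_dataset(truth, n_vials_per_genotype=15, seed=1000 + rep)
            sub = df[df["genotype"].isin(["SR", "ST"])]
            full = fit_mortality_glm(sub, formula="per_class")
            red = fit_mortality_glm(sub, formula="per_class_additive_dose")
            res = lrt_drop(full, red, assume_nested=True)
            assert res.df == 1
            rejections += res.pvalue < 0.05
        rate = rejections / n_rep
        # 99.7% interval for 300 draws at p=0.05 is about +/- 0.038
        assert 0.012 <= rate <= 0.088, rate


class TestFecundityMixed:
    def test_singular_fit_falls_back_to_vial_only(self):
        # generating individual-level variance is zero; seed chosen so the
        # boundary estimate actually lands below the singularity tolerance
        df = generate_fecundity_dataset(n_females_per_genotype=120, seed=2)
        fit = fit_fecundity_mixed(df, random_spec="individual_in_vial",
                                  formula="genotype+dose")
        assert fit.singular
        assert fit.random_structure == "vial"
        assert set(fit.variance_components) == {"vial_sd"}

    def test_nonzero_individual_variance_is_estimated(self):
        params = TrueFecundityParams(
            log_means={"SRSR": np.log(15), "SRST": np.log(25), "STST": np.log(20)},
            dose_effect=-0.3, sigma_vial=0.2, sigma_individual=0.3,
        )
        df = generate_fecundity_dataset(params, n_females_per_genotype=150, seed=5)
        fit = fit_fecundity_mixed(df, random_spec="individual_in_vial",
                                  formula="genotype+dose")
        assert not fit.singular
        assert fit.random_structure == "individual_in_vial"
        assert 0.15 < fit.variance_components["individual_sd"] < 0.45
        assert 0.1 < fit.variance_components["vial_sd"] < 0.35

    def test_fixed_effect_recovery_within_3_se(self):
        params = TrueFecundityParams(
            log_means={"SRSR": np.log(15), "SRST": np.log(25), "STST": np.log(20)},
            dose_effect=-0.3, sigma_vial=0.2, sigma_individual=0.0,
        )
        df = generate_fecundity_dataset(params, n_females_per_genotype=400, seed=31)
        fit = fit_fecundity_mixed(df, random_spec="vial", formula="genotype+dose")
        truth = {
            "const": np.log(15),
            "g[SRST]": np.log(25) - np.log(15),
            "g[STST]": np.log(20) - np.log(15),
            "dose": -0.3,
        }
        se = np.sqrt(np.diag(fit.cov))
        for i, name in enumerate(fit.terms):
            assert abs(fit.params[i] - truth[name]) < 3 * se[i], name

    def test_dose_lrt_type_i_error_near_nominal(self):
        # truth has no dose effect; vial-only fits on small datasets
        params = TrueFecundityParams(
            log_means={"SRSR": np.log(15), "SRST": np.log(25), "STST": np.log(20)},
            dose_effect=0.0, sigma_vial=0.2,
        )
        n_rep = 150
        rejections = 0
        for rep in range(n_rep):
            df = generate_fecundity_dataset(params, n_females_per_genotype=24,
                                            dose_values=[0.0, 0.6, 1.2, 1.8],
                                            seed=5000 + rep)
            full = fit_fecundity_mixed(df, random_spec="vial", formula="genotype+dose")
            red = fit_fecundity_mixed(df, random_spec="vial", formula="genotype")
            res = lrt_drop(full, red)
            assert res.df == 1
            rejections += res.pvalue < 0.05
        rate = rejections / n_rep
        assert 0.005 <= rate <= 0.12, rate

    def test_input_validation(self, fecundity_df):
        with pytest.raises(ValueError):
            fit_fecundity_mixed(fecundity_df.iloc[:0])
        bad = fecundity_df.copy()
        bad.loc[bad.index[0], "offspring"] = 0
        with pytest.raises(ValueError, match=">= 1"):
            fit_fecundity_mixed(bad)
        const = fecundity_df.copy()
        const["offspring"] = 7
        with pytest.raises(ValueError, match="degenerate"):
            fit_fecundity_mixed(const)


def _toy_mixed_fit(coefs, cov, levels=("SRSR", "SRST", "STST")):
    from srdrive.parametrize import _fecundity_design

    terms = ["const"] + [f"g[{t}]" for t in levels[1:]] + ["dose"]
    return MixedFit(
        formula="genotype+dose",
        terms=tuple(terms),
        params=np.asarray(coefs, float),
        cov=np.asarray(cov, float),
        llf=0.0,
        df_resid=100,
        n_obs=104,
        random_structure="vial",
        variance_components={"vial_sd": 0.2},
        singular=False,
        converged=True,
        design_builder=lambda df, _l=tuple(levels): _fecundity_design(df, "genotype+dose", _l)[0],
    )


class TestContrasts:
    def test_three_genotypes_give_three_contrasts(self, fecundity_df):
        fit = fit_fecundity_mixed(fecundity_df, random_spec="vial", formula="genotype+dose")
        contrasts = genotype_contrasts(fit, dose_values=np.linspace(0, 1.8, 10))
        assert len(contrasts) == 3
        assert {tuple(c.pair) for c in contrasts} == {
            ("SRSR", "SRST"), ("SRSR", "STST"), ("SRST", "STST")
        }

    def test_identical_coefficients_give_null_contrast(self):
        fit = _toy_mixed_fit([2.0, 0.0, 0.0, -0.1], np.eye(4) * 0.01)
        contrasts = genotype_contrasts(fit, dose_values=[0.0, 1.0])
        for c in contrasts:
            assert c.estimate == pytest.approx(0.0, abs=1e-12)
            assert c.pvalue > 0.99
            assert c.pvalue_adjusted > 0.99

    def test_contrast_recovery_of_known_difference(self):
        params = TrueFecundityParams(
            log_means={"SRSR": 2.5, "SRST": 3.0, "STST": 2.5},
            dose_effect=0.0, sigma_vial=0.1,
        )
        df = generate_fecundity_dataset(params, n_females_per_genotype=400, seed=77)
        fit = fit_fecundity_mixed(df, random_spec="vial", formula="genotype+dose")
        contrasts = {tuple(c.pair): c for c in genotype_contrasts(fit, [0.0, 0.9, 1.8])}
        c = contrasts[("SRSR", "SRST")]
        assert abs(c.estimate - (-0.5)) < 3 * c.se

    def test_adjustment_monotone_and_conservative(self, fecundity_df):
        fit = fit_fecundity_mixed(fecundity_df, random_spec="vial", formula="genotype+dose")
        contrasts = genotype_contrasts(fit, dose_values=np.linspace(0, 1.8, 5))
        for c in contrasts:
            assert c.pvalue_adjusted >= c.pvalue - 1e-12
            assert 0.0 <= c.pvalue_adjusted <= 1.0
        by_z = sorted(contrasts, key=lambda c: abs(c.z))
        adj = [c.pvalue_adjusted for c in by_z]
        assert all(a >= b - 1e-12 for a, b in zip(adj, adj[1:]))

    def test_null_truth_rejects_at_nominal_rate(self):
        # with no genotype effect, the smallest adjusted p over the three
        # contrasts should reject at about the familywise nominal level
        params = TrueFecundityParams(
            log_means={"SRSR": 3.0, "SRST": 3.0, "STST": 3.0},
            dose_effect=0.0, sigma_vial=0.15,
        )
        n_rep = 60
        rejections = 0
        for rep in range(n_rep):
            df = generate_fecundity_dataset(params, n_females_per_genotype=30,
                                            seed=9000 + rep)
            fit = fit_fecundity_mixed(df, random_spec="vial", formula="genotype+dose")
            contrasts = genotype_contrasts(fit, [0.0, 0.9, 1.8])
            rejections += min(c.pvalue_adjusted for c in contrasts) < 0.05
        assert rejections / n_rep <= 0.18


class TestDoseResponseExport:
    def test_curves_match_fit_predictions_to_machine_tolerance(self, glm_fit):
        rng = np.random.default_rng(0)
        curves = build_dose_response(glm_fit)
        assert set(curves) == set(GENOTYPE_TOKENS)
        for tok, curve in curves.items():
            doses = rng.uniform(0.0, 1.8, 20)
            probe = pd.DataFrame({"genotype": tok, "dose_ml": doses})
            np.testing.assert_allclose(
                curve.death_probability(doses), glm_fit.predict(probe),
                rtol=0.0, atol=1e-12,
            )

    def test_curve_at_zero_is_inverse_logit_intercept(self, glm_fit):
        for curve in build_dose_response(glm_fit).values():
            assert curve.death_probability(0.0) == pytest.approx(
                expit(curve.intercept), abs=1e-15
            )

    def test_monotone_when_slope_nonnegative(self):
        curve = DoseResponseCurve("SR", intercept=-2.0, slope=1.3)
        doses = np.linspace(0, 3, 50)
        assert np.all(np.diff(curve.death_probability(doses)) >= 0)

    def test_missing_genotype_level_raises(self, mortality_df):
        males = mortality_df[mortality_df["genotype"].isin(["SR", "ST"])]
        fit = fit_mortality_glm(males, formula="per_class")
        with pytest.raises(ValueError, match="absent"):
            build_dose_response(fit)


class TestFecundityExport:
    def test_mean_and_range_arithmetic(self):
        df = pd.DataFrame({
            "genotype": ["SRSR", "SRSR", "SRST", "STST"],
            "offspring": [10, 20, 30, 25],
        })
        fec = build_fecundity_params(df)
        assert fec.b_SRSR == 15.0
        assert fec.sweep_range("SRSR") == (5.0, 25.0)

    def test_missing_genotype_names_it(self):
        df = pd.DataFrame({"genotype": ["SRST", "STST"], "offspring": [30, 25]})
        with pytest.raises(ValueError, match="SRSR"):
            build_fecundity_params(df)

    def test_zero_truncated_mean_recovered(self):
        lam = 20.0
        params = TrueFecundityParams(
            log_means={t: np.log(lam) for t in ("SRSR", "SRST", "STST")},
            dose_effect=0.0, sigma_vial=0.0,
        )
        df = generate_fecundity_dataset(params, n_females_per_genotype=1500,
                                        dose_values=[0.0], seed=55)
        fec = build_fecundity_params(df)
        expected = lam / (1.0 - np.exp(-lam))
        n = (df["genotype"] == "SRSR").sum()
        se = np.sqrt(lam / n)
        assert abs(fec.b_SRSR - expected) < 3 * se

    def test_negative_brood_size_rejected(self):
        with pytest.raises(ValueError):
            FecundityParams(b_SRSR=-1.0, b_SRST=10.0, b_STST=10.0)
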