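import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from naccsubtypes import mixed_models as mm
from conftest import make_grouped_data

TABLE2_TERMS = [
    "subtype", "condition", "diagnosis", "age", "gender",
    "subtype:condition", "subtype:diagnosis", "condition:diagnosis",
    "subtype:condition:diagnosis",
]


def roi_design(n_subtypes, seed=0):
    """89 subjects (45 HC / 44 MDD) x 4 monetary conditions with a subtype
    factor of the requested size — the shape of the group-level ROI model."""
    rng = np.random.default_rng(seed)
    n_sub = 89
    labels = [f"s{i % n_subtypes}" for i in range(n_sub)]
    rows = []
    for i in range(n_sub):
        b = rng.normal()
        age = rng.uniform(20, 55)
        gender = rng.choice(["male", "female"])
        diag = "HC" if i < 45 else "MDD"
        for cond in ("-$1.0", "-$0.25", "+$0.25", "+$1.0"):
            rows.append((f"S{i:03d}", labels[i], cond, diag, age, gender,
                         b + rng.normal()))
    return pd.DataFrame(rows, columns=["subject", "subtype", "condition",
                                       "diagnosis", "age", "gender", "response"])


class TestContainmentDf:
    def test_left_roi_between_and_within_df(self):
        """Four-subtype ROI model: between-subject terms tested on 79 df,
        within-subject terms on 243 df."""
        df = mm.containment_df(
            mm.LmmSpec("response", TABLE2_TERMS, "subject"), roi_design(4))
        assert df.loc["subtype", "num_df"] == 3
        assert df.loc["subtype", "den_df"] == 79
        assert df.loc["condition", "den_df"] == 243
        assert df.loc["subtype:condition", "num_df"] == 9
        assert df.loc["subtype:condition", "den_df"] == 243
        assert df.loc["diagnosis", "den_df"] == 79
        assert df.loc["subtype:condition:diagnosis", "den_df"] == 243

    def test_right_roi_between_and_within_df(self):
        df = mm.containment_df(
            mm.LmmSpec("response", TABLE2_TERMS, "subject"), roi_design(3))
        assert df.loc["subtype", "num_df"] == 2
        assert df.loc["subtype", "den_df"] == 81
        assert df.loc["condition", "den_df"] == 249
        assert df.loc["subtype:condition", "den_df"] == 249

    def test_symptom_model_df(self):
        """44 single-row subjects, 3 subtypes + age + gender: den df 39."""
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "subject": [f"M{i}" for i in range(44)],
            "subtype": [f"s{i % 3}" for i in range(44)],
            "age": rng.uniform(20, 55, 44),
            "gender": rng.choice(["male", "female"], 44),
            "score": rng.normal(size=44),
        })
        out = mm.containment_df(mm.LmmSpec("score", ["subtype", "age", "gender"],
                                           "subject"), df)
        assert out.loc["subtype", "num_df"] == 2
        assert out.loc["subtype", "den_df"] == 39


class TestFitLmm:
    def test_single_row_per_subject_reduces_to_ols(self):
        df = make_grouped_data(n_subjects=50, n_cond=1, seed=2)
        spec = mm.LmmSpec("response", ["grp", "age", "gender"], "subject")
        fit = mm.fit_lmm(df, spec)
        ols = smf.ols("response ~ grp + age + gender", df).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-8)
        assert fit.sigma2_subject == 0.0
        f_ours = fit.f_table.loc["grp", "F"]
        f_ols = float(ols.f_test("grp[T.B] = 0").fvalue)
        assert f_ours == pytest.approx(f_ols, abs=1e-8)

    def test_reml_matches_statsmodels_mixedlm(self):
        df = make_grouped_data(n_subjects=40, n_cond=4, seed=3)
        spec = mm.LmmSpec("response", ["grp", "condition", "age"], "subject")
        fit = mm.fit_lmm(df, spec, method="REML")
        sm_fit = smf.mixedlm("response ~ grp + condition + age", df,
                             groups=df["subject"]).fit(reml=True)
        assert fit.sigma2_subject == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-4)
        assert fit.sigma2_resid == pytest.approx(float(sm_fit.scale), rel=1e-4)
        assert fit.loglik_reml == pytest.approx(float(sm_fit.llf), abs=1e-5)
        assert np.allclose(fit.params.to_numpy(), sm_fit.fe_params.to_numpy(), atol=1e-6)

    def test_ml_matches_statsmodels_mixedlm(self):
        df = make_grouped_data(n_subjects=40, n_cond=3, seed=4)
        spec = mm.LmmSpec("response", ["grp", "condition"], "subject")
        fit = mm.fit_lmm(df, spec, method="ML")
        sm_fit = smf.mixedlm("response ~ grp + condition", df,
                             groups=df["subject"]).fit(reml=False)
        assert fit.loglik_ml == pytest.approx(float(sm_fit.llf), abs=1e-5)

    def test_variance_component_recovery(self):
        """Planted sigma_subject = sigma_resid = 1 recovered within 15% on
        average over 50 seeded simulations of 200 subjects x 4 rows."""
        est_s, est_e = [], []
        for seed in range(50):
            df = make_grouped_data(n_subjects=200, n_cond=4, sigma_subject=1.0,
                                   sigma_resid=1.0, seed=seed)
            fit = mm.fit_lmm(df, mm.LmmSpec("response", ["grp"], "subject"))
            est_s.append(fit.sigma2_subject)
            est_e.append(fit.sigma2_resid)
        assert abs(np.mean(est_s) - 1.0) < 0.15
        assert abs(np.mean(est_e) - 1.0) < 0.15

    def test_constant_response_degenerates_with_warning(self):
        df = make_grouped_data(n_subjects=20, n_cond=2, seed=5)
        df["response"] = 4.2
        with pytest.warns(RuntimeWarning, match="constant response"):
            fit = mm.fit_lmm(df, mm.LmmSpec("response", ["grp"], "subject"))
        assert fit.sigma2_resid == 0.0
        assert np.isnan(fit.f_table.loc["grp", "F"])

    def test_rank_deficient_design_names_terms(self):
        df = make_grouped_data(n_subjects=20, n_cond=2, seed=6)
        df["grp2"] = df["grp"]
        with pytest.raises(ValueError, match="aliased"):
            mm.fit_lmm(df, mm.LmmSpec("response", ["grp", "grp2"], "subject"))

    def test_adding_constant_shifts_only_intercept(self):
        df = make_grouped_data(n_subjects=30, n_cond=3, seed=7)
        spec = mm.LmmSpec("response", ["grp", "condition"], "subject")
        f1 = mm.fit_lmm(df, spec)
        df2 = df.assign(response=df["response"] + 10.0)
        f2 = mm.fit_lmm(df2, spec)
        assert f2.params["Intercept"] == pytest.approx(f1.params["Intercept"] + 10.0, abs=1e-8)
        others = [c for c in f1.params.index if c != "Intercept"]
        assert np.allclose(f1.params[others], f2.params[others], atol=1e-8)

    def test_missing_values_rejected(self):
        df = make_grouped_data(n_subjects=10, n_cond=2, seed=8)
        df.loc[0, "response"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            mm.fit_lmm(df, mm.LmmSpec("response", ["grp"], "subject"))


class TestBic:
    def test_formula_shift(self):
        df = make_grouped_data(n_subjects=30, n_cond=2, seed=9)
        fit = mm.fit_lmm(df, mm.LmmSpec("response", ["grp"], "subject"))
        b = mm.bic(fit)
        fit.loglik_ml += 1.0
        assert mm.bic(fit) == pytest.approx(b - 2.0)

    def test_identical_fits_identical_bic(self):
        df = make_grouped_data(n_subjects=25, n_cond=3, seed=10)
        spec = mm.LmmSpec("response", ["grp", "condition"], "subject")
        assert mm.bic(mm.fit_lmm(df, spec)) == mm.bic(mm.fit_lmm(df, spec))

    def test_pure_noise_factor_increases_bic(self):
        """Adding an unrelated 5-level factor raises BIC in >= 90% of 50 seeds."""
        wins = 0
        for seed in range(50):
            df = make_grouped_data(n_subjects=40, n_cond=3, seed=seed,
                                   effects={("A", 0): 1.0})
            rng = np.random.default_rng(seed + 999)
            df["noisefac"] = rng.choice([f"n{j}" for j in range(5)],
                                        size=len(df))
            base = mm.fit_lmm(df, mm.LmmSpec("response", ["grp", "condition"], "subject"))
            wide = mm.fit_lmm(df, mm.LmmSpec("response", ["grp", "condition", "noisefac"],
                                             "subject"))
            wins += mm.bic(wide) > mm.bic(base)
        assert wins >= 45

    def test_reml_likelihood_never_used(self):
        df = make_grouped_data(n_subjects=20, n_cond=2, seed=11)
        fit = mm.fit_lmm(df, mm.LmmSpec("response", ["grp"], "subject"))
        assert fit.bic_uses_ml
        with pytest.raises(ValueError):
            mm.bic(fit, likelihood="REML")


class TestTukey:
    def test_two_levels_equal_t_test(self):
        df = make_grouped_data(n_subjects=40, n_cond=1, seed=12,
                               effects={("A", 0): 0.8})
        fit = mm.fit_lmm(df, mm.LmmSpec("response", ["grp", "age"], "subject"))
        tk = mm.tukey_posthoc(fit, "grp")
        ols = smf.ols("response ~ grp + age", df).fit()
        assert len(tk) == 1
        assert tk.loc[0, "p_corrected"] == pytest.approx(
            float(ols.pvalues["grp[T.B]"]), abs=1e-6)

    def test_pair_count(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({
            "subject": [f"S{i}" for i in range(60)],
            "lvl": rng.choice(list("abcd"), 60),
            "response": rng.normal(size=60),
        })
        fit = mm.fit_lmm(df, mm.LmmSpec("response", ["lvl"], "subject"))
        assert len(mm.tukey_posthoc(fit, "lvl")) == 4 * 3 / 2

    def test_null_type_one_error_calibrated(self):
        """Identical group means: the family-wise rejection rate of any
        pairwise comparison stays near the nominal 5%."""
        rng = np.random.default_rng(14)
        hits = 0
        reps = 1000
        for _ in range(reps):
            df = pd.DataFrame({
                "subject": [f"S{i}" for i in range(45)],
                "lvl": np.repeat(list("abc"), 15),
                "response": rng.normal(size=45),
            })
            fit = mm.fit_lmm(df, mm.LmmSpec("response", ["lvl"], "subject"))
            tk = mm.tukey_posthoc(fit, "lvl")
            hits += bool((tk["p_corrected"] < 0.05).any())
        assert 0.03 <= hits / reps <= 0.07

    def test_single_level_factor_rejected(self):
        df = make_grouped_data(n_subjects=20, n_cond=1, seed=15)
        df["one"] = "x"
        fit = mm.fit_lmm(df, mm.LmmSpec("response", ["grp"], "subject"))
        with pytest.raises(ValueError):
            mm.tukey_posthoc(fit, "one")


def test_forced_zero_between_variance_matches_anova():
    """With all subjects observed once, every F and p agrees with a
    fixed-effects ANOVA computed independently."""
    df = make_grouped_data(n_subjects=80, n_cond=1, seed=16,
                           effects={("A", 0): 0.5})
    fit = mm.fit_lmm(df, mm.LmmSpec("response", ["grp", "gender"], "subject"))
    ols = smf.ols("response ~ grp + gender", df).fit()
    for term, contrast in (("grp", "grp[T.B] = 0"), ("gender", "gender[T.male] = 0")):
        ftest = ols.f_test(contrast)
        assert fit.f_table.loc[term, "F"] == pytest.approx(float(ftest.fvalue), abs=1e-6)
        assert fit.f_table.loc[term, "p"] == pytest.approx(float(ftest.pvalue), abs=1e-6)
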