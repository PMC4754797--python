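import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from naccsubtypes import symptom_association as sa
from naccsubtypes import synthetic_data as sdata


def toy_classes(n=60, p=5, sep=2.0, k=3, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.choice([f"c{i}" for i in range(k)], size=n)
    X = rng.normal(size=(n, p))
    for i in range(k):
        X[y == f"c{i}", i % p] += sep * i
    return X, y


class TestShrinkCorrelation:
    def test_single_variable(self):
        P, lam = sa.shrink_correlation(np.random.default_rng(0).normal(size=(20, 1)))
        assert P.shape == (1, 1) and P[0, 0] == 1.0

    def test_independent_columns_shrink_to_identity(self):
        rng = np.random.default_rng(1)
        P, lam = sa.shrink_correlation(rng.normal(size=(2000, 10)))
        off = P[~np.eye(10, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_forced_zero_gives_sample_correlation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        P, lam = sa.shrink_correlation(X, lam=0.0)
        assert lam == 0.0
        assert np.allclose(P, np.corrcoef(X, rowvar=False), atol=1e-12)

    def test_lambda_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for n, p in ((10, 8), (30, 5), (8, 20)):
            _, lam = sa.shrink_correlation(rng.normal(size=(n, p)))
            assert 0.0 <= lam <= 1.0

    def test_constant_column_named(self):
        X = pd.DataFrame({"a": np.random.default_rng(4).normal(size=10), "flat": 1.0})
        with pytest.raises(ValueError, match="flat"):
            sa.shrink_correlation(X)


class TestCatScores:
    def test_identity_correlation_reduces_to_t_scores(self):
        X, y = toy_classes(seed=5)
        cat, _ = sa.cat_scores(X, y, P=np.eye(X.shape[1]))
        # brute-force t-scores
        n = len(y)
        labels = np.unique(y)
        grand = X.mean(axis=0)
        ss = sum(np.sum((X[y == lab] - X[y == lab].mean(axis=0)) ** 2, axis=0)
                 for lab in labels)
        s = np.sqrt(ss / (n - len(labels)))
        for k, lab in enumerate(labels):
            nk = np.sum(y == lab)
            t = (X[y == lab].mean(axis=0) - grand) / (np.sqrt(1 / nk - 1 / n) * s)
            assert np.allclose(cat[:, k], t, atol=1e-10)

    def test_single_variable_cat_equals_t(self):
        X, y = toy_classes(p=1, seed=6)
        cat_id, _ = sa.cat_scores(X, y, P=np.eye(1))
        cat, _ = sa.cat_scores(X, y)
        assert np.allclose(cat, cat_id, atol=1e-12)

    def test_matches_brute_force_inverse_sqrt(self):
        """p=3 oracle: explicit eigendecomposition of P^{-1/2} t."""
        X, y = toy_classes(p=3, seed=7)
        P, _ = sa.shrink_correlation(X)
        cat, ranking = sa.cat_scores(X, y, P=P)
        t_id, _ = sa.cat_scores(X, y, P=np.eye(3))
        vals, vecs = np.linalg.eigh(P)
        P_inv_sqrt = vecs @ np.diag(vals ** -0.5) @ vecs.T
        expected = P_inv_sqrt @ t_id
        assert np.allclose(cat, expected, atol=1e-10)
        assert np.allclose(ranking, np.sum(expected**2, axis=1), atol=1e-10)

    def test_small_class_rejected(self):
        X = np.random.default_rng(8).normal(size=(5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            sa.cat_scores(X, y)


class TestFitSda:
    def test_large_separation_trains_perfectly(self):
        X, y = toy_classes(n=40, sep=10.0, k=2, seed=9)
        model = sa.fit_sda(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_identical_distributions_chance_accuracy(self):
        accs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 4))
            y = np.array(["a"] * 40 + ["b"] * 20)
            model = sa.fit_sda(X, y)
            accs.append(np.mean(model.predict(X) == y))
        # training accuracy hovers at/above the majority prior
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 2 / 3) < max(3 * se, 0.1)

    def test_single_class_rejected(self):
        X = np.random.default_rng(10).normal(size=(10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            sa.fit_sda(X, np.array(["a"] * 10))

    def test_priors_sum_to_one_and_lambda_in_range(self):
        X, y = toy_classes(seed=11)
        model = sa.fit_sda(X, y)
        assert model.priors.sum() == pytest.approx(1.0)
        assert 0.0 <= model.shrinkage_lambda <= 1.0
        P = model.shrunken_correlation
        assert np.allclose(P, P.T) and np.allclose(np.diag(P), 1.0)

    def test_matches_classical_lda_without_shrinkage(self):
        """lambda = 0 and n >> p: predictions coincide with a shared-covariance
        Gaussian LDA fitted independently."""
        X, y = toy_classes(n=400, p=4, sep=1.5, k=3, seed=12)
        model = sa.fit_sda(X, y, shrinkage=0.0)
        lda = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        rng = np.random.default_rng(13)
        Xtest = rng.normal(size=(100, 4)) + X.mean(axis=0)
        agree = np.mean(model.predict(Xtest) == lda.predict(Xtest))
        assert agree >= 0.97


class TestLooAccuracy:
    def test_separable_data_perfect(self):
        X, y = toy_classes(n=30, sep=12.0, k=2, seed=14)
        assert sa.loo_accuracy(X, y) == 1.0

    def test_shuffled_labels_at_chance(self):
        """Permutation null: mean LOO accuracy sits at the majority-class
        proportion within Monte-Carlo error."""
        rng = np.random.default_rng(15)
        accs = []
        for _ in range(50):
            X = rng.normal(size=(30, 3))
            y = rng.permutation(np.array(["a"] * 18 + ["b"] * 12))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                accs.append(sa.loo_accuracy(X, y))
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.6) < max(3 * se, 0.12)

    def test_variable_subset_restriction(self):
        X, y = toy_classes(n=40, p=6, sep=8.0, k=2, seed=16)
        df = pd.DataFrame(X, columns=[f"v{j}" for j in range(6)])
        acc_inf = sa.loo_accuracy(df, y, variable_set=["v0", "v1"])
        assert acc_inf > 0.9


class TestRfe:
    def test_trace_length(self):
        X, y = toy_classes(n=40, p=6, seed=17)
        with pytest.warns(UserWarning, match="overestimates"):
            trace = sa.rfe(X, y, min_variables=1)
        assert len(trace.steps) == 6
        assert trace.steps["removed"].iloc[-1] is None

    def test_two_variables_two_steps(self):
        X, y = toy_classes(n=30, p=2, seed=18)
        with pytest.warns(UserWarning):
            trace = sa.rfe(X, y, min_variables=1)
        assert len(trace.steps) == 2

    def test_each_step_removes_one_variable(self):
        X, y = toy_classes(n=40, p=5, seed=19)
        with pytest.warns(UserWarning):
            trace = sa.rfe(X, y)
        sizes = trace.steps["n_variables"].tolist()
        assert sizes == [5, 4, 3, 2, 1]

    def test_planted_informative_variables_survive(self):
        """Two informative items (2 pooled-sd shift) among 20 noise items are
        retained in the best set (single-seed sanity; the multi-seed rate is
        exercised in the acceptance suite)."""
        rng = np.random.default_rng(20)
        y = rng.choice(["a", "b", "c"], size=44, p=[0.3, 0.45, 0.25])
        X = rng.normal(size=(44, 22))
        X[y == "a", 0] += 2.0
        X[y == "c", 1] += 2.0
        df = pd.DataFrame(X, columns=[f"v{j}" for j in range(22)])
        with pytest.warns(UserWarning):
            trace = sa.rfe(df, y)
        assert {"v0", "v1"} <= set(trace.best_set)


class TestScaleInvariance:
    def test_column_scaling_changes_nothing(self):
        X, y = toy_classes(n=40, p=5, sep=1.5, seed=21)
        Xs = X.copy()
        Xs[:, 2] *= 37.5
        cat1, r1 = sa.cat_scores(X, y)
        cat2, r2 = sa.cat_scores(Xs, y)
        assert np.allclose(cat1, cat2, atol=1e-8)
        assert np.allclose(r1, r2, atol=1e-8)
        m1, m2 = sa.fit_sda(X, y), sa.fit_sda(Xs, y)
        assert np.array_equal(m1.predict(X), m2.predict(Xs))
        assert sa.loo_accuracy(X, y) == sa.loo_accuracy(Xs, y)


class TestDiscriminantCorrelations:
    def test_single_driving_feature_correlates_perfectly(self):
        rng = np.random.default_rng(22)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(6, 1, 20)])
        y = np.array(["lo"] * 20 + ["hi"] * 20)
        X = pd.DataFrame({"driver": x})
        model = sa.fit_sda(X, y)
        out = sa.discriminant_correlations(X, model)
        assert np.allclose(np.abs(out["r"]), 1.0, atol=1e-10)
        assert out["r"].between(-1, 1).all()

    def test_planted_item_has_max_correlation(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.choice(["a", "b"], size=40)
            X = rng.normal(size=(40, 6))
            X[y == "a", 3] += 3.0
            df = pd.DataFrame(X, columns=[f"v{j}" for j in range(6)])
            model = sa.fit_sda(df, y)
            out = sa.discriminant_correlations(df, model)
            best = out.loc[out["r"].abs().idxmax(), "item"]
            wins += best == "v3"
        assert wins >= 9


class TestPosthoc:
    def _symptom_frame(self, n, n_subtypes, seed=0):
        rng = np.random.default_rng(seed)
        subj = [f"M{i:02d}" for i in range(n)]
        symptoms = pd.DataFrame({
            "subject": subj,
            "itemA": rng.integers(0, 5, n).astype(float),
            "itemB": rng.integers(0, 5, n).astype(float),
        })
        labels = pd.Series([f"c{i % n_subtypes}" for i in range(n)], index=subj)
        cov = pd.DataFrame({"subject": subj, "age": rng.uniform(20, 55, n),
                            "gender": rng.choice(["male", "female"], n)})
        return symptoms, labels, cov

    def test_df_pair_44_subjects_3_subtypes(self):
        symptoms, labels, cov = self._symptom_frame(44, 3, seed=23)
        out = sa.posthoc_symptom_tests(symptoms, labels, cov)
        assert (out["num_df"] == 2).all()
        assert (out["den_df"] == 39).all()

    def test_df_pair_44_subjects_4_subtypes(self):
        symptoms, labels, cov = self._symptom_frame(44, 4, seed=24)
        out = sa.posthoc_symptom_tests(symptoms, labels, cov)
        assert (out["num_df"] == 3).all()
        assert (out["den_df"] == 38).all()

    def test_bonferroni_over_items_tested(self):
        symptoms, labels, cov = self._symptom_frame(44, 3, seed=25)
        out = sa.posthoc_symptom_tests(symptoms, labels, cov)
        assert np.allclose(out["p_corrected"],
                           np.minimum(out["p"] * len(out), 1.0))

    def test_missing_values_rejected(self):
        symptoms, labels, cov = self._symptom_frame(20, 2, seed=26)
        symptoms.loc[0, "itemA"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            sa.posthoc_symptom_tests(symptoms, labels, cov)
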