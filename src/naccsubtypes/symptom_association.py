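"""Shrinkage discriminant analysis (SDA) of symptom items against subtypes.

The discriminant model works on standardized features.  The pooled
within-class feature correlation matrix is shrunk toward the identity,
``P = (1-lambda) R + lambda I``, with the analytic variance-minimizing
intensity (the ratio of the
summed sampling variances of the off-diagonal correlations to their summed
squares) — the standard remedy when items outnumber subjects.  Per-class
correlation-adjusted t-scores ("cat" scores), ``P^{-1/2} t_k``, rank each
item's contribution to group separation after decorrelation; recursive
feature elimination (RFE) removes the lowest-ranked item step by step while
leave-one-out cross-validation tracks generalization, and the best-scoring
item set is retained.  Selected items are then related to the discriminant
outputs by Pearson correlation with Bonferroni flags, and per-item post-hoc
linear models (subtype + age + gender) confirm univariate associations.

The discovery analysis is run on patient (MDD) subjects only: control
subjects have little or no variance on these clinical items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import mixed_models

__all__ = [
    "SdaModel",
    "RfeTrace",
    "shrink_correlation",
    "cat_scores",
    "fit_sda",
    "loo_accuracy",
    "rfe",
    "discriminant_correlations",
    "posthoc_symptom_tests",
]


@dataclass
class SdaModel:
    class_labels: list
    priors: np.ndarray
    feature_means: np.ndarray  # K x p, raw scale
    grand_mean: np.ndarray
    pooled_sd: np.ndarray
    shrunken_correlation: np.ndarray
    shrinkage_lambda: float
    cat_matrix: np.ndarray  # p x K
    coef: np.ndarray  # K x p, weights on standardized features
    offset: np.ndarray  # K

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """LD_k(x) for each row; proportional to the log posterior of class k."""
        Z = (np.asarray(X, dtype=float) - self.grand_mean) / self.pooled_sd
        return Z @ self.coef.T + self.offset

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return np.asarray(self.class_labels, dtype=object)[np.argmax(scores, axis=1)]


@dataclass
class RfeTrace:
    steps: pd.DataFrame  # step, n_variables, removed, loo_accuracy
    variable_sets: list[list[str]]
    best_set: list[str]
    best_accuracy: float


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def shrink_correlation(X, lam: float | None = None) -> tuple[np.ndarray, float]:
    """Shrunken correlation matrix ``(1-lambda) R + lambda I``.

    ``lam=None`` (default) uses the analytic variance-minimizing intensity,
    clipped to [0, 1]; passing a value forces that intensity (``lam=0``
    returns the sample correlation unchanged).
    """
    M, names = _as_matrix(X)
    n, p = M.shape
    if n < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    sd = M.std(axis=0, ddof=1)
    bad = [names[j] for j in np.flatnonzero(sd < 1e-12)]
    if bad:
        raise ValueError(f"constant columns cannot be correlated: {bad}")
    if p == 1:
        return np.ones((1, 1)), 0.0
    Z = (M - M.mean(axis=0)) / sd
    R = Z.T @ Z / (n - 1)
    np.fill_diagonal(R, 1.0)
    # Sampling variance of each off-diagonal r via the variance of the
    # centered cross-products w_kij = z_ki z_kj.
    W = np.einsum("ki,kj->ij", Z**2, Z**2)  # sum_k (z_ki z_kj)^2
    sum_w = R * (n - 1)
    var_r = n / (n - 1.0) ** 3 * (W - sum_w**2 / n)
    if lam is None:
        off = ~np.eye(p, dtype=bool)
        denom = float(np.sum(R[off] ** 2))
        lam = 1.0 if denom == 0 else float(np.clip(np.sum(var_r[off]) / denom, 0.0, 1.0))
    elif not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage intensity must lie in [0, 1]")
    P = (1.0 - lam) * R + lam * np.eye(p)
    return P, lam


def _class_stats(M: np.ndarray, y: np.ndarray, min_class_size: int = 2):
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < min_class_size):
        small = labels[counts < min_class_size]
        raise ValueError(f"classes with fewer than {min_class_size} members: {list(small)}")
    n, p = M.shape
    means = np.vstack([M[y == lab].mean(axis=0) for lab in labels])
    ss = np.zeros(p)
    for lab in labels:
        d = M[y == lab] - M[y == lab].mean(axis=0)
        ss += np.sum(d**2, axis=0)
    pooled_sd = np.sqrt(ss / (n - len(labels)))
    pooled_sd = np.where(pooled_sd < 1e-12, 1e-12, pooled_sd)
    return labels, counts, means, pooled_sd


def _within_class_correlation(M, y, labels, means, lam=None):
    """Shrunken correlation of the pooled within-class residuals.

    Group-mean separation must not leak into the correlation the
    discriminant inverts, so each class is centered on its own mean first.
    Columns with no within-class variance are carried as identity rows."""
    res = M.astype(float).copy()
    for lab, mu in zip(labels, means):
        res[y == lab] -= mu
    p = res.shape[1]
    sd = res.std(axis=0, ddof=1)
    ok = sd > 1e-12
    P = np.eye(p)
    lam_est = 1.0 if lam is None else lam
    if ok.sum() >= 2:
        Psub, lam_est = shrink_correlation(res[:, ok], lam=lam)
        P[np.ix_(ok, ok)] = Psub
    return P, float(lam_est)


def _inv_sqrt(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(P)
    vals = np.maximum(vals, 1e-12)
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def cat_scores(X, labels, P: np.ndarray | None = None, min_class_size: int = 2):
    """Correlation-adjusted t-scores per (feature, class) and the per-feature
    ranking score (sum of squared cat scores across classes).

    The class-k t-vector is ``(mu_k - mu) / (m_k s)`` with
    ``m_k = sqrt(1/n_k - 1/n)`` and pooled within-class sd ``s``; the cat
    vector decorrelates it with ``P^{-1/2}`` (eigendecomposition inverse
    square root of the shrunken correlation).
    """
    M, _names = _as_matrix(X)
    y = np.asarray(labels)
    class_labels, counts, means, pooled_sd = _class_stats(M, y, min_class_size)
    n = len(y)
    if P is None:
        P, _ = _within_class_correlation(M, y, class_labels, means)
    grand = M.mean(axis=0)
    T = np.empty((M.shape[1], len(class_labels)))
    for k, (lab, nk) in enumerate(zip(class_labels, counts)):
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        T[:, k] = (means[k] - grand) / (mk * pooled_sd)
    cat = _inv_sqrt(P) @ T
    ranking = np.sum(cat**2, axis=1)
    return cat, ranking


def fit_sda(X, labels, min_class_size: int = 2,
            shrinkage: float | None = None) -> SdaModel:
    """Fit the shrinkage discriminant model.

    Features are standardized by grand mean and pooled within-class sd;
    ``LD_k(z) = mu_k' P^-1 z - mu_k' P^-1 mu_k / 2 + log pi_k`` with
    standardized class means and empirical priors.  ``shrinkage`` forces the
    correlation-shrinkage intensity (``0`` gives classical LDA behaviour and
    is only safe when subjects clearly outnumber variables).
    """
    M, names = _as_matrix(X)
    y = np.asarray(labels)
    class_labels, counts, means, pooled_sd = _class_stats(M, y, min_class_size)
    n = len(y)
    P, lam = _within_class_correlation(M, y, class_labels, means, lam=shrinkage)
    if lam == 0.0 and M.shape[1] >= n:
        cond = np.linalg.cond(P)
        if cond > 1e10:
            raise ValueError(
                "correlation matrix is singular with no shrinkage; "
                "shrinkage regularization is required when p >= n"
            )
    grand = M.mean(axis=0)
    mu_std = (means - grand) / pooled_sd  # K x p
    Pinv_mu = np.linalg.solve(P, mu_std.T).T  # K x p
    priors = counts / n
    offset = -0.5 * np.sum(mu_std * Pinv_mu, axis=1) + np.log(priors)
    cat, _ = cat_scores(M, y, P=P, min_class_size=min_class_size)
    return SdaModel(
        class_labels=list(class_labels),
        priors=priors,
        feature_means=means,
        grand_mean=grand,
        pooled_sd=pooled_sd,
        shrunken_correlation=P,
        shrinkage_lambda=lam,
        cat_matrix=cat,
        coef=Pinv_mu,
        offset=offset,
    )


def loo_accuracy(X, labels, variable_set=None) -> float:
    """Leave-one-out accuracy of the SDA classifier on the given variables."""
    if isinstance(X, pd.DataFrame):
        df = X if variable_set is None else X[list(variable_set)]
        M = df.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if variable_set is not None:
            M = M[:, list(variable_set)]
    y = np.asarray(labels)
    n = len(y)
    if n < len(np.unique(y)) + 2:
        raise ValueError("too few subjects for leave-one-out evaluation")
    correct = 0
    idx = np.arange(n)
    warned = False
    for i in range(n):
        tr = idx != i
        if not warned and np.any(np.unique(y[tr], return_counts=True)[1] < 2):
            warnings.warn(
                "a class is down to a single member in some leave-one-out "
                "folds; its mean is estimated from that one subject",
                RuntimeWarning, stacklevel=2,
            )
            warned = True
        model = fit_sda(M[tr], y[tr], min_class_size=1)
        pred = model.predict(M[i: i + 1])[0]
        correct += pred == y[i]
    return correct / n


def rfe(X, labels, min_variables: int = 1) -> RfeTrace:
    """Recursive feature elimination with LOO-tracked accuracy.

    At each step the LOO accuracy of the current variable set is recorded,
    cat-score rankings are recomputed on the full data restricted to the set,
    and the lowest-ranked variable is removed (ties broken by column order)
    until ``min_variables`` remain.  The best set is the one with maximum
    accuracy, the earliest (largest) set winning ties.  Because the best step
    is picked after seeing all accuracies, the reported best accuracy is an
    optimistic (overestimated) measure of generalization.
    """
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        M, names = _as_matrix(X)
        df = pd.DataFrame(M, columns=names)
    if df.shape[1] < 2:
        raise ValueError("RFE needs at least 2 variables")
    y = np.asarray(labels)
    current = list(df.columns)
    records = []
    sets = []
    step = 0
    while True:
        acc = loo_accuracy(df[current], y)
        sets.append(list(current))
        if len(current) > min_variables:
            _, ranking = cat_scores(df[current], y)
            drop_idx = int(np.argmin(ranking))  # argmin keeps first on ties
            removed = current[drop_idx]
        else:
            removed = None
        records.append((step, len(current), removed, acc))
        if removed is None:
            break
        current = [c for c in current if c != removed]
        step += 1
    steps = pd.DataFrame(records, columns=["step", "n_variables", "removed", "loo_accuracy"])
    best_idx = int(steps["loo_accuracy"].idxmax())  # idxmax keeps first (largest set)
    best_acc = float(steps.loc[best_idx, "loo_accuracy"])
    warnings.warn(
        "best RFE accuracy is selected post hoc and overestimates generalization",
        UserWarning, stacklevel=2,
    )
    return RfeTrace(steps=steps, variable_sets=sets, best_set=sets[best_idx],
                    best_accuracy=best_acc)


def discriminant_correlations(X_selected, model: SdaModel, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each selected item with each discriminant
    output, with Bonferroni-corrected significance flags (family = items x
    classes)."""
    if isinstance(X_selected, pd.DataFrame):
        names = list(X_selected.columns)
        M = X_selected.to_numpy(dtype=float)
    else:
        M, names = _as_matrix(X_selected)
    scores = model.decision_function(M)
    K = scores.shape[1]
    family = len(names) * K
    rows = []
    for j, item in enumerate(names):
        for k, lab in enumerate(model.class_labels):
            ld = scores[:, k]
            if np.std(ld) < 1e-12 or np.std(M[:, j]) < 1e-12:
                rows.append((item, lab, np.nan, np.nan, False))
                continue
            r, p = stats.pearsonr(M[:, j], ld)
            rows.append((item, lab, float(r), float(p), bool(p < alpha / family)))
    return pd.DataFrame(rows, columns=["item", "class", "r", "p", "bonferroni_significant"])


def posthoc_symptom_tests(
    symptoms: pd.DataFrame,
    subtype_labels: pd.Series,
    covariates: pd.DataFrame,
    items: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-item confirmatory models ``item ~ subtype + age + gender``.

    One row per subject, so the mixed model reduces to fixed-effects least
    squares with containment df equal to the residual df.  P-values are
    Bonferroni-corrected over the number of items tested.
    """
    items = list(items) if items is not None else [c for c in symptoms.columns if c != "subject"]
    df = symptoms.merge(covariates, on="subject")
    df = df.merge(subtype_labels.rename("subtype").rename_axis("subject").reset_index(),
                  on="subject")
    if df[items].isna().any().any():
        raise ValueError("missing symptom values; exclude incomplete subjects first")
    rows = []
    n_tested = 0
    for item in items:
        if df[item].std() < 1e-12:
            warnings.warn(f"skipping zero-variance item {item!r}", RuntimeWarning,
                          stacklevel=2)
            continue
        n_tested += 1
    for item in items:
        if df[item].std() < 1e-12:
            continue
        df = df.rename(columns={item: "_resp"})
        spec = mixed_models.LmmSpec("_resp", ["subtype", "age", "gender"], "subject")
        fit = mixed_models.fit_lmm(df, spec)
        row = fit.f_table.loc["subtype"]
        df = df.rename(columns={"_resp": item})
        p_corr = min(float(row["p"]) * n_tested, 1.0)
        rows.append((item, float(row["F"]), int(row["num_df"]), int(row["den_df"]),
                     float(row["p"]), p_corr, p_corr < alpha))
    return pd.DataFrame(rows, columns=["item", "F", "num_df", "den_df", "p",
                                       "p_corrected", "corrected_significant"])
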