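"""Response-pattern subtype discovery.

PCA (with jackknife standard errors and leave-one-out principal scores)
describes the variation of the 4-dimensional condition-versus-neutral
response vectors across subjects.  Subjects are then clustered by Ward's
minimum-variance method on Euclidean distances, the dendrogram is cut at
every candidate level k = 2..k_max, and each partition is scored with a
random-intercept mixed model of the long-format responses
(``response ~ cluster + condition + cluster:condition + age + gender``).
The selected level is the one with a significant cluster main effect and the
minimum ML-likelihood BIC; when no level reaches significance a no-solution
marker is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from . import mixed_models

__all__ = [
    "PcaResult",
    "ClusterSolution",
    "pca_with_jackknife",
    "euclidean_distance_matrix",
    "ward_tree",
    "enumerate_cut_levels",
    "candidate_levels",
    "select_optimal_level",
    "discover_subtypes",
]


@dataclass
class PcaResult:
    component_loadings: np.ndarray  # columns = components
    explained_percent: np.ndarray
    jackknife_se: np.ndarray
    loo_scores: np.ndarray  # n x 2 (PC1, PC2)
    full_scores: np.ndarray  # n x n_components, full-data projection


@dataclass
class ClusterSolution:
    n_clusters: int | None
    labels: pd.Series | None  # subject -> "c1".."ck"
    selection_bic: float | None
    cluster_effect_p: float | None
    linkage_heights: np.ndarray
    selection_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def selected(self) -> bool:
        return self.n_clusters is not None


def _pca_eig(X: np.ndarray):
    """Eigendecomposition of the sample covariance of mean-centered columns,
    eigenvalues descending."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order], Xc


def pca_with_jackknife(patterns: np.ndarray) -> PcaResult:
    """PCA of mean-centered (unscaled) response patterns.

    Explained-variance percentages carry jackknife standard errors from the
    n delete-one refits; leave-one-out principal scores project each held-out
    subject onto loadings fitted without it, sign-aligned to the full-data
    loadings (eigenvector sign is arbitrary).
    """
    X = np.asarray(patterns, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5:
        raise ValueError("need an n x p matrix with n >= 5")
    if np.isnan(X).any():
        raise ValueError("missing values in response patterns")
    n, p = X.shape
    vals, vecs, Xc = _pca_eig(X)
    explained = 100.0 * vals / vals.sum()
    full_scores = Xc @ vecs

    jack = np.empty((n, p))
    loo = np.empty((n, 2))
    idx = np.arange(n)
    for i in range(n):
        Xi = X[idx != i]
        vals_i, vecs_i, _ = _pca_eig(Xi)
        jack[i] = 100.0 * vals_i / vals_i.sum()
        # align held-out loadings to the full-data orientation
        signs = np.sign(np.sum(vecs_i * vecs, axis=0))
        signs[signs == 0] = 1.0
        vecs_i = vecs_i * signs
        loo[i] = ((X[i] - Xi.mean(axis=0)) @ vecs_i)[:2]
    se = np.sqrt((n - 1) / n * np.sum((jack - jack.mean(axis=0)) ** 2, axis=0))
    return PcaResult(
        component_loadings=vecs,
        explained_percent=explained,
        jackknife_se=se,
        loo_scores=loo,
        full_scores=full_scores,
    )


def euclidean_distance_matrix(patterns: np.ndarray) -> np.ndarray:
    """Symmetric n x n Euclidean distance matrix between response vectors."""
    X = np.asarray(patterns, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in response patterns")
    return squareform(pdist(X, metric="euclidean"))


def ward_tree(distances: np.ndarray) -> np.ndarray:
    """Ward linkage (minimum-variance on squared Euclidean distances,
    Lance-Williams update) from a full or condensed distance matrix."""
    d = np.asarray(distances, dtype=float)
    if d.ndim == 2:
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        d = squareform(d, checks=False)
    return linkage(d, method="ward")


def enumerate_cut_levels(tree: np.ndarray, k_max: int = 8) -> dict[int, np.ndarray]:
    """Nested partitions from horizontal dendrogram cuts at k = 2..k_max."""
    n = tree.shape[0] + 1
    if k_max > n:
        raise ValueError(f"k_max {k_max} exceeds number of observations {n}")
    return {k: fcluster(tree, t=k, criterion="maxclust") for k in range(2, k_max + 1)}


def candidate_levels(tree: np.ndarray, k_max: int = 8) -> list[int]:
    """Dendrogram levels supported by the tree geometry.

    Cutting into k clusters severs the merge with height ``h[n - k]``; the
    deepest supported level k* is the one just above the largest relative gap
    ``h[n - k] / h[n - k - 1]`` for k = 2..k_max, and every level 2..k* is
    proposed.  Separated clusters produce a sharp height drop immediately
    below their own level, so the ratio peaks at the true cluster count;
    structureless data produce a flat ratio profile and an arbitrary shallow
    k*.  The mixed-model/BIC selection then arbitrates among the proposed
    levels only, which keeps it from rewarding noise-driven splits that Ward
    has already optimised.
    """
    n = tree.shape[0] + 1
    k_hi = min(k_max, n - 2)
    if k_hi < 2:
        return [2] if n > 2 else []
    h = tree[:, 2]
    ratios = {}
    for k in range(2, k_hi + 1):
        below = h[n - k - 1]
        ratios[k] = h[n - k] / below if below > 0 else np.inf
    k_star = max(ratios, key=lambda k: (ratios[k], -k))
    return list(range(2, k_star + 1))


def select_optimal_level(
    partitions: dict[int, np.ndarray],
    responses: pd.DataFrame,
    subjects: list[str],
    tree: np.ndarray | None = None,
    alpha: float = 0.05,
    include_diagnosis: bool = False,
) -> ClusterSolution:
    """Score each candidate partition with the selection mixed model and pick
    the significant level with minimum BIC.

    ``responses`` is long format with columns ``subject, condition, response,
    age, gender`` (plus ``diagnosis`` when included); ``subjects`` gives the
    row order of the clustered pattern matrix so labels can be joined on.
    """
    terms = ["cluster", "condition", "cluster:condition", "age", "gender"]
    if include_diagnosis:
        terms += ["diagnosis"]
    spec = mixed_models.LmmSpec("response", terms, "subject")
    heights = tree[:, 2] if tree is not None else np.array([])

    rows = []
    fits = {}
    for k, labels in sorted(partitions.items()):
        lab = pd.Series([f"c{v}" for v in labels], index=subjects, name="cluster")
        if lab.nunique() < 2:
            continue
        df = responses.merge(lab.rename_axis("subject").reset_index(), on="subject")
        try:
            fit = mixed_models.fit_lmm(df, spec, method="REML")
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"skipping level k={k}: {exc}", RuntimeWarning, stacklevel=2)
            continue
        p = float(fit.f_table.loc["cluster", "p"])
        b = mixed_models.bic(fit)
        rows.append((k, b, p))
        fits[k] = lab
    table = pd.DataFrame(rows, columns=["k", "bic", "p"])
    table["significant"] = table["p"] < alpha

    eligible = table[table["significant"]]
    if eligible.empty:
        table["selected"] = False
        return ClusterSolution(None, None, None, None, heights, table)
    best = eligible.loc[eligible["bic"].idxmin()]
    k_best = int(best["k"])
    table["selected"] = table["k"] == k_best
    return ClusterSolution(
        n_clusters=k_best,
        labels=fits[k_best],
        selection_bic=float(best["bic"]),
        cluster_effect_p=float(best["p"]),
        linkage_heights=heights,
        selection_table=table,
    )


def discover_subtypes(
    patterns: np.ndarray,
    subjects: list[str],
    responses: pd.DataFrame,
    k_max: int = 8,
    alpha: float = 0.05,
    include_diagnosis: bool = False,
) -> tuple[ClusterSolution, PcaResult]:
    """Full subtype discovery for one ROI/phase.

    Runs PCA, builds the Ward tree on Euclidean distances, extracts the
    tree-supported candidate levels and applies the mixed-model/BIC level
    selection to them.  ``responses`` is the long table the selection model
    is fit on (see :func:`select_optimal_level`).
    """
    pca = pca_with_jackknife(patterns)
    tree = ward_tree(euclidean_distance_matrix(patterns))
    partitions = enumerate_cut_levels(tree, k_max=k_max)
    keep = candidate_levels(tree, k_max=k_max)
    partitions = {k: v for k, v in partitions.items() if k in keep}
    solution = select_optimal_level(
        partitions, responses, subjects, tree=tree, alpha=alpha,
        include_diagnosis=include_diagnosis,
    )
    return solution, pca
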