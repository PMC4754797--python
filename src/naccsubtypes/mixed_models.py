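"""Random-intercept linear mixed-effects models with containment degrees of freedom.

The model is ``y = X beta + Z b + e`` with a single random intercept per
subject, ``b ~ N(0, sigma2_subject I)`` and ``e ~ N(0, sigma2_resid I)``.
This induces a compound-symmetry covariance within subject.  Estimation
profiles the likelihood (ML or REML) over the variance ratio
``theta = sigma2_subject / sigma2_resid``; at each candidate ratio the fixed
effects are the GLS solution and the residual scale is solved in closed form,
so the optimisation is a one-dimensional search.

Wald F statistics are reported per fixed-effect term (marginal tests on the
full model, treatment coding with the first level as reference).  Denominator
degrees of freedom follow the containment (inner-outer) rule used by classic
mixed-model software: a term whose design columns are constant within every
subject is "outer" and is tested against between-subject information
(``n_subjects - p_outer``); a term varying within subject is "inner" and is
tested against within-subject information (``n_obs - n_subjects - p_inner``).

BIC is always computed from the ML log-likelihood, ``-2 ll + k log(n_obs)``
with ``k`` the number of fixed-effect coefficients plus the two variance
parameters; REML likelihoods are not comparable across fixed-effect
structures and are never used for model selection here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy.linalg import qr
from scipy.optimize import minimize_scalar
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

__all__ = [
    "LmmSpec",
    "LmmFit",
    "fit_lmm",
    "containment_df",
    "bic",
    "tukey_posthoc",
]

# Residual-variance floor for likelihood evaluation; keeps degenerate
# (noise-free) fits finite and mutually comparable.
_VAR_FLOOR = 1e-12
_WITHIN_TOL = 1e-10


@dataclass
class LmmSpec:
    """Model specification: response column, ordered fixed-effect terms
    (patsy syntax, e.g. ``["subtype", "condition", "subtype:condition",
    "age", "gender"]``) and the subject grouping column."""

    response: str
    fixed_terms: list[str]
    grouping: str

    @property
    def rhs(self) -> str:
        return " + ".join(self.fixed_terms) if self.fixed_terms else "1"


@dataclass
class LmmFit:
    spec: LmmSpec
    method: str
    params: pd.Series
    cov_params: np.ndarray
    sigma2_subject: float
    sigma2_resid: float
    loglik_ml: float
    loglik_reml: float
    f_table: pd.DataFrame
    n_obs: int
    n_subjects: int
    n_fixed: int
    bic_uses_ml: bool = True
    design_info: object = field(default=None, repr=False)
    _emm_state: dict = field(default_factory=dict, repr=False)

    @property
    def bic(self) -> float:
        return bic(self)


def _design(spec: LmmSpec, data: pd.DataFrame):
    cols = [spec.response, spec.grouping]
    missing = [c for c in cols if c in data.columns and data[c].isna().any()]
    if missing:
        raise ValueError(f"missing values in columns {missing}")
    X = dmatrix("~ " + spec.rhs, data, NA_action="raise", return_type="matrix")
    di = X.design_info
    X = np.asarray(X, dtype=float)
    y = np.asarray(data[spec.response], dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"missing values in response {spec.response!r}")
    groups, group_idx = np.unique(np.asarray(data[spec.grouping]), return_inverse=True)
    return y, X, di, groups, group_idx


def _rank_check(X, di):
    p = X.shape[1]
    r = np.linalg.matrix_rank(X)
    if r < p:
        _, R, piv = qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        bad = sorted(piv[r:])
        names = [di.column_names[j] for j in bad]
        raise ValueError(f"rank-deficient fixed-effect design; aliased columns: {names}")


def _group_stats(y, X, group_idx, n_groups):
    n, p = X.shape
    sizes = np.bincount(group_idx, minlength=n_groups).astype(float)
    SX = np.zeros((n_groups, p))
    np.add.at(SX, group_idx, X)
    Sy = np.bincount(group_idx, weights=y, minlength=n_groups)
    return {
        "n": n,
        "p": p,
        "sizes": sizes,
        "SX": SX,
        "Sy": Sy,
        "XtX": X.T @ X,
        "Xty": X.T @ y,
        "yty": float(y @ y),
    }


def _gls(theta, st):
    """GLS pieces at variance ratio theta: A = X'V0^-1 X, b = X'V0^-1 y,
    q = y'V0^-1 y, with V0 = I + theta * ZZ' (block compound symmetry)."""
    # (I + theta J)^-1 = I - [theta/(1+n_i theta)] J per subject block
    c = theta / (1.0 + st["sizes"] * theta)
    A = st["XtX"] - (st["SX"] * c[:, None]).T @ st["SX"]
    b = st["Xty"] - st["SX"].T @ (c * st["Sy"])
    q = st["yty"] - float(c @ (st["Sy"] ** 2))
    beta = np.linalg.solve(A, b)
    rss = max(q - 2.0 * float(beta @ b) + float(beta @ (A @ beta)), 0.0)
    logdetV0 = float(np.sum(np.log1p(st["sizes"] * theta)))
    return A, beta, rss, logdetV0


def _neg2ll(theta, st, reml):
    n, p = st["n"], st["p"]
    A, beta, rss, logdetV0 = _gls(theta, st)
    if reml:
        df = n - p
        s2 = max(rss / df, _VAR_FLOOR)
        sign, logdetA = np.linalg.slogdet(A)
        val = df * np.log(2.0 * np.pi * s2) + logdetV0 + logdetA + df
    else:
        s2 = max(rss / n, _VAR_FLOOR)
        val = n * np.log(2.0 * np.pi * s2) + logdetV0 + n
    return val


def _optimize_theta(st, reml):
    if np.all(st["sizes"] <= 1):
        return 0.0
    f0 = _neg2ll(0.0, st, reml)
    res = minimize_scalar(
        lambda u: _neg2ll(np.exp(u), st, reml),
        bounds=(-15.0, 12.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if res.fun < f0 - 1e-10:
        return float(np.exp(res.x))
    return 0.0


def _term_slices(di):
    return {name: di.term_name_slices[name] for name in di.term_names}


def _classify_terms(di, X, group_idx, n_groups):
    """Split terms into within-subject ("inner") and between-subject ("outer")
    by whether any design column varies within any subject."""
    inner = {}
    order = np.argsort(group_idx, kind="stable")
    Xs = X[order]
    gs = group_idx[order]
    starts = np.searchsorted(gs, np.arange(n_groups))
    stops = np.append(starts[1:], len(gs))
    for name, sl in _term_slices(di).items():
        cols = Xs[:, sl]
        varies = False
        for a, b in zip(starts, stops):
            blk = cols[a:b]
            if blk.shape[0] > 1 and np.any(np.ptp(blk, axis=0) > _WITHIN_TOL):
                varies = True
                break
        inner[name] = varies
    return inner


def _containment_from_design(di, X, group_idx, n_groups):
    inner = _classify_terms(di, X, group_idx, n_groups)
    slices = _term_slices(di)
    p_inner = sum(slices[t].stop - slices[t].start for t in slices if inner[t])
    p_outer = sum(slices[t].stop - slices[t].start for t in slices if not inner[t])
    n_obs = X.shape[0]
    den_outer = n_groups - p_outer
    den_inner = n_obs - n_groups - p_inner
    rows = {}
    for t, sl in slices.items():
        rows[t] = (sl.stop - sl.start, den_inner if inner[t] else den_outer)
    return rows


def containment_df(spec: LmmSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Numerator and containment denominator df for every fixed-effect term.

    Returns a DataFrame indexed by term name with ``num_df`` and ``den_df``
    columns (the intercept row is included).
    """
    y, X, di, groups, group_idx = _design(spec, data)
    rows = _containment_from_design(di, X, group_idx, len(groups))
    out = pd.DataFrame(
        [(t, nd, dd) for t, (nd, dd) in rows.items()],
        columns=["term", "num_df", "den_df"],
    ).set_index("term")
    return out


def fit_lmm(data: pd.DataFrame, spec: LmmSpec, method: str = "REML") -> LmmFit:
    """Fit the random-intercept LMM by profiled ML/REML.

    ``method`` selects which criterion supplies the reported variance
    components and fixed-effect covariance; both log-likelihoods (each at its
    own optimum) are always reported so that BIC can use ML.
    """
    if method not in ("REML", "ML"):
        raise ValueError("method must be 'REML' or 'ML'")
    y, X, di, groups, group_idx = _design(spec, data)
    _rank_check(X, di)
    n, p = X.shape
    n_groups = len(groups)
    st = _group_stats(y, X, group_idx, n_groups)

    degenerate = float(np.var(y)) < 1e-14

    theta_ml = _optimize_theta(st, reml=False)
    theta_reml = _optimize_theta(st, reml=True)
    loglik_ml = -0.5 * _neg2ll(theta_ml, st, reml=False)
    loglik_reml = -0.5 * _neg2ll(theta_reml, st, reml=True)

    theta = theta_reml if method == "REML" else theta_ml
    A, beta, rss, _ = _gls(theta, st)
    ddof = (n - p) if method == "REML" else n
    s2 = rss / ddof
    if degenerate:
        warnings.warn("constant response: variance components are zero and F "
                      "statistics are undefined", RuntimeWarning, stacklevel=2)
        s2 = 0.0
    sigma2_resid = s2
    sigma2_subject = theta * s2
    cov = max(s2, _VAR_FLOOR) * np.linalg.inv(A)

    dfs = _containment_from_design(di, X, group_idx, n_groups)
    slices = _term_slices(di)
    rows = []
    for t, sl in slices.items():
        if t == "Intercept":
            continue
        num_df, den_df = dfs[t]
        bsub = beta[sl]
        Csub = cov[sl, sl]
        if degenerate or den_df <= 0 or num_df == 0:
            F = pv = np.nan  # one-level factors contribute no columns
        else:
            F = float(bsub @ np.linalg.solve(Csub, bsub)) / num_df
            pv = float(f_dist.sf(F, num_df, den_df))
        rows.append((t, num_df, den_df, F, pv))
    f_table = pd.DataFrame(rows, columns=["term", "num_df", "den_df", "F", "p"]).set_index("term")

    # state needed to build estimated-marginal-mean rows later
    factors = {}
    for factor, fi in di.factor_infos.items():
        name = factor.name()
        if fi.type == "categorical":
            factors[name] = ("categorical", list(fi.categories))
        else:
            col = pd.to_numeric(data[name], errors="coerce") if name in data.columns else None
            factors[name] = ("numerical", float(np.mean(col)) if col is not None else 0.0)

    return LmmFit(
        spec=spec,
        method=method,
        params=pd.Series(beta, index=di.column_names),
        cov_params=cov,
        sigma2_subject=float(sigma2_subject),
        sigma2_resid=float(sigma2_resid),
        loglik_ml=float(loglik_ml),
        loglik_reml=float(loglik_reml),
        f_table=f_table,
        n_obs=n,
        n_subjects=n_groups,
        n_fixed=p,
        design_info=di,
        _emm_state={"factors": factors},
    )


def bic(fit: LmmFit, likelihood: str = "ML") -> float:
    """Bayesian information criterion, ``-2 ll_ML + k log(n_obs)`` with
    ``k = n_fixed + 2`` (two variance parameters)."""
    if likelihood != "ML":
        raise ValueError("BIC is defined on the ML likelihood only")
    assert fit.bic_uses_ml
    k = fit.n_fixed + 2
    return -2.0 * fit.loglik_ml + k * np.log(fit.n_obs)


def _emm_rows(fit: LmmFit, factor: str):
    """Design rows of estimated marginal means for each level of `factor`:
    balanced average over the other categorical factors, covariates at their
    sample mean."""
    factors = fit._emm_state["factors"]
    if factor not in factors or factors[factor][0] != "categorical":
        raise ValueError(f"{factor!r} is not a categorical model factor")
    levels = factors[factor][1]
    others = {k: v for k, v in factors.items() if k != factor}
    cat_others = {k: v[1] for k, v in others.items() if v[0] == "categorical"}
    num_others = {k: v[1] for k, v in others.items() if v[0] == "numerical"}

    grids = [dict(zip(cat_others, combo)) for combo in _product(list(cat_others.values()))]
    rows = {}
    for lev in levels:
        recs = []
        for g in grids:
            rec = {factor: lev, **g, **num_others}
            recs.append(rec)
        df = pd.DataFrame(recs)
        (M,) = build_design_matrices([fit.design_info], df)
        rows[lev] = np.asarray(M, dtype=float).mean(axis=0)
    return rows


def _product(lists):
    if not lists:
        return [()]
    out = [()]
    for lst in lists:
        out = [t + (v,) for t in out for v in lst]
    return out


def tukey_posthoc(fit: LmmFit, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise comparisons of estimated marginal means for `factor`,
    corrected with the studentized-range distribution at the factor's
    containment denominator df."""
    rows = _emm_rows(fit, factor)
    levels = list(rows)
    if len(levels) < 2:
        raise ValueError("post-hoc comparisons need a factor with >= 2 levels")
    if factor in fit.f_table.index:
        den_df = int(fit.f_table.loc[factor, "den_df"])
    else:  # factor only appears inside interactions; fall back to outer df
        den_df = fit.n_subjects - 1
    beta = fit.params.to_numpy()
    out = []
    L = len(levels)
    for i in range(L):
        for j in range(i + 1, L):
            ell = rows[levels[i]] - rows[levels[j]]
            est = float(ell @ beta)
            se = float(np.sqrt(ell @ fit.cov_params @ ell))
            if se == 0.0:
                q = np.inf if est != 0 else 0.0
            else:
                q = abs(est) / se * np.sqrt(2.0)
            pv = float(studentized_range.sf(q, L, den_df))
            out.append((levels[i], levels[j], est, se, q, pv, pv < alpha))
    return pd.DataFrame(
        out,
        columns=["level_a", "level_b", "estimate", "se", "q", "p_corrected", "significant"],
    )
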