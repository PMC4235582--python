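"""Shared estimators for the movement analyses.

* conditional (matched case-control) logistic regression for 1:10 step
  strata, maximized directly as a per-stratum softmax likelihood, with a
  territory-clustered sandwich ("GEE-type") variance;
* Gaussian linear mixed models with data-set-in-territory nested random
  intercepts (REML via statsmodels MixedLM) and Nakagawa marginal /
  conditional R2;
* random-intercept logistic regression fitted by a Laplace approximation
  with the same nested grouping;
* stepwise backward elimination honouring marginality (interactions and
  quadratics leave before the main effects they contain);
* the paired one-sided Wilcoxon signed rank test, Spearman rank correlation,
  and the pairwise Pearson collinearity screen (|r| < 0.6).

Wald P-values are used throughout, on robust SEs wherever a cluster term is
declared, matching the reported beta +/- SE convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "UnidentifiableError",
    "SeparationError",
    "build_design",
    "fit_conditional_logistic",
    "fit_lmm",
    "fit_logistic_rim",
    "fit_ols",
    "nakagawa_r2",
    "backward_eliminate",
    "wilcoxon_signed_rank",
    "spearman",
    "pearson_screen",
]


class UnidentifiableError(ValueError):
    """A covariate carries no within-stratum (or overall) variation."""


class SeparationError(RuntimeError):
    """The conditional likelihood diverges (complete separation)."""


@dataclass
class FitResult:
    """Uniform container for every model fit in the pipeline."""

    method: str
    terms: list[str]
    params: pd.Series
    se: pd.Series
    robust_se: pd.Series
    pvalues: pd.Series
    term_pvalues: dict[str, float]
    loglik: float
    n_obs: int
    n_groups: int
    vc: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    term_columns: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def predict_linear(self, X: pd.DataFrame) -> np.ndarray:
        """Fixed-effect linear predictor for a design built with the same terms."""
        cols = [c for c in self.params.index if c != "Intercept"]
        eta = np.zeros(len(X))
        if "Intercept" in self.params.index and "Intercept" in X.columns:
            eta += self.params["Intercept"] * X["Intercept"].to_numpy()
        for c in cols:
            eta += self.params[c] * X[c].to_numpy()
        return eta

    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "terms": self.terms,
            "params": self.params.to_dict(),
            "se": self.se.to_dict(),
            "robust_se": self.robust_se.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "term_pvalues": self.term_pvalues,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "vc": self.vc,
            "flags": self.flags,
            "meta": {k: v for k, v in self.meta.items() if np.isscalar(v) or isinstance(v, str)},
        }

    def summary(self) -> str:
        lines = [f"{self.method}: n={self.n_obs}, groups={self.n_groups}, logLik={self.loglik:.2f}"]
        lines.append(f"{'term':<42}{'beta':>10}{'SE':>9}{'robSE':>9}{'P':>10}")
        for name in self.params.index:
            lines.append(
                f"{name:<42}{self.params[name]:>10.3f}{self.se[name]:>9.3f}"
                f"{self.robust_se[name]:>9.3f}{self.pvalues[name]:>10.4g}"
            )
        for k, v in self.vc.items():
            lines.append(f"  var({k}) = {v:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def build_design(
    df: pd.DataFrame, terms: Sequence[str], drop_intercept: bool = False
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Patsy design matrix plus a term -> columns map.

    With ``drop_intercept`` the intercept column is removed after treatment
    coding (conditional logistic models: the intercept cancels from the
    within-stratum likelihood but reference-level contrasts are kept).
    """
    formula = " + ".join(terms) if terms else "1"
    X = patsy.dmatrix(formula, df, return_type="dataframe")
    info = X.design_info
    term_map: dict[str, list[str]] = {}
    for name, sl in info.term_name_slices.items():
        if name == "Intercept":
            continue
        term_map[name] = list(info.column_names[sl])
    if drop_intercept and "Intercept" in X.columns:
        X = X.drop(columns="Intercept")
    return X, term_map


def _term_wald(
    term_map: dict[str, list[str]],
    params: pd.Series,
    vcov: pd.DataFrame,
) -> dict[str, float]:
    """Joint Wald chi-square P-value per model term (robust vcov)."""
    out = {}
    for term, cols in term_map.items():
        cols = [c for c in cols if c in params.index]
        if not cols:
            continue
        b = params[cols].to_numpy()
        V = vcov.loc[cols, cols].to_numpy()
        try:
            w = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            w = np.inf
        out[term] = float(stats.chi2.sf(w, df=len(cols)))
    return out


# ---------------------------------------------------------------------------
# Conditional logistic regression (matched 1:k strata)
# ---------------------------------------------------------------------------


def _stratum_blocks(stratum_ids: np.ndarray) -> np.ndarray:
    """Start offsets of contiguous stratum blocks (input must be sorted)."""
    change = np.r_[True, stratum_ids[1:] != stratum_ids[:-1]]
    return np.flatnonzero(change)


def fit_conditional_logistic(
    df: pd.DataFrame,
    terms: Sequence[str],
    stratum_col: str = "stratum_id",
    case_col: str = "y",
    cluster_col: str = "territory_id",
    tol: float = 1e-8,
    max_iter: int = 60,
    on_separation: str = "flag",
) -> FitResult:
    """Maximize the matched case-control conditional likelihood by Newton.

    Each stratum holds one case (the real step) and its matched controls;
    the stratum likelihood is the softmax probability of the case,
    exp(b'x_case) / sum_j exp(b'x_j). Iterates to a gradient max-norm below
    ``tol``. The robust variance is the clustered sandwich A^-1 B A^-1 with
    scores summed within ``cluster_col`` (territories).

    Complete separation drives coefficients to +/-inf; by default the fit is
    stopped at a large magnitude and flagged (``flags['separation']``),
    mirroring the huge-coefficient rows such fits produce in practice; with
    ``on_separation='raise'`` a :class:`SeparationError` is raised.
    """
    work = df.sort_values(stratum_col, kind="stable").reset_index(drop=True)
    X, term_map = build_design(work, terms, drop_intercept=True)
    y = work[case_col].to_numpy().astype(float)
    sid = work[stratum_col].to_numpy()
    starts = _stratum_blocks(sid)
    n_strata = len(starts)
    if n_strata < 2:
        raise ValueError("need at least 2 strata")
    counts = np.diff(np.r_[starts, len(work)])
    case_per = np.add.reduceat(y, starts)
    if not np.allclose(case_per, 1.0):
        raise ValueError("every stratum must contain exactly one case")

    Xv = X.to_numpy()
    # identifiability: within-stratum variation of each column
    stratum_mean = np.repeat(
        np.add.reduceat(Xv, starts, axis=0) / counts[:, None], counts, axis=0
    )
    Xc = Xv - stratum_mean
    dead = np.max(np.abs(Xc), axis=0) < 1e-12
    if np.all(dead):
        raise UnidentifiableError("no covariate varies within any stratum")
    if np.any(dead):
        raise UnidentifiableError(
            f"covariates constant within every stratum: {list(X.columns[dead])}"
        )

    p = Xv.shape[1]
    beta = np.zeros(p)
    case_idx = np.flatnonzero(y == 1.0)
    x_case = Xv[case_idx]

    def loglik_grad_hess(b, want_hess=True):
        eta = Xv @ b
        # per-stratum log-sum-exp
        m = np.maximum.reduceat(eta, starts)
        w = np.exp(eta - np.repeat(m, counts))
        denom = np.add.reduceat(w, starts)
        ll = float(np.sum(eta[case_idx]) - np.sum(np.log(denom) + m))
        prob = w / np.repeat(denom, counts)
        Ex = np.add.reduceat(prob[:, None] * Xv, starts, axis=0)
        grad = (x_case - Ex).sum(axis=0)
        if not want_hess:
            return ll, grad, None
        # sum over strata of E[xx'] - E[x]E[x]'
        Exx = (Xv * prob[:, None]).T @ Xv
        H = -(Exx - Ex.T @ Ex)
        return ll, grad, H

    ll_old = -np.inf
    separated = False
    for _ in range(max_iter):
        ll, grad, H = loglik_grad_hess(beta)
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(H - 1e-10 * np.eye(p), -grad)
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped Newton
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new, _, _ = loglik_grad_hess(cand, want_hess=False)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if np.max(np.abs(beta)) > 15.0:
            separated = True
            if on_separation == "raise":
                raise SeparationError(
                    "conditional likelihood diverges (complete separation); "
                    f"|beta| reached {np.max(np.abs(beta)):.1f}"
                )
            break
        ll_old = ll

    ll, grad, H = loglik_grad_hess(beta)
    A = -H
    Ainv = np.linalg.pinv(A)
    # stratum-level scores, summed per cluster
    eta = Xv @ beta
    m = np.maximum.reduceat(eta, starts)
    w = np.exp(eta - np.repeat(m, counts))
    denom = np.add.reduceat(w, starts)
    prob = w / np.repeat(denom, counts)
    Ex = np.add.reduceat(prob[:, None] * Xv, starts, axis=0)
    scores = x_case - Ex  # (n_strata, p)
    clusters = work[cluster_col].to_numpy()[starts]
    cdf = pd.DataFrame(scores)
    cdf["__c"] = clusters
    G = cdf.groupby("__c").sum().to_numpy()
    B = G.T @ G
    V_rob = Ainv @ B @ Ainv
    V_mod = Ainv

    names = list(X.columns)
    params = pd.Series(beta, index=names)
    se = pd.Series(np.sqrt(np.clip(np.diag(V_mod), 0, None)), index=names)
    rse = pd.Series(np.sqrt(np.clip(np.diag(V_rob), 0, None)), index=names)
    z = params / rse.replace(0.0, np.nan)
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    vrob_df = pd.DataFrame(V_rob, index=names, columns=names)
    return FitResult(
        method="conditional_logistic",
        terms=list(terms),
        params=params,
        se=se,
        robust_se=rse,
        pvalues=pvals,
        term_pvalues=_term_wald(term_map, params, vrob_df),
        loglik=ll,
        n_obs=len(work),
        n_groups=len(np.unique(clusters)),
        flags={"separation": separated},
        term_columns=term_map,
        meta={"n_strata": n_strata, "vcov_robust": vrob_df, "vcov_model": pd.DataFrame(V_mod, index=names, columns=names)},
    )


# ---------------------------------------------------------------------------
# Gaussian linear mixed model (nested random intercepts)
# ---------------------------------------------------------------------------


def fit_lmm(
    df: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    dataset_col: str = "dataset_id",
    territory_col: str = "territory_id",
    reml: bool = True,
) -> FitResult:
    """REML fit of ``response ~ terms`` with data set nested in territory.

    Random intercepts at the territory level plus a variance component for
    data sets within territory; Wald P-values for the fixed effects.
    """
    import statsmodels.formula.api as smf

    if df[territory_col].nunique() < 2:
        raise ValueError("need at least 2 territories")
    formula = f"{response} ~ {' + '.join(terms) if terms else '1'}"
    # with one data set per territory the data-set indicator duplicates the
    # territory intercept exactly; drop the redundant component
    nested = df.groupby(territory_col)[dataset_col].nunique()
    vc = {"dataset": f"0 + C({dataset_col})"} if nested.max() > 1 else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula,
            data=df,
            groups=df[territory_col],
            re_formula="1",
            vc_formula=vc,
        )
        res = None
        for methods in (["lbfgs", "powell"], ["cg"], ["nm"]):
            try:
                res = model.fit(reml=reml, method=methods, maxiter=500)
            except np.linalg.LinAlgError:
                continue
            # boundary fits (variance -> 0) can leave lbfgs at a broken
            # profiled solution with non-finite SEs; retry on a safe path
            if np.all(np.isfinite(np.asarray(res.bse_fe))):
                break
            try:
                alt = model.fit(reml=reml, method=["nm"], maxiter=1000)
                if np.all(np.isfinite(np.asarray(alt.bse_fe))):
                    res = alt
                    break
            except np.linalg.LinAlgError:
                pass
            break
        if res is None:
            raise np.linalg.LinAlgError("mixed model optimization failed")

    fe = res.fe_params
    se = res.bse_fe
    names = list(fe.index)
    params = pd.Series(fe.to_numpy(), index=names)
    ses = pd.Series(se.to_numpy()[: len(names)], index=names)
    z = params / ses
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)

    var_territory = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    var_dataset = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    var_resid = float(res.scale)

    _, term_map = build_design(df, terms)
    vcov = pd.DataFrame(
        np.asarray(res.cov_params())[: len(names), : len(names)], index=names, columns=names
    )
    X, _ = build_design(df, terms)
    eta_fixed = X.to_numpy() @ params.reindex(X.columns).to_numpy()
    return FitResult(
        method="lmm",
        terms=list(terms),
        params=params,
        se=ses,
        robust_se=ses,
        pvalues=pvals,
        term_pvalues=_term_wald(term_map, params, vcov),
        loglik=float(res.llf),
        n_obs=len(df),
        n_groups=int(df[territory_col].nunique()),
        vc={
            "territory": max(var_territory, 0.0),
            "dataset": max(var_dataset, 0.0),
            "residual": var_resid,
        },
        term_columns=term_map,
        meta={"var_fixed": float(np.var(eta_fixed)), "converged": bool(res.converged)},
    )


def nakagawa_r2(fit: FitResult) -> tuple[float, float]:
    """Marginal and conditional R2 for a Gaussian LMM.

    R2m = var_fixed / total, R2c = (var_fixed + sum random) / total, where
    total = var_fixed + sum of random-intercept variances + residual variance
    and var_fixed is the variance of the fixed-effect linear predictor over
    the data.
    """
    vf = fit.meta.get("var_fixed", 0.0)
    vr = sum(v for k, v in fit.vc.items() if k != "residual")
    ve = fit.vc.get("residual", 0.0)
    total = vf + vr + ve
    if total <= 0:
        return (0.0, 0.0)
    return (vf / total, (vf + vr) / total)


# ---------------------------------------------------------------------------
# Random-intercept logistic regression (Laplace approximation)
# ---------------------------------------------------------------------------


def _logistic_joint_newton(Xa, y, q1, q2, v1, v2, z0=None, max_iter=60, tol=1e-9):
    """Penalized Newton for (beta, u) of a 2-level random-intercept logistic."""
    n, ptot = Xa.shape
    p = ptot - q1 - q2
    pen = np.r_[np.zeros(p), np.full(q1, 1.0 / v1), np.full(q2, 1.0 / v2)]
    z = np.zeros(ptot) if z0 is None else z0.copy()

    def objective(zv):
        eta = Xa @ zv
        ll = float(y @ eta - np.sum(np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(np.sum(pen * zv * zv))

    obj = objective(z)
    for _ in range(max_iter):
        eta = Xa @ z
        mu = 1.0 / (1.0 + np.exp(-eta))
        g = Xa.T @ (y - mu) - pen * z
        if np.max(np.abs(g)) < tol:
            break
        Wd = mu * (1.0 - mu)
        H = (Xa * Wd[:, None]).T @ Xa + np.diag(pen)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            cand = z + t * step
            if objective(cand) >= obj - 1e-12:
                break
            t *= 0.5
        z = z + t * step
        obj = objective(z)
    eta = Xa @ z
    mu = 1.0 / (1.0 + np.exp(-eta))
    Wd = mu * (1.0 - mu)
    H = (Xa * Wd[:, None]).T @ Xa + np.diag(pen)
    return z, H, obj


def fit_logistic_rim(
    df: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    dataset_col: str = "dataset_id",
    territory_col: str = "territory_id",
) -> FitResult:
    """Random-intercept logistic regression, Laplace-approximated.

    Random intercepts for territory and for data set nested in territory.
    The two variance components are profiled out on the log scale with
    Nelder-Mead around an inner penalized Newton solve for (beta, u). With a
    single grouping level present (one territory) the model degrades to
    plain logistic regression with a warning.
    """
    X, term_map = build_design(df, terms)
    y = df[response].to_numpy().astype(float)
    names = list(X.columns)
    p = len(names)

    n_terr = df[territory_col].nunique()
    if n_terr < 2:
        warnings.warn("single territory: falling back to plain logistic regression")
        return _plain_logistic(X, y, term_map, terms, n_groups=1)

    terr = pd.Categorical(df[territory_col])
    dset = pd.Categorical(df[dataset_col])
    q1, q2 = len(terr.categories), len(dset.categories)
    Z1 = np.zeros((len(df), q1))
    Z1[np.arange(len(df)), terr.codes] = 1.0
    Z2 = np.zeros((len(df), q2))
    Z2[np.arange(len(df)), dset.codes] = 1.0
    Xa = np.hstack([X.to_numpy(), Z1, Z2])

    state = {"z": None}

    def neg_laplace(theta):
        v1, v2 = np.exp(np.clip(theta, -23.0, 5.0))
        z, H, pen_ll = _logistic_joint_newton(Xa, y, q1, q2, v1, v2, z0=state["z"])
        state["z"] = z
        Huu = H[p:, p:]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return 1e12
        # Laplace marginal: penalized loglik - 0.5(q1 ln v1 + q2 ln v2) - 0.5 ln|Huu|
        ll = pen_ll - 0.5 * (q1 * np.log(v1) + q2 * np.log(v2)) - 0.5 * logdet
        return -ll

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = optimize.minimize(
            neg_laplace,
            x0=np.array([-1.5, -1.5]),
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 120},
        )
    v1, v2 = np.exp(np.clip(opt.x, -23.0, 5.0))
    z, H, _ = _logistic_joint_newton(Xa, y, q1, q2, v1, v2, z0=state["z"])
    beta = z[:p]
    Hinv = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(Hinv)[:p], 0, None))

    quasi_sep = bool(np.max(np.abs(beta)) > 10.0)
    if quasi_sep:
        warnings.warn("quasi-separation suspected: some coefficients very large")

    params = pd.Series(beta, index=names)
    ses = pd.Series(se, index=names)
    zstat = params / ses.replace(0.0, np.nan)
    pvals = pd.Series(2 * stats.norm.sf(np.abs(zstat)), index=names)
    vcov = pd.DataFrame(Hinv[:p, :p], index=names, columns=names)
    return FitResult(
        method="logistic_rim",
        terms=list(terms),
        params=params,
        se=ses,
        robust_se=ses,
        pvalues=pvals,
        term_pvalues=_term_wald(term_map, params, vcov),
        loglik=float(-opt.fun),
        n_obs=len(df),
        n_groups=int(n_terr),
        vc={"territory": float(v1), "dataset": float(v2)},
        flags={"quasi_separation": quasi_sep},
        term_columns=term_map,
        meta={"laplace_converged": bool(opt.success)},
    )


def _plain_logistic(X, y, term_map, terms, n_groups):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200)
    names = list(X.columns)
    params = pd.Series(res.params, index=names)
    ses = pd.Series(res.bse, index=names)
    pvals = pd.Series(res.pvalues, index=names)
    vcov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    return FitResult(
        method="logistic",
        terms=list(terms),
        params=params,
        se=ses,
        robust_se=ses,
        pvalues=pvals,
        term_pvalues=_term_wald(term_map, params, vcov),
        loglik=float(res.llf),
        n_obs=len(y),
        n_groups=n_groups,
        term_columns=term_map,
    )


# ---------------------------------------------------------------------------
# Ordinary least squares (functional-response regressions)
# ---------------------------------------------------------------------------


def fit_ols(df: pd.DataFrame, response: str, terms: Sequence[str]) -> FitResult:
    import statsmodels.api as sm

    X, term_map = build_design(df, terms)
    y = df[response].to_numpy().astype(float)
    res = sm.OLS(y, X.to_numpy()).fit()
    names = list(X.columns)
    params = pd.Series(res.params, index=names)
    ses = pd.Series(res.bse, index=names)
    pvals = pd.Series(res.pvalues, index=names)
    vcov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    return FitResult(
        method="ols",
        terms=list(terms),
        params=params,
        se=ses,
        robust_se=ses,
        pvalues=pvals,
        term_pvalues=_term_wald(term_map, params, vcov),
        loglik=float(res.llf),
        n_obs=len(y),
        n_groups=len(y),
        term_columns=term_map,
        meta={"r2": float(res.rsquared), "df_resid": float(res.df_resid)},
    )


# ---------------------------------------------------------------------------
# Backward elimination with marginality
# ---------------------------------------------------------------------------


def _lower_order(term: str) -> set[str]:
    """Terms protected by this term under marginality rules."""
    protected = set()
    if ":" in term:
        protected.update(t.strip() for t in term.split(":"))
    t = term.replace(" ", "")
    if t.startswith("I(") and "**2" in t:
        base = t[2:].split("**")[0].strip("()")
        protected.add(base)
        # centered quadratics stored as plain columns: "x_sq" protects "x"
    if term.endswith("_sq"):
        protected.add(term[:-3])
    return protected


def backward_eliminate(
    fit_fn: Callable[[list[str]], FitResult],
    terms: Sequence[str],
    alpha: float = 0.05,
    protected: Sequence[str] = (),
) -> tuple[FitResult, list[tuple[str, float]]]:
    """Stepwise backward elimination of terms with Wald P > alpha.

    ``fit_fn(terms)`` must return a :class:`FitResult` whose
    ``term_pvalues`` covers the given terms. At each round the removable
    term with the largest P above alpha is dropped; a main effect is not
    removable while any retained interaction or quadratic contains it, and
    ``protected`` terms are never removed. Returns the final fit and the
    elimination trace.
    """
    current = list(terms)
    trace: list[tuple[str, float]] = []
    while True:
        fit = fit_fn(current)
        # a term shields its lower-order terms while it is still present
        shielded = set(protected)
        for t in current:
            for low in _lower_order(t):
                if low in current:
                    shielded.add(low)
        removable = {
            t: fit.term_pvalues.get(t, 0.0)
            for t in current
            if t not in shielded and fit.term_pvalues.get(t, 0.0) > alpha
        }
        if not removable:
            return fit, trace
        worst = max(removable, key=removable.get)
        trace.append((worst, removable[worst]))
        current.remove(worst)
        if not current:
            return fit_fn(current), trace


# ---------------------------------------------------------------------------
# Rank statistics and the collinearity screen
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    diffs: np.ndarray, alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided paired Wilcoxon signed rank test.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties in |d|, the tie-corrected normal approximation
    otherwise. Returns (V, P) with V the positive-rank sum, as reported by
    R's ``wilcox.test``.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if len(d) == 0:
        raise ValueError("all differences are zero: test undefined")
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def pearson_screen(
    df: pd.DataFrame,
    covariates: Sequence[str],
    r_max: float = 0.6,
    priority: Optional[Sequence[str]] = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy collinearity screen: keep covariates pairwise |r| < r_max.

    Covariates are admitted in priority order (default: the given order);
    a candidate correlated at |r| >= r_max with any already-kept covariate
    is dropped, and the offending pair recorded.
    """
    order = list(priority) if priority is not None else list(covariates)
    order += [c for c in covariates if c not in order]
    order = [c for c in order if c in covariates]
    corr = df[list(covariates)].corr()
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for c in order:
        clash = None
        for k in kept:
            r = corr.loc[c, k]
            if np.isfinite(r) and abs(r) >= r_max:
                clash = (c, k, float(r))
                break
        if clash is None:
            kept.append(c)
        else:
            dropped.append(clash)
    return kept, dropped
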