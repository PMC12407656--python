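"""Genetic-nurture vs transmission association models.

Offspring outcomes are regressed jointly on the combined transmitted and
non-transmitted polygenic scores with sex and age as covariates and a family
random intercept for sibling relatedness.  Continuous outcomes use a
restricted-maximum-likelihood linear mixed model (statsmodels MixedLM);
binary outcomes use a random-intercept logistic model fitted by Gauss-Hermite
quadrature.  The direct-transmission effect is the contrast
beta_DGT = beta_T - beta_NT, and the set of non-transmitted-score tests is
controlled at 5% FDR by Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "AssocModelSpec",
    "AssocResult",
    "fit_linear_mixed",
    "fit_logistic_mixed",
    "dgt",
    "bh_fdr",
    "run_table2",
    "TABLE2_OUTCOMES",
]

# outcome name -> (family, restrict-to-initiators flag)
TABLE2_OUTCOMES = {
    "smk_init": ("binary", False),
    "cig_day": ("continuous", True),
    "pack_years": ("continuous", True),
    "alc_gday": ("continuous", False),
    "cannabis_ever": ("binary", False),
}


@dataclass
class AssocModelSpec:
    outcome: str
    family: str = "continuous"                    # 'continuous' | 'binary'
    predictors: tuple = ("pgs_t", "pgs_nt")
    covariates: tuple = ("sex", "age")
    group: str = "family_id"
    restrict_to_initiators: bool = False


@dataclass
class AssocResult:
    """Joint PGS_T / PGS_NT estimates for one outcome.

    ``beta`` holds standardized coefficients (continuous outcomes) or
    log-odds (binary; ``odds_ratio`` exposes exp(beta)).
    """

    outcome: str
    family: str
    n: int
    beta: dict
    se: dict
    ci: dict
    p: dict
    p_fdr: dict = field(default_factory=dict)
    group_var: float = float("nan")
    degenerate: bool = False
    t_name: str = "pgs_t"
    nt_name: str = "pgs_nt"

    @property
    def beta_dgt(self) -> float:
        return dgt(self.beta[self.t_name], self.beta[self.nt_name])

    def odds_ratio(self, term: str) -> float:
        return float(np.exp(self.beta[term]))

    def or_ci(self, term: str) -> tuple:
        lo, hi = self.ci[term]
        return float(np.exp(lo)), float(np.exp(hi))


def dgt(beta_t: float, beta_nt: float) -> float:
    """Direct genetic transmission contrast: beta_T - beta_NT."""
    if not (np.isfinite(beta_t) and np.isfinite(beta_nt)):
        raise ValueError("coefficients must be finite")
    return float(beta_t) - float(beta_nt)


def bh_fdr(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    ``m`` defaults to the number of tests supplied; a larger family size can
    be imposed explicitly.
    """
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = m or len(p)
    if m < len(p):
        raise ValueError("family size m cannot be smaller than the number of tests")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _design(data: pd.DataFrame, spec: AssocModelSpec):
    cols = [spec.outcome, *spec.predictors, *spec.covariates, spec.group]
    d = data[cols].dropna(subset=[spec.outcome, *spec.predictors, *spec.covariates])
    y = d[spec.outcome].to_numpy(float)
    X = pd.DataFrame({"const": 1.0}, index=d.index)
    for c in spec.predictors:
        X[c] = d[c]
    for c in spec.covariates:
        v = d[c].to_numpy(float)
        if c == "age":
            s = v.std()
            v = (v - v.mean()) / s if s > 0 else v * 0.0
        X[c] = v
    return y, X, d[spec.group].to_numpy()


def _pack(spec, n, names, beta, se, group_var, degenerate=False):
    zcrit = stats.norm.ppf(0.975)
    b = dict(zip(names, map(float, beta)))
    s = dict(zip(names, map(float, se)))
    ci = {k: (b[k] - zcrit * s[k], b[k] + zcrit * s[k]) for k in b}
    p = {
        k: float(2 * stats.norm.sf(abs(b[k] / s[k]))) if s[k] > 0 else float("nan")
        for k in b
    }
    return AssocResult(spec.outcome, spec.family, n, b, s, ci, p,
                       group_var=group_var, degenerate=degenerate,
                       t_name=spec.predictors[0], nt_name=spec.predictors[1])


def fit_linear_mixed(spec: AssocModelSpec, data: pd.DataFrame) -> AssocResult:
    """Random-intercept linear mixed model (REML) with standardized outcome.

    The continuous outcome is z-scored before fitting so that, with
    standardized scores, coefficients are on the standardized scale.  A
    singular fit (zero family variance) degenerates to ordinary least squares
    and is flagged.
    """
    y, X, groups = _design(data, spec)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two families")
    sd = y.std()
    if sd > 0:
        y = (y - y.mean()) / sd
    names = list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X.to_numpy(float), groups=groups)
        fit = model.fit(reml=True)
    group_var = float(np.squeeze(fit.cov_re))
    degenerate = group_var < 1e-8
    if degenerate:
        import statsmodels.api as sm

        ols = sm.OLS(y, X.to_numpy(float)).fit()
        return _pack(spec, len(y), names,
                     ols.params, ols.bse, 0.0, degenerate=True)
    return _pack(spec, len(y), names,
                 fit.fe_params, fit.bse_fe, group_var)


def fit_logistic_mixed(
    spec: AssocModelSpec,
    data: pd.DataFrame,
    n_quad: int = 15,
) -> AssocResult:
    """Random-intercept logistic regression via Gauss-Hermite quadrature.

    The family log-likelihood integrates the random intercept u ~ N(0, s^2)
    with ``n_quad`` Hermite nodes.  Coefficients are log-odds per unit (per
    SD for standardized scores); Wald CIs come from the numerical Hessian.
    Complete separation raises with a message.
    """
    y, X, groups = _design(data, spec)
    names = list(X.columns)
    Xm = X.to_numpy(float)
    order = np.argsort(groups, kind="stable")
    y, Xm, groups = y[order], Xm[order], groups[order]
    starts = np.concatenate([[0], np.flatnonzero(groups[1:] != groups[:-1]) + 1])
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(wts / np.sqrt(np.pi))
    k = Xm.shape[1]

    def nll(theta):
        beta, log_sigma = theta[:k], theta[k]
        sigma = np.exp(log_sigma)
        eta = Xm @ beta
        lp = eta[:, None] + np.sqrt(2.0) * sigma * nodes[None, :]
        ll_obs = y[:, None] * lp - np.logaddexp(0.0, lp)
        fam = np.add.reduceat(ll_obs, starts, axis=0)
        return -float(special.logsumexp(fam + log_w, axis=1).sum())

    theta0 = np.zeros(k + 1)
    theta0[k] = np.log(0.5)
    res = optimize.minimize(nll, theta0, method="BFGS",
                            options={"gtol": 1e-7, "maxiter": 500})
    beta = res.x[:k]
    if np.abs(beta).max() > 15:
        raise RuntimeError("separation detected: a coefficient diverged")
    # numerical Hessian for the fixed effects
    h = _numerical_hessian(nll, res.x)
    cov = np.linalg.pinv(h)
    se = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
    sigma2 = float(np.exp(res.x[k]) ** 2)
    return _pack(spec, len(y), names, beta, se, sigma2)


def _numerical_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


def run_table2(
    data: pd.DataFrame,
    score_cols: tuple = ("pgs_t_std", "pgs_nt_std"),
    outcomes: dict | None = None,
    fdr_m: int = 5,
) -> pd.DataFrame:
    """Fit the five-outcome association table with FDR control.

    ``data`` merges standardized scores with phenotypes (columns sex, age,
    family_id and the outcome columns).  Quantity outcomes (cigarettes/day,
    pack-years) are restricted to smoking initiators by their generative
    missingness.  FDR is applied across the non-transmitted-score tests
    (family size ``fdr_m``) and, separately, across the transmitted-score
    tests.
    """
    outcomes = outcomes or TABLE2_OUTCOMES
    results = []
    for outcome, (family, initiators_only) in outcomes.items():
        spec = AssocModelSpec(
            outcome=outcome,
            family=family,
            predictors=score_cols,
            restrict_to_initiators=initiators_only,
        )
        d = data
        if initiators_only and "smk_init" in data:
            d = data[data["smk_init"] == 1]
        if family == "continuous":
            res = fit_linear_mixed(spec, d)
        else:
            res = fit_logistic_mixed(spec, d)
        results.append(res)

    t_col, nt_col = score_cols
    for col in (t_col, nt_col):
        adj = bh_fdr([r.p[col] for r in results], m=fdr_m)
        for r, a in zip(results, adj):
            r.p_fdr[col] = float(a)

    rows = []
    for r in results:
        is_bin = r.family == "binary"
        rows.append(
            {
                "outcome": r.outcome,
                "n": r.n,
                "beta_t": r.odds_ratio(t_col) if is_bin else r.beta[t_col],
                "ci_t_low": (r.or_ci(t_col) if is_bin else r.ci[t_col])[0],
                "ci_t_high": (r.or_ci(t_col) if is_bin else r.ci[t_col])[1],
                "p_t": r.p[t_col],
                "p_fdr_t": r.p_fdr[t_col],
                "beta_nt": r.odds_ratio(nt_col) if is_bin else r.beta[nt_col],
                "ci_nt_low": (r.or_ci(nt_col) if is_bin else r.ci[nt_col])[0],
                "ci_nt_high": (r.or_ci(nt_col) if is_bin else r.ci[nt_col])[1],
                "p_nt": r.p[nt_col],
                "p_fdr_nt": r.p_fdr[nt_col],
                "dgt": np.nan if is_bin else dgt(r.beta[t_col], r.beta[nt_col]),
                "family": r.family,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)
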