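"""Linear path models with full-information maximum likelihood (FIML).

Recursive (acyclic) systems of linear regressions over observed variables are
fitted under a joint multivariate-normal model.  Exogenous variables get free
means and a free covariance matrix; each endogenous equation contributes path
coefficients, an intercept, and a residual variance.  With missing data the
observed-data log-likelihood sums, over rows grouped by missingness pattern,
the normal log-density of each row's observed subvector under the
model-implied mean and covariance.

Fitting strategy: when the system is *saturated-equivalent* (each equation
regresses on every causally prior variable, so the model can represent any
mean/covariance) the FIML optimum is obtained exactly by EM on the saturated
moments followed by moment-matching; otherwise a quasi-Newton (L-BFGS)
optimizer maximizes the observed-data likelihood directly.  Under complete
data both routes coincide with equation-by-equation ordinary least squares.

Also provided: Wald equality tests on standardized coefficients (delta
method), parent-of-origin and parallel-mediation model builders, cluster
bootstrap confidence intervals, and chi-square/RMSEA/CFI fit indices against
the saturated and independence models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from ._rng import substream

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)

__all__ = [
    "PathModelSpec",
    "FIMLFit",
    "WaldResult",
    "MediationResult",
    "BootstrapResult",
    "FitIndices",
    "fiml_fit",
    "fit_parent_of_origin",
    "fit_mediation",
    "wald_equality",
    "bootstrap_cis",
    "fit_indices",
    "proportion_mediated",
]


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathModelSpec:
    """Recursive path model: ordered equations (outcome, (predictors, ...)).

    Variables never appearing on a left-hand side are exogenous and receive
    free means and a free full covariance matrix.  Equations must be ordered
    so that an endogenous predictor appears as an outcome earlier in the list
    (recursiveness).
    """

    equations: tuple

    def __post_init__(self) -> None:
        seen_endo = []
        for lhs, rhs in self.equations:
            if lhs in seen_endo:
                raise ValueError(f"variable {lhs!r} has two equations")
            for v in rhs:
                if v in [e for e, _ in self.equations] and v not in seen_endo:
                    raise ValueError(
                        f"equation for {lhs!r} uses {v!r} before it is defined "
                        "(system must be recursive)"
                    )
            seen_endo.append(lhs)

    @property
    def endogenous(self) -> list:
        return [lhs for lhs, _ in self.equations]

    @property
    def exogenous(self) -> list:
        endo = set(self.endogenous)
        out = []
        for _, rhs in self.equations:
            for v in rhs:
                if v not in endo and v not in out:
                    out.append(v)
        return out

    @property
    def variables(self) -> list:
        return self.exogenous + self.endogenous

    def n_parameters(self) -> int:
        k = len(self.exogenous)
        n_eq = sum(len(rhs) + 2 for _, rhs in self.equations)  # coefs + intercept + var
        return n_eq + k + k * (k + 1) // 2

    def is_saturated_equivalent(self) -> bool:
        """True when every equation regresses on all causally prior variables."""
        prior = list(self.exogenous)
        for lhs, rhs in self.equations:
            if set(rhs) != set(prior):
                return False
            prior.append(lhs)
        return True


# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------


class _Layout:
    """Maps between named parameters and the flat theta vector.

    Order: per equation [coefs..., intercept, log resid sd], then exogenous
    means, then the log-Cholesky of the exogenous covariance (diagonal as
    logs, then row-wise sub-diagonal entries).
    """

    def __init__(self, spec: PathModelSpec):
        self.spec = spec
        self.names = []
        for lhs, rhs in spec.equations:
            self.names += [f"{lhs}~{v}" for v in rhs]
            self.names += [f"{lhs}~1", f"log_sd({lhs})"]
        ex = spec.exogenous
        self.names += [f"{v}~1" for v in ex]
        self.names += [f"log_sd({v})" for v in ex]
        for i in range(len(ex)):
            for j in range(i):
                self.names += [f"chol({ex[i]},{ex[j]})"]
        self.size = len(self.names)
        self.index = {n: i for i, n in enumerate(self.names)}

    def unpack(self, theta: np.ndarray):
        """Return (coefs per eq, intercepts, resid vars, exog mean, exog cov)."""
        spec = self.spec
        pos = 0
        coefs, alphas, psis = [], [], []
        for lhs, rhs in spec.equations:
            k = len(rhs)
            coefs.append(theta[pos:pos + k]); pos += k
            alphas.append(theta[pos]); pos += 1
            psis.append(np.exp(theta[pos]) ** 2); pos += 1
        kx = len(spec.exogenous)
        mu_x = theta[pos:pos + kx]; pos += kx
        L = np.zeros((kx, kx))
        np.fill_diagonal(L, np.exp(theta[pos:pos + kx])); pos += kx
        for i in range(kx):
            for j in range(i):
                L[i, j] = theta[pos]; pos += 1
        phi = L @ L.T
        return coefs, np.asarray(alphas), np.asarray(psis), mu_x, phi

    def pack(self, coefs, alphas, psis, mu_x, phi) -> np.ndarray:
        theta = np.empty(self.size)
        pos = 0
        for c, a, v in zip(coefs, alphas, psis):
            k = len(c)
            theta[pos:pos + k] = c; pos += k
            theta[pos] = a; pos += 1
            theta[pos] = 0.5 * np.log(max(v, 1e-12)); pos += 1
        kx = len(mu_x)
        theta[pos:pos + kx] = mu_x; pos += kx
        L = np.linalg.cholesky(_nearest_pd(phi))
        theta[pos:pos + kx] = np.log(np.maximum(np.diag(L), 1e-8)); pos += kx
        for i in range(kx):
            for j in range(i):
                theta[pos] = L[i, j]; pos += 1
        return theta


def _nearest_pd(a: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    if w.min() > floor:
        return a
    w = np.maximum(w, floor)
    return v @ np.diag(w) @ v.T


def _implied_moments(spec: PathModelSpec, layout: _Layout, theta: np.ndarray):
    """Model-implied mean vector and covariance over spec.variables order."""
    coefs, alphas, psis, mu_x, phi = layout.unpack(theta)
    ex, endo = spec.exogenous, spec.endogenous
    kx, ky = len(ex), len(endo)
    col = {v: i for i, v in enumerate(ex)}
    ecol = {v: i for i, v in enumerate(endo)}
    G = np.zeros((ky, kx))
    B = np.zeros((ky, ky))
    for e, (lhs, rhs) in enumerate(spec.equations):
        for c, v in zip(coefs[e], rhs):
            if v in col:
                G[e, col[v]] = c
            else:
                B[e, ecol[v]] = c
    T = np.linalg.inv(np.eye(ky) - B)
    mu_y = T @ (alphas + G @ mu_x)
    sxx = phi
    sxy = phi @ G.T @ T.T
    syy = T @ (G @ phi @ G.T + np.diag(psis)) @ T.T
    mu = np.concatenate([mu_x, mu_y])
    sigma = np.block([[sxx, sxy], [sxy.T, syy]])
    return mu, sigma


# ---------------------------------------------------------------------------
# observed-data log-likelihood
# ---------------------------------------------------------------------------


class _PatternData:
    """Rows grouped by missingness pattern for fast FIML evaluation."""

    def __init__(self, X: np.ndarray):
        self.n, self.p = X.shape
        miss = np.isnan(X)
        keep = ~miss.all(axis=1)
        self.n_dropped = int((~keep).sum())
        X, miss = X[keep], miss[keep]
        self.n = X.shape[0]
        patterns, inverse = np.unique(miss, axis=0, return_inverse=True)
        self.groups = []
        for g, pat in enumerate(patterns):
            rows = X[inverse == g][:, ~pat]
            self.groups.append((np.flatnonzero(~pat), rows))
        self.complete = len(self.groups) == 1 and len(self.groups[0][0]) == self.p
        self.X = X

    def loglik(self, mu: np.ndarray, sigma: np.ndarray) -> float:
        total = 0.0
        for obs, rows in self.groups:
            k = len(obs)
            sub = sigma[np.ix_(obs, obs)]
            try:
                chol = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return -np.inf
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            d = rows - mu[obs]
            sol = solve_triangular(chol, d.T, lower=True, check_finite=False)
            quad = (sol ** 2).sum()
            total += -0.5 * (rows.shape[0] * (k * LOG2PI + logdet) + quad)
        return float(total)


def _em_saturated(pdata: _PatternData, tol: float = 1e-9, max_iter: int = 1000):
    """ML mean and covariance of a multivariate normal with missing data (EM)."""
    p = pdata.p
    # initialize from available-case moments
    mu = np.array([np.nanmean(pdata.X[:, j]) for j in range(p)])
    sigma = np.diag([max(np.nanvar(pdata.X[:, j]), 1e-6) for j in range(p)])
    if pdata.complete:
        X = pdata.groups[0][1]
        mu = X.mean(axis=0)
        d = X - mu
        sigma = _nearest_pd(d.T @ d / len(X))
        return mu, sigma, pdata.loglik(mu, sigma), 0
    ll_old = -np.inf
    for it in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for obs, rows in pdata.groups:
            m = rows.shape[0]
            mis = np.setdiff1d(np.arange(p), obs)
            xhat = np.empty((m, p))
            xhat[:, obs] = rows
            cc = np.zeros((p, p))
            if len(mis):
                soo = sigma[np.ix_(obs, obs)]
                smo = sigma[np.ix_(mis, obs)]
                bmat = np.linalg.solve(soo, smo.T).T
                xhat[:, mis] = mu[mis] + (rows - mu[obs]) @ bmat.T
                cond = sigma[np.ix_(mis, mis)] - bmat @ smo.T
                cc[np.ix_(mis, mis)] = m * cond
            s1 += xhat.sum(axis=0)
            s2 += xhat.T @ xhat + cc
        mu = s1 / pdata.n
        sigma = _nearest_pd(s2 / pdata.n - np.outer(mu, mu))
        ll = pdata.loglik(mu, sigma)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            return mu, sigma, ll, it + 1
        ll_old = ll
    logger.warning("saturated EM hit max_iter without full convergence")
    return mu, sigma, ll_old, max_iter


def _moments_to_theta(spec: PathModelSpec, layout: _Layout,
                      mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Moment-match structural parameters to a given mean/covariance."""
    variables = spec.variables
    pos = {v: i for i, v in enumerate(variables)}
    coefs, alphas, psis = [], [], []
    for lhs, rhs in spec.equations:
        yi = pos[lhs]
        pi = [pos[v] for v in rhs]
        spp = sigma[np.ix_(pi, pi)]
        spy = sigma[np.ix_(pi, [yi])].ravel()
        beta = np.linalg.solve(spp, spy) if len(pi) else np.empty(0)
        coefs.append(beta)
        alphas.append(mu[yi] - beta @ mu[pi])
        psis.append(max(sigma[yi, yi] - beta @ spy, 1e-10))
    exi = [pos[v] for v in spec.exogenous]
    return layout.pack(coefs, alphas, psis, mu[exi], sigma[np.ix_(exi, exi)])


# ---------------------------------------------------------------------------
# fit object
# ---------------------------------------------------------------------------


@dataclass
class FIMLFit:
    spec: PathModelSpec
    layout: _Layout
    theta: np.ndarray
    loglik: float
    n_used: int
    n_dropped: int
    converged: bool
    method: str                      # 'closed_form' | 'em_saturated' | 'quasi_newton'
    _pdata: _PatternData = field(repr=False, default=None)
    _vcov: np.ndarray | None = field(repr=False, default=None)

    @property
    def params(self) -> dict:
        """Named parameter estimates on the raw (unstandardized) scale."""
        out = dict(zip(self.layout.names, self.theta))
        coefs, alphas, psis, mu_x, phi = self.layout.unpack(self.theta)
        for e, (lhs, rhs) in enumerate(self.spec.equations):
            for c, v in zip(coefs[e], rhs):
                out[f"{lhs}~{v}"] = float(c)
            out[f"{lhs}~~{lhs}"] = float(psis[e])
        ex = self.spec.exogenous
        for i, vi in enumerate(ex):
            out[f"{vi}~~{vi}"] = float(phi[i, i])
            for j in range(i):
                out[f"{vi}~~{ex[j]}"] = float(phi[i, j])
        return out

    def implied_moments(self):
        return _implied_moments(self.spec, self.layout, self.theta)

    def standardized_coef(self, name: str, theta: np.ndarray | None = None) -> float:
        """Standardized path coefficient: beta * sd(predictor) / sd(outcome)."""
        theta = self.theta if theta is None else theta
        lhs, rhs = name.split("~")
        mu, sigma = _implied_moments(self.spec, self.layout, theta)
        pos = {v: i for i, v in enumerate(self.spec.variables)}
        raw = None
        coefs, *_ = self.layout.unpack(theta)
        for e, (l, r) in enumerate(self.spec.equations):
            if l == lhs and rhs in r:
                raw = coefs[e][list(r).index(rhs)]
        if raw is None:
            raise KeyError(f"no path {name!r} in the model")
        sdx = np.sqrt(sigma[pos[rhs], pos[rhs]])
        sdy = np.sqrt(sigma[pos[lhs], pos[lhs]])
        return float(raw * sdx / sdy)

    def standardized_solution(self) -> dict:
        out = {}
        for lhs, rhs in self.spec.equations:
            for v in rhs:
                out[f"{lhs}~{v}"] = self.standardized_coef(f"{lhs}~{v}")
        return out

    def vcov(self) -> np.ndarray:
        """Observed-information covariance of theta (numerical Hessian)."""
        if self._vcov is None:
            def nll(t):
                mu, sigma = _implied_moments(self.spec, self.layout, t)
                return -self._pdata.loglik(mu, sigma)

            from .assoc import _numerical_hessian

            h = _numerical_hessian(nll, self.theta, eps=1e-4)
            self._vcov = np.linalg.pinv(h)
        return self._vcov


def fiml_fit(
    spec: PathModelSpec,
    data: pd.DataFrame,
    force_optimizer: bool = False,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FIMLFit:
    """Fit a recursive path model by full-information maximum likelihood.

    Rows with every model variable missing are dropped (count recorded).
    Complete data reduce to equation-by-equation OLS (closed form);
    saturated-equivalent systems under missingness are solved exactly by EM +
    moment matching; anything else goes through L-BFGS on the observed-data
    log-likelihood (relative tolerance ``tol``).
    """
    variables = spec.variables
    X = data[variables].to_numpy(float)
    pdata = _PatternData(X)
    if pdata.n < len(variables) + 2:
        raise ValueError("too few usable rows to fit the model")
    layout = _Layout(spec)

    if pdata.complete:
        Xc = pdata.groups[0][1]
        mu = Xc.mean(axis=0)
        d = Xc - mu
        sigma = _nearest_pd(d.T @ d / pdata.n)
        theta = _moments_to_theta(spec, layout, mu, sigma)
        if not force_optimizer:
            mi, si = _implied_moments(spec, layout, theta)
            ll = pdata.loglik(mi, si)
            return FIMLFit(spec, layout, theta, ll, pdata.n, pdata.n_dropped,
                           True, "closed_form", pdata)
        theta0 = theta
    else:
        mu, sigma, ll_sat, _ = _em_saturated(pdata)
        theta0 = _moments_to_theta(spec, layout, mu, sigma)
        if spec.is_saturated_equivalent() and not force_optimizer:
            mi, si = _implied_moments(spec, layout, theta0)
            ll = pdata.loglik(mi, si)
            return FIMLFit(spec, layout, theta0, ll, pdata.n, pdata.n_dropped,
                           True, "em_saturated", pdata)

    def nll(t):
        mu_i, sigma_i = _implied_moments(spec, layout, t)
        v = pdata.loglik(mu_i, sigma_i)
        return np.inf if not np.isfinite(v) else -v

    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B",
        options={"ftol": tol, "gtol": 1e-6, "maxiter": max_iter, "maxfun": 200000},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        logger.warning("FIML optimizer: %s", res.message)
    if not np.isfinite(res.fun):
        raise RuntimeError("FIML optimization failed: non-finite likelihood")
    mu_i, sigma_i = _implied_moments(spec, layout, res.x)
    if np.linalg.eigvalsh(sigma_i).min() <= 0:
        raise RuntimeError("implied covariance not positive definite at optimum")
    return FIMLFit(spec, layout, res.x, -res.fun, pdata.n, pdata.n_dropped,
                   bool(res.success), "quasi_newton", pdata)


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------


def parent_of_origin_spec(
    outcome: str,
    scores: tuple = ("mt_std", "mnt_std", "pt_std", "pnt_std"),
    covariates: tuple = ("sex", "age"),
) -> PathModelSpec:
    """Outcome on the four parent-specific scores plus covariates; all
    covariances among the predictors freely estimated (accounting for
    potential genetic assortative mating)."""
    return PathModelSpec(((outcome, tuple(scores) + tuple(covariates)),))


def fit_parent_of_origin(
    data: pd.DataFrame,
    outcome: str,
    scores: tuple = ("mt_std", "mnt_std", "pt_std", "pnt_std"),
    covariates: tuple = ("sex", "age"),
) -> FIMLFit:
    """Parent-of-origin SEM: maternal/paternal transmitted and non-transmitted
    scores predicting the outcome jointly, FIML over missing parental scores."""
    return fiml_fit(parent_of_origin_spec(outcome, scores, covariates), data)


@dataclass
class MediationResult:
    """Parallel mediation decomposition for an exposure pair (PGS_T, PGS_NT).

    Effects are standardized path coefficients.  ``indirect = a * b``;
    ``total = c' + a * b``; ``proportion_mediated`` is 100 x indirect / total,
    reported only when the two share a sign.
    """

    fit: FIMLFit
    mediator: str
    outcome: str
    a_t: float
    a_nt: float
    b: float
    c_t: float
    c_nt: float

    @property
    def indirect_t(self) -> float:
        return self.a_t * self.b

    @property
    def indirect_nt(self) -> float:
        return self.a_nt * self.b

    @property
    def total_t(self) -> float:
        return self.c_t + self.indirect_t

    @property
    def total_nt(self) -> float:
        return self.c_nt + self.indirect_nt

    @property
    def proportion_mediated_t(self) -> float:
        return proportion_mediated(self.indirect_t, self.total_t)

    @property
    def proportion_mediated_nt(self) -> float:
        return proportion_mediated(self.indirect_nt, self.total_nt)

    def as_dict(self) -> dict:
        return {
            "aT": self.a_t, "aNT": self.a_nt, "b": self.b,
            "cT_direct": self.c_t, "cNT_direct": self.c_nt,
            "indirect_T": self.indirect_t, "indirect_NT": self.indirect_nt,
            "total_T": self.total_t, "total_NT": self.total_nt,
            "proportion_mediated_T": self.proportion_mediated_t,
            "proportion_mediated_NT": self.proportion_mediated_nt,
        }


def proportion_mediated(indirect: float, total: float) -> float:
    """Percentage of the total effect carried by the indirect path.

    NaN (non-interpretable) when indirect and total disagree in sign or the
    total is zero.
    """
    if total == 0 or np.sign(indirect) != np.sign(total):
        return float("nan")
    return 100.0 * indirect / total


def mediation_spec(
    mediator: str,
    outcome: str,
    exposures: tuple = ("pgs_t_std", "pgs_nt_std"),
    covariates: tuple = ("sex", "age"),
) -> PathModelSpec:
    t, nt = exposures
    return PathModelSpec(
        (
            (mediator, (t, nt) + tuple(covariates)),
            (outcome, (mediator, t, nt) + tuple(covariates)),
        )
    )


def fit_mediation(
    data: pd.DataFrame,
    mediator: str,
    outcome: str,
    exposures: tuple = ("pgs_t_std", "pgs_nt_std"),
    covariates: tuple = ("sex", "age"),
) -> MediationResult:
    """Two-equation parallel mediation model fitted by FIML.

    mediator ~ aT*PGS_T + aNT*PGS_NT + covariates;
    outcome ~ b*mediator + c'T*PGS_T + c'NT*PGS_NT + covariates.
    Standardized paths, indirect/total effects and proportions mediated are
    derived from the fitted parameters.
    """
    spec = mediation_spec(mediator, outcome, exposures, covariates)
    fit = fiml_fit(spec, data)
    t, nt = exposures
    return MediationResult(
        fit=fit,
        mediator=mediator,
        outcome=outcome,
        a_t=fit.standardized_coef(f"{mediator}~{t}"),
        a_nt=fit.standardized_coef(f"{mediator}~{nt}"),
        b=fit.standardized_coef(f"{outcome}~{mediator}"),
        c_t=fit.standardized_coef(f"{outcome}~{t}"),
        c_nt=fit.standardized_coef(f"{outcome}~{nt}"),
    )


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------


@dataclass
class WaldResult:
    chi2: float
    df: int
    p: float
    contrast: float
    degenerate: bool = False


def wald_equality(
    fit: FIMLFit, coef_a: str, coef_b: str, standardized: bool = True
) -> WaldResult:
    """Wald test of equality of two path coefficients.

    On the standardized scale (default) the contrast variance comes from the
    delta method over the observed-information covariance of theta.
    """
    if coef_a == coef_b:
        return WaldResult(0.0, 1, 1.0, 0.0, degenerate=True)

    if standardized:
        def g(theta):
            return (fit.standardized_coef(coef_a, theta)
                    - fit.standardized_coef(coef_b, theta))
    else:
        ia, ib = fit.layout.index[coef_a], fit.layout.index[coef_b]

        def g(theta):
            return theta[ia] - theta[ib]

    theta = fit.theta
    contrast = g(theta)
    grad = np.empty_like(theta)
    eps = 1e-5
    for i in range(len(theta)):
        tp = theta.copy(); tp[i] += eps
        tm = theta.copy(); tm[i] -= eps
        grad[i] = (g(tp) - g(tm)) / (2 * eps)
    var = float(grad @ fit.vcov() @ grad)
    if var <= 0:
        raise ValueError("non-positive contrast variance; covariance unavailable")
    chi2 = contrast**2 / var
    return WaldResult(float(chi2), 1, float(stats.chi2.sf(chi2, 1)), float(contrast))


@dataclass
class BootstrapResult:
    estimates: pd.DataFrame         # one row per successful replicate
    ci: dict                        # name -> (lo, hi) percentile 95% CI
    se: dict
    b_requested: int
    b_failed: int
    unit: str
    seed: int


def bootstrap_cis(
    fitter,
    data: pd.DataFrame,
    b: int = 1000,
    unit: str = "family",
    cluster_col: str = "family_id",
    seed: int = 0,
    max_failure_frac: float = 0.10,
) -> BootstrapResult:
    """Percentile bootstrap over ``b`` resamples of family clusters.

    ``fitter`` maps a DataFrame to a dict of named scalar estimates.
    Resampling draws clusters (or individuals with ``unit='individual'``)
    with replacement; failed replicates are excluded and counted, erroring
    out beyond ``max_failure_frac``.
    """
    if b < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = substream(seed, "bootstrap")
    if unit == "family":
        clusters = data[cluster_col].to_numpy()
        uniq = pd.unique(clusters)
        if len(uniq) < 2:
            raise ValueError("resampling cannot vary with fewer than two clusters")
        groups = {c: data.index[clusters == c] for c in uniq}
    elif unit == "individual":
        if len(data) < 2:
            raise ValueError("resampling cannot vary with fewer than two rows")
    else:
        raise ValueError(f"unknown resampling unit {unit!r}")

    rows, failed = [], 0
    for _ in range(b):
        if unit == "family":
            draw = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([groups[c] for c in draw])
        else:
            idx = rng.choice(data.index.to_numpy(), size=len(data), replace=True)
        try:
            rows.append(fitter(data.loc[idx]))
        except Exception:   # noqa: BLE001 — replicate failures are counted
            failed += 1
    if failed > max_failure_frac * b:
        raise RuntimeError(f"{failed}/{b} bootstrap replicates failed")
    est = pd.DataFrame(rows)
    ci = {c: (float(np.percentile(est[c], 2.5)), float(np.percentile(est[c], 97.5)))
          for c in est.columns}
    se = {c: float(est[c].std(ddof=1)) for c in est.columns}
    return BootstrapResult(est, ci, se, b, failed, unit, seed)


@dataclass
class FitIndices:
    chi2: float
    df: int
    p: float
    rmsea: float
    cfi: float
    loglik_model: float
    loglik_saturated: float
    loglik_baseline: float
    n: int
    exact_fit: bool = False


def fit_indices(fit: FIMLFit) -> FitIndices:
    """Chi-square, RMSEA and CFI of a fitted model vs the saturated model.

    chi2 = 2 (loglik_saturated - loglik_model) with df the parameter-count
    difference (n-multiplier convention: the raw likelihood ratio, no n-1
    rescaling).  RMSEA = sqrt(max(0, (chi2 - df) / (df * n))); CFI uses the
    independence model (all covariances zero) as baseline.  A model with as
    many parameters as the saturated model reports exact-fit constants.
    """
    pdata = fit._pdata
    n = fit.n_used
    p = len(fit.spec.variables)
    mu_s, sigma_s, ll_sat, _ = _em_saturated(pdata)
    n_sat = p + p * (p + 1) // 2
    df = n_sat - fit.spec.n_parameters()

    # independence baseline: per-variable normal MLE over observed entries
    ll_base = 0.0
    for j in range(p):
        col = pdata.X[:, j]
        col = col[~np.isnan(col)]
        v = max(col.var(), 1e-12)
        ll_base += -0.5 * len(col) * (LOG2PI + np.log(v) + 1.0)
    df_base = n_sat - 2 * p

    if df <= 0:
        return FitIndices(0.0, 0, 1.0, 0.0, 1.0, fit.loglik, ll_sat, ll_base,
                          n, exact_fit=True)
    chi2 = max(0.0, 2.0 * (ll_sat - fit.loglik))
    chi2_base = max(0.0, 2.0 * (ll_sat - ll_base))
    rmsea = np.sqrt(max(0.0, (chi2 - df) / (df * n)))
    denom = max(0.0, chi2_base - df_base)
    cfi = 1.0 if denom == 0 else 1.0 - max(0.0, chi2 - df) / denom
    return FitIndices(
        float(chi2), int(df), float(stats.chi2.sf(chi2, df)), float(rmsea),
        float(min(cfi, 1.0)), fit.loglik, ll_sat, ll_base, n,
    )
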