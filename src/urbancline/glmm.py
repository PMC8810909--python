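"""Binomial GLMM with a single random intercept, fit by Laplace
approximation.

The model is logistic regression with a per-city normal random
intercept:

    logit P(y_ij = 1) = x_ij' beta + u_j,   u_j ~ N(0, sigma_city^2).

Estimation profiles the fixed effects and conditional modes out of the
Laplace-approximated marginal likelihood: for a candidate sigma, a
penalized IRLS jointly optimizes (beta, u) — the random-intercept
structure makes each IRLS solve a cheap Schur-complement system — and a
bounded scalar optimizer maximizes the resulting profiled objective
over log sigma.  Standard errors come from the fixed-effect block of
the inverse penalized information at the optimum, conditional on the
estimated sigma (the usual Wald machinery for this model class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import norm

from .geoprep import ModelFrame, StandardizationStats

__all__ = [
    "GLMMSpec",
    "GLMMFit",
    "fit_glmm",
    "wald_tests",
    "predict_cline",
    "binned_residuals",
    "build_design",
    "DEFAULT_TERMS",
]

DEFAULT_TERMS = (
    "intercept",
    "x_imperv",
    "x_temp",
    "x_forest",
    "x_logsize",
    "x_imperv:x_temp",
    "x_imperv:x_forest",
    "x_imperv:x_logsize",
)


@dataclass(frozen=True)
class GLMMSpec:
    """Fixed-effect structure; the random part is always an intercept by
    city."""

    terms: tuple[str, ...] = DEFAULT_TERMS
    autocovariate: bool = False

    def all_terms(self) -> tuple[str, ...]:
        return self.terms + (("x_autocov",) if self.autocovariate else ())


@dataclass
class GLMMFit:
    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    sigma_city: float
    u: np.ndarray
    city_ids: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    fitted_prob: np.ndarray
    resid_response: np.ndarray
    vcov: np.ndarray
    stats: StandardizationStats | None = None
    sigma_boundary: bool = False

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def summary_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "z": self.z.tolist(),
            "p": self.p.tolist(),
            "sigma_city": self.sigma_city,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def build_design(frame_df: pd.DataFrame, terms=DEFAULT_TERMS) -> np.ndarray:
    """Design matrix: mains taken from the frame columns, interactions
    as elementwise products of the standardized mains."""
    n = len(frame_df)
    cols = []
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(n))
        elif ":" in t:
            a, b = t.split(":")
            cols.append(frame_df[a].to_numpy(dtype=float) * frame_df[b].to_numpy(dtype=float))
        else:
            cols.append(frame_df[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, terms) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        names = [terms[k] for k in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient design; collinear columns: {names}")


def _pirls(X, y, city, q, sigma, beta0, u0, tol=1e-10, max_iter=60):
    """Penalized IRLS for (beta, u) at fixed sigma, with step-halving
    so the penalized log-likelihood increases monotonically.

    Returns beta, u, mu, Schur complement matrix M (information for
    beta), d = per-city curvature, penalized loglik, n_iter, converged.
    """
    n, p = X.shape
    beta = beta0.copy()
    u = u0.copy() if sigma != 0 else np.zeros(q)
    inv_s2 = 0.0 if sigma == 0 else 1.0 / (sigma * sigma)

    def pen_obj(b, uu):
        eta = X @ b + (0.0 if sigma == 0 else uu[city])
        mu = expit(eta)
        mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(mu_c) + (1 - y) @ np.log1p(-mu_c))
        return ll - 0.5 * inv_s2 * float(uu @ uu), mu

    prev, mu = pen_obj(beta, u)
    M = d = None
    for it in range(1, max_iter + 1):
        eta = X @ beta + (0.0 if sigma == 0 else u[city])
        mu = expit(eta)
        W = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / W
        Wz = W * z
        A = (X * W[:, None]).T @ X
        bx = X.T @ Wz
        if sigma == 0:
            M = A
            try:
                beta_new = np.linalg.solve(M, bx)
            except np.linalg.LinAlgError:
                beta_new = np.linalg.lstsq(M, bx, rcond=None)[0]
            u_new = np.zeros(q)
            d = np.bincount(city, weights=W, minlength=q)
        else:
            S = np.bincount(city, weights=W, minlength=q)
            d = S + inv_s2
            B = np.empty((p, q))
            for k in range(p):
                B[k] = np.bincount(city, weights=W * X[:, k], minlength=q)
            cu = np.bincount(city, weights=Wz, minlength=q)
            M = A - (B / d) @ B.T
            rhs = bx - B @ (cu / d)
            beta_new = np.linalg.solve(M, rhs)
            u_new = (cu - B.T @ beta_new) / d
        # step-halving: never accept a step that lowers the objective
        t = 1.0
        for _ in range(30):
            bc = beta + t * (beta_new - beta)
            uc = u + t * (u_new - u)
            obj, mu_c = pen_obj(bc, uc)
            if np.isfinite(obj) and obj >= prev - 1e-10 * (abs(prev) + 1.0):
                break
            t *= 0.5
        beta, u, mu = bc, uc, mu_c
        if abs(obj - prev) < tol * (abs(obj) + 1.0):
            return beta, u, mu, M, d, obj, it, True
        prev = obj
    return beta, u, mu, M, d, prev, max_iter, False


def _laplace_loglik(pen_obj, d, sigma, q):
    """Laplace marginal log-likelihood from the penalized optimum."""
    if sigma == 0:
        return pen_obj
    return pen_obj - 0.5 * float(np.log(sigma * sigma * d).sum())


def _inner_modes(xbeta, y, city, q, sigma, u0, tol=1e-11, max_iter=80):
    """Newton solve for the conditional modes u_j at fixed (beta, sigma).

    The random-intercept structure makes this q independent scalar
    problems, iterated as one vectorized Newton update.
    """
    u = u0.copy()
    inv_s2 = 1.0 / (sigma * sigma)
    for _ in range(max_iter):
        eta = xbeta + u[city]
        mu = expit(eta)
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = np.bincount(city, weights=y - mu, minlength=q) - u * inv_s2
        hess = np.bincount(city, weights=W, minlength=q) + inv_s2
        step = np.clip(grad / hess, -4.0, 4.0)
        u = u + step
        if np.abs(step).max() < tol:
            break
    eta = xbeta + u[city]
    mu = expit(eta)
    W = np.clip(mu * (1.0 - mu), 1e-12, None)
    hess = np.bincount(city, weights=W, minlength=q) + inv_s2
    return u, mu, hess


def _laplace_objective(X, y, city, q, beta, sigma, u0):
    """Laplace marginal log-likelihood at (beta, sigma), with u profiled."""
    u, mu, hess = _inner_modes(X @ beta, y, city, q, sigma, u0)
    mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = float(y @ np.log(mu_c) + (1 - y) @ np.log1p(-mu_c))
    pen = 0.5 * float(u @ u) / (sigma * sigma)
    return ll - pen - 0.5 * float(np.log(sigma * sigma * hess).sum()), u, mu


def fit_glmm(
    frame,
    spec: GLMMSpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    sigma_fixed: float | None = None,
) -> GLMMFit:
    """Fit the binomial random-intercept GLMM.

    ``frame`` is a :class:`~urbancline.geoprep.ModelFrame` (or a bare
    DataFrame with the standardized columns, ``melanic`` and
    ``city_id``).  ``sigma_fixed`` pins the random-intercept SD (0
    reduces the model to plain logistic IRLS).
    """
    if spec is None:
        spec = GLMMSpec()
    stats = None
    if isinstance(frame, ModelFrame):
        stats = frame.stats
        df = frame.data
    else:
        df = frame
    terms = spec.all_terms()
    X = build_design(df, terms)
    y = df["melanic"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary")
    cities, city = np.unique(df["city_id"].to_numpy(), return_inverse=True)
    q = len(cities)
    if q < 2 and sigma_fixed is None:
        raise ValueError("need >= 2 cities to estimate a random intercept")
    _check_rank(X, terms)
    n, p = X.shape

    state = {"beta": np.zeros(p), "u": np.zeros(q), "evals": 0}

    def profiled_negloglik(log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        beta, u, mu, M, d, pen_obj, it, ok = _pirls(
            X, y, city, q, sigma, state["beta"], state["u"]
        )
        state["beta"], state["u"] = beta, u
        state["evals"] += it
        return -_laplace_loglik(pen_obj, d, sigma, q)

    sigma_boundary = False
    lo, hi = -8.0, 3.0
    if sigma_fixed is not None and sigma_fixed < 0:
        raise ValueError("sigma_fixed must be nonnegative")

    if sigma_fixed is not None and sigma_fixed == 0.0:
        # plain logistic IRLS limit
        beta, u, mu, M, d, pen_obj, it, inner_ok = _pirls(
            X, y, city, q, 0.0, state["beta"], state["u"], tol=min(tol, 1e-12),
            max_iter=max_iter,
        )
        sigma_hat = 0.0
        outer_ok = inner_ok
        loglik = _laplace_loglik(pen_obj, d, 0.0, q)
        n_outer = it
    else:
        # stage 0: cheap profile over log sigma with beta absorbed into
        # the penalized IRLS; gives starting values only
        if sigma_fixed is None:
            res0 = minimize_scalar(
                profiled_negloglik,
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-4, "maxiter": max_iter},
            )
            log_sigma0 = float(res0.x)
        else:
            log_sigma0 = float(np.log(sigma_fixed))
            profiled_negloglik(log_sigma0)  # warm the (beta, u) state

        from scipy.optimize import minimize

        # stage 1: quasi-Newton on (beta, log sigma) over the full
        # Laplace objective, with only u profiled by the inner solve
        u_state = {"u": state["u"].copy()}

        def negloglik(params: np.ndarray) -> float:
            beta_p = params[:p]
            sigma_p = float(np.exp(params[p])) if sigma_fixed is None else float(sigma_fixed)
            val, u, _ = _laplace_objective(X, y, city, q, beta_p, sigma_p, u_state["u"])
            u_state["u"] = u
            return -val

        x0 = np.concatenate([state["beta"], [log_sigma0]])
        nfree = p + 1 if sigma_fixed is None else p
        bounds = [(None, None)] * p + ([(lo, hi)] if sigma_fixed is None else [(log_sigma0, log_sigma0)])
        res = minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
        )
        beta = res.x[:p]
        sigma_hat = float(np.exp(res.x[p])) if sigma_fixed is None else float(sigma_fixed)
        outer_ok = bool(res.success)
        n_outer = int(res.nit)
        if sigma_fixed is None and res.x[p] < lo + 0.2:
            sigma_boundary = True
            warnings.warn(
                "random-intercept SD collapsed toward 0; model is near the "
                "plain-GLM boundary",
                stacklevel=2,
            )
        loglik_val, u, mu = _laplace_objective(
            X, y, city, q, beta, sigma_hat, u_state["u"]
        )
        loglik = loglik_val
        # information for beta at the optimum (Schur complement of the
        # u block of the penalized joint Hessian)
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        A = (X * W[:, None]).T @ X
        d = np.bincount(city, weights=W, minlength=q) + 1.0 / (sigma_hat * sigma_hat)
        B = np.empty((p, q))
        for k in range(p):
            B[k] = np.bincount(city, weights=W * X[:, k], minlength=q)
        M = A - (B / d) @ B.T
        it = n_outer
        inner_ok = True
    vcov = np.linalg.inv(M)
    se = np.sqrt(np.diag(vcov))
    fit = GLMMFit(
        terms=terms,
        beta=beta,
        se=se,
        sigma_city=sigma_hat,
        u=u,
        city_ids=cities,
        loglik=float(loglik),
        converged=bool(outer_ok and inner_ok),
        n_iter=state["evals"] + it,
        fitted_prob=mu,
        resid_response=y - mu,
        vcov=vcov,
        stats=stats,
        sigma_boundary=sigma_boundary,
    )
    if not fit.converged:
        warnings.warn("GLMM fit did not converge", stacklevel=2)
    return fit


def wald_tests(fit: GLMMFit) -> pd.DataFrame:
    """Two-sided Wald tests (z = estimate/SE against the standard
    normal) for every fixed-effect term."""
    return pd.DataFrame(
        {
            "term": list(fit.terms),
            "estimate": fit.beta,
            "se": fit.se,
            "z": fit.z,
            "p": fit.p,
        }
    )


def predict_cline(
    fit: GLMMFit,
    imperv_grid: np.ndarray,
    winter_temp: float,
    forest_pct: float,
    city_area_ha: float,
) -> pd.DataFrame:
    """Population-level melanism probability along the within-city
    urbanization gradient (rescaled impervious cover in [0, 1]) at the
    stated raw covariate values; the random effect is set to 0.
    """
    if fit.stats is None:
        raise ValueError("fit carries no standardization statistics")
    st = fit.stats
    grid = np.asarray(imperv_grid, dtype=float)
    x_imp = st.standardize("x_imperv", grid)
    x_temp = float(st.standardize("x_temp", winter_temp))
    x_forest = float(st.standardize("x_forest", forest_pct))
    x_logsize = float(st.standardize("x_logsize", np.log(city_area_ha)))
    for name, val in (("x_temp", x_temp), ("x_forest", x_forest), ("x_logsize", x_logsize)):
        if abs(val) > 3.0:
            warnings.warn(
                f"{name} setting is {val:.1f} SD from the training mean",
                stacklevel=2,
            )
    df = pd.DataFrame(
        {
            "x_imperv": x_imp,
            "x_temp": x_temp,
            "x_forest": x_forest,
            "x_logsize": x_logsize,
        }
    )
    if "x_autocov" in fit.terms:
        df["x_autocov"] = 0.0
    X = build_design(df, fit.terms)
    eta = X @ fit.beta
    return pd.DataFrame(
        {"imperv_rescaled": grid, "eta": eta, "prob_melanic": expit(eta)}
    )


def binned_residuals(fit: GLMMFit, n_bins: int | None = None) -> pd.DataFrame:
    """Binned-residual calibration table for a binary response.

    Rows are sorted by fitted probability (stable, then by row index)
    and cut into equal-count bins; each bin reports the mean fitted
    value, mean response residual, and a ±2 SE band.
    """
    n = len(fit.fitted_prob)
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(n)))
    if n_bins > n:
        raise ValueError("n_bins cannot exceed the number of observations")
    order = np.argsort(fit.fitted_prob, kind="stable")
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    rows = []
    for b in range(n_bins):
        idx = order[edges[b] : edges[b + 1]]
        if len(idx) == 0:
            continue
        res = fit.resid_response[idx]
        se2 = 2.0 * res.std(ddof=0) / np.sqrt(len(idx))
        rows.append(
            {
                "bin": b,
                "n": len(idx),
                "mean_fitted": float(fit.fitted_prob[idx].mean()),
                "mean_resid": float(res.mean()),
                "band_2se": float(se2),
            }
        )
    return pd.DataFrame(rows)
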