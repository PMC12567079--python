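"""Gamma log-link mixed model with a scalar random intercept.

The model for observation j in group g (court) is

    y_gj ~ Gamma(shape k, mean mu_gj),   log mu_gj = x_gj' beta + b_g,
    b_g ~ Normal(0, sigma_b^2),

fitted by maximizing the Laplace-approximated marginal likelihood. The
random-intercept posterior mode is found by a damped Newton step that is
concave in b (the Gamma log-link log-likelihood is concave in the linear
predictor), vectorized across groups, and the outer optimization over
(beta, log sigma_b, log k) uses L-BFGS-B. Standard errors come from the
finite-difference Hessian of the negative log marginal likelihood at the
optimum; Wald chi-square statistics are (beta / se)^2 on 1 d.f.

When the grouping factor has fewer than two levels, or the outer
optimization fails, the fit falls back to a fixed-effects Gamma GLM
(statsmodels) with a warning and is flagged accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

import statsmodels.api as sm

__all__ = ["GammaGLMMFit", "fit_gamma_glmm_arrays"]

_SINGULAR_SD = 1e-3  # below this, the random intercept is reported singular


@dataclass
class GammaGLMMFit:
    """Result of a Gamma log-link (mixed) fit."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    wald_chi2: np.ndarray
    pvalues: np.ndarray
    ranef_var: float
    ranef_sd: float
    shape: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool
    method: str  # "laplace" or "glm"
    messages: list[str] = field(default_factory=list)
    ranef_modes: np.ndarray | None = None

    def table(self) -> pd.DataFrame:
        """Per-coefficient estimate (s.e.), chi-square and p, Table-style."""
        return pd.DataFrame(
            {
                "estimate": self.coef,
                "se": self.se,
                "chi2": self.wald_chi2,
                "p": self.pvalues,
            },
            index=self.names,
        )

    def confint(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.coef - z * self.se, self.coef + z * self.se])


def _gamma_loglik_terms(y: np.ndarray, eta: np.ndarray, k: float) -> np.ndarray:
    """Pointwise Gamma(log-link) log density with shape k, mean exp(eta)."""
    return (
        k * np.log(k)
        - special.gammaln(k)
        + (k - 1) * np.log(y)
        - k * eta
        - k * y * np.exp(-eta)
    )


def _solve_modes(
    y: np.ndarray,
    eta0: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
    k: float,
    s2: float,
    b0: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior modes b* of the random intercepts and -h''(b*) per group.

    h(b) is strictly concave (h'' = -k sum y exp(-eta) - 1/s2 < 0), so a
    damped Newton iteration from the previous modes converges quickly.
    """
    b = b0.copy()
    for _ in range(max_iter):
        eta = eta0 + b[groups]
        w = k * y * np.exp(-eta)  # positive
        g1 = np.bincount(groups, weights=w, minlength=n_groups) \
            - k * np.bincount(groups, minlength=n_groups) - b / s2
        g2 = -np.bincount(groups, weights=w, minlength=n_groups) - 1.0 / s2
        step = -g1 / g2
        step = np.clip(step, -2.0, 2.0)  # damp: exp(-eta) explodes on overshoot
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    eta = eta0 + b[groups]
    neg_h2 = np.bincount(groups, weights=k * y * np.exp(-eta), minlength=n_groups) + 1.0 / s2
    return b, neg_h2


def _laplace_nll_factory(y, X, groups, n_groups):
    state = {"b": np.zeros(n_groups)}

    def nll(theta: np.ndarray) -> float:
        p = X.shape[1]
        beta = theta[:p]
        s2 = np.exp(2.0 * theta[p])
        k = np.exp(theta[p + 1])
        eta0 = X @ beta
        b, neg_h2 = _solve_modes(y, eta0, groups, n_groups, k, s2, state["b"])
        state["b"] = b
        eta = eta0 + b[groups]
        ll = _gamma_loglik_terms(y, eta, k).sum()
        ll += -0.5 * np.sum(b**2) / s2 - 0.5 * n_groups * np.log(s2)
        ll += -0.5 * np.sum(np.log(neg_h2))
        if not np.isfinite(ll):
            return 1e12
        return -ll

    return nll, state


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _glm_fallback(y, X, names, n_groups, message: str) -> GammaGLMMFit:
    warnings.warn(f"falling back to fixed-effects Gamma GLM: {message}", stacklevel=3)
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    res = model.fit()
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    wald = (coef / se) ** 2
    return GammaGLMMFit(
        names=list(names),
        coef=coef,
        se=se,
        wald_chi2=wald,
        pvalues=stats.chi2.sf(wald, 1),
        ranef_var=0.0,
        ranef_sd=0.0,
        shape=1.0 / float(res.scale),
        loglik=float(res.llf),
        n_obs=int(y.size),
        n_groups=n_groups,
        converged=bool(res.converged),
        singular=True,
        method="glm",
        messages=[message],
    )


def fit_gamma_glmm_arrays(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
) -> GammaGLMMFit:
    """Fit the Laplace Gamma GLMM from raw arrays.

    ``X`` must already contain the intercept column. ``groups`` is an
    integer code per observation.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per observation")
    if np.any(y <= 0):
        raise ValueError(
            "response contains non-positive values; a Gamma model needs a "
            "strictly positive response (apply zero handling first)"
        )
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = int(codes.max()) + 1 if codes.size else 0

    if n_groups < 2:
        return _glm_fallback(y, X, names, n_groups, "grouping factor has < 2 levels")

    # starting values: log-scale least squares for beta, moments for k
    log_y = np.log(y)
    beta0, *_ = np.linalg.lstsq(X, log_y, rcond=None)
    resid = log_y - X @ beta0
    var_r = max(float(np.var(resid)), 1e-3)
    k0 = min(max(1.0 / var_r, 0.1), 1e4)
    theta0 = np.concatenate([beta0, [np.log(0.3), np.log(k0)]])

    nll, _state = _laplace_nll_factory(y, X, codes, n_groups)
    p = X.shape[1]
    bounds = [(None, None)] * p + [(np.log(1e-5), np.log(50.0)), (np.log(1e-3), np.log(1e6))]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    if not res.success or not np.isfinite(res.fun):
        return _glm_fallback(y, X, names, n_groups, f"optimizer: {res.message}")

    theta = res.x
    sigma = float(np.exp(theta[p]))
    shape_k = float(np.exp(theta[p + 1]))
    H = _fd_hessian(nll, theta)
    se = np.full(p, np.nan)
    messages: list[str] = []
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:p]
        if np.any(d <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        se = np.sqrt(d)
    except np.linalg.LinAlgError:
        # near-singular curvature (usually sigma at the boundary):
        # invert the beta block alone
        try:
            covb = np.linalg.inv(H[:p, :p])
            se = np.sqrt(np.maximum(np.diag(covb), 0.0))
            messages.append("SEs from beta block of the Hessian (boundary fit)")
        except np.linalg.LinAlgError:
            return _glm_fallback(y, X, names, n_groups, "Hessian not invertible")
    se = np.where(se > 0, se, np.nan)

    coef = theta[:p]
    with np.errstate(invalid="ignore"):
        wald = (coef / se) ** 2
    singular = sigma < _SINGULAR_SD
    if singular:
        messages.append(f"random-intercept sd at boundary ({sigma:.2e})")
    eta0 = X @ coef
    b, _ = _solve_modes(y, eta0, codes, n_groups, shape_k, sigma**2, np.zeros(n_groups))
    return GammaGLMMFit(
        names=names,
        coef=coef,
        se=se,
        wald_chi2=wald,
        pvalues=stats.chi2.sf(wald, 1),
        ranef_var=sigma**2,
        ranef_sd=sigma,
        shape=shape_k,
        loglik=-float(res.fun),
        n_obs=int(y.size),
        n_groups=n_groups,
        converged=True,
        singular=singular,
        method="laplace",
        messages=messages,
        ranef_modes=b,
    )
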