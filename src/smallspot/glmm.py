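"""Logistic mixed-effects regression with scalar random intercepts,
fit by maximum likelihood under the Laplace approximation.

The model for Bernoulli outcome y with fixed design X and grouping
factors f = 1..F (q_f levels each) is

    logit P(y = 1) = X beta + sum_f Z_f u_f,   u_f ~ N(0, sigma_f^2 I)

Fitting profiles (beta, u) out with penalized IRLS at each candidate set
of variance parameters, evaluates the Laplace-approximate marginal
log-likelihood

    l(beta, u*) - 1/2 sum_f |u_f|^2 / sigma_f^2 - 1/2 log det(I + D Z'WZ)

and optimizes the variance parameters on the log scale with Nelder-Mead.
This mirrors the standard Laplace (nAGQ = 1) scheme of lme4/fitglme and
yields a genuine log-likelihood, so nested models can be compared by
likelihood-ratio test.  With grouping factors of only two levels each
(the design this package meets in practice) variance estimation can be
degenerate; in that case the model can fall back to a fixed-effects
logistic fit (statsmodels GLM) with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2

from .exceptions import InvalidInputError, SeparationError

_SIGMA_FLOOR = 1e-6
_DEGENERATE_SIGMA = 1e-3


@dataclass
class MixedLogitResult:
    """Fit summary: coefficients, Wald covariance, variance components,
    Laplace log-likelihood and AIC."""

    params: pd.Series
    cov_params: pd.DataFrame
    sigmas: dict[str, float]
    ranef: dict[str, pd.Series]
    loglik: float
    loglik_null: float
    n_obs: int
    n_params: int
    converged: bool
    method: str = "laplace"
    exog_names: list[str] = field(default_factory=list)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        se = self.bse
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se}
        )

    def odds_factors(self, alpha: float = 0.05) -> pd.DataFrame:
        """exp(beta) with CIs: multiplicative odds change per unit predictor."""
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "odds_factor": np.exp(self.params),
                "lower": np.exp(ci["lower"]),
                "upper": np.exp(ci["upper"]),
            }
        )

    def pvalues(self) -> pd.Series:
        from scipy.stats import norm

        z = self.params / self.bse
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.params.index)

    @property
    def pseudo_r2_adjusted(self) -> float:
        """Adjusted McFadden pseudo-R^2: 1 - (loglik - k) / loglik_null."""
        return 1.0 - (self.loglik - self.n_params) / self.loglik_null


def _encode_groups(groups: dict[str, np.ndarray], n: int):
    """One-hot random-effect design per factor; returns Z, slices, level labels."""
    blocks, slices, levels = [], {}, {}
    start = 0
    for name, codes in groups.items():
        codes = np.asarray(codes)
        if codes.shape[0] != n:
            raise InvalidInputError(f"grouping factor {name!r} has wrong length")
        labs, idx = np.unique(codes, return_inverse=True)
        q = labs.size
        z = np.zeros((n, q))
        z[np.arange(n), idx] = 1.0
        blocks.append(z)
        slices[name] = slice(start, start + q)
        levels[name] = labs
        start += q
    Z = np.hstack(blocks) if blocks else np.zeros((n, 0))
    return Z, slices, levels


def _pirls(y, X, Z, dinv_diag, coef0, max_iter=100, tol=1e-9):
    """Penalized IRLS over the joint coefficient vector [beta, u]."""
    n, p = X.shape
    q = Z.shape[1]
    C = np.hstack([X, Z])
    pen = np.concatenate([np.zeros(p), dinv_diag])
    coef = coef0.copy()
    for _ in range(max_iter):
        eta = C @ coef
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = C.T @ (y - mu) - pen * coef
        H = (C.T * w) @ C + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # dampen huge steps (separation-prone data)
        m = np.max(np.abs(step))
        if m > 10.0:
            step *= 10.0 / m
        coef = coef + step
        if np.max(np.abs(grad)) < tol or np.max(np.abs(step)) < 1e-10:
            break
    eta = C @ coef
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    ll = float(np.sum(np.where(y > 0.5, np.log(np.clip(mu, 1e-12, None)),
                               np.log(np.clip(1 - mu, 1e-12, None)))))
    H = (C.T * w) @ C + np.diag(pen)
    return coef, ll, w, H


def _laplace_loglik(y, X, Z, log_sigma_per_col, coef0):
    dinv = np.exp(-2.0 * log_sigma_per_col)  # 1/sigma^2 per u column
    coef, ll, w, H = _pirls(y, X, Z, dinv, coef0)
    p = X.shape[1]
    u = coef[p:]
    quad = float(np.sum(u**2 * dinv))
    # log det(I + D Z'WZ), stable as sigma -> 0
    ZtWZ = (Z.T * w) @ Z
    D = np.diag(np.exp(2.0 * log_sigma_per_col))
    sign, logdet = np.linalg.slogdet(np.eye(Z.shape[1]) + D @ ZtWZ)
    lap = ll - 0.5 * quad - 0.5 * logdet
    return lap, coef, H


def fit_logistic_mixed(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    groups: dict[str, np.ndarray],
    allow_fallback: bool = True,
    separation_bound: float = 15.0,
) -> MixedLogitResult:
    """Fit the Laplace-ML logistic mixed model.

    ``X`` must include the intercept column.  ``groups`` maps factor name
    to a length-n array of level codes; each factor contributes an
    independent random-intercept variance.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    names = [str(c) for c in Xdf.columns]
    Xm = Xdf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if y.shape[0] != n:
        raise InvalidInputError("y and X have different lengths")
    if n < p + 2:
        raise InvalidInputError("too few observations")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise InvalidInputError("y must be binary 0/1")

    Z, slices, levels = _encode_groups(groups, n)
    q = Z.shape[1]
    factor_of_col = np.empty(q, dtype=object)
    for name, sl in slices.items():
        factor_of_col[sl] = name

    coef0 = np.zeros(p + q)
    state = {"coef": coef0}

    def objective(log_sigmas: np.ndarray) -> float:
        ls = np.clip(log_sigmas, np.log(_SIGMA_FLOOR), 5.0)
        per_col = np.array([ls[list(slices).index(f)] for f in factor_of_col])
        lap, coef, _ = _laplace_loglik(y, Xm, Z, per_col, state["coef"])
        state["coef"] = coef
        return -lap

    nf = len(slices)
    opt = minimize(
        objective,
        x0=np.zeros(nf),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
    )
    log_sigmas = np.clip(opt.x, np.log(_SIGMA_FLOOR), 5.0)
    per_col = np.array([log_sigmas[list(slices).index(f)] for f in factor_of_col])
    lap, coef, H = _laplace_loglik(y, Xm, Z, per_col, state["coef"])

    beta = coef[:p]
    # separation check on the fixed effects (scaled by predictor spread)
    scales = np.where(np.std(Xm, axis=0) > 0, np.std(Xm, axis=0), 1.0)
    z_extent = np.abs(beta) * scales
    if np.any(z_extent > separation_bound):
        worst = names[int(np.argmax(z_extent))]
        raise SeparationError(
            f"apparent complete separation on predictor {worst!r} "
            f"(|beta|*sd = {z_extent.max():.1f})"
        )

    sigmas = {name: float(np.exp(log_sigmas[i])) for i, name in enumerate(slices)}
    degenerate = any(s < _DEGENERATE_SIGMA for s in sigmas.values())
    method = "laplace"
    if degenerate and allow_fallback:
        warnings.warn(
            "random-intercept variance estimated at the boundary; "
            "falling back to a fixed-effects logistic fit",
            stacklevel=2,
        )
        return _fixed_effects_fallback(y, Xdf, groups, sigmas)

    cov_all = np.linalg.inv(H)
    cov_beta = pd.DataFrame(cov_all[:p, :p], index=names, columns=names)
    ranef = {
        name: pd.Series(coef[p:][sl], index=levels[name]) for name, sl in slices.items()
    }
    # null model: intercept-only fixed effect, same random structure
    null_lap, _, _ = _laplace_loglik(y, np.ones((n, 1)), Z, per_col, np.zeros(1 + q))
    return MixedLogitResult(
        params=pd.Series(beta, index=names),
        cov_params=cov_beta,
        sigmas=sigmas,
        ranef=ranef,
        loglik=float(lap),
        loglik_null=float(null_lap),
        n_obs=n,
        n_params=p + nf,
        converged=bool(opt.success),
        method=method,
        exog_names=names,
    )


def _fixed_effects_fallback(y, Xdf, groups, sigmas) -> MixedLogitResult:
    import statsmodels.api as sm

    X = Xdf.copy()
    for name, codes in groups.items():
        d = pd.get_dummies(pd.Series(np.asarray(codes)), prefix=name, drop_first=True)
        for c in d.columns:
            X[str(c)] = d[c].to_numpy(dtype=float)
    model = sm.GLM(y, X.to_numpy(dtype=float), family=sm.families.Binomial())
    res = model.fit()
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
    names = [str(c) for c in X.columns]
    return MixedLogitResult(
        params=pd.Series(res.params, index=names),
        cov_params=pd.DataFrame(res.cov_params(), index=names, columns=names),
        sigmas=sigmas,
        ranef={},
        loglik=float(res.llf),
        loglik_null=float(null.llf),
        n_obs=int(res.nobs),
        n_params=len(names),
        converged=True,
        method="fixed_fallback",
        exog_names=names,
    )


def fit_logistic_fixed(y: np.ndarray, X: pd.DataFrame) -> MixedLogitResult:
    """Plain fixed-effects logistic fit (statsmodels GLM), same result type."""
    return _fixed_effects_fallback(np.asarray(y, float), X, {}, {})


def likelihood_ratio_test(full: MixedLogitResult, reduced: MixedLogitResult):
    """LR test of nested fits: (lr_stat, delta_df, delta_aic, p).

    delta_aic is aic_full - aic_reduced (negative favours the full model).
    """
    if full.n_obs != reduced.n_obs:
        raise InvalidInputError("models were fit to different data")
    if reduced.n_params > full.n_params:
        raise InvalidInputError("reduced model is not nested in the full model")
    lr = 2.0 * (full.loglik - reduced.loglik)
    ddf = full.n_params - reduced.n_params
    daic = full.aic - reduced.aic
    if ddf == 0:
        p = 1.0 if lr <= 1e-10 else 0.0
    else:
        p = float(chi2.sf(max(lr, 0.0), ddf))
    return float(lr), int(ddf), float(daic), p
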