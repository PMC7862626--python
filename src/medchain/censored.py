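"""Left-censored lognormal maximum-likelihood multiple imputation.

CRP below an assay's detection limit is recorded only as "below L". The
observed-data likelihood on the log scale combines Gaussian densities for
observed values with Gaussian CDF terms at log-limits for censored ones.
Proper multiple imputation draws model parameters from the asymptotic
normal of the MLE and then censored records from the truncated conditional
distribution; downstream estimates are pooled with Rubin's rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from ._rng import substream


@dataclass
class CensoredFit:
    """MLE of a censored lognormal regression.

    ``params`` stacks the regression coefficients and log(sigma); ``cov``
    is the asymptotic covariance of that stacked vector (inverse observed
    information).
    """

    beta: np.ndarray
    sigma: float
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    exog_names: list[str] | None = None


@dataclass
class ImputationResult:
    m: int
    estimates: np.ndarray
    variances: np.ndarray
    theta_bar: float
    within: float
    between: float
    total: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))


def _neg_loglik(params, X, logy, logL, censored):
    beta = params[:-1]
    sigma = np.exp(params[-1])
    mu = X @ beta
    ll = 0.0
    obs = ~censored
    if obs.any():
        ll += np.sum(stats.norm.logpdf(logy[obs], mu[obs], sigma))
    if censored.any():
        ll += np.sum(stats.norm.logcdf((logL[censored] - mu[censored]) / sigma))
    return -ll


def fit_censored_lognormal(
    value: np.ndarray,
    censored: np.ndarray,
    limit: np.ndarray,
    X: np.ndarray,
    exog_names: list[str] | None = None,
) -> CensoredFit:
    """Fit a lognormal regression by censored maximum likelihood.

    ``value`` holds the observed outcome (mg/L; entries for censored
    records are ignored), ``censored`` flags records below their
    ``limit``, and ``X`` is the design matrix (include the intercept
    column). Maximizes

        sum_obs log phi((log y - x b)/s)/s + sum_cens log Phi((log L - x b)/s)

    and returns the MLE with its asymptotic covariance over (b, log s).
    Observed values below their nominal limit are treated as observed with
    a warning.
    """
    value = np.asarray(value, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    limit = np.asarray(limit, dtype=float)
    X = np.asarray(X, dtype=float)
    if censored.all():
        raise ValueError("all records censored: location is not identifiable")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    low_obs = (~censored) & (value < limit)
    if low_obs.any():
        warnings.warn(f"{int(low_obs.sum())} observed values below their nominal limit; kept as observed")

    obs = ~censored
    logy = np.where(obs, np.log(np.where(obs, value, 1.0)), 0.0)
    logL = np.log(limit)

    # start from OLS on observed records, censored filled at their limit
    y0 = np.where(obs, logy, logL)
    beta0, _, _, _ = np.linalg.lstsq(X, y0, rcond=None)
    resid = y0 - X @ beta0
    s0 = max(np.std(resid), 1e-3)
    x0 = np.append(beta0, np.log(s0))

    res = optimize.minimize(
        _neg_loglik, x0, args=(X, logy, logL, censored), method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    # polish with Nelder-Mead if BFGS stalls on a rough surface
    if not res.success:
        res = optimize.minimize(
            _neg_loglik, res.x, args=(X, logy, logL, censored), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
    params = res.x
    H = approx_hess(params, _neg_loglik, args=(X, logy, logL, censored))
    cov = np.linalg.inv(H)
    return CensoredFit(
        beta=params[:-1].copy(),
        sigma=float(np.exp(params[-1])),
        params=params,
        cov=cov,
        loglik=float(-res.fun),
        exog_names=exog_names,
    )


def draw_imputations(
    fit: CensoredFit,
    value: np.ndarray,
    censored: np.ndarray,
    limit: np.ndarray,
    X: np.ndarray,
    m: int = 30,
    seed: int = 0,
    proper: bool = True,
) -> list[np.ndarray]:
    """Draw ``m`` completed outcome vectors (mg/L scale).

    With ``proper=True`` each imputation first draws (beta*, log sigma*)
    from the asymptotic normal of the MLE; censored records are then drawn
    from the lognormal conditional distribution truncated above at the
    record's detection limit, via inverse-CDF sampling. Observed records
    are passed through untouched.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    value = np.asarray(value, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    limit = np.asarray(limit, dtype=float)
    X = np.asarray(X, dtype=float)
    rng = substream(seed, "imputation")
    out = []
    for _ in range(m):
        if proper:
            params = rng.multivariate_normal(fit.params, fit.cov, method="cholesky")
        else:
            params = fit.params
        beta, sigma = params[:-1], float(np.exp(params[-1]))
        completed = value.copy()
        if censored.any():
            mu = X[censored] @ beta
            z_lim = (np.log(limit[censored]) - mu) / sigma
            u = rng.random(int(censored.sum()))
            z = stats.norm.ppf(u * stats.norm.cdf(z_lim))
            completed[censored] = np.exp(mu + sigma * z)
        out.append(completed)
    return out


def rubin_pool(estimates: np.ndarray, variances: np.ndarray) -> ImputationResult:
    """Pool per-imputation estimates with Rubin's rules.

    theta_bar = mean estimate, W = mean within-imputation variance,
    B = between-imputation sample variance, T = W + (1 + 1/m) B.
    """
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if estimates.shape != variances.shape:
        raise ValueError("estimates and variances must have equal length")
    m = estimates.size
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    theta_bar = float(np.mean(estimates))
    within = float(np.mean(variances))
    between = float(np.var(estimates, ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    return ImputationResult(m, estimates, variances, theta_bar, within, between, total)
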