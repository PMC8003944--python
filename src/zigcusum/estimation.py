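"""Parameter estimation from an observed count series.

Two fitters are provided, both conditioning on the first observation:

* conditional least squares (CLS) — the conditional mean of the process is
  E[X_t | X_{t-1} = x] = alpha (1-beta) x + mu_eps, so an ordinary
  regression of X_t on X_{t-1} identifies the autocorrelation product
  rho = alpha (1-beta) but not alpha and beta separately; (theta, p) come
  from inverting the closed-form marginal mean/variance, and the (alpha,
  beta) split is completed by a one-dimensional profile of the conditional
  likelihood along the ridge alpha (1-beta) = rho_hat;
* conditional maximum likelihood (CML) — direct maximization of
  sum_t log P(X_t | X_{t-1}) over a smooth reparameterization of the
  constrained parameter region, multi-started from the CLS estimate plus
  seeded random perturbations.

Model-selection criteria use 4 free parameters:
AIC = -2 loglik + 8, BIC = -2 loglik + 4 log(n-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit

from .model import ZIGParams, transition_matrix
from .series import as_counts

__all__ = ["FitResult", "conditional_loglik", "cls_fit", "cml_fit"]

N_PARAMS = 4
_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with likelihood-based summaries.

    ``n_used`` is the number of transitions entering the conditional
    likelihood (series length minus one).
    """

    params: ZIGParams
    loglik: float
    aic: float
    bic: float
    method: str
    converged: bool
    n_used: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "theta": self.params.theta,
            "p": self.params.p,
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "method": self.method,
            "converged": self.converged,
            "n_used": self.n_used,
            "message": self.message,
        }


def conditional_loglik(params: ZIGParams, series) -> float:
    """Sum of log one-step transition probabilities along the series."""
    x = as_counts(series)
    if x.size < 2:
        raise ValueError("series must contain at least two observations")
    T = transition_matrix(params, int(x.max()))
    probs = T[x[:-1], x[1:]]
    if np.any(probs < _LOG_FLOOR):
        warnings.warn("transition probability underflow; floored at 1e-300", stacklevel=2)
        probs = np.maximum(probs, _LOG_FLOOR)
    return float(np.log(probs).sum())


def _result(params: ZIGParams, x: np.ndarray, method: str, converged: bool, msg: str = "") -> FitResult:
    ll = conditional_loglik(params, x)
    n_used = x.size - 1
    return FitResult(
        params=params,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * N_PARAMS,
        bic=-2.0 * ll + N_PARAMS * np.log(n_used),
        method=method,
        converged=converged,
        n_used=n_used,
        message=msg,
    )


def _marginal_moment_inversion(x: np.ndarray) -> tuple[float, float]:
    """(theta, p) from the sample mean and variance of the marginal.

    mean = (1-p) theta and variance = (1-p) theta [(1+p) theta + 1] give
    theta (1-p) = mean and theta (1+p) = variance/mean - 1, hence
    theta = (A + B)/2 and p = (B - A)/(A + B) with A = mean,
    B = variance/mean - 1.  Solvable in the valid region only under
    overdispersion beyond mean (1 + mean).
    """
    a = float(x.mean())
    v = float(x.var(ddof=1))
    if v <= a:
        raise ValueError(
            "sample variance <= sample mean: the zero-inflated geometric moment "
            "equations have no solution; use cml_fit instead"
        )
    b = v / a - 1.0
    theta = 0.5 * (a + b)
    p = (b - a) / (a + b)
    if not 0 < p < 1 or theta <= 0:
        raise ValueError(
            f"moment inversion left the valid region (theta={theta:.4g}, p={p:.4g}); "
            "use cml_fit instead"
        )
    return theta, p


def _complete_alpha_beta(
    x: np.ndarray, theta: float, p: float, rho: float
) -> tuple[float, float]:
    """Split rho = alpha (1-beta) by profiling the likelihood over beta."""
    eps = 1e-4
    beta_hi = 1.0 - rho - eps  # alpha = rho/(1-beta) < 1

    def neg_profile(beta: float) -> float:
        alpha = rho / (1.0 - beta)
        try:
            cand = ZIGParams(theta, p, alpha, beta)
        except ValueError:
            return 1e12
        return -conditional_loglik(cand, x)

    if beta_hi <= eps:
        raise ValueError(f"autocorrelation estimate rho={rho:.4g} leaves no room for beta")
    res = minimize_scalar(neg_profile, bounds=(eps, beta_hi), method="bounded")
    beta = float(res.x)
    return rho / (1.0 - beta), beta


def cls_fit(series) -> FitResult:
    """Conditional least squares fit (with profile completion of alpha, beta)."""
    x = as_counts(series)
    if x.size < 3:
        raise ValueError("CLS needs at least three observations")
    if np.unique(x).size < 2:
        raise ValueError("CLS needs at least two distinct values")
    theta, p = _marginal_moment_inversion(x)
    ols = sm.OLS(x[1:], sm.add_constant(x[:-1].astype(float))).fit()
    rho = float(ols.params[1])
    if not 0 < rho < 1:
        warnings.warn(
            f"lag-1 regression slope {rho:.4g} outside (0,1); clamped", stacklevel=2
        )
        rho = float(np.clip(rho, 1e-3, 1.0 - 1e-3))
    alpha, beta = _complete_alpha_beta(x, theta, p, rho)
    return _result(ZIGParams(theta, p, alpha, beta), x, "CLS", True)


# ---------------------------------------------------------------------------
# conditional maximum likelihood

def _pack(params: ZIGParams) -> np.ndarray:
    lo = params.stationarity_bound
    u = logit(min(max((params.alpha - lo) / (1.0 - lo), 1e-9), 1 - 1e-9))
    return np.array([np.log(params.theta), logit(params.p), logit(params.beta), u])


def _unpack(z: np.ndarray) -> ZIGParams:
    theta = float(np.exp(np.clip(z[0], -20, 20)))
    p = float(expit(np.clip(z[1], -30, 30)))
    beta = float(expit(np.clip(z[2], -30, 30)))
    lo = p / (beta + p * (1.0 - beta))
    alpha = lo + (1.0 - lo) * float(expit(np.clip(z[3], -30, 30)))
    # keep strictly interior
    alpha = min(max(alpha, lo + 1e-10), 1.0 - 1e-10)
    return ZIGParams(theta, p, alpha, beta)


def cml_fit(series, starts: int = 10, seed: int = 0) -> FitResult:
    """Conditional maximum likelihood fit.

    Optimizes over (log theta, logit p, logit beta, u) where u maps through a
    logistic onto the interval the stationarity constraint leaves for alpha,
    so every iterate is a valid parameter set.  ``starts`` seeded starting
    points (the CLS estimate when obtainable, plus random perturbations) are
    polished with Nelder–Mead and the best local optimum is returned.
    """
    x = as_counts(series)
    if x.size < 30:
        raise ValueError("CML needs at least 30 observations")
    degenerate = np.unique(x).size < 2

    def neg_ll(z: np.ndarray) -> float:
        try:
            return -conditional_loglik(_unpack(z), x)
        except (ValueError, FloatingPointError):
            return 1e12

    rng = np.random.default_rng(seed)
    z_list = []
    try:
        z_list.append(_pack(cls_fit(x).params))
    except ValueError:
        pass
    base = z_list[0] if z_list else np.array([np.log(max(x.mean(), 0.5)), 0.0, 0.0, 0.0])
    while len(z_list) < max(1, starts):
        z_list.append(base + rng.normal(scale=1.0, size=4))

    best = None
    any_ok = False
    for z0 in z_list:
        res = minimize(neg_ll, z0, method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        any_ok = any_ok or bool(res.success)
    params = _unpack(best.x)
    on_boundary = bool(np.any(np.abs(best.x[1:]) > 12))
    converged = any_ok and not degenerate and not on_boundary
    msg = ""
    if degenerate:
        msg = "degenerate series (fewer than two distinct values)"
    elif on_boundary:
        msg = "estimate on the boundary of the parameter region"
    elif not any_ok:
        msg = "no start converged"
    return _result(params, x, "CML", converged, msg)
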