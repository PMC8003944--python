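"""Zero-inflated geometric INAR(1) process with a random thinning coefficient.

The process is the integer-valued autoregression

    X_t = a_t ∘ X_{t-1} + eps_t,

where ``a_t ∘ X`` is randomized binomial thinning: with probability ``1 - beta``
it equals ordinary binomial thinning ``alpha ∘ X`` (a Binomial(X, alpha) draw),
and with probability ``beta`` it equals 0.  The innovations ``eps_t`` are chosen
so that the stationary marginal of ``X_t`` is the zero-inflated geometric
distribution ZIG(p, theta):

    P(X = 0) = p + (1 - p) / (1 + theta),
    P(X = j) = (1 - p) theta^j / (1 + theta)^{j+1},   j >= 1.

Stationarity of this construction requires p / (beta + p(1-beta)) < alpha < 1;
outside that region the innovation law is not a probability distribution and
construction of :class:`ZIGParams` fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ZIGParams",
    "ProcessMoments",
    "marginal_pmf",
    "innovation_pmf",
    "innovation_mixture",
    "transition_pmf",
    "transition_matrix",
    "process_moments",
    "simulate_path",
    "sample_marginal",
]

#: cumulative-mass threshold used when a pmf has to be truncated for
#: normalization checks or inverse-CDF tables; geometric tails decay
#: exponentially so the truncation point is cheap to find.
TAIL_MASS = 1e-12


@dataclass(frozen=True)
class ZIGParams:
    """Parameters (theta, p, alpha, beta) of the process.

    theta : geometric scale of the marginal (mean of the geometric part).
    p     : zero-inflation weight of the marginal, in (0, 1).
    alpha : survival probability used by the binomial thinning, in (0, 1).
    beta  : probability that the random coefficient is 0 at a given step.

    Raises ``ValueError`` if a parameter is out of range or if the
    stationarity constraint p/(beta + p(1-beta)) < alpha is violated.
    """

    theta: float
    p: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        for name in ("p", "alpha", "beta"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        lo = self.stationarity_bound
        if not lo < self.alpha:
            raise ValueError(
                "stationarity constraint p/(beta + p(1-beta)) < alpha violated: "
                f"requires alpha > {lo:.6g}, got alpha = {self.alpha}"
            )

    @property
    def stationarity_bound(self) -> float:
        """Lower bound p/(beta + p(1-beta)) that alpha must exceed."""
        return self.p / (self.beta + self.p * (1.0 - self.beta))

    def replace(self, **kwargs) -> "ZIGParams":
        """Return a copy with some fields replaced (re-validated)."""
        fields = {"theta": self.theta, "p": self.p, "alpha": self.alpha, "beta": self.beta}
        fields.update(kwargs)
        return ZIGParams(**fields)


@dataclass(frozen=True)
class ProcessMoments:
    """Stationary mean, variance and lag-1 autocorrelation."""

    mean: float
    variance: float
    acf1: float


def _check_support(j) -> np.ndarray:
    j = np.asarray(j)
    if not np.issubdtype(j.dtype, np.integer):
        ji = np.asarray(j, dtype=float)
        if not np.all(ji == np.floor(ji)):
            raise ValueError("support points must be integers")
        j = ji.astype(np.int64)
    if np.any(j < 0):
        raise ValueError("support points must be nonnegative")
    return j


def _geom_pmf(j: np.ndarray, scale: float) -> np.ndarray:
    # pmf scale^j / (1+scale)^(j+1); "failures before first success" geometric
    # with success probability 1/(1+scale).
    return np.exp(j * np.log(scale) - (j + 1) * np.log1p(scale))


def marginal_pmf(params: ZIGParams, j) -> np.ndarray | float:
    """Stationary ZIG(p, theta) pmf; depends only on (theta, p)."""
    jj = _check_support(j)
    out = (1.0 - params.p) * _geom_pmf(jj, params.theta)
    out = np.where(jj == 0, out + params.p, out)
    return out if np.ndim(j) else float(out)


def innovation_mixture(params: ZIGParams) -> tuple[np.ndarray, float]:
    """Mixing weights of the innovation law and the second geometric scale.

    The innovation is a three-component mixture: a point mass at 0, a
    Geometric with scale theta and a Geometric with scale
    alpha*theta*(beta + p(1-beta)).  Returns ``(weights, scale2)`` where
    ``weights`` has the three mixing portions (summing to 1) and ``scale2``
    is the scale of the third component.
    """
    theta, p, alpha, beta = params.theta, params.p, params.alpha, params.beta
    s = beta + p * (1.0 - beta)
    w0 = p / s
    w1 = (1.0 - p) * (1.0 - alpha) / (1.0 - alpha * s)
    w2 = (1.0 - p) * (1.0 - beta) * (alpha * s - p) / ((1.0 - alpha * s) * s)
    return np.array([w0, w1, w2]), alpha * theta * s


def innovation_pmf(params: ZIGParams, j) -> np.ndarray | float:
    """Pmf of the innovation eps_t (three-component mixture)."""
    jj = _check_support(j)
    (w0, w1, w2), scale2 = innovation_mixture(params)
    out = w1 * _geom_pmf(jj, params.theta) + w2 * _geom_pmf(jj, scale2)
    out = np.where(jj == 0, out + w0, out)
    return out if np.ndim(j) else float(out)


def transition_pmf(params: ZIGParams, j: int, i: int) -> float:
    """One-step transition probability P(X_t = j | X_{t-1} = i)."""
    j = int(_check_support(j))
    i = int(_check_support(i))
    row = _transition_row(params, i, j)
    return float(row[j])


def _transition_row(params: ZIGParams, i: int, jmax: int) -> np.ndarray:
    """P(X_t = j | X_{t-1} = i) for j = 0..jmax as a vector.

    The convolution term Binomial(i, alpha) * eps is computed with an exact
    convolution of pmf vectors; scipy's binomial pmf works in log space
    internally, so large i poses no overflow problem.
    """
    eps = innovation_pmf(params, np.arange(jmax + i + 1))
    if i == 0:
        return eps[: jmax + 1]
    binom = stats.binom.pmf(np.arange(i + 1), i, params.alpha)
    conv = np.convolve(binom, eps)[: jmax + 1]
    return params.beta * eps[: jmax + 1] + (1.0 - params.beta) * conv


def transition_matrix(params: ZIGParams, nmax: int) -> np.ndarray:
    """Dense matrix T[i, j] = P(X_t = j | X_{t-1} = i), i, j in 0..nmax.

    Rows are sub-stochastic (mass beyond nmax is truncated).
    """
    T = np.empty((nmax + 1, nmax + 1))
    for i in range(nmax + 1):
        T[i] = _transition_row(params, i, nmax)
    return T


def process_moments(params: ZIGParams) -> ProcessMoments:
    """Closed-form stationary moments.

    mean = (1-p) theta, variance = (1-p) theta [(1+p) theta + 1],
    lag-1 autocorrelation = alpha (1-beta).
    """
    mu = (1.0 - params.p) * params.theta
    var = mu * ((1.0 + params.p) * params.theta + 1.0)
    return ProcessMoments(mean=mu, variance=var, acf1=params.alpha * (1.0 - params.beta))


def _mixture_table(params: ZIGParams) -> tuple[np.ndarray, np.ndarray]:
    """(weights, geometric success probs) for inverse-CDF innovation sampling."""
    weights, scale2 = innovation_mixture(params)
    succ = np.array([1.0, 1.0 / (1.0 + params.theta), 1.0 / (1.0 + scale2)])
    return weights, succ


def sample_innovations(params: ZIGParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n innovations by component choice followed by a geometric draw."""
    weights, succ = _mixture_table(params)
    comp = rng.choice(3, size=n, p=weights)
    out = np.zeros(n, dtype=np.int64)
    for c in (1, 2):
        m = comp == c
        if m.any():
            # numpy's geometric counts trials >= 1; the mixture uses failures
            out[m] = rng.geometric(succ[c], size=int(m.sum())) - 1
    return out


def sample_marginal(params: ZIGParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n variates from the stationary ZIG(p, theta) marginal."""
    zero = rng.random(n) < params.p
    geo = rng.geometric(1.0 / (1.0 + params.theta), size=n) - 1
    return np.where(zero, 0, geo).astype(np.int64)


def simulate_path(
    params: ZIGParams,
    n: int,
    x0: int | str = "stationary",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate n observations of the process.

    ``x0`` is either a nonnegative integer starting value or ``"stationary"``
    (the default), in which case X_0 is drawn from the ZIG marginal.  The same
    seed always yields the same path.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if x0 == "stationary":
        x = int(sample_marginal(params, 1, rng)[0])
    else:
        x = int(_check_support(x0))
    eps = sample_innovations(params, n, rng)
    survives = rng.random(n) >= params.beta  # a_t = alpha with prob 1-beta
    out = np.empty(n, dtype=np.int64)
    for t in range(n):
        thinned = rng.binomial(x, params.alpha) if (survives[t] and x > 0) else 0
        x = thinned + int(eps[t])
        out[t] = x
    return out
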