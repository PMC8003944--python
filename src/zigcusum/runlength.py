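"""Exact run-length analysis of CUSUM and Shewhart charts for the process.

The pair (X_t, C_t) — the count and the upper CUSUM statistic
C_t = max(0, X_t - k + C_{t-1}) — is a bivariate Markov chain.  Before the
chart signals (C_t > h) the chain lives on the finite control region

    CR = {(n, i) : i in 0..h, n in max(0, i+k-h) .. i+k},

so the run-length distribution is that of the absorption time of a finite
sub-stochastic chain and the standard Markov-chain (Brook–Evans) machinery
applies: with Q the within-CR transition matrix, the first and second
factorial moments of the run length solve

    (I - Q) u1 = 1        and        (I - Q) u2 = 2 Q u1,

and ARL / SDRL follow by weighting with the distribution of (X_1, C_1).

The primary ``arl`` / ``sdrl`` weight the moment vectors by the distribution
of (X_1, C_1) over CR only, which is the classical form of the result.  The
event that the very first observation already signals ((X_1, C_1) outside
CR) has probability ``escape_mass`` — negligible when c0 = 0 but up to a few
percent for large c0 — and variants that count that event as a run of length
1 are exposed as ``arl_with_escape`` / ``sdrl_with_escape``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix, identity
from scipy.sparse.linalg import spsolve

from .model import ZIGParams, marginal_pmf, transition_matrix

__all__ = [
    "ChartDesign",
    "ShewhartDesign",
    "MarkovChartModel",
    "RunLengthSummary",
    "cusum_update",
    "build_chart_model",
    "arl_sdrl",
    "cusum_arl_sdrl",
    "shewhart_arl",
    "simulate_run_length",
]


@dataclass(frozen=True)
class ChartDesign:
    """Upper CUSUM chart configuration: limit h, reference value k, start c0."""

    h: int
    k: int
    c0: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"reference value k must be >= 1, got {self.k}")
        if self.h < 1:
            raise ValueError(f"control limit h must be >= 1, got {self.h}")
        if not 0 <= self.c0 < self.h:
            raise ValueError(f"initial value c0 must satisfy 0 <= c0 < h, got {self.c0}")


@dataclass(frozen=True)
class ShewhartDesign:
    """Shewhart chart: signal when the raw count exceeds ucl."""

    ucl: int

    def __post_init__(self) -> None:
        if self.ucl < 0:
            raise ValueError(f"ucl must be >= 0, got {self.ucl}")


def cusum_update(c_prev: int, x: int, k: int) -> int:
    """One step of the CUSUM recursion, C_t = max(0, X_t - k + C_{t-1})."""
    return max(0, x - k + c_prev)


@dataclass(frozen=True)
class MarkovChartModel:
    """Finite-chain representation of the chart on its control region.

    ``states`` lists (n, i) pairs — count value and CUSUM value — in a fixed
    canonical order (i ascending, then n ascending).  ``Q[s, s']`` is the
    in-control probability of moving from state s to state s' without
    signalling; row deficiencies 1 - sum(Q[s]) are one-step signal
    probabilities.  ``init`` is the distribution of (X_1, C_1) over CR and
    ``escape_mass`` the probability that (X_1, C_1) already signals.
    """

    states: tuple[tuple[int, int], ...]
    Q: csr_matrix
    init: np.ndarray
    escape_mass: float
    design: ChartDesign = field(compare=False)


def control_region(design: ChartDesign) -> list[tuple[int, int]]:
    """Enumerate CR as (count n, cusum i) pairs, i ascending then n ascending.

    A pair (n, i) is reachable when some previous CUSUM value c in 0..h
    satisfies i = max(0, n - k + c): for i >= 1 that pins n to
    i + k - h .. i + k, while the floor state i = 0 accepts every n <= k
    (for h >= k the lower bound is vacuous and both cases reduce to the
    usual max(0, i + k - h) .. i + k band).
    """
    h, k = design.h, design.k
    out = [(n, 0) for n in range(min(k, h + k) + 1)]
    out += [(n, i) for i in range(1, h + 1) for n in range(max(0, i + k - h), i + k + 1)]
    return out


def build_chart_model(params: ZIGParams, design: ChartDesign) -> MarkovChartModel:
    """Assemble the sub-stochastic transition matrix and initial distribution.

    From state (m, i) the next pair is (n, max(0, n - k + i)) with probability
    P(X_t = n | X_{t-1} = m); it stays inside CR exactly when n <= h + k - i.
    The initial pair from C_0 = c0 is (n, max(0, n - k + c0)) with the
    stationary marginal probability of n.
    """
    h, k, c0 = design.h, design.k, design.c0
    states = control_region(design)
    index = {s: r for r, s in enumerate(states)}
    nmax = h + k  # largest count reachable inside CR

    T = transition_matrix(params, nmax)

    rows, cols, vals = [], [], []
    for (m, i) in states:
        r = index[(m, i)]
        ncap = h + k - i
        for n in range(ncap + 1):
            j = max(0, n - k + i)
            rows.append(r)
            cols.append(index[(n, j)])
            vals.append(T[m, n])
    Q = csr_matrix((vals, (rows, cols)), shape=(len(states), len(states)))

    init = np.zeros(len(states))
    pmarg = marginal_pmf(params, np.arange(nmax + 1))
    ncap0 = h + k - c0
    for n in range(ncap0 + 1):
        init[index[(n, max(0, n - k + c0))]] = pmarg[n]
    escape = float(max(0.0, 1.0 - init.sum()))
    return MarkovChartModel(
        states=tuple(states), Q=Q, init=init, escape_mass=escape, design=design
    )


@dataclass(frozen=True)
class RunLengthSummary:
    """ARL, SDRL and the factorial-moment vectors behind them.

    ``arl``/``sdrl`` use the classical control-region sums; the
    ``*_with_escape`` variants additionally count the immediate-signal event
    as a run of length 1 (weight ``escape_mass``).  With c0 = 0 the two
    conventions agree to well beyond two decimals.
    """

    arl: float
    sdrl: float
    u1: np.ndarray
    u2: np.ndarray
    escape_mass: float
    arl_with_escape: float
    sdrl_with_escape: float


def arl_sdrl(model: MarkovChartModel) -> RunLengthSummary:
    """Solve the factorial-moment systems and combine with the start law."""
    n = model.Q.shape[0]
    A = (identity(n, format="csr") - model.Q).tocsc()
    ones = np.ones(n)
    u1 = spsolve(A, ones)
    if not np.all(np.isfinite(u1)):
        raise np.linalg.LinAlgError("I - Q is singular: degenerate chart")
    u2 = spsolve(A, 2.0 * (model.Q @ u1))

    w, esc = model.init, model.escape_mass
    arl = float(w @ u1)
    m2 = float(w @ (u2 + u1))
    sdrl = float(np.sqrt(max(0.0, m2 - arl**2)))
    arl_esc = arl + esc * 1.0  # an immediate signal is a run of length 1
    m2_esc = m2 + esc * 1.0  # r(r-1) + r = 1 at r = 1
    sdrl_esc = float(np.sqrt(max(0.0, m2_esc - arl_esc**2)))
    return RunLengthSummary(
        arl=arl,
        sdrl=sdrl,
        u1=u1,
        u2=u2,
        escape_mass=esc,
        arl_with_escape=arl_esc,
        sdrl_with_escape=sdrl_esc,
    )


def cusum_arl_sdrl(params: ZIGParams, design: ChartDesign) -> RunLengthSummary:
    """Convenience wrapper: build the chain and solve in one call."""
    return arl_sdrl(build_chart_model(params, design))


def shewhart_arl(params: ZIGParams, design: ShewhartDesign) -> float:
    """Exact in-control ARL of the Shewhart chart via the univariate chain.

    In-control states are the counts 0..ucl; the chart signals as soon as the
    count exceeds ucl, so the restriction of the transition kernel to those
    states is sub-stochastic and (I - Q) u = 1 gives conditional expected run
    lengths, combined with the stationary marginal of X_1 (an immediate
    exceedance is a run of length 1).
    """
    ucl = design.ucl
    T = transition_matrix(params, ucl)
    A = np.eye(ucl + 1) - T
    u = np.linalg.solve(A, np.ones(ucl + 1))
    pmarg = marginal_pmf(params, np.arange(ucl + 1))
    return float(pmarg @ u + (1.0 - pmarg.sum()) * 1.0)


def simulate_run_length(
    params: ZIGParams,
    design: ChartDesign | ShewhartDesign,
    reps: int,
    seed: int | np.random.Generator | None = None,
    max_steps: int = 10_000_000,
) -> np.ndarray:
    """Monte-Carlo run lengths, the independent check on the exact solves.

    Each replicate starts the process from the stationary marginal (and the
    CUSUM from c0), steps until the first signal, and records that time.
    All replicates are advanced in lock-step with vectorized draws.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    from .model import sample_innovations, sample_marginal

    is_cusum = isinstance(design, ChartDesign)
    # X_0 from the stationary marginal; C_0 = c0 (CUSUM) / no statistic (Shewhart)
    x = sample_marginal(params, reps, rng)
    c = np.full(reps, design.c0 if is_cusum else 0, dtype=np.int64)
    rl = np.zeros(reps, dtype=np.int64)
    alive = np.arange(reps)
    t = 0
    while alive.size and t < max_steps:
        t += 1
        n_alive = alive.size
        eps = sample_innovations(params, n_alive, rng)
        thin = rng.binomial(x[alive], params.alpha)
        thin[rng.random(n_alive) < params.beta] = 0
        x_new = thin + eps
        x[alive] = x_new
        if is_cusum:
            c_new = np.maximum(0, x_new - design.k + c[alive])
            c[alive] = c_new
            signal = c_new > design.h
        else:
            signal = x_new > design.ucl
        done = alive[signal]
        rl[done] = t
        alive = alive[~signal]
    if alive.size:
        raise RuntimeError(f"{alive.size} replicates did not signal within {max_steps} steps")
    return rl
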