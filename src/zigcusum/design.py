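"""Chart design search and out-of-control shift parameterizations.

The design convention for an upper CUSUM on this process is: take the
reference value k as the smallest integer no less than the in-control mean,
then pick the integer decision limit h whose in-control ARL is closest to a
target (370 by convention).  Out-of-control conditions are parameterized as

* mean shifts — the mean moves to mu1 = mu0 + delta * sigma0, carried either
  by theta alone (``mean_theta``) or by p alone (``mean_p``);
* correlation shifts — alpha or beta moves additively while everything else
  stays fixed (``corr_alpha``, ``corr_beta``); the lag-1 autocorrelation is
  alpha * (1 - beta), so increasing alpha or decreasing beta raises it.

Shifted parameter sets are re-validated, so a shift that leaves the valid
region (or breaks the stationarity constraint) raises rather than silently
producing a non-process.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .model import ZIGParams, process_moments
from .runlength import ChartDesign, cusum_arl_sdrl

__all__ = [
    "ShiftSpec",
    "recommend_k",
    "find_h",
    "apply_shift",
    "dev_percent",
    "arl_profile",
]

ShiftKind = Literal["mean_theta", "mean_p", "corr_alpha", "corr_beta"]


@dataclass(frozen=True)
class ShiftSpec:
    """An out-of-control condition.

    kind : which parameter carries the shift.
    delta : for mean shifts, the shift of the mean in units of the in-control
        standard deviation; for correlation shifts, the additive change of
        alpha (``corr_alpha``) or beta (``corr_beta``).
    """

    kind: ShiftKind
    delta: float

    def __post_init__(self) -> None:
        if self.kind not in ("mean_theta", "mean_p", "corr_alpha", "corr_beta"):
            raise ValueError(f"unknown shift kind {self.kind!r}")


def recommend_k(params: ZIGParams) -> int:
    """Reference value k = ceil(mu0), the smallest integer >= the mean."""
    return max(1, math.ceil(process_moments(params).mean))


def apply_shift(params: ZIGParams, shift: ShiftSpec) -> ZIGParams:
    """Return the out-of-control parameter set for a shift specification."""
    if shift.delta == 0:
        return params
    mom = process_moments(params)
    if shift.kind == "mean_theta":
        mu1 = mom.mean + shift.delta * math.sqrt(mom.variance)
        return params.replace(theta=mu1 / (1.0 - params.p))
    if shift.kind == "mean_p":
        mu1 = mom.mean + shift.delta * math.sqrt(mom.variance)
        return params.replace(p=1.0 - mu1 / params.theta)
    if shift.kind == "corr_alpha":
        return params.replace(alpha=params.alpha + shift.delta)
    return params.replace(beta=params.beta + shift.delta)


def dev_percent(arl: float, arl0: float) -> float:
    """Relative ARL change under a shift, 100 * (ARL - ARL0) / ARL0."""
    if arl0 <= 0:
        raise ValueError("arl0 must be positive")
    return 100.0 * (arl - arl0) / arl0


def find_h(
    params: ZIGParams,
    k: int,
    target_arl0: float = 370.0,
    c0: int = 0,
) -> tuple[int, float]:
    """Integer decision limit h whose in-control ARL is closest to the target.

    ARL0 is strictly increasing in h, so an exponential bracket followed by
    bisection on integers finds the crossing; of the two integers straddling
    the target the one with the smaller |ARL0 - target| wins, ties going to
    the smaller h.  If even h = 1 overshoots the target, (1, ARL0(1)) is
    returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cache: dict[int, float] = {}

    def arl0(h: int) -> float:
        if h not in cache:
            cache[h] = cusum_arl_sdrl(params, ChartDesign(h, k, c0)).arl
        return cache[h]

    lo = max(1, c0 + 1)
    if arl0(lo) >= target_arl0:
        if arl0(lo) > target_arl0:
            warnings.warn(
                f"target ARL0={target_arl0} unreachable: ARL0(h={lo})={arl0(lo):.2f}",
                stacklevel=2,
            )
        return lo, arl0(lo)
    hi = lo
    while arl0(hi) < target_arl0:
        hi = max(hi + 1, 2 * hi)
    while hi - lo > 1:  # arl0(lo) < target <= arl0(hi)
        mid = (lo + hi) // 2
        if arl0(mid) < target_arl0:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi), key=lambda h: (abs(arl0(h) - target_arl0), h))
    return best, arl0(best)


def arl_profile(
    params: ZIGParams,
    design: ChartDesign,
    shifts: Iterable[ShiftSpec],
) -> pd.DataFrame:
    """ARL and dev(%) for a grid of shifts, one row per shift.

    The baseline ARL0 is recomputed from (params, design); a null shift
    (delta = 0) therefore reproduces it exactly and has dev(%) = 0.
    """
    arl0 = cusum_arl_sdrl(params, design).arl
    rows = []
    for shift in shifts:
        shifted = apply_shift(params, shift)
        arl = cusum_arl_sdrl(shifted, design).arl
        rows.append(
            {
                "kind": shift.kind,
                "delta": shift.delta,
                "theta": shifted.theta,
                "p": shifted.p,
                "alpha": shifted.alpha,
                "beta": shifted.beta,
                "h": design.h,
                "k": design.k,
                "arl": arl,
                "dev_percent": dev_percent(arl, arl0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kind", "delta", "theta", "p", "alpha", "beta", "h", "k", "arl", "dev_percent",
        ],
    )
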