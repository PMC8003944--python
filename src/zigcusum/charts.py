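"""Applying CUSUM and Shewhart charts to observed count series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ZIGParams
from .runlength import ChartDesign, ShewhartDesign, cusum_update
from .series import as_counts

__all__ = ["ChartRunResult", "apply_cusum", "apply_shewhart"]


@dataclass(frozen=True)
class ChartRunResult:
    """Plotted statistics and signal times of a chart run.

    ``statistics`` holds the CUSUM values C_t (or the raw counts for a
    Shewhart chart), one per observation; ``signal_times`` are 1-based time
    indices at which the chart is out of control.
    """

    statistics: np.ndarray
    signal_times: tuple[int, ...]
    design: ChartDesign | ShewhartDesign
    params: ZIGParams | None = field(default=None, compare=False)

    @property
    def first_signal(self) -> int | None:
        return self.signal_times[0] if self.signal_times else None


def apply_cusum(
    series,
    design: ChartDesign,
    reset_on_signal: bool = False,
    params: ZIGParams | None = None,
) -> ChartRunResult:
    """Run the CUSUM recursion over a series and collect all signal times.

    Monitoring continues after a signal; by default the statistic is not
    reset, so sustained shifts produce runs of consecutive alarms.  With
    ``reset_on_signal`` the statistic restarts from c0 after each alarm.
    """
    x = as_counts(series)
    if x.size == 0:
        raise ValueError("series must be nonempty")
    stats = np.empty(x.size, dtype=np.int64)
    signals = []
    c = design.c0
    for t, xt in enumerate(x):
        c = cusum_update(c, int(xt), design.k)
        stats[t] = c
        if c > design.h:
            signals.append(t + 1)
            if reset_on_signal:
                c = design.c0
    return ChartRunResult(stats, tuple(signals), design, params)


def apply_shewhart(
    series, design: ShewhartDesign, params: ZIGParams | None = None
) -> ChartRunResult:
    """Signal at every observation exceeding the upper control limit."""
    x = as_counts(series)
    if x.size == 0:
        raise ValueError("series must be nonempty")
    signals = tuple(int(t + 1) for t in np.nonzero(x > design.ucl)[0])
    return ChartRunResult(x.copy(), signals, design, params)
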