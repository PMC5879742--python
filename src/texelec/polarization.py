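"""Electrode polarization statistics.

A pair of electrodes at rest on the skin develops a slowly drifting DC
potential (the half-cell/polarization offset).  Two summaries characterize
it: the mean polarization level (mean absolute DC potential, millivolt) and
the standard average exchange ratio — the mean absolute difference between
consecutive samples,

    Xbar_i = sum_t |X_i(t) - X_i(t+1)| / (N - 1)

reported in microvolt per sampling interval (0.1 s at the protocol's 10
samples/s).  Per-series ratios are averaged unweighted across individuals,
``Xbar = sum_i Xbar_i / n``.  Outliers within a series are removed by the
Tukey interquartile-range rule before aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolarizationSeries",
    "exchange_ratio",
    "group_exchange_ratio",
    "iqr_filter",
    "mean_polarization",
]


@dataclass
class PolarizationSeries:
    """DC potential samples (millivolt) for one electrode pair."""

    samples: np.ndarray  # millivolt
    fs: float = 10.0  # hertz; 10 samples/s per protocol
    subject: str = ""
    material: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a polarization series needs at least 2 samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be > 0")

    @property
    def interval_s(self) -> float:
        return 1.0 / self.fs


def exchange_ratio(series: PolarizationSeries) -> float:
    """Standard average exchange ratio in microvolt per sampling interval.

    Mean absolute first difference of the series; for i.i.d. Gaussian noise
    of standard deviation sigma the expectation is ``2 sigma / sqrt(pi)``
    (the mean absolute value of a zero-mean normal with variance
    ``2 sigma**2``), which makes the statistic a drift-robust variability
    measure.
    """
    x = series.samples
    return float(np.mean(np.abs(np.diff(x))) * 1000.0)  # mV -> uV


def group_exchange_ratio(series_list) -> float:
    """Unweighted mean of per-series exchange ratios (microvolt)."""
    ratios = [
        s if np.isscalar(s) else exchange_ratio(s) for s in series_list
    ]
    if len(ratios) == 0:
        raise ValueError("need at least one series")
    return float(np.mean(ratios))


def iqr_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Tukey interquartile-range outlier rule.

    Values outside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` (quartiles by linear
    interpolation) are flagged.  The fences are re-evaluated on the retained
    values until no further point falls outside them, so the filter is
    idempotent: running it on its own output removes nothing.  A single pass
    suffices for most data; the iteration only matters when removing a gross
    outlier shrinks the quartile range enough to expose another.

    Returns ``(retained, outlier_mask)`` where the mask is True for removed
    values (indexed against the input).  Fewer than 4 values pass through
    unfiltered with a warning, since quartiles are meaningless there.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn(
            "fewer than 4 values: IQR filtering skipped", stacklevel=2
        )
        return values, np.zeros(values.shape, dtype=bool)
    mask = np.zeros(values.shape, dtype=bool)
    while True:
        kept = values[~mask]
        if kept.size < 4:
            break
        q1, q3 = np.percentile(kept, [25.0, 75.0], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        new = ~mask & ((values < lo) | (values > hi))
        if not new.any():
            break
        mask |= new
    return values[~mask], mask


def mean_polarization(series: PolarizationSeries, outlier_removal: bool = False) -> float:
    """Mean polarization level: mean absolute DC potential in millivolt.

    With ``outlier_removal`` the sample values are first screened by
    :func:`iqr_filter`, discarding transient excursions (e.g. motion steps)
    before averaging.
    """
    x = series.samples
    if outlier_removal:
        x, mask = iqr_filter(x)
        if x.size == 0:
            raise ValueError("all samples removed as outliers")
    return float(np.mean(np.abs(x)))
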