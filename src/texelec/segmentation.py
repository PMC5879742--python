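"""QRS detection, PQRST delineation and the segmentation error rate.

The fidelity of an electrode is judged by how many *complete* heartbeats —
all five P, Q, R, S, T fiducials — can be extracted from its channel,
relative to a simultaneously recorded reference electrode:

    error_rate = 100 * (1 - N_complete_test / N_complete_ref)  [% , clipped]

QRS detection follows the Pan-Tompkins recipe: bandpass 5-15 Hz,
differentiation, squaring, moving-window integration, adaptive dual
thresholds with search-back, and a 200 ms refractory period.  Delineation
then places Q and S as the nearest opposite-polarity extrema within 80 ms of
R, and P and T as smoothed peaks in physiological windows ([-300, -50] ms
before Q and [+80, +450] ms after S) subject to an amplitude floor of 5% of
the beat's R amplitude.  Beats whose windows run off the record edges are
marked incomplete rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "BeatAnnotation",
    "detect_qrs",
    "delineate",
    "error_rate",
    "longterm_table",
]


@dataclass
class BeatAnnotation:
    """Fiducial sample indices for one beat; missing waves are None."""

    p: int | None = None
    q: int | None = None
    r: int | None = None
    s: int | None = None
    t: int | None = None

    def __post_init__(self) -> None:
        present = [v for v in (self.p, self.q, self.r, self.s, self.t) if v is not None]
        if any(np.diff(present) <= 0):
            raise ValueError("fiducials must be strictly ordered P < Q < R < S < T")

    @property
    def complete(self) -> bool:
        return None not in (self.p, self.q, self.r, self.s, self.t)

    def to_dict(self) -> dict:
        return {"P": self.p, "Q": self.q, "R": self.r, "S": self.s, "T": self.t}


# --------------------------------------------------------------------- QRS


def detect_qrs(x: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins QRS detector; returns R-peak sample indices.

    Stages: 5-15 Hz bandpass (zero-phase Butterworth), five-point
    derivative, squaring, 150 ms moving-window integration, then adaptive
    signal/noise threshold tracking with a 200 ms refractory period and a
    search-back pass at half threshold when an expected beat is missed.
    R-peak locations are refined to the absolute maximum of |bandpassed
    signal| within 75 ms of each integrator peak.
    """
    x = np.asarray(x, dtype=float)
    if fs < 200:
        raise ValueError("fs must be >= 200 Hz")
    if x.size < 5 * fs:
        raise ValueError("record must be at least 5 s long")
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)

    deriv = np.gradient(bp) * fs
    squared = deriv**2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    peaks, _ = sps.find_peaks(mwi, distance=refractory)
    if peaks.size == 0:
        return np.array([], dtype=int)

    # adaptive dual thresholds (Pan-Tompkins running estimates)
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5 if mwi[: int(2 * fs)].size else 0.0
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5 if mwi[: int(2 * fs)].size else 0.0
    qrs: list[int] = []
    rr_history: list[float] = []
    last_qrs = -np.inf

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for pk in peaks:
        val = mwi[pk]
        if val > threshold() and pk - last_qrs > refractory:
            qrs.append(int(pk))
            if last_qrs > 0:
                rr_history.append(pk - last_qrs)
                if len(rr_history) > 8:
                    rr_history.pop(0)
            last_qrs = pk
            spki = 0.125 * val + 0.875 * spki
        else:
            npki = 0.125 * val + 0.875 * npki
        # search-back: if a beat seems missed, accept the best peak above
        # half threshold in the gap
        if rr_history and pk - last_qrs > 1.66 * np.mean(rr_history):
            gap = peaks[(peaks > last_qrs + refractory) & (peaks < pk)]
            if gap.size:
                best = gap[np.argmax(mwi[gap])]
                if mwi[best] > 0.5 * threshold():
                    qrs.append(int(best))
                    spki = 0.25 * mwi[best] + 0.75 * spki
                    last_qrs = best
                    qrs.sort()

    # refine to the extremum of the bandpassed signal near each MWI peak
    half = int(round(0.075 * fs))
    refined = []
    for pk in qrs:
        lo, hi = max(0, pk - half), min(x.size, pk + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    # enforce refractory after refinement
    out: list[int] = []
    for r in refined:
        if out and r - out[-1] <= refractory:
            if np.abs(bp[r]) > np.abs(bp[out[-1]]):
                out[-1] = int(r)
        else:
            out.append(int(r))
    return np.asarray(out, dtype=int)


# --------------------------------------------------------------- delineation


def _nearest_extremum(x: np.ndarray, center: int, lo: int, hi: int, mode: str):
    """Index of the min/max of x[lo:hi], or None if the window is empty."""
    lo, hi = max(0, lo), min(x.size, hi)
    if hi - lo < 3:
        return None
    seg = x[lo:hi]
    idx = int(np.argmin(seg)) if mode == "min" else int(np.argmax(seg))
    return lo + idx


def _smooth(x: np.ndarray, fs: float, cutoff: float = 12.0) -> np.ndarray:
    sos = sps.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def delineate(
    x: np.ndarray,
    fs: float,
    r_peaks: np.ndarray,
    amplitude_floor_frac: float = 0.05,
) -> list[BeatAnnotation]:
    """Locate P, Q, S, T around each detected R peak.

    Q and S are the minima within 80 ms before/after R.  P and T are the
    largest peaks of a 12 Hz-smoothed copy of the signal inside
    physiological windows ([-300, -50] ms before Q; [+80, +450] ms after S),
    measured against the beat's local baseline, and must exceed
    ``amplitude_floor_frac`` of the beat's R amplitude to count — otherwise
    the wave is declared absent and the beat incomplete.  Windows truncated
    by the record edges likewise yield incomplete beats.
    """
    x = np.asarray(x, dtype=float)
    if len(r_peaks) == 0:
        raise ValueError("need at least one R peak to delineate")
    smooth = _smooth(x, fs)
    w80 = int(round(0.080 * fs))
    anns: list[BeatAnnotation] = []
    for r in np.asarray(r_peaks, dtype=int):
        q = _nearest_extremum(x, r, r - w80, r, "min")
        s = _nearest_extremum(x, r, r + 1, r + w80 + 1, "min")
        p = t = None
        if q is not None and s is not None and q < r < s:
            # local baseline: median of the smoothed beat neighbourhood
            lo_b = max(0, r - int(0.35 * fs))
            hi_b = min(x.size, r + int(0.50 * fs))
            baseline = float(np.median(smooth[lo_b:hi_b]))
            floor = amplitude_floor_frac * abs(x[r] - baseline)

            p_lo, p_hi = q - int(0.300 * fs), q - int(0.050 * fs)
            if p_lo >= 0:
                cand = _nearest_extremum(smooth, q, p_lo, p_hi, "max")
                if cand is not None and smooth[cand] - baseline >= floor:
                    p = cand
            t_lo, t_hi = s + int(0.080 * fs), s + int(0.450 * fs)
            if t_hi <= x.size:
                cand = _nearest_extremum(smooth, s, t_lo, t_hi, "max")
                if cand is not None and smooth[cand] - baseline >= floor:
                    t = cand
        try:
            anns.append(BeatAnnotation(p=p, q=q, r=int(r), s=s, t=t))
        except ValueError:
            # ordering violated by a degenerate beat: keep R only
            anns.append(BeatAnnotation(r=int(r)))
    return anns


# ---------------------------------------------------------------- error rate


def count_complete(x: np.ndarray, fs: float) -> int:
    """Number of complete PQRST segments detected in one channel."""
    r = detect_qrs(x, fs)
    if r.size == 0:
        return 0
    return sum(a.complete for a in delineate(x, fs, r))


def error_rate(test: np.ndarray, ref: np.ndarray, fs: float) -> float:
    """Segmentation error rate between simultaneous channels, percent.

    ``100 * (1 - N_complete_test / N_complete_ref)`` clipped to [0, 100].

    Raises
    ------
    ValueError
        If the reference channel yields no complete segments (the ratio is
        undefined).
    """
    n_ref = count_complete(np.asarray(ref, dtype=float), fs)
    if n_ref == 0:
        raise ValueError("reference channel has no complete PQRST segments")
    n_test = count_complete(np.asarray(test, dtype=float), fs)
    return float(np.clip(100.0 * (1.0 - n_test / n_ref), 0.0, 100.0))


@dataclass
class LongTermSummary:
    """Per-timepoint distribution of segmentation error rates."""

    table: pd.DataFrame  # hours, n, median_error, q1, q3
    errors: dict = field(default_factory=dict)  # hours -> list of error rates


def longterm_table(recordings) -> LongTermSummary:
    """Tabulate error rates over a wear-time schedule.

    Parameters
    ----------
    recordings : iterable of (hours, ECGRecording)
        Repeated two-channel recordings taken at increasing wear times.

    Returns
    -------
    LongTermSummary
        With a frame of per-timepoint count, median and quartiles (the data
        behind a box plot of error versus hours).
    """
    groups: dict[float, list[float]] = {}
    for hours, rec in recordings:
        err = error_rate(rec.test_channel, rec.ref_channel, rec.fs)
        groups.setdefault(float(hours), []).append(err)
    if not groups:
        raise ValueError("need at least one timepoint")
    rows = []
    for hours in sorted(groups):
        vals = np.asarray(groups[hours])
        q1, med, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
        rows.append(
            {"hours": hours, "n": vals.size, "median_error": med, "q1": q1, "q3": q3}
        )
    return LongTermSummary(table=pd.DataFrame(rows), errors=groups)
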