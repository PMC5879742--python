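"""Phasor extraction from sampled waveforms.

Impedance sweeps record voltages as time series; the circuit algebra works on
phasors (magnitude and phase at a single frequency).  This module provides the
bridge: DC-offset removal, peak-based amplitude estimation, and two
independent phase estimators — the Lissajous y-intercept method and the
cross-correlation lag method — plus quadrant disambiguation when the two are
combined.

Phase conventions
-----------------
A waveform ``y(t) = Y0 sin(w t + theta)`` *leads* the reference
``x(t) = X0 sin(w t)`` by ``theta`` degrees; positive angles mean ``y``
reaches its features earlier in time.  All phases are reported in degrees in
``(-180, 180]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "Phasor",
    "remove_dc",
    "amplitude_peaks",
    "phase_lissajous",
    "phase_xcorr",
    "waveform_to_phasor",
]


@dataclass(frozen=True)
class Phasor:
    """Magnitude and phase of a sinusoidal quantity at one frequency.

    Parameters
    ----------
    magnitude : float
        Non-negative amplitude (volt or ohm depending on context).
    phase_deg : float
        Phase in degrees, normalized to ``(-180, 180]``.
    frequency : float
        Frequency in hertz.
    """

    magnitude: float
    phase_deg: float
    frequency: float

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("phasor magnitude must be >= 0")
        object.__setattr__(self, "phase_deg", wrap_phase_deg(self.phase_deg))

    @property
    def complex(self) -> complex:
        return self.magnitude * np.exp(1j * np.deg2rad(self.phase_deg))

    @classmethod
    def from_complex(cls, z: complex, frequency: float) -> "Phasor":
        return cls(abs(z), float(np.rad2deg(np.angle(z))), frequency)


def wrap_phase_deg(phase):
    """Wrap an angle (scalar or array, degrees) to the interval ``(-180, 180]``."""
    wrapped = (np.asarray(phase, dtype=float) + 180.0) % 360.0 - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.ndim(phase) == 0:
        return float(wrapped)
    return wrapped


def dc_blocker_taps(order: int, window: str = "hann") -> np.ndarray:
    """Linear-phase FIR high-pass that subtracts a windowed running mean.

    The kernel is an impulse at the center tap minus a normalized window, so
    the frequency response is exactly zero at DC and within 0.1% of unity
    beyond roughly two window-lengths' worth of frequency resolution.  For a
    2000-tap filter at 1 kHz that places the passband edge near 1 Hz, which
    preserves every sweep frequency down to 0.1 Hz up to a common (and hence
    ratio-cancelling) complex gain.  The Hann window is chosen for its
    1/f^3 sidelobe decay: the passband deviation falls below 1e-6 within a
    few hertz of the edge, so repeated application is idempotent there.
    """
    if order < 2:
        raise ValueError("filter order must be >= 2")
    if order % 2:
        order += 1  # keep the group delay an integer number of samples
    w = sps.get_window(window, order + 1)
    taps = -w / w.sum()
    taps[order // 2] += 1.0
    return taps


def remove_dc(x: np.ndarray, fs: float, order: int = 2000) -> np.ndarray:
    """Remove the DC offset from a waveform with a zero-phase FIR high-pass.

    The filter is applied by 'same'-mode convolution, which for a symmetric
    FIR is equivalent to compensating the ``order/2`` group delay: features of
    the output stay aligned with the input.  Records shorter than the nominal
    order get a reduced order of ``len(x) // 3`` (with a warning) so the
    kernel still fits.

    Parameters
    ----------
    x : array_like
        Input waveform.
    fs : float
        Sampling rate in hertz (recorded for provenance; the kernel is
        defined in samples).
    order : int
        FIR order; the default 2000 mirrors an offline acquisition-rate
        design.

    Raises
    ------
    ValueError
        If the record is too short to support even a reduced-order filter.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("remove_dc expects a 1-D waveform")
    n = x.size
    if n <= order:
        reduced = n // 3
        if reduced < 2:
            raise ValueError(
                f"record of {n} samples is too short for DC-removal filtering"
            )
        warnings.warn(
            f"record shorter than filter order {order}; reducing order to {reduced}",
            stacklevel=2,
        )
        order = reduced
    taps = dc_blocker_taps(order)
    return sps.oaconvolve(x, taps, mode="same")


def _refine_peak(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Parabolic interpolation of peak values at integer indices `idx`."""
    idx = idx[(idx > 0) & (idx < x.size - 1)]
    if idx.size == 0:
        return np.array([])
    y0, y1, y2 = x[idx - 1], x[idx], x[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom != 0.0, 0.5 * (y0 - y2) / denom, 0.0)
    return y1 - 0.25 * (y0 - y2) * delta


def _extrema_values(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Refined values of cycle maxima and minima (prominence-gated)."""
    span = np.ptp(x)
    if span <= 0:
        return np.array([]), np.array([])
    prominence = 0.1 * span
    hi, _ = sps.find_peaks(x, prominence=prominence)
    lo, _ = sps.find_peaks(-x, prominence=prominence)
    return _refine_peak(x, hi), -_refine_peak(-x, lo)


def _oscillation_center(x: np.ndarray) -> float:
    """DC level of an oscillation, robust to partial-cycle records.

    The raw mean of a sinusoid is biased by up to ``A / (pi * n_cycles)``
    when the record holds a non-integer number of cycles; the midpoint
    between the mean cycle maximum and the mean cycle minimum is not.
    Falls back to the raw mean when no extrema are found.
    """
    x = np.asarray(x, dtype=float)
    mu = float(x.mean())
    top, bot = _extrema_values(x - mu)
    if top.size == 0 or bot.size == 0:
        return mu
    return mu + 0.5 * (float(np.mean(top)) + float(np.mean(bot)))


def amplitude_peaks(x: np.ndarray) -> float:
    """Estimate the amplitude of an oscillation from its cycle extrema.

    Cycle maxima and minima are located with a prominence gate at 10% of the
    signal's peak-to-peak span and refined by parabolic interpolation, so the
    estimate is sub-sample accurate even at modest sampling densities.  The
    amplitude is half the distance between the mean maximum and the mean
    minimum, which makes it independent of any DC offset and of records
    holding a non-integer number of cycles.

    Raises
    ------
    ValueError
        If no cycle maximum or no cycle minimum is found (no detectable
        oscillation).
    """
    x = np.asarray(x, dtype=float)
    top, bot = _extrema_values(x - x.mean())
    if top.size == 0 or bot.size == 0:
        raise ValueError("no detectable oscillation in the waveform")
    return float(0.5 * (np.mean(top) - np.mean(bot)))


def _upward_zero_crossings(x: np.ndarray) -> np.ndarray:
    """Sub-sample positions of positive-going zero crossings (linear interp)."""
    s = np.signbit(x)
    idx = np.nonzero(s[:-1] & ~s[1:])[0]
    if idx.size == 0:
        return np.array([])
    frac = -x[idx] / (x[idx + 1] - x[idx])
    return idx + frac


def phase_lissajous(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Phase of ``y`` relative to ``x`` from the Lissajous y-axis intercept.

    Plotting ``y`` against ``x`` traces an ellipse; its intersection ``y0``
    with the y axis (where ``x`` crosses zero going positive) satisfies
    ``y0 = Y0 sin(theta)``, so ``theta = arcsin(y0 / Y0)``.  ``y0`` is read at
    every positive-going zero crossing of ``x`` (linearly interpolated) and
    averaged; ``Y0`` comes from :func:`amplitude_peaks`.

    Returns
    -------
    (theta_deg, clipped) : tuple of float and bool
        Phase in degrees restricted to ``[-90, 90]`` (the arcsin principal
        branch), and a flag set when noise pushed ``|y0|`` beyond ``Y0`` and
        the ratio was clamped.

    Notes
    -----
    The principal branch cannot distinguish ``theta`` from ``180 - theta``;
    see :func:`waveform_to_phasor` for the disambiguated estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("waveforms must have the same length")
    xc = x - _oscillation_center(x)
    yc = y - _oscillation_center(y)
    crossings = _upward_zero_crossings(xc)
    if crossings.size == 0:
        raise ValueError("no zero crossings found in the reference waveform")
    i = crossings.astype(int)
    frac = crossings - i
    y0 = np.mean(yc[i] * (1.0 - frac) + yc[np.minimum(i + 1, yc.size - 1)] * frac)
    big_y = amplitude_peaks(yc)
    ratio = y0 / big_y
    clipped = False
    if abs(ratio) > 1.0:
        warnings.warn("Lissajous intercept exceeds the amplitude; clamping", stacklevel=2)
        ratio = float(np.clip(ratio, -1.0, 1.0))
        clipped = True
    return float(np.rad2deg(np.arcsin(ratio))), clipped


def phase_xcorr(
    x: np.ndarray, y: np.ndarray, f: float, fs: float, refine: bool = True
) -> float:
    """Phase of ``y`` relative to ``x`` from the cross-correlation lag.

    The lag ``l`` maximizing ``r_xy(l) = sum_n x(n) y(n - l)`` converts to a
    phase ``theta = 360 * l * f / fs`` degrees.  The correlation is
    length-normalized (unbiased) so finite records do not bias the peak toward
    zero lag; lags are restricted to one period so the answer is unique, and
    among ties the smallest ``|l|`` wins.  With ``refine=True`` (default) the
    peak is interpolated parabolically between neighbouring lags, giving
    sub-lag resolution; the interpolation is a no-op when the true shift is an
    integer number of samples.  Without refinement the resolution is one lag
    step, i.e. ``360 * f / fs`` degrees — a warning is emitted if that exceeds
    5 degrees, and fewer than 8 samples per cycle is rejected outright.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("waveforms must have the same length")
    if fs / f < 8:
        raise ValueError("fewer than 8 samples per cycle: phase resolution too coarse")
    step = 360.0 * f / fs
    if step > 5.0:
        warnings.warn(
            f"phase resolution {step:.1f} deg per lag exceeds 5 deg", stacklevel=2
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation phase")
    xc = x - _oscillation_center(x)
    yc = y - _oscillation_center(y)
    n = xc.size
    # full cross-correlation; r[k] corresponds to lag l = k - (n - 1) in the
    # convention r(l) = sum_n x(n) y(n - l)
    period = fs / f
    half = int(np.floor(period / 2.0))
    if n <= 2 * (half + 1):
        raise ValueError("record too short to scan one full period of lags")
    # full-overlap correlation: x is trimmed by half a period (plus one sample
    # for peak interpolation) on each side so every lag sums over the same x
    # window -- no triangular edge bias that would pull the peak toward 0
    m = half + 1
    xw = xc[m : n - m]
    c = sps.correlate(yc, xw, mode="valid")  # c[k] = sum_j xw[j] y[j + k]
    lags_all = m - np.arange(c.size)  # r(l) = sum_n x(n) y(n - l)
    keep = np.abs(lags_all) <= half
    r = c[keep]
    lags = lags_all[keep]
    best = r.max()
    candidates = lags[np.isclose(r, best, rtol=1e-12, atol=0.0)]
    lag = int(candidates[np.argmin(np.abs(candidates))])
    frac = 0.0
    if refine:
        k = int(np.nonzero(lags_all == lag)[0][0])
        if 0 < k < c.size - 1:
            # the correlation of two same-frequency sinusoids is a cosine in
            # the lag, so a three-point cosine fit recovers the peak exactly
            yp, y0, ym = c[k - 1], c[k], c[k + 1]  # lags decrease with k
            omega = 2.0 * np.pi * f / fs
            s = (ym - yp) / (2.0 * np.sin(omega))
            if s != 0.0 or y0 != 0.0:
                frac = float(np.clip(-np.arctan2(s, y0) / omega, -0.5, 0.5))
    return wrap_phase_deg(360.0 * (lag + frac) * f / fs)


def waveform_to_phasor(
    x: np.ndarray,
    reference: np.ndarray,
    f: float,
    fs: float,
    method: str = "xcorr",
) -> Phasor:
    """Extract the phasor of ``x`` measured against ``reference``.

    Magnitude comes from :func:`amplitude_peaks`; phase from the chosen
    estimator.  With ``method="lissajous"`` the arcsin-branch ambiguity is
    resolved by the sign of the zero-lag cross-correlation: anti-correlated
    waveforms (|phase| > 90 deg) are mapped from ``theta`` to
    ``+-180 - theta``.

    Parameters
    ----------
    method : {"xcorr", "lissajous"}
    """
    x = np.asarray(x, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mag = amplitude_peaks(x)
    if method == "xcorr":
        phase = phase_xcorr(reference, x, f, fs)
    elif method == "lissajous":
        phase, _ = phase_lissajous(reference, x)
        xc = reference - _oscillation_center(reference)
        yc = x - _oscillation_center(x)
        if np.dot(xc, yc) < 0.0:  # obtuse phase: reflect off the arcsin branch
            phase = 180.0 - phase if phase >= 0 else -180.0 - phase
    else:
        raise ValueError(f"unknown phase method: {method!r}")
    return Phasor(mag, wrap_phase_deg(phase), f)
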