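"""ECG noise quantification: filter bank, noise power and channel similarity.

A recording made simultaneously with a test electrode and a reference
Ag/AgCl electrode should contain the same cardiac signal; what differs is
noise.  Three tools quantify that:

* a fixed FIR filter bank — two Kaiser-window (beta = 0.5) order-150
  bandstops at 60 and 120 Hz (10 Hz total stop width) and one order-150
  Kaiser bandpass 0.05-150 Hz — restricting the record to the cardiac band;
* the noise power, the mean squared difference between the raw and filtered
  signal, ``P = mean(|ECG_original - ECG_filtered|**2)``;
* the Pearson correlation between the two channels, a morphology-similarity
  index.

The filters are modest by design (order 150): the 0.05 Hz high-pass edge in
particular is far below what 151 taps can realize, so the measured frequency
response is exported rather than an idealized one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ECGRecording",
    "FilterBank",
    "design_filter_bank",
    "filter_ecg",
    "noise_power",
    "pearson_similarity",
]


@dataclass
class ECGRecording:
    """Two synchronized ECG channels (millivolt) at a fixed sampling rate."""

    test_channel: np.ndarray
    ref_channel: np.ndarray
    fs: float
    label: str = ""
    annotations: list | None = None  # ground-truth per-beat fiducials, if known
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.test_channel = np.asarray(self.test_channel, dtype=float)
        self.ref_channel = np.asarray(self.ref_channel, dtype=float)
        if self.test_channel.shape != self.ref_channel.shape:
            raise ValueError("channels must have equal length")
        if not self.fs >= 500:
            raise ValueError("sampling rate must be >= 500 Hz to resolve the QRS")

    @property
    def duration(self) -> float:
        return self.test_channel.size / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.test_channel.size) / self.fs


@dataclass
class FilterBank:
    """Designed FIR stages and their measured frequency responses."""

    fs: float
    stages: dict[str, np.ndarray]  # name -> taps

    def response(self, freqs) -> dict[str, np.ndarray]:
        """Complex frequency response of each stage at the given hertz."""
        out = {}
        for name, taps in self.stages.items():
            _, h = sps.freqz(taps, worN=np.atleast_1d(freqs), fs=self.fs)
            out[name] = h
        return out

    def cascade_gain(self, freqs) -> np.ndarray:
        """Magnitude of the full cascade at the given frequencies."""
        g = np.ones(np.atleast_1d(freqs).shape, dtype=complex)
        for h in self.response(freqs).values():
            g = g * h
        return np.abs(g)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Run a waveform through every stage, delay-compensated.

        Each stage is a linear-phase FIR applied with 'same'-mode
        convolution, equivalent to removing the order/2 group delay, so
        fiducial annotations stay aligned with the filtered output.
        """
        y = np.asarray(x, dtype=float)
        for taps in self.stages.values():
            y = sps.oaconvolve(y, taps, mode="same")
        return y

    @property
    def max_order(self) -> int:
        return max(t.size - 1 for t in self.stages.values())


def design_filter_bank(fs: float, order: int = 150, beta: float = 0.5) -> FilterBank:
    """Design the cardiac-band FIR filter bank for a given sampling rate.

    Stages (all Kaiser window, odd tap count ``order + 1``):

    * ``stop60``: bandstop 55-65 Hz;
    * ``stop120``: bandstop 115-125 Hz (omitted with a warning when the
      Nyquist frequency cannot accommodate it);
    * ``bandpass``: 0.05-150 Hz (upper edge clipped below Nyquist when
      needed).

    The full three-stage design needs ``fs > 300`` (Nyquist above the 150 Hz
    passband edge).  Between 150 and 300 Hz a degraded bank is still
    produced: the 120 Hz stopband is dropped with a warning once its 125 Hz
    edge no longer fits below Nyquist with margin, and the bandpass upper
    edge is clipped.  Below ``fs = 150`` even the 60 Hz stopband and a
    useful cardiac passband cannot be placed, so that is a hard error.
    """
    if not fs > 150:
        raise ValueError("sampling rate must exceed 150 Hz")
    numtaps = order + 1 if order % 2 == 0 else order + 2
    window = ("kaiser", beta)
    nyq = fs / 2.0
    stages: dict[str, np.ndarray] = {}
    stages["stop60"] = sps.firwin(
        numtaps, [55.0, 65.0], window=window, pass_zero="bandstop", fs=fs
    )
    if 125.0 < 0.95 * nyq:
        stages["stop120"] = sps.firwin(
            numtaps, [115.0, 125.0], window=window, pass_zero="bandstop", fs=fs
        )
    else:
        warnings.warn(
            "sampling rate too low to place the 120 Hz stopband below "
            "Nyquist: stage omitted",
            stacklevel=2,
        )
    hi_edge = min(150.0, 0.95 * nyq)
    stages["bandpass"] = sps.firwin(
        numtaps, [0.05, hi_edge], window=window, pass_zero="bandpass", fs=fs
    )
    return FilterBank(fs=fs, stages=stages)


def filter_ecg(rec: ECGRecording, bank: FilterBank | None = None) -> ECGRecording:
    """Filter both channels of a recording through the cardiac filter bank.

    The output keeps the input's length, sampling rate and annotations (the
    group delay of each linear-phase stage is compensated).
    """
    if bank is None:
        bank = design_filter_bank(rec.fs)
    if rec.test_channel.size <= 3 * bank.max_order:
        raise ValueError(
            "record shorter than 3x the filter order; too short to filter"
        )
    return ECGRecording(
        test_channel=bank.apply(rec.test_channel),
        ref_channel=bank.apply(rec.ref_channel),
        fs=rec.fs,
        label=rec.label,
        annotations=rec.annotations,
        meta={**rec.meta, "filtered": True},
    )


def noise_power(original: np.ndarray, filtered: np.ndarray) -> float:
    """Mean squared removed component, ``mean(|original - filtered|**2)``.

    Units are the square of the input's (millivolt squared for mV signals).
    """
    original = np.asarray(original, dtype=float)
    filtered = np.asarray(filtered, dtype=float)
    if original.shape != filtered.shape:
        raise ValueError("waveforms must have equal length")
    e = np.abs(original - filtered)
    return float(np.mean(e**2))


def pearson_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation of two DC-removed waveforms."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("waveforms must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0.0:
        raise ValueError("zero-variance input has no defined correlation")
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))
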