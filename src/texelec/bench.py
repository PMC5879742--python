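"""Synthetic measurement bench.

Every downstream stage of the pipeline consumes data this module can
generate: two-configuration impedance sweeps with circuit-exact ground-truth
phasors, sinusoid pairs with a known phase shift, two-channel synthetic ECG
with per-beat PQRST annotations and controllable corruption, and DC
polarization series with drift and step artifacts.  All generators are
bit-reproducible under a fixed seed.

The simulated impedance bench mirrors the physical setup: an AC source
(5 Vpp by default) drives a series loop of electrode contact impedances, the
inter-electrode tissue impedance and a reference resistor.  Configuration A
probes the voltage at the second electrode's node (giving ``Z_sum =
Z_contact + Z_SB12``); configuration B uses the source itself as the probe
(giving ``Z_12 = 2*Z_contact + Z_SB12``).  The three electrode contacts are
assumed identical — the subtraction algebra that isolates a single contact
requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cole import ColeParameters, cole_eval
from .phasors import Phasor
from .polarization import PolarizationSeries
from .quality import ECGRecording

__all__ = [
    "CircuitSpec",
    "ECGSynthSpec",
    "PolarizationSynthSpec",
    "SweepMeasurement",
    "SweepResult",
    "default_frequency_grid",
    "default_fs_rule",
    "simulate_sweep",
    "synth_sinusoid_pair",
    "synth_ecg",
    "synth_polarization",
]


def default_frequency_grid(
    f_min: float = 0.1, f_max: float = 1.0e4, points_per_decade: int = 10
) -> np.ndarray:
    """Log-spaced sweep grid; the default spans 0.1 Hz-10 kHz at 10/decade."""
    n = int(round(np.log10(f_max / f_min) * points_per_decade)) + 1
    return np.logspace(np.log10(f_min), np.log10(f_max), n)


def default_fs_rule(f: float) -> float:
    """Sampling-rate policy: ``fs = clip(50*f, 1 kHz, 1 MHz)``.

    Resolves the phase comfortably at 10 kHz while keeping sub-hertz records
    a tractable length.
    """
    return float(min(1.0e6, max(1.0e3, 50.0 * f)))


# --------------------------------------------------------------------------
# impedance sweeps


@dataclass
class CircuitSpec:
    """Series measurement circuit for the two-configuration sweep.

    Parameters
    ----------
    z_contact_model : ColeParameters or complex
        Contact impedance of each (identical) electrode: a Cole model or a
        frequency-independent complex/real value.
    z_tissue : complex
        Inter-electrode tissue impedance; purely resistive 1 kOhm by default.
    r_ref : float
        Reference resistor in ohm.
    v_source_pp : float
        Source amplitude, volt peak-to-peak (5 Vpp by default).
    frequencies : ndarray
        Strictly increasing sweep frequencies in hertz.
    """

    z_contact_model: ColeParameters | complex
    z_tissue: complex = 1000.0 + 0.0j
    r_ref: float = 1000.0
    v_source_pp: float = 5.0
    frequencies: np.ndarray = field(default_factory=default_frequency_grid)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if not self.r_ref > 0:
            raise ValueError("r_ref must be > 0")
        if not self.v_source_pp > 0:
            raise ValueError("v_source_pp must be > 0")
        if self.frequencies.size == 0:
            raise ValueError("frequency grid is empty")
        if np.any(self.frequencies <= 0) or (
            self.frequencies.size > 1 and np.any(np.diff(self.frequencies) <= 0)
        ):
            raise ValueError("frequencies must be strictly positive and increasing")

    def z_contact(self, f) -> np.ndarray:
        """Contact impedance of one electrode at the given frequencies."""
        f = np.atleast_1d(np.asarray(f, dtype=float))
        if isinstance(self.z_contact_model, ColeParameters):
            return cole_eval(self.z_contact_model, f).z
        return np.full(f.shape, complex(self.z_contact_model))


@dataclass
class SweepMeasurement:
    """Sampled waveforms for one sweep frequency, with circuit-exact truth."""

    frequency: float
    fs: float
    v_r: np.ndarray  # voltage across the reference resistor
    v_probe: np.ndarray  # V_e2 (config A) or the source V_g (config B)
    truth: dict  # ground-truth phasors and impedances


@dataclass
class SweepResult:
    config: str  # "A" or "B"
    r_ref: float
    measurements: list[SweepMeasurement]


def simulate_sweep(
    circuit: CircuitSpec,
    config: str,
    fs_rule=None,
    n_cycles: int = 10,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SweepResult:
    """Simulate one configuration of the impedance sweep.

    For each frequency the series loop is solved exactly in the phasor
    domain (``I = V_g / (R_ref + 2*Z_contact + Z_SB12)``), the probe and
    reference-resistor voltages are sampled over ``n_cycles`` full cycles at
    the policy's sampling rate, and the exact phasors and impedances are
    attached as ground truth:

    * ``truth["z_sum"]``  = ``Z_contact + Z_SB12``
    * ``truth["z_12"]``   = ``2*Z_contact + Z_SB12``
    * ``truth["z_contact"]``, ``truth["v_r"]``, ``truth["v_probe"]``,
      ``truth["i"]``, ``truth["v_g"]``

    Parameters
    ----------
    config : {"A", "B"}
        A probes the electrode-2 node voltage ``V_e2``; B records the source
        ``V_g`` as the probe (``V_21 = V_g - V_r``).
    fs_rule : callable, optional
        Maps frequency to sampling rate; :func:`default_fs_rule` by default.
        A rule yielding fewer than 20 samples per cycle is rejected.
    noise_sd : float
        Additive white Gaussian noise on the sampled waveforms, volt.
    """
    if config not in ("A", "B"):
        raise ValueError("config must be 'A' or 'B'")
    if fs_rule is None:
        fs_rule = default_fs_rule
    rng = np.random.default_rng(seed)
    amp_g = circuit.v_source_pp / 2.0
    v_g = complex(amp_g)  # phase reference

    measurements = []
    for f in circuit.frequencies:
        fs = float(fs_rule(f))
        if fs / f < 20.0:
            raise ValueError(
                f"sampling-rate policy gives {fs / f:.1f} samples/cycle at "
                f"{f:g} Hz; at least 20 are required"
            )
        zc = complex(circuit.z_contact(f)[0])
        zt = complex(circuit.z_tissue)
        z_12 = 2.0 * zc + zt
        z_sum = zc + zt
        i_ph = v_g / (circuit.r_ref + z_12)
        v_r = i_ph * circuit.r_ref
        if config == "A":
            v_probe = v_r + i_ph * z_sum  # potential at the electrode-2 node
        else:
            v_probe = v_g

        n = int(round(n_cycles * fs / f))
        t = np.arange(n) / fs
        w = 2.0 * np.pi * f

        def sample(ph: complex) -> np.ndarray:
            wave = abs(ph) * np.sin(w * t + np.angle(ph))
            if noise_sd > 0:
                wave = wave + rng.normal(0.0, noise_sd, size=n)
            return wave

        measurements.append(
            SweepMeasurement(
                frequency=float(f),
                fs=fs,
                v_r=sample(v_r),
                v_probe=sample(v_probe),
                truth={
                    "v_g": v_g,
                    "i": i_ph,
                    "v_r": Phasor.from_complex(v_r, f),
                    "v_probe": Phasor.from_complex(v_probe, f),
                    "z_sum": z_sum,
                    "z_12": z_12,
                    "z_contact": zc,
                    "z_tissue": zt,
                },
            )
        )
    return SweepResult(config=config, r_ref=circuit.r_ref, measurements=measurements)


def synth_sinusoid_pair(
    f: float,
    fs: float,
    duration: float,
    phase_deg: float,
    amplitudes: tuple[float, float] = (1.0, 1.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference/shifted sinusoid pair ``x = X0 sin(wt)``, ``y = Y0 sin(wt + theta)``."""
    if fs <= 2.0 * f:
        raise ValueError("fs must exceed 2f to avoid aliasing")
    if duration < 3.0 / f:
        raise ValueError("duration must cover at least 3 cycles")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration * fs))) / fs
    w = 2.0 * np.pi * f
    x0, y0 = amplitudes
    x = x0 * np.sin(w * t)
    y = y0 * np.sin(w * t + np.deg2rad(phase_deg))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, t.size)
        y = y + rng.normal(0.0, noise_sd, t.size)
    return x, y


# --------------------------------------------------------------------------
# ECG

# per-wave Gaussian template: center offset from the R peak (s), width (s)
WAVE_OFFSETS_S = {"P": -0.200, "Q": -0.048, "R": 0.0, "S": 0.048, "T": 0.300}
WAVE_WIDTHS_S = {"P": 0.025, "Q": 0.010, "R": 0.014, "S": 0.010, "T": 0.055}
DEFAULT_WAVE_AMPLITUDES_MV = {"P": 0.15, "Q": -0.10, "R": 1.0, "S": -0.15, "T": 0.30}


@dataclass
class ECGSynthSpec:
    """Parameters of the two-channel synthetic ECG generator.

    Amplitudes are in millivolt.  ``powerline`` maps 60/120 Hz to tone
    amplitude; ``baseline_wander`` is ``(amplitude_mv, frequency_hz)`` with
    the frequency below 0.5 Hz; ``channel_noise_scale`` multiplies the white
    noise per channel ``(test, ref)``.  ``corruption`` optionally names waves
    to suppress in a stated fraction of beats on the test channel only, e.g.
    ``{"waves": ["P"], "fraction": 0.1}``.
    """

    fs: float = 1000.0
    duration: float = 60.0
    heart_rate: float = 60.0
    wave_amplitudes: dict = field(
        default_factory=lambda: dict(DEFAULT_WAVE_AMPLITUDES_MV)
    )
    powerline: dict = field(default_factory=lambda: {60.0: 0.0, 120.0: 0.0})
    baseline_wander: tuple[float, float] = (0.0, 0.2)
    white_noise_sd: float = 0.0
    channel_noise_scale: tuple[float, float] = (1.0, 1.0)
    corruption: dict | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.fs >= 500:
            raise ValueError("fs must be >= 500 Hz (QRS and 150 Hz band edge)")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.heart_rate > 0:
            raise ValueError("heart rate must be > 0")
        if not self.baseline_wander[1] < 0.5:
            raise ValueError("baseline wander frequency must be < 0.5 Hz")
        if self.corruption is not None:
            frac = self.corruption.get("fraction", 0.0)
            if not 0.0 <= frac <= 1.0:
                raise ValueError("corruption fraction must be in [0, 1]")
            bad = set(self.corruption.get("waves", [])) - set("PQRST")
            if bad:
                raise ValueError(f"unknown wave names in corruption rule: {bad}")


def synth_ecg(spec: ECGSynthSpec) -> ECGRecording:
    """Generate a two-channel lead-II-like recording with known fiducials.

    Both channels share the same beat train (sum-of-Gaussians PQRST
    morphology), powerline tones and baseline wander; white noise is drawn
    independently per channel.  The corruption rule removes the named waves
    from exactly ``round(fraction * n_beats)`` seeded-random beats on the
    test channel, and the affected beats are recorded in each annotation's
    ``"suppressed"`` list.

    Returns
    -------
    ECGRecording
        With ``annotations`` set to a list of per-beat dicts holding the
        P/Q/R/S/T sample indices and the suppressed-wave list.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    rr = 60.0 / spec.heart_rate

    # R-peak times: leave room for the P wave before the first beat and the
    # T wave after the last
    lead_in = 0.40
    r_times = []
    tr = lead_in
    while tr < spec.duration - 0.05:
        r_times.append(tr)
        tr += rr
    n_beats = len(r_times)

    suppressed_beats: dict[int, list[str]] = {}
    if spec.corruption is not None and n_beats:
        frac = spec.corruption.get("fraction", 0.0)
        waves = list(spec.corruption.get("waves", []))
        k = int(round(frac * n_beats))
        chosen = rng.choice(n_beats, size=min(k, n_beats), replace=False)
        suppressed_beats = {int(b): waves for b in chosen}

    def beat_train(skip: dict[int, list[str]]) -> np.ndarray:
        sig = np.zeros(n)
        for b, tr_ in enumerate(r_times):
            for wave, amp in spec.wave_amplitudes.items():
                if wave in skip.get(b, []):
                    continue
                mu = tr_ + WAVE_OFFSETS_S[wave]
                sd = WAVE_WIDTHS_S[wave]
                lo = max(0, int((mu - 5 * sd) * spec.fs))
                hi = min(n, int((mu + 5 * sd) * spec.fs) + 1)
                if lo < hi:
                    sig[lo:hi] += amp * np.exp(
                        -0.5 * ((t[lo:hi] - mu) / sd) ** 2
                    )
        return sig

    clean_ref = beat_train({})
    clean_test = beat_train(suppressed_beats) if suppressed_beats else clean_ref.copy()

    common = np.zeros(n)
    for f_line, amp in spec.powerline.items():
        if amp:
            common += amp * np.sin(2.0 * np.pi * float(f_line) * t)
    bw_amp, bw_f = spec.baseline_wander
    if bw_amp:
        common += bw_amp * np.sin(2.0 * np.pi * bw_f * t)

    s_test, s_ref = spec.channel_noise_scale
    noise_test = (
        rng.normal(0.0, spec.white_noise_sd * s_test, n) if spec.white_noise_sd else 0.0
    )
    noise_ref = (
        rng.normal(0.0, spec.white_noise_sd * s_ref, n) if spec.white_noise_sd else 0.0
    )

    annotations = []
    for b, tr_ in enumerate(r_times):
        ann = {
            wave: int(round((tr_ + WAVE_OFFSETS_S[wave]) * spec.fs))
            for wave in "PQRST"
        }
        ann["suppressed"] = suppressed_beats.get(b, [])
        annotations.append(ann)

    return ECGRecording(
        test_channel=clean_test + common + noise_test,
        ref_channel=clean_ref + common + noise_ref,
        fs=spec.fs,
        label="synthetic",
        annotations=annotations,
        meta={"spec": spec, "n_beats": n_beats},
    )


# --------------------------------------------------------------------------
# polarization


@dataclass
class PolarizationSynthSpec:
    """Parameters of the DC polarization-series generator.

    ``dc_offset`` and the step amplitudes are millivolt; ``drift_rate`` is
    millivolt per minute; ``noise_sd`` is microvolt (sample-to-sample
    variability on the scale seen in practice, tens to hundreds of
    microvolt per 0.1 s).
    """

    fs: float = 10.0
    duration: float = 1800.0
    dc_offset: float = 15.0
    drift_rate: float = 0.0
    step_artifacts: tuple = ()
    noise_sd: float = 0.0  # microvolt
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")


def synth_polarization(spec: PolarizationSynthSpec) -> PolarizationSeries:
    """Generate a drifting DC potential series in millivolt.

    The noise-free component is ``dc_offset + drift_rate * t_minutes`` plus
    any step artifacts; its mean over the record is the offset plus the
    drift midpoint (steps aside).  Gaussian noise of ``noise_sd`` microvolt
    is added per sample.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(np.floor(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    x = spec.dc_offset + spec.drift_rate * (t / 60.0)
    for t_step, amp in spec.step_artifacts:
        x = x + np.where(t >= t_step, amp, 0.0)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd / 1000.0, n)  # uV -> mV
    return PolarizationSeries(samples=x, fs=spec.fs, meta={"spec": spec})
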