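"""Two-configuration contact-impedance algebra and the AUC spectral score.

The skin-electrode contact impedance cannot be probed directly: any series
measurement also includes the tissue between electrodes.  Two measurements
fix that.  With a reference resistor ``R_ref`` in series, configuration A
measures ``Z_sum = Z_contact + Z_SB12`` (one contact plus inter-electrode
tissue) and configuration B measures ``Z_12 = 2*Z_contact + Z_SB12`` (both
contacts plus tissue); the difference isolates a single contact:

    Z = V21 / I,   I = V_r / R_ref,   Z_contact = Z_12 - Z_sum

All quantities are phasors, so the division carries both magnitude and
phase.  Spectra are summarized for group comparison by the area under the
|Z|-versus-log10(f) curve (the "AUC score").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .phasors import Phasor, amplitude_peaks, remove_dc, waveform_to_phasor

__all__ = [
    "ImpedanceSpectrum",
    "impedance_from_phasors",
    "v21_config_a",
    "v21_config_b",
    "decompose",
    "sweep_pipeline",
    "auc_score",
]

logger = logging.getLogger(__name__)


@dataclass
class ImpedanceSpectrum:
    """Complex impedance on a strictly increasing frequency grid."""

    frequencies: np.ndarray  # hertz
    z: np.ndarray  # complex ohm
    label: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.z = np.asarray(self.z, dtype=complex)
        if self.frequencies.shape != self.z.shape:
            raise ValueError("frequency and impedance arrays must match in length")
        if self.frequencies.size and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(np.abs(self.z))):
            raise ValueError("impedance values must be finite")

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.z)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.rad2deg(np.angle(self.z))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "f_hz": self.frequencies,
                "z_real": self.z.real,
                "z_imag": self.z.imag,
                "z_abs": self.magnitude,
                "z_phase_deg": self.phase_deg,
            }
        )


def impedance_from_phasors(v21: Phasor, vr: Phasor, r_ref: float) -> complex:
    """Series impedance ``Z = V21 / I`` with ``I = V_r / R_ref``.

    Phasor division: magnitudes divide, phases subtract.
    """
    if r_ref <= 0:
        raise ValueError("r_ref must be > 0")
    if vr.magnitude == 0:
        raise ValueError("V_r is zero: no current flows, impedance undefined")
    return v21.complex / (vr.complex / r_ref)


def _check_same_frequency(a: Phasor, b: Phasor) -> None:
    if not np.isclose(a.frequency, b.frequency, rtol=1e-9):
        raise ValueError(
            f"phasor frequencies differ: {a.frequency} Hz vs {b.frequency} Hz"
        )


def v21_config_a(ve2: Phasor, vr: Phasor) -> Phasor:
    """``V21 = V_e2 - V_r`` (probe at electrode 2, configuration A)."""
    _check_same_frequency(ve2, vr)
    return Phasor.from_complex(ve2.complex - vr.complex, ve2.frequency)


def v21_config_b(vg: Phasor, vr: Phasor) -> Phasor:
    """``V21 = V_g - V_r`` (source as probe, configuration B)."""
    _check_same_frequency(vg, vr)
    return Phasor.from_complex(vg.complex - vr.complex, vg.frequency)


def decompose(z_sum: complex, z_12: complex) -> tuple[complex, complex, bool]:
    """Split the two series measurements into contact and tissue impedance.

    Returns ``(z_contact, z_sb, physical)`` where ``z_contact = z_12 - z_sum``
    and ``z_sb = 2*z_sum - z_12``; the flag is False when the contact
    impedance comes out with a negative real part, which is non-physical and
    usually indicates measurement noise exceeding the contact contribution.
    Flagged values are returned, not discarded.
    """
    z_contact = z_12 - z_sum
    z_sb = 2.0 * z_sum - z_12
    physical = z_contact.real >= 0.0
    if not physical:
        warnings.warn(
            "decomposed contact impedance has negative real part", stacklevel=2
        )
    return z_contact, z_sb, physical


def sweep_pipeline(
    sweep_a,
    sweep_b,
    r_ref: float,
    method: str = "xcorr",
    label: str = "",
) -> ImpedanceSpectrum:
    """Full waveform-to-spectrum pipeline over a two-configuration sweep.

    Per frequency: DC removal, phasor extraction of the probe voltage against
    the reference-resistor voltage (config A) and of the reference-resistor
    voltage against the source (config B), the two ``V21`` subtractions, the
    ``V21/I`` divisions, and the final decomposition.  Frequencies where any
    step fails are logged and dropped; if every frequency fails, an error is
    raised.

    Parameters
    ----------
    sweep_a, sweep_b : SweepResult
        Output of :func:`texelec.bench.simulate_sweep` (or equivalently
        structured measured data) for configurations A and B on matching
        frequency grids.
    r_ref : float
        Reference resistance in ohm.
    method : {"xcorr", "lissajous"}
        Phase-estimation method, recorded in the provenance.
    """
    fa = np.asarray([m.frequency for m in sweep_a.measurements])
    fb = np.asarray([m.frequency for m in sweep_b.measurements])
    if fa.size == 0 or fb.size == 0:
        raise ValueError("empty frequency grid")
    if fa.size != fb.size or not np.allclose(fa, fb, rtol=1e-12):
        raise ValueError("configuration A and B frequency grids do not match")

    freqs, z_contact = [], []
    for ma, mb in zip(sweep_a.measurements, sweep_b.measurements):
        f = ma.frequency
        try:
            z_c, _ = _single_frequency(ma, mb, r_ref, method)
        except Exception as exc:  # noqa: BLE001 - record and continue per spec
            logger.warning("frequency %g Hz dropped: %s", f, exc)
            continue
        freqs.append(f)
        z_contact.append(z_c)
    if not freqs:
        raise ValueError("pipeline failed at every frequency")
    return ImpedanceSpectrum(
        np.asarray(freqs),
        np.asarray(z_contact),
        label=label,
        provenance={"method": method, "r_ref": r_ref},
    )


def _trim_edges(x: np.ndarray, margin: int) -> np.ndarray:
    if x.size > 3 * margin and margin > 0:
        return x[margin:-margin]
    return x


def _single_frequency(ma, mb, r_ref, method):
    """Process one frequency of a two-configuration sweep."""
    f, fs = ma.frequency, ma.fs
    order = min(2000, max(2, ma.v_r.size // 3 - 1))
    margin = order // 2 + 1

    # configuration A: phase of V_e2 measured against V_r
    vr_a = _trim_edges(remove_dc(ma.v_r, fs, order), margin)
    ve2 = _trim_edges(remove_dc(ma.v_probe, fs, order), margin)
    vr_a_ph = Phasor(amplitude_peaks(vr_a), 0.0, f)
    ve2_ph = waveform_to_phasor(ve2, vr_a, f, fs, method)
    v21_a = v21_config_a(ve2_ph, vr_a_ph)
    z_sum = impedance_from_phasors(v21_a, vr_a_ph, r_ref)

    # configuration B: phase of V_r measured against the source V_g
    fs_b = mb.fs
    order_b = min(2000, max(2, mb.v_r.size // 3 - 1))
    margin_b = order_b // 2 + 1
    vg = _trim_edges(remove_dc(mb.v_probe, fs_b, order_b), margin_b)
    vr_b = _trim_edges(remove_dc(mb.v_r, fs_b, order_b), margin_b)
    vg_ph = Phasor(amplitude_peaks(vg), 0.0, f)
    vr_b_ph = waveform_to_phasor(vr_b, vg, f, fs_b, method)
    v21_b = v21_config_b(vg_ph, vr_b_ph)
    z_12 = impedance_from_phasors(v21_b, vr_b_ph, r_ref)

    z_contact, z_sb, _ = decompose(z_sum, z_12)
    return z_contact, z_sb


def auc_score(spectrum: ImpedanceSpectrum) -> float:
    """Area under |Z| versus log10(frequency), in ohm-decades.

    A scalar summary of a whole spectrum: the trapezoidal integral of the
    magnitude against log-frequency, matching how the spectra are displayed
    on a Bode magnitude plot.
    """
    if len(spectrum) < 2:
        raise ValueError("need at least 2 frequencies for an AUC score")
    if np.any(spectrum.frequencies <= 0):
        raise ValueError("AUC abscissa is log10(f); frequencies must be > 0")
    return float(
        np.trapezoid(spectrum.magnitude, np.log10(spectrum.frequencies))
    )
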