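"""Plain-text data formats: waveform CSV with JSON sidecar, spectra, annotations.

Waveforms travel as CSV with a header row ``t,<channel>[,<channel>...]``
(time in seconds) plus a JSON sidecar ``<name>.json`` holding ``fs``,
``units`` and optional ground truth.  Impedance spectra are CSV with columns
``f_hz,z_real,z_imag,z_abs,z_phase_deg``.  Beat annotations are a JSON list
of per-beat fiducial-index dicts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .impedance import ImpedanceSpectrum
from .quality import ECGRecording

__all__ = [
    "write_waveform_csv",
    "read_waveform_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_annotations",
    "read_annotations",
    "write_recording",
    "read_recording",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_waveform_csv(path, t, channels: dict, fs: float, units: str = "V", extra: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"t": np.asarray(t), **{k: np.asarray(v) for k, v in channels.items()}})
    df.to_csv(path, index=False)
    meta = {"fs": fs, "units": units}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_waveform_csv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    return df, meta


def write_spectrum_csv(path, spectrum: ImpedanceSpectrum) -> None:
    spectrum.to_frame().to_csv(path, index=False)


def read_spectrum_csv(path, label: str = "") -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    return ImpedanceSpectrum(
        df["f_hz"].to_numpy(),
        df["z_real"].to_numpy() + 1j * df["z_imag"].to_numpy(),
        label=label,
    )


def write_annotations(path, annotations: list) -> None:
    def coerce(v):
        if isinstance(v, np.generic):  # numpy scalar -> native python
            return v.item()
        return v

    def clean(a):
        if hasattr(a, "to_dict"):
            a = a.to_dict()
        return {k: coerce(v) for k, v in a.items()}

    Path(path).write_text(json.dumps([clean(a) for a in annotations], indent=0))


def read_annotations(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def write_recording(path, rec: ECGRecording) -> None:
    """Recording CSV ``t,test_mv,ref_mv`` with sidecar and annotation file."""
    path = Path(path)
    write_waveform_csv(
        path,
        rec.time,
        {"test_mv": rec.test_channel, "ref_mv": rec.ref_channel},
        fs=rec.fs,
        units="mV",
        extra={"label": rec.label},
    )
    if rec.annotations is not None:
        write_annotations(path.with_suffix(".annotations.json"), rec.annotations)


def read_recording(path) -> ECGRecording:
    path = Path(path)
    df, meta = read_waveform_csv(path)
    ann_path = path.with_suffix(".annotations.json")
    annotations = read_annotations(ann_path) if ann_path.exists() else None
    return ECGRecording(
        test_channel=df["test_mv"].to_numpy(),
        ref_channel=df["ref_mv"].to_numpy(),
        fs=float(meta["fs"]),
        label=meta.get("label", ""),
        annotations=annotations,
    )
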