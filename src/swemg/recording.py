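"""The in-memory recording container and its on-disk format.

A recording is a ``(n_samples, 64)`` float matrix in microvolts sampled at a
single rate (1000 Hz by default), plus task metadata: subject id, dysphagia
severity label, and the volume-viscosity swallow-test task (viscosity x
bolus volume).

On disk a recording is a CSV matrix with header ``ch01..ch64`` and a JSON
sidecar (same stem, ``.json``) holding ``fs_hz``, ``subject``, ``severity``,
``viscosity``, ``volume_ml`` and ``seed``.  Chosen for inspectability with
any spreadsheet or text tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import N_CHANNELS

SEVERITIES = ("none", "mild", "moderate", "severe")
VISCOSITIES = ("nectar", "liquid", "pudding")
VOLUMES_ML = (5, 10, 20)


class FormatError(ValueError):
    """Raised when an on-disk recording does not match the documented format."""


@dataclass
class Recording:
    signal: np.ndarray              # (n_samples, 64), microvolts
    fs: float = 1000.0
    subject: str = ""
    severity: str | None = None
    viscosity: str | None = None
    volume_ml: int | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[1] != N_CHANNELS:
            raise FormatError(
                f"signal must be (n_samples, {N_CHANNELS}), got {self.signal.shape}")
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")
        if self.severity is not None and self.severity not in SEVERITIES:
            raise FormatError(f"unknown severity {self.severity!r}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs * 1000.0

    def channel(self, channel_id: int) -> np.ndarray:
        """Single-channel series by 1-based channel id."""
        return self.signal[:, channel_id - 1]

    def with_signal(self, signal: np.ndarray) -> "Recording":
        """Copy of this recording carrying *signal*, metadata preserved."""
        return replace(self, signal=signal)

    def slice_ms(self, start_ms: float, duration_ms: float) -> "Recording":
        """Time slice ``[start, start + duration)``; all channels together."""
        if duration_ms <= 0:
            raise ValueError("duration must be positive")
        i0 = int(round(start_ms * self.fs / 1000.0))
        i1 = i0 + int(round(duration_ms * self.fs / 1000.0))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError(
                f"window [{start_ms}, {start_ms + duration_ms}) ms outside "
                f"recording of {self.duration_ms:.0f} ms")
        return self.with_signal(self.signal[i0:i1])


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write *rec* as CSV + JSON sidecar, losslessly round-trippable."""
    path = Path(path)
    cols = [f"ch{c:02d}" for c in range(1, N_CHANNELS + 1)]
    pd.DataFrame(rec.signal, columns=cols).to_csv(
        path, index=False, float_format="%.17g")
    meta = {"fs_hz": rec.fs, "subject": rec.subject, "severity": rec.severity,
            "viscosity": rec.viscosity, "volume_ml": rec.volume_ml,
            "seed": rec.seed}
    meta.update(rec.extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    expected = [f"ch{c:02d}" for c in range(1, N_CHANNELS + 1)]
    if list(df.columns) != expected:
        raise FormatError(
            f"expected columns ch01..ch{N_CHANNELS}, got {len(df.columns)} "
            "columns or wrong names")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs_hz" not in meta:
        raise FormatError("sidecar missing sampling rate fs_hz")
    known = {"fs_hz", "subject", "severity", "viscosity", "volume_ml", "seed"}
    seed = meta.get("seed")
    return Recording(
        signal=df.to_numpy(dtype=float),
        fs=float(meta["fs_hz"]),
        subject=meta.get("subject", ""),
        severity=meta.get("severity"),
        viscosity=meta.get("viscosity"),
        volume_ml=None if meta.get("volume_ml") is None else int(meta["volume_ml"]),
        seed=None if seed is None else int(seed),
        extra={k: v for k, v in meta.items() if k not in known},
    )
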