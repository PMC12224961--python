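"""Synthetic 64-channel swallowing sEMG with controllable severity structure.

Each channel is the sum of

* baseline Gaussian tone (instrumentation + resting muscle noise),
* one or more muscle bursts: a band-limited (20-250 Hz) stochastic carrier,
  unit RMS, amplitude-modulated by a raised-cosine (Tukey) envelope, and
* an optional common-mode 50 Hz powerline sinusoid.

The 20-250 Hz carrier band reflects where surface-EMG spectral mass
concentrates; no motor-unit or volume-conductor physiology is modelled.
Bilateral asymmetry is imposed by scaling every left-side channel
(``x > 0``) by the left/right RMS ratio ``r`` while right-side channels
keep unit scale, so the generated pairwise RMS ratio equals ``r`` exactly
up to baseline-noise dilution.

Severity presets encode four phenotypes:

* ``none``     — one strong, symmetric, sequential swallow (submental leads
  infrahyoid), ``r ~ 1``;
* ``mild``     — the same sequence but weaker with a prolonged relaxation
  tail;
* ``moderate`` — low-level submental pre-activation before the main burst
  and prolonged infrahyoid activity, mild asymmetry;
* ``severe``   — simultaneous submental + infrahyoid recruitment, strong
  asymmetry (``r = 2``), and a repeat swallow.

All randomness flows from one integer seed; per-recording sub-seeds are
spawned deterministically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .grid import ElectrodeGrid, SUBMENTAL
from .recording import Recording, SEVERITIES, VISCOSITIES, VOLUMES_ML

CARRIER_BAND_HZ = (20.0, 250.0)


class ParameterError(ValueError):
    """Simulation parameters are inconsistent (e.g. burst outside recording)."""


@dataclass
class BurstTrain:
    """Burst timing for one muscle region."""

    onsets_ms: list[float]
    durations_ms: list[float]
    rel_amps: list[float] | None = None   # per-burst scale, default all 1

    def __post_init__(self) -> None:
        if len(self.onsets_ms) != len(self.durations_ms):
            raise ParameterError("onsets and durations must align")
        if self.rel_amps is None:
            self.rel_amps = [1.0] * len(self.onsets_ms)
        if len(self.rel_amps) != len(self.onsets_ms):
            raise ParameterError("rel_amps must align with onsets")


@dataclass
class SwallowSimParams:
    """Full parameterization of one synthetic swallowing trial."""

    severity: str = "none"
    bursts: dict[str, BurstTrain] = field(default_factory=dict)
    amplitude_uv: dict[str, float] = field(default_factory=lambda: {
        "submental": 30.0, "infrahyoid": 25.0})
    asymmetry_ratio: float = 1.0
    baseline_tone_uv: float = 2.0
    powerline_amp_uv: float = 5.0
    carrier_band_hz: tuple[float, float] = CARRIER_BAND_HZ
    envelope_alpha: float = 0.3       # Tukey taper fraction
    fs: float = 1000.0
    duration_ms: float = 6000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.asymmetry_ratio <= 0:
            raise ParameterError("asymmetry_ratio must be > 0")
        for region, train in self.bursts.items():
            for onset, dur in zip(train.onsets_ms, train.durations_ms):
                if onset < 0 or onset + dur > self.duration_ms:
                    raise ParameterError(
                        f"{region} burst [{onset}, {onset + dur}] ms outside "
                        f"recording of {self.duration_ms} ms")

    @property
    def n_swallows(self) -> int:
        return max((len(t.onsets_ms) for t in self.bursts.values()), default=0)

    @property
    def true_onset_ms(self) -> float:
        """Earliest full-amplitude burst onset (ground truth for detection)."""
        onsets = [o for t in self.bursts.values()
                  for o, a in zip(t.onsets_ms, t.rel_amps) if a >= 0.99]
        return min(onsets)


def severity_preset(severity: str, seed: int = 0,
                    **overrides) -> SwallowSimParams:
    """The four severity phenotypes as ready-to-simulate parameter sets."""
    if severity == "none":
        p = SwallowSimParams(
            severity="none",
            bursts={"submental": BurstTrain([2000.0], [900.0]),
                    "infrahyoid": BurstTrain([2250.0], [1000.0])},
            amplitude_uv={"submental": 30.0, "infrahyoid": 25.0},
            asymmetry_ratio=1.0, seed=seed)
    elif severity == "mild":
        p = SwallowSimParams(
            severity="mild",
            bursts={"submental": BurstTrain([2000.0], [1500.0]),
                    "infrahyoid": BurstTrain([2300.0], [1700.0])},
            amplitude_uv={"submental": 16.0, "infrahyoid": 13.0},
            asymmetry_ratio=1.05, envelope_alpha=0.5, seed=seed)
    elif severity == "moderate":
        p = SwallowSimParams(
            severity="moderate",
            bursts={"submental": BurstTrain([1700.0, 2400.0], [500.0, 1100.0],
                                            rel_amps=[0.35, 1.0]),
                    "infrahyoid": BurstTrain([2400.0], [1900.0])},
            amplitude_uv={"submental": 22.0, "infrahyoid": 18.0},
            asymmetry_ratio=1.15, seed=seed)
    elif severity == "severe":
        p = SwallowSimParams(
            severity="severe",
            bursts={"submental": BurstTrain([2000.0, 4000.0], [800.0, 700.0]),
                    "infrahyoid": BurstTrain([2000.0, 4000.0], [900.0, 800.0])},
            amplitude_uv={"submental": 35.0, "infrahyoid": 28.0},
            asymmetry_ratio=2.0, seed=seed)
    else:
        raise ParameterError(f"unknown severity {severity!r}")
    return replace(p, **overrides) if overrides else p


def bandlimited_carrier(n: int, fs: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to *band* (4th-order Butterworth,
    zero phase)."""
    hi = min(band[1], 0.998 * fs / 2.0)
    sos = sps.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    # pad so filter transients do not bias the burst edges
    pad = int(fs)  # 1 s
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:pad + n]
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def simulate_recording(params: SwallowSimParams,
                       grid: ElectrodeGrid) -> Recording:
    """Generate one 64-channel trial from *params* on *grid*.

    Deterministic for a fixed seed.  The recording's ``extra`` metadata
    carries the ground-truth onset and asymmetry ratio for downstream
    recovery checks.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_ms * params.fs / 1000.0))
    sig = rng.normal(0.0, params.baseline_tone_uv, size=(n, 64))

    region_channels = {
        "submental": grid.channels_in_region(SUBMENTAL),
        "infrahyoid": grid.channels_in_region("infrahyoid"),
    }
    r = params.asymmetry_ratio
    for region, train in params.bursts.items():
        amp = params.amplitude_uv.get(region, 0.0)
        channels = region_channels[region]
        for onset, dur, rel in zip(train.onsets_ms, train.durations_ms,
                                   train.rel_amps):
            i0 = int(round(onset * params.fs / 1000.0))
            nb = int(round(dur * params.fs / 1000.0))
            env = sps.windows.tukey(nb, alpha=params.envelope_alpha)
            for c in channels:
                side = r if grid.electrode(c).x_mm > 0 else 1.0
                carrier = bandlimited_carrier(nb, params.fs,
                                              params.carrier_band_hz, rng)
                sig[i0:i0 + nb, c - 1] += amp * rel * side * env * carrier

    if params.powerline_amp_uv > 0:
        t = np.arange(n) / params.fs
        phase = rng.uniform(0, 2 * np.pi)
        sig += params.powerline_amp_uv * np.sin(
            2 * np.pi * 50.0 * t + phase)[:, None]

    return Recording(
        signal=sig, fs=params.fs, severity=params.severity, seed=params.seed,
        extra={"true_onset_ms": params.true_onset_ms,
               "asymmetry_ratio": params.asymmetry_ratio,
               "n_swallows": params.n_swallows})


def _jitter(params: SwallowSimParams,
            rng: np.random.Generator) -> SwallowSimParams:
    """Within-class trial-to-trial variation: onset +/-100 ms, duration
    +/-10%, amplitude +/-15%, asymmetry +/-3%."""
    bursts = {}
    for region, train in params.bursts.items():
        bursts[region] = BurstTrain(
            [o + rng.uniform(-100, 100) for o in train.onsets_ms],
            [d * rng.uniform(0.9, 1.1) for d in train.durations_ms],
            list(train.rel_amps))
    amps = {k: v * rng.uniform(0.85, 1.15)
            for k, v in params.amplitude_uv.items()}
    return replace(params, bursts=bursts, amplitude_uv=amps,
                   asymmetry_ratio=params.asymmetry_ratio * rng.uniform(0.97, 1.03))


def simulate_cohort(counts: dict[str, int], grid: ElectrodeGrid,
                    seed: int = 0, jitter: bool = True) -> list[Recording]:
    """Generate a labeled cohort: ``counts`` recordings per severity class.

    Each recording gets cycling volume-viscosity task metadata (3
    viscosities x 3 volumes) and a deterministic per-recording sub-seed
    spawned from *seed*.
    """
    if not counts:
        raise ParameterError("empty cohort specification")
    for sev, cnt in counts.items():
        if sev not in SEVERITIES:
            raise ParameterError(f"unknown severity {sev!r}")
        if cnt < 1:
            raise ParameterError("counts must be >= 1 per class")
    tasks = list(itertools.product(VISCOSITIES, VOLUMES_ML))
    rng = np.random.default_rng(seed)
    recordings: list[Recording] = []
    for sev in [s for s in SEVERITIES if s in counts]:
        for i in range(counts[sev]):
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            params = severity_preset(sev, seed=sub_seed)
            if jitter:
                params = _jitter(params, np.random.default_rng(sub_seed + 1))
            rec = simulate_recording(params, grid)
            visc, vol = tasks[i % len(tasks)]
            rec.subject = f"{sev}-{i:03d}"
            rec.viscosity, rec.volume_ml = visc, vol
            recordings.append(rec)
    return recordings
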