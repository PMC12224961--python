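"""Filtering, envelope and amplitude metrics for swallowing sEMG.

The conditioning chain is a zero-phase 4th-order Butterworth band-pass
(20-500 Hz) followed by IIR notches at 50 Hz and its harmonics, matching
common powerline rejection for surface EMG acquired at 1000 Hz.  At a
1000 Hz sampling rate the 500 Hz upper edge coincides with Nyquist, so the
design edge is clipped just below it (0.998 x Nyquist) to keep the stated
band-pass topology.

Amplitude metrics are the standard EMG trio: RMS, MAV, and SNR defined as
the active/rest RMS ratio in dB.  The envelope is a moving-RMS of the
rectified signal (default 100 ms window) with a shrinking window at the
edges, so its length always equals the input's.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .recording import Recording

BAND_HZ = (20.0, 500.0)
NOTCH_BASE_HZ = 50.0
NOTCH_Q = 30.0
DEFAULT_ENVELOPE_WINDOW_MS = 100.0


def design_bandpass(fs: float, band: tuple[float, float] = BAND_HZ,
                    order: int = 4) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass.

    The upper edge is clipped to 0.998 x Nyquist when it would otherwise
    reach or exceed Nyquist.
    """
    lo, hi = band
    nyq = fs / 2.0
    if fs <= 2.0 * lo:
        raise ValueError(f"sampling rate {fs} Hz too low for a {lo} Hz low edge")
    hi = min(hi, 0.998 * nyq)
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def notch_frequencies(fs: float, base: float = NOTCH_BASE_HZ,
                      upper: float | None = None) -> np.ndarray:
    """Powerline notch centers: the fundamental and its odd harmonics
    (50, 150, 250, ... Hz) up to the usable band.

    Interference harmonics on a 50 Hz mains are predominantly odd
    (symmetric nonlinear loads suppress even ones), and keeping 100 Hz
    and its neighbours un-notched preserves the EMG spectrum there.
    """
    if upper is None:
        upper = min(BAND_HZ[1], 0.998 * fs / 2.0)
    return np.arange(base, upper + 1e-9, 2.0 * base)


def design_notches(fs: float, base: float = NOTCH_BASE_HZ,
                   q: float = NOTCH_Q,
                   upper: float | None = None) -> list[np.ndarray]:
    """2nd-order IIR notches at the powerline fundamental and odd
    harmonics up to the usable band."""
    freqs = notch_frequencies(fs, base=base, upper=upper)
    return [np.hstack(sps.iirnotch(f, q, fs=fs)).reshape(1, 6) for f in freqs]


def _subtract_coherent_lines(y: np.ndarray, fs: float,
                             freqs: np.ndarray) -> np.ndarray:
    """Least-squares removal of stationary sinusoids at *freqs*.

    A high-Q notch rings for ~0.2 s when the padded extension kinks at the
    recording edges; regressing out the coherent line component first
    leaves the notch nothing to ring on, so the envelope near the edges
    stays artifact-free.
    """
    t = np.arange(y.shape[0]) / fs
    basis = np.column_stack(
        [f(2 * np.pi * fr * t) for fr in freqs for f in (np.cos, np.sin)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return y - basis @ coef


def _filter_matrix(x: np.ndarray, fs: float) -> np.ndarray:
    padlen = min(x.shape[0] - 1, int(fs))
    # take the coherent line component out before filtering so neither the
    # band-pass nor the notches ring on it at the recording edges
    y = _subtract_coherent_lines(np.asarray(x, dtype=float), fs,
                                 notch_frequencies(fs))
    sos = design_bandpass(fs)
    y = sps.sosfiltfilt(sos, y, axis=0, padlen=padlen)
    for notch in design_notches(fs):
        y = sps.sosfiltfilt(notch, y, axis=0, padlen=padlen)
    return y


def bandpass_notch(rec: Recording) -> Recording:
    """Zero-phase band-pass + powerline-harmonic notch conditioning.

    Forward-backward application keeps envelope timing (and hence the
    detected onset) free of group delay.
    """
    return rec.with_signal(_filter_matrix(rec.signal, rec.fs))


def bandpass_line_removed(rec: Recording) -> Recording:
    """Band-pass + coherent powerline regression, without the notch stages.

    Intended for the onset-detection envelope: the Q=30 notches are
    zero-phase, so their ~0.2 s ringing smears burst energy backwards and
    would bias the threshold-crossing time early.  Spectral features and
    the symmetry indicators use the fully notched chain instead.
    """
    x = np.asarray(rec.signal, dtype=float)
    padlen = min(x.shape[0] - 1, int(rec.fs))
    y = _subtract_coherent_lines(x, rec.fs, notch_frequencies(rec.fs))
    sos = design_bandpass(rec.fs)
    return rec.with_signal(sps.sosfiltfilt(sos, y, axis=0, padlen=padlen))


def filter_series(x: np.ndarray, fs: float) -> np.ndarray:
    """Same conditioning as :func:`bandpass_notch` for a bare array
    (samples or samples x channels)."""
    x = np.asarray(x, dtype=float)
    return _filter_matrix(x if x.ndim > 1 else x[:, None], fs).reshape(x.shape)


def compute_envelope(x: np.ndarray, fs: float,
                     window_ms: float = DEFAULT_ENVELOPE_WINDOW_MS) -> np.ndarray:
    """Moving-RMS envelope of a single-channel (or multi-channel) series.

    Nonnegative, same length as the input; the averaging window shrinks at
    the boundaries instead of zero-padding, so a constant signal maps to a
    constant envelope.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    w = max(1, int(round(window_ms * fs / 1000.0)))
    kernel = np.ones(w)
    sq = x ** 2
    if x.ndim == 1:
        num = np.convolve(sq, kernel, mode="same")
        cnt = np.convolve(np.ones_like(sq), kernel, mode="same")
    else:
        num = np.stack([np.convolve(sq[:, j], kernel, mode="same")
                        for j in range(x.shape[1])], axis=1)
        cnt = np.convolve(np.ones(x.shape[0]), kernel, mode="same")[:, None]
    return np.sqrt(num / cnt)


def compute_rms(segment: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.sqrt(np.mean(segment ** 2)))


def compute_mav(segment: np.ndarray) -> float:
    """Mean absolute value."""
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.mean(np.abs(segment)))


def compute_snr(active_segment: np.ndarray, rest_segment: np.ndarray) -> float:
    """Signal-to-noise ratio in dB: ``20 log10(RMS_active / RMS_rest)``."""
    rms_rest = compute_rms(rest_segment)
    if rms_rest == 0.0:
        raise ZeroDivisionError("rest segment has zero RMS; SNR undefined")
    return float(20.0 * np.log10(compute_rms(active_segment) / rms_rest))
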