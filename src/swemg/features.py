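"""Per-channel feature extraction for severity classification.

Seven features per channel, over the 2000 ms swallow window
``[T_s, T_e]``, giving 64 x 7 = 448 features per trial:

1. kurtosis (non-excess: a Gaussian scores 3),
2. full width at half maximum (ms) of the envelope's main peak,
3. sample entropy (m = 2, r = 0.2 x SD),
4. power-spectrum peak frequency (Hz),
5. peak frequency normalized by Nyquist (dimensionless),
6. total spectral power (sum of PSD x frequency bin, ~ variance),
7. spectral centroid (Hz).

PSDs are Welch estimates (256-sample Hann segments, 50% overlap).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import signal as sps
from scipy import stats

from .preprocess import compute_envelope
from .recording import Recording

FEATURE_NAMES = ("kurtosis", "fwhm", "sampen", "psd_peak_f",
                 "psd_norm_peak_f", "psd_total_power", "psd_centroid")
N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES)
N_FEATURES = 64 * N_FEATURES_PER_CHANNEL

WELCH_NPERSEG = 256


def feature_names() -> list[str]:
    """The 448 column names, channel-major: ch01_kurtosis .. ch64_psd_centroid."""
    return [f"ch{c:02d}_{f}" for c in range(1, 65) for f in FEATURE_NAMES]


@njit(cache=True)
def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Template-match counts for sample entropy.

    B = pairs of length-m templates within Chebyshev distance r,
    A = pairs also matching at length m+1; self-matches excluded.
    """
    n = x.shape[0]
    nt = n - m          # number of (m+1)-templates = n - m; m-templates n-m+1
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(x: np.ndarray, m: int = 2,
                   r: float | None = None) -> float:
    """Sample entropy: -ln(A/B), the (negative log) conditional probability
    that sequences matching for *m* points keep matching at m+1.

    ``r`` defaults to 0.2 x SD of the series (population SD), so the value
    is invariant to positive affine scaling.  Returns inf when no template
    pair persists (A = 0) and 0 for a constant series (all pairs persist).
    """
    x = np.asarray(x, dtype=float)
    if x.size <= m + 1:
        raise ValueError(f"series too short for m={m}")
    if r is None:
        r = 0.2 * float(np.std(x))
    a, b = _sampen_counts(x, m, float(r))
    if b == 0:
        return float("inf")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def envelope_fwhm(x: np.ndarray, fs: float,
                  window_ms: float = 100.0) -> float:
    """Width (ms) of the envelope's main peak at half its maximum.

    The main peak is the global envelope maximum in the window; half-max
    crossings are located by linear interpolation on each side, falling
    back to the window edge when the envelope never drops below half-max.
    """
    env = compute_envelope(x, fs, window_ms=window_ms)
    peak = env.max()
    if peak <= 0:
        raise ValueError("flat zero envelope has no peak")
    half = peak / 2.0
    ipk = int(np.argmax(env))

    def _cross(idx_range, reverse):
        prev = ipk
        for i in idx_range:
            if env[i] < half:
                # linear interpolation between i and the sample nearer the peak
                frac = (half - env[i]) / (env[prev] - env[i])
                return i + frac * (prev - i)
            prev = i
        return idx_range[-1] if len(idx_range) else ipk

    left = _cross(range(ipk - 1, -1, -1), True) if ipk > 0 else 0
    right = (_cross(range(ipk + 1, env.shape[0]), False)
             if ipk < env.shape[0] - 1 else env.shape[0] - 1)
    return float((right - left) / fs * 1000.0)


def _welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(WELCH_NPERSEG, x.shape[0])
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2)


def channel_features(x: np.ndarray, fs: float,
                     excess_kurtosis: bool = False) -> np.ndarray:
    """The 7 features of one channel's swallow-window segment."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    if np.std(x) == 0:
        raise ValueError("constant segment: kurtosis undefined")
    kurt = stats.kurtosis(x, fisher=excess_kurtosis, bias=True)
    fwhm = envelope_fwhm(x, fs)
    sampen = sample_entropy(x)
    if not np.isfinite(sampen):        # no persisting template pair
        sampen = np.log(x.size)        # finite ceiling ~ ln(n)
    f, psd = _welch_psd(x, fs)
    ipk = int(np.argmax(psd))
    peak_f = float(f[ipk])
    df = float(f[1] - f[0])
    total_power = float(psd.sum() * df)
    centroid = float((f * psd).sum() / psd.sum())
    return np.array([kurt, fwhm, sampen, peak_f, peak_f / (fs / 2.0),
                     total_power, centroid])


def recording_features(window: Recording,
                       excess_kurtosis: bool = False) -> np.ndarray:
    """448-vector for one swallow window, channel-major then feature."""
    return np.concatenate([
        channel_features(window.signal[:, c], window.fs,
                         excess_kurtosis=excess_kurtosis)
        for c in range(64)])


def build_feature_matrix(windows: list[Recording],
                         zscore: bool = False,
                         ) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack per-trial 448-vectors into (n_samples, 448) plus labels.

    With ``zscore`` the columns are standardized in place (mean 0, SD 1);
    in the classification pipeline standardization is instead fitted on
    the training split only, to avoid leakage.  Zero-variance columns are
    left unscaled.
    """
    if not windows:
        raise ValueError("no windows")
    X = np.stack([recording_features(w) for w in windows])
    labels = [w.severity for w in windows]
    if zscore:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        nz = sd > 0
        X[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return X, feature_names(), labels
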