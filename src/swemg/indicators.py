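"""The three quantitative dysphagia indicators.

1. **Muscle-activity intensity maps** — a 3000 ms capture starting at
   ``T_s`` is split into 6 equal 500 ms frames; per-frame, per-channel RMS
   is min-max normalized over the whole window and spatially expanded by
   biharmonic-spline interpolation into a continuous field per region.

2. **Degree of symmetry (DOS)** — a 1500 ms capture starting at ``T_c`` is
   split into 15 equal segments; for every mirrored left/right channel
   pair the segment-wise RMS ratio ``RMS_left / RMS_right`` is formed, and

       DOS = (1 / (N x M)) * sum(RMS_left / RMS_right)

   with N = 15 segments and M = 8 pairs (submental) or 24 (infrahyoid).
   DOS = 1 means perfectly balanced bilateral activity.

3. **Activity barycenter and 95% confidence ellipse** — per segment, the
   RMS-weighted centroid of the region's electrode coordinates

       B_x = sum(RMS_i * x_i) / sum(RMS_i),   B_y likewise,

   with n = 16 channels for submental and 48 for infrahyoid.  The scatter
   of barycenters is summarized by an ellipse centered at the sample mean
   whose axes follow the covariance eigenvectors, semi-axis lengths
   ``sqrt(chi2_quantile(level, 2) * eigenvalue)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .grid import ElectrodeGrid
from .recording import Recording

INTENSITY_WINDOW_MS = 3000.0
N_INTENSITY_FRAMES = 6
DOS_WINDOW_MS = 1500.0
N_DOS_SEGMENTS = 15
RMS_FLOOR_UV = 1e-9


class DegenerateRatioError(ZeroDivisionError):
    """A right-side segment RMS fell below the floor; the left/right ratio
    would be unbounded."""


def _segment_rms(window: Recording, n_segments: int) -> np.ndarray:
    """(n_segments, 64) per-segment per-channel RMS."""
    n = window.n_samples
    edges = np.linspace(0, n, n_segments + 1).round().astype(int)
    return np.stack([
        np.sqrt(np.mean(window.signal[edges[k]:edges[k + 1]] ** 2, axis=0))
        for k in range(n_segments)])


# ---------------------------------------------------------------------------
# biharmonic spline interpolation
# ---------------------------------------------------------------------------

def _biharmonic_green(dist: np.ndarray) -> np.ndarray:
    """2-D biharmonic Green's function g(d) = d^2 (ln d - 1), with g(0) = 0."""
    out = np.zeros_like(dist)
    nz = dist > 0
    out[nz] = dist[nz] ** 2 * (np.log(dist[nz]) - 1.0)
    return out


class BiharmonicSpline:
    """Exact scattered-data interpolation via biharmonic Green's functions.

    The interpolant is ``f(p) = sum_j w_j g(|p - p_j|)`` with weights
    solving ``G w = v`` at the data sites; a 1e-10 diagonal regularizer
    keeps the system well conditioned without visibly smoothing.
    """

    def __init__(self, points: np.ndarray, values: np.ndarray,
                 regularization: float = 1e-10) -> None:
        self.points = np.asarray(points, dtype=float)
        values = np.asarray(values, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        d = np.linalg.norm(self.points[:, None, :] - self.points[None, :, :],
                           axis=-1)
        G = _biharmonic_green(d) + regularization * np.eye(len(values))
        self.weights = np.linalg.solve(G, values)

    def __call__(self, query: np.ndarray) -> np.ndarray:
        query = np.atleast_2d(np.asarray(query, dtype=float))
        d = np.linalg.norm(query[:, None, :] - self.points[None, :, :],
                           axis=-1)
        return _biharmonic_green(d) @ self.weights


@dataclass
class IntensityFrame:
    """One 500 ms frame: channel values plus interpolated regional fields."""

    channel_values: np.ndarray                   # (64,) normalized RMS
    fields: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    # region -> (grid_x (nx,), grid_y (ny,), field (ny, nx))


@dataclass
class IntensityMap:
    frames: list[IntensityFrame]
    frame_duration_ms: float = INTENSITY_WINDOW_MS / N_INTENSITY_FRAMES


def intensity_map(window: Recording, grid: ElectrodeGrid,
                  resolution_mm: float = 2.0,
                  regions: tuple[str, ...] = ("submental", "infrahyoid"),
                  ) -> IntensityMap:
    """Six consecutive normalized-RMS activity frames from a 3000 ms window.

    Normalization is min-max over all 6 x 64 RMS values, so the single
    most active channel-frame maps to 1 (red) and the least active to 0
    (blue).  If all values coincide the map is identically 0.
    """
    expected = int(round(INTENSITY_WINDOW_MS * window.fs / 1000.0))
    if window.n_samples != expected:
        raise ValueError(
            f"intensity window must be {INTENSITY_WINDOW_MS:.0f} ms "
            f"({expected} samples at {window.fs:g} Hz), got {window.n_samples}")
    rms = _segment_rms(window, N_INTENSITY_FRAMES)          # (6, 64)
    lo, hi = rms.min(), rms.max()
    norm = np.zeros_like(rms) if hi == lo else (rms - lo) / (hi - lo)

    frames = []
    for k in range(N_INTENSITY_FRAMES):
        fields = {}
        for region in regions:
            chans = grid.channels_in_region(region)
            pts = grid.positions(chans)
            vals = norm[k, [c - 1 for c in chans]]
            spline = BiharmonicSpline(pts, vals)
            gx = np.arange(pts[:, 0].min(), pts[:, 0].max() + 1e-9,
                           resolution_mm)
            gy = np.arange(pts[:, 1].min(), pts[:, 1].max() + 1e-9,
                           resolution_mm)
            xx, yy = np.meshgrid(gx, gy)
            fld = spline(np.column_stack([xx.ravel(), yy.ravel()]))
            fields[region] = (gx, gy, fld.reshape(xx.shape))
        frames.append(IntensityFrame(channel_values=norm[k], fields=fields))
    return IntensityMap(frames=frames)


# ---------------------------------------------------------------------------
# degree of symmetry
# ---------------------------------------------------------------------------

@dataclass
class DOSResult:
    region: str
    dos: float
    n_segments: int
    n_pairs: int
    ratios: np.ndarray          # (N, M) RMS_left / RMS_right


def dos(window: Recording, grid: ElectrodeGrid, region: str,
        clamp_floor: bool = False) -> DOSResult:
    """Degree of symmetry over a 1500 ms, 15-segment window.

    Ratios are oriented left/right literally, so a right-dominant subject
    yields DOS < 1.  A right-side segment RMS below ``RMS_FLOOR_UV``
    raises :class:`DegenerateRatioError` unless ``clamp_floor`` substitutes
    the floor value.
    """
    expected = int(round(DOS_WINDOW_MS * window.fs / 1000.0))
    if window.n_samples != expected:
        raise ValueError(
            f"DOS window must be {DOS_WINDOW_MS:.0f} ms "
            f"({expected} samples at {window.fs:g} Hz), got {window.n_samples}")
    pairs = grid.pairs(region)
    rms = _segment_rms(window, N_DOS_SEGMENTS)              # (15, 64)
    left = rms[:, [l - 1 for l, _ in pairs]]
    right = rms[:, [r - 1 for _, r in pairs]]
    if np.any(right < RMS_FLOOR_UV):
        if not clamp_floor:
            raise DegenerateRatioError(
                f"right-side segment RMS below {RMS_FLOOR_UV} uV in "
                f"region {region!r}")
        right = np.maximum(right, RMS_FLOOR_UV)
    ratios = left / right
    return DOSResult(region=region, dos=float(ratios.mean()),
                     n_segments=N_DOS_SEGMENTS, n_pairs=len(pairs),
                     ratios=ratios)


# ---------------------------------------------------------------------------
# barycenter and confidence ellipse
# ---------------------------------------------------------------------------

@dataclass
class BarycenterPoint:
    b_x_mm: float
    b_y_mm: float
    region: str
    segment: int = 0


def barycenter(segment: Recording, grid: ElectrodeGrid, region: str,
               segment_index: int = 0) -> BarycenterPoint:
    """RMS-weighted centroid of one region's electrode coordinates."""
    chans = grid.channels_in_region(region)
    rms = np.sqrt(np.mean(segment.signal[:, [c - 1 for c in chans]] ** 2,
                          axis=0))
    total = rms.sum()
    if total <= 0:
        raise ValueError(f"all-zero RMS in region {region!r}; "
                         "barycenter undefined")
    pts = grid.positions(chans)
    bx, by = (rms @ pts) / total
    return BarycenterPoint(float(bx), float(by), region, segment_index)


def barycenter_series(window: Recording, grid: ElectrodeGrid, region: str,
                      n_segments: int = N_DOS_SEGMENTS) -> list[BarycenterPoint]:
    """Barycenter per segment of the same 15-segment window used for DOS,
    yielding the scatter points the confidence ellipse summarizes."""
    n = window.n_samples
    edges = np.linspace(0, n, n_segments + 1).round().astype(int)
    return [barycenter(window.with_signal(window.signal[edges[k]:edges[k + 1]]),
                       grid, region, segment_index=k)
            for k in range(n_segments)]


@dataclass
class ConfidenceEllipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]       # major, minor
    orientation_rad: float               # major-axis angle from +x
    level: float
    covariance: np.ndarray = field(repr=False, default=None)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: Mahalanobis distance within the chi-square bound."""
        points = np.atleast_2d(points)
        q = chi2.ppf(self.level, df=2)
        diff = points - np.asarray(self.center)
        md2 = np.einsum("ij,jk,ik->i", diff,
                        np.linalg.inv(self.covariance), diff)
        return md2 <= q


def chi2_quantile(level: float = 0.95, df: int = 2) -> float:
    """Critical value scaling the ellipse axes (about 5.991 at 95%, 2 dof)."""
    return float(chi2.ppf(level, df=df))


def confidence_ellipse(points: np.ndarray,
                       level: float = 0.95) -> ConfidenceEllipse:
    """Covariance-eigendecomposition confidence ellipse of a 2-D scatter.

    Center = sample mean; axis directions = covariance eigenvectors;
    semi-axis lengths = sqrt(chi2_quantile(level, 2) * eigenvalue).
    Requires at least 3 non-collinear points.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 0 or not np.isfinite(eigvals).all():
        raise ValueError("singular covariance; ellipse degenerate")
    q = chi2_quantile(level)
    order = np.argsort(eigvals)[::-1]                 # major first
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    major = eigvecs[:, 0]
    if major[0] < 0 or (major[0] == 0 and major[1] < 0):
        major = -major                                # tie broken toward +x
    return ConfidenceEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(np.sqrt(q * eigvals[0])),
                   float(np.sqrt(q * eigvals[1]))),
        orientation_rad=float(np.arctan2(major[1], major[0])),
        level=level, covariance=cov)
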