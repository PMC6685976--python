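"""Automated detection of Ca2+ flickers in TIRF movies.

The chain: per-pixel F/F0 ratio (camera black level subtracted, baseline
from the first ~100 frames) → zero-phase temporal high-pass Butterworth
(removes drift and bleaching) → division by each pixel's baseline
standard deviation, so the noise of the "normalized" movie is ~N(0, 1)
→ per-frame Gaussian smoothing and thresholding → density-peak
clustering of supra-threshold voxels (see :mod:`flickermap.cluster`) →
subpixel localization by fitting a symmetric 2D Gaussian to the
cluster-duration mean image.

Because the chain divides by F0 and by the baseline noise, detection is
invariant to multiplying the raw movie by any positive gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .cluster import (
    ClusterEvent,
    VoxelStats,
    assign_clusters,
    compute_density_delta,
    pick_cluster_centers,
)
from .config import RunConfig
from .errors import DegenerateInputError, ParameterError
from .gaussfit import GaussianFit, fit_gaussian_2d
from .io_ import Movie

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMovie",
    "DetectionParams",
    "FlickerEvent",
    "DetectionResult",
    "compute_ratio_movie",
    "temporal_highpass",
    "normalize_variance",
    "make_binary_volume",
    "localize_event",
    "detect_flickers",
]

_F0_EPS = 1e-6  # counts; F0 at or below this is indistinguishable from zero


@dataclass
class NormalizedMovie:
    """Unit-variance z-score movie plus provenance of the steps applied."""

    data: np.ndarray
    baseline_frames: int
    frame_interval: float
    pixel_size: float
    valid: np.ndarray
    provenance: list = field(default_factory=list)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class DetectionParams:
    """All tunables of the flicker-detection chain (see config docstrings)."""

    baseline_frames: int = 100
    butterworth_cutoff: float = 0.1
    butterworth_order: int = 2
    spatial_sigma: float = 1.0
    z_threshold: float = 3.0
    radii: tuple[float, float, float] = (3.0, 2.0, 2.0)  # (r_t, r_y, r_x)
    rho_min: float = 8.0
    delta_min: float = 2.0
    min_cluster_size: int = 4
    fit_window: int = 5

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "DetectionParams":
        p, c, l = cfg.preprocessing, cfg.clustering, cfg.localization
        return cls(
            baseline_frames=p.baseline_frames,
            butterworth_cutoff=p.butterworth_cutoff,
            butterworth_order=p.butterworth_order,
            spatial_sigma=c.spatial_sigma,
            z_threshold=c.z_threshold,
            radii=(c.radius_t, c.radius_y, c.radius_x),
            rho_min=c.rho_min,
            delta_min=c.delta_min,
            min_cluster_size=c.min_cluster_size,
            fit_window=l.fit_window,
        )


@dataclass
class FlickerEvent:
    """One detected flicker with subpixel centroid and amplitude metrics.

    The centroid comes from a symmetric 2D Gaussian fit to the mean of the
    normalized movie over the event duration; ``peak_amplitude`` is the
    maximum dF/F0 (site-ROI mean of the ratio movie minus 1) within the
    event interval, so amplitudes are comparable to raw ratio traces.
    """

    cluster: ClusterEvent
    x: float
    y: float
    x_um: float
    y_um: float
    duration: float
    fit: GaussianFit
    peak_amplitude: float = float("nan")

    @property
    def t_start(self) -> int:
        return self.cluster.t_start

    @property
    def t_end(self) -> int:
        return self.cluster.t_end

    @property
    def n_voxels(self) -> int:
        return self.cluster.n_voxels

    @property
    def fit_sigma(self) -> float:
        return self.fit.sigma

    @property
    def fit_ok(self) -> bool:
        return self.fit.ok


@dataclass
class DetectionResult:
    """Full output of :func:`detect_flickers`."""

    events: list[FlickerEvent]
    voxel_stats: VoxelStats
    ratio: Movie
    normalized: NormalizedMovie
    site_traces: list[np.ndarray] = field(default_factory=list)


def compute_ratio_movie(movie: Movie, baseline_frames: int) -> Movie:
    """F/F0 ratio movie: black level subtracted, per-pixel baseline division.

    F0(y, x) is the mean of (F - black) over the first ``baseline_frames``
    frames; pixels with F0 <= eps are flagged invalid (their ratio is set
    to 1.0 so downstream filters stay finite) and stay invalid downstream.
    """
    if baseline_frames < 2:
        raise ParameterError(f"baseline_frames must be >= 2, got {baseline_frames}")
    if baseline_frames > movie.n_frames:
        raise ParameterError(
            f"baseline_frames={baseline_frames} exceeds movie length {movie.n_frames}"
        )
    f = movie.data.astype(float) - movie.black_level
    f0 = f[:baseline_frames].mean(axis=0)
    valid = movie.valid_mask() & (f0 > _F0_EPS)
    if not valid.any():
        raise DegenerateInputError(
            "every pixel has baseline fluorescence at or below the black level"
        )
    safe_f0 = np.where(valid, f0, 1.0)
    ratio = f / safe_f0
    ratio[:, ~valid] = 1.0
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("%d pixel(s) flagged invalid (F0 <= %g counts)", n_bad, _F0_EPS)
    return movie.with_data(ratio, valid=valid)


def temporal_highpass(ratio: Movie, cutoff: float, order: int = 2) -> Movie:
    """Zero-phase high-pass Butterworth along time, per pixel.

    Applied forward-backward (sosfiltfilt) so event onsets are not
    shifted in time; the DC component (and slow drift/bleaching below
    ``cutoff`` Hz) is removed.
    """
    fs = 1.0 / ratio.frame_interval
    nyq = fs / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(
            f"cutoff must be in (0, Nyquist={nyq:.4g} Hz), got {cutoff}"
        )
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    # sosfiltfilt needs a few times the filter order worth of samples
    min_frames = 3 * (2 * order + 1)
    if ratio.n_frames < min_frames:
        raise ParameterError(
            f"movie too short for order-{order} zero-phase filtering "
            f"({ratio.n_frames} < {min_frames} frames)"
        )
    out = signal.sosfiltfilt(sos, ratio.data, axis=0)
    return ratio.with_data(out)


def normalize_variance(highpassed: Movie, baseline_frames: int) -> NormalizedMovie:
    """Divide each pixel trace by its own baseline standard deviation.

    After this step pure noise is ~N(0, 1) per pixel over the baseline.
    Pixels with zero baseline std are flagged invalid, not fatal.
    """
    if baseline_frames < 2 or baseline_frames > highpassed.n_frames:
        raise ParameterError(
            f"baseline_frames must be in [2, {highpassed.n_frames}], got {baseline_frames}"
        )
    std = highpassed.data[:baseline_frames].std(axis=0, ddof=1)
    valid = highpassed.valid_mask() & (std > 0)
    safe = np.where(valid, std, 1.0)
    data = highpassed.data / safe
    data[:, ~valid] = 0.0
    return NormalizedMovie(
        data=data,
        baseline_frames=baseline_frames,
        frame_interval=highpassed.frame_interval,
        pixel_size=highpassed.pixel_size,
        valid=valid,
        provenance=[("normalize_variance", {"baseline_frames": baseline_frames})],
    )


def make_binary_volume(
    normalized: NormalizedMovie, spatial_sigma: float, z_threshold: float
) -> np.ndarray:
    """Gaussian-smooth each frame, then threshold: True where z > threshold.

    Invalid pixels are always False. An all-false volume is a legitimate
    "no events" outcome, not an error.
    """
    if z_threshold <= 0:
        raise ParameterError(f"z_threshold must be > 0, got {z_threshold}")
    if spatial_sigma <= 0:
        raise ParameterError(f"spatial_sigma must be > 0, got {spatial_sigma}")
    smoothed = ndimage.gaussian_filter(
        normalized.data, sigma=(0.0, spatial_sigma, spatial_sigma)
    )
    vol = smoothed > z_threshold
    vol[:, ~normalized.valid] = False
    return vol


def localize_event(
    normalized: NormalizedMovie, cluster: ClusterEvent, fit_window: int = 5
) -> FlickerEvent:
    """Subpixel centroid of one clustered event.

    The normalized movie is averaged over [t_start, t_end] and a
    symmetric 2D Gaussian is least-squares-fitted in a window of
    half-width ``fit_window`` px around the cluster footprint's center of
    mass. On fit failure (or a center escaping the window) the centroid
    falls back to the center of mass and ``fit_ok`` is False.
    """
    if cluster.n_voxels == 0:
        raise ParameterError("cannot localize an empty cluster")
    mean_img = normalized.data[cluster.t_start : cluster.t_end + 1].mean(axis=0)
    h, w = mean_img.shape
    com_x, com_y = cluster.footprint_com()
    cx, cy = int(round(com_x)), int(round(com_y))
    x0 = max(0, cx - fit_window)
    x1 = min(w, cx + fit_window + 1)
    y0 = max(0, cy - fit_window)
    y1 = min(h, cy + fit_window + 1)
    if (x1 - x0) < 2 * fit_window + 1 or (y1 - y0) < 2 * fit_window + 1:
        logger.warning(
            "fit window clipped at image border for cluster at (%d, %d)", cx, cy
        )
    window = mean_img[y0:y1, x0:x1]
    fit = fit_gaussian_2d(
        window, x_offset=x0, y_offset=y0, init_xy=(com_x, com_y), init_sigma=1.5
    )
    if fit.ok:
        x, y = fit.x0, fit.y0
    else:
        x, y = com_x, com_y
    duration = (cluster.t_end - cluster.t_start + 1) * normalized.frame_interval
    return FlickerEvent(
        cluster=cluster,
        x=x,
        y=y,
        x_um=x * normalized.pixel_size,
        y_um=y * normalized.pixel_size,
        duration=duration,
        fit=fit,
    )


def _site_trace(ratio: Movie, x: float, y: float) -> np.ndarray:
    """Mean dF/F0+1 trace of the 3x3 px ROI centered at the (rounded) site."""
    h, w = ratio.data.shape[1:]
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = max(0, cx - 1), min(w, cx + 2)
    y0, y1 = max(0, cy - 1), min(h, cy + 2)
    roi = ratio.data[:, y0:y1, x0:x1]
    v = ratio.valid_mask()[y0:y1, x0:x1]
    if v.any():
        return roi[:, v].mean(axis=1)
    return roi.reshape(ratio.n_frames, -1).mean(axis=1)


def detect_flickers(movie: Movie, params: DetectionParams | None = None) -> DetectionResult:
    """Run the full flicker-detection chain on a raw movie.

    Returns the detected events (with site dF/F0 traces and peak
    amplitudes read off the ratio movie), plus the rho-delta decision
    table so the center thresholds can also be chosen by eye.
    """
    params = params or DetectionParams()
    ratio = compute_ratio_movie(movie, params.baseline_frames)
    hp = temporal_highpass(ratio, params.butterworth_cutoff, params.butterworth_order)
    norm = normalize_variance(hp, params.baseline_frames)
    volume = make_binary_volume(norm, params.spatial_sigma, params.z_threshold)
    stats = compute_density_delta(volume, params.radii)
    centers = pick_cluster_centers(stats, params.rho_min, params.delta_min)
    clusters = assign_clusters(stats, centers, params.min_cluster_size)
    events = [localize_event(norm, c, params.fit_window) for c in clusters]
    traces = []
    for ev in events:
        trace = _site_trace(ratio, ev.x, ev.y)
        seg = trace[ev.t_start : ev.t_end + 1]
        ev.peak_amplitude = float(seg.max() - 1.0) if len(seg) else float("nan")
        traces.append(trace)
    logger.info("detected %d flicker event(s) from %d supra-threshold voxel(s)",
                len(events), stats.n)
    return DetectionResult(
        events=events, voxel_stats=stats, ratio=ratio, normalized=norm,
        site_traces=traces,
    )
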