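"""Single-particle tracking of channel puncta and diffusion estimation.

Each frame is band-pass filtered with a difference of Gaussians (DoG)
tuned to the puncta size; contiguous supra-threshold pixels form
candidate particles, each refined to subpixel precision with a symmetric
2D Gaussian fit initialized at the blob's binary center of mass.
Localizations in consecutive frames within ``max_link_dist`` pixels
(default 3) are linked greedily in ascending distance order — no gap
closing, no motion model. The ensemble mean-squared displacement over
all tracks and start times is fit with a straight line over the first
few lags; for 2D Brownian motion MSD = 4*D*tau, so D = slope / 4. The
intercept is retained because static localization error adds a
lag-independent offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .config import TrackingParams
from .errors import DegenerateInputError, ParameterError
from .gaussfit import fit_gaussian_2d
from .io_ import Movie

logger = logging.getLogger(__name__)

__all__ = [
    "Localization",
    "Track",
    "MSDResult",
    "dog_detect",
    "detect_movie",
    "link_tracks",
    "ensemble_msd",
    "fit_diffusion",
    "track_movie",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class Localization:
    frame: int
    x: float
    y: float
    n_pixels: int
    fit_ok: bool


@dataclass
class Track:
    """Linked localizations with strictly consecutive frames."""

    id: int
    frames: np.ndarray
    x: np.ndarray  # px
    y: np.ndarray  # px

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MSDResult:
    lags: np.ndarray  # seconds
    msd: np.ndarray  # um^2
    sem: np.ndarray  # um^2
    n_pairs: np.ndarray
    D: float | None = None  # um^2/s
    intercept: float | None = None  # um^2
    r_squared: float | None = None
    fit_lags: int = 0
    n_tracks: int = 0


def robust_noise_sigma(image: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * median absolute deviation."""
    img = np.asarray(image, dtype=float)
    return float(1.4826 * np.median(np.abs(img - np.median(img))))


def dog_detect(
    frame: np.ndarray,
    sigma_small: float = 1.0,
    sigma_large: float = 3.0,
    threshold: float | None = None,
    min_pixels: int = 3,
    threshold_nsigma: float = 5.0,
    fit_halfwidth: int = 4,
    frame_index: int = 0,
) -> list[Localization]:
    """Detect puncta in one frame via DoG filtering + Gaussian refinement.

    ``threshold`` is in DoG-image counts; ``None`` uses
    ``threshold_nsigma`` times the robust noise sigma of the DoG image.
    Connected components (8-connectivity) with >= ``min_pixels`` pixels
    become particles; the Gaussian fit runs on the DoG image in a window
    around each blob's center of mass (background is already removed by
    the band-pass, so the fit offset only absorbs residuals).
    """
    if not sigma_small < sigma_large:
        raise ParameterError("sigma_small must be < sigma_large")
    img = np.asarray(frame, dtype=float)
    dog = ndimage.gaussian_filter(img, sigma_small) - ndimage.gaussian_filter(
        img, sigma_large
    )
    if threshold is None:
        threshold = threshold_nsigma * robust_noise_sigma(dog)
    if threshold <= 0:
        raise ParameterError(f"threshold must be > 0, got {threshold}")
    binary = dog > threshold
    labels, n_blobs = ndimage.label(binary, structure=_EIGHT_CONN)
    if n_blobs == 0:
        return []
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n_blobs + 1))
    coms = ndimage.center_of_mass(binary, labels, index=np.arange(1, n_blobs + 1))
    h, w = img.shape
    out: list[Localization] = []
    for size, (cy, cx) in zip(sizes, coms):
        if size < min_pixels:
            continue
        icx, icy = int(round(cx)), int(round(cy))
        x0, x1 = max(0, icx - fit_halfwidth), min(w, icx + fit_halfwidth + 1)
        y0, y1 = max(0, icy - fit_halfwidth), min(h, icy + fit_halfwidth + 1)
        fit = fit_gaussian_2d(
            dog[y0:y1, x0:x1], x_offset=x0, y_offset=y0, init_xy=(cx, cy), init_sigma=sigma_small
        )
        x, y = (fit.x0, fit.y0) if fit.ok else (cx, cy)
        x = float(np.clip(x, 0, w - 1))
        y = float(np.clip(y, 0, h - 1))
        out.append(
            Localization(frame=frame_index, x=x, y=y, n_pixels=int(size), fit_ok=fit.ok)
        )
    return out


def detect_movie(movie: Movie, params: TrackingParams | None = None) -> list[list[Localization]]:
    """Run :func:`dog_detect` on every frame; returns per-frame lists."""
    params = params or TrackingParams()
    return [
        dog_detect(
            movie.data[t],
            sigma_small=params.sigma_small,
            sigma_large=params.sigma_large,
            threshold=params.threshold,
            min_pixels=params.min_pixels,
            threshold_nsigma=params.threshold_nsigma,
            frame_index=t,
        )
        for t in range(movie.n_frames)
    ]


def link_tracks(
    locs_per_frame: list[list[Localization]], max_link_dist: float = 3.0
) -> list[Track]:
    """Greedy nearest-neighbor linking between consecutive frames only.

    Candidate pairs within ``max_link_dist`` px are matched in ascending
    distance order (ties broken by the previous then current
    localization's (y, x)); each localization is used at most once;
    unmatched localizations start new tracks. No gap closing.
    """
    if max_link_dist <= 0:
        raise ParameterError("max_link_dist must be > 0")
    tracks: list[list[Localization]] = []
    active: dict[int, int] = {}  # index into prev frame's locs -> track index
    prev: list[Localization] = []
    for locs in locs_per_frame:
        links: dict[int, int] = {}  # cur idx -> prev idx
        if prev and locs:
            cands = []
            for i, a in enumerate(prev):
                for j, b in enumerate(locs):
                    d = float(np.hypot(a.x - b.x, a.y - b.y))
                    if d <= max_link_dist:
                        cands.append((d, a.y, a.x, b.y, b.x, i, j))
            used_prev: set[int] = set()
            used_cur: set[int] = set()
            for d, _, _, _, _, i, j in sorted(cands):
                if i in used_prev or j in used_cur:
                    continue
                used_prev.add(i)
                used_cur.add(j)
                links[j] = i
        new_active: dict[int, int] = {}
        for j, loc in enumerate(locs):
            if j in links and links[j] in active:
                ti = active[links[j]]
                tracks[ti].append(loc)
            else:
                ti = len(tracks)
                tracks.append([loc])
            new_active[j] = ti
        active = new_active
        prev = locs
    out = []
    for tid, locs in enumerate(tracks):
        out.append(
            Track(
                id=tid,
                frames=np.array([l.frame for l in locs], dtype=int),
                x=np.array([l.x for l in locs], dtype=float),
                y=np.array([l.y for l in locs], dtype=float),
            )
        )
    return out


def ensemble_msd(
    tracks: list[Track],
    pixel_size: float,
    frame_interval: float,
    max_lag: int = 20,
    overlapping: bool = True,
) -> MSDResult:
    """Ensemble MSD over all tracks and start times.

    MSD(k*dt) averages |r(t + k*dt) - r(t)|^2 in um^2 over every
    displacement pair at lag k from every track; the SEM is taken over
    all contributing pairs. By default start times overlap (all pairs);
    ``overlapping=False`` restricts lag-k pairs to start times spaced k
    frames apart (independent displacements).
    """
    usable = [t for t in tracks if len(t) >= 2]
    if not usable:
        raise DegenerateInputError("no track of length >= 2 to compute an MSD from")
    if max_lag < 1:
        raise ParameterError("max_lag must be >= 1")
    sums = np.zeros(max_lag)
    sq_sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for tr in usable:
        x = tr.x * pixel_size
        y = tr.y * pixel_size
        n = len(tr)
        for k in range(1, min(max_lag, n - 1) + 1):
            dx = x[k:] - x[:-k]
            dy = y[k:] - y[:-k]
            if not overlapping:
                dx = dx[::k]
                dy = dy[::k]
            sq = dx**2 + dy**2
            sums[k - 1] += sq.sum()
            sq_sums[k - 1] += (sq**2).sum()
            counts[k - 1] += len(sq)
    have = counts > 0
    lags = (np.arange(1, max_lag + 1) * frame_interval)[have]
    n_pairs = counts[have]
    msd = sums[have] / n_pairs
    var = np.maximum(sq_sums[have] / n_pairs - msd**2, 0.0)
    sem = np.sqrt(var / n_pairs)
    return MSDResult(lags=lags, msd=msd, sem=sem, n_pairs=n_pairs, n_tracks=len(usable))


def fit_diffusion(msd: MSDResult, fit_lags: int = 10) -> MSDResult:
    """OLS line through the first ``fit_lags`` (lag, MSD) points; D = slope/4.

    The intercept absorbs the static localization-error offset; R^2 of
    the fit is reported alongside.
    """
    if fit_lags < 2:
        raise ParameterError("fit_lags must be >= 2")
    if fit_lags > len(msd.lags):
        raise ParameterError(
            f"fit_lags={fit_lags} exceeds available lags ({len(msd.lags)})"
        )
    res = stats.linregress(msd.lags[:fit_lags], msd.msd[:fit_lags])
    msd.D = float(res.slope / 4.0)
    msd.intercept = float(res.intercept)
    msd.r_squared = float(res.rvalue**2)
    msd.fit_lags = fit_lags
    return msd


def track_movie(movie: Movie, params: TrackingParams | None = None) -> tuple[list[Track], MSDResult]:
    """Full pipeline: detect -> link -> ensemble MSD -> diffusion fit."""
    params = params or TrackingParams()
    locs = detect_movie(movie, params)
    tracks = link_tracks(locs, params.max_link_dist)
    msd = ensemble_msd(tracks, movie.pixel_size, movie.frame_interval, params.max_lag)
    return tracks, fit_diffusion(msd, min(params.fit_lags, len(msd.lags)))
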