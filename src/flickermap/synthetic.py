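"""Seeded synthetic-data generators with ground-truth manifests.

Every pipeline in the package can be exercised end-to-end on data whose
truth is known: TIRF-like flicker movies (stationary baseline, transient
local Gaussian-profile events with instant rise and exponential decay,
camera black level, Gaussian noise, optional slow drift), Brownian
puncta movies at the tracking rig's acquisition constants (0.1 s/frame,
0.16 um/px), and donor/acceptor FRET pairs inverted from a ground-truth
force map through the same index/efficiency/force equations the analysis
uses. All generators are bit-reproducible given (params, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeneratorError, ParameterError
from .fret import FretCalibration, FretPair
from .io_ import CellMask, Movie

__all__ = [
    "FlickerEventSpec",
    "FlickerMovieParams",
    "FlickerTruth",
    "DiffusionMovieParams",
    "TrackTruth",
    "ForceSceneParams",
    "ForceTruth",
    "generate_flicker_movie",
    "generate_diffusion_movie",
    "generate_force_scene",
    "generate_fret_pair",
    "synthetic_force_curve",
]

# Acquisition constants of the flicker imaging rig (frames/s) and the
# puncta-tracking rig (s/frame, um/px).
FLICKER_FPS = 9.54
TRACKING_FRAME_INTERVAL = 0.1
TRACKING_PIXEL_SIZE = 0.16


# --------------------------------------------------------------------------
# flicker movies
# --------------------------------------------------------------------------

@dataclass
class FlickerEventSpec:
    """Ground truth for one implanted flicker."""

    t_start: int
    duration: int  # frames the event is active
    x: float  # subpixel, px
    y: float
    peak_dff: float  # peak dF/F0
    sigma: float = 1.5  # spatial width, px
    tau: float = 0.3  # decay time constant, s


@dataclass
class FlickerMovieParams:
    """Defaults: a 200-frame 128x128 movie at the imaging frame rate.

    ``noise_sigma`` is the camera noise in counts; with baseline 500
    counts the ratio-movie noise is noise_sigma / f0 = 4%, so an event of
    peak dF/F0 = a has peak z ~ a * f0 / noise_sigma after variance
    normalization.
    """

    n_frames: int = 200
    height: int = 128
    width: int = 128
    frame_interval: float = 1.0 / FLICKER_FPS
    pixel_size: float = 0.1  # um/px
    black_level: float = 100.0
    f0: float = 500.0  # baseline counts above black
    noise_sigma: float = 20.0
    drift: str = "none"  # 'none' | 'linear' | 'exponential'
    drift_amplitude: float = 0.0  # fractional change over the movie
    poisson_noise: bool = False

    def peak_dff_for_z(self, z: float) -> float:
        """dF/F0 amplitude producing approximately peak z-score ``z``."""
        return z * self.noise_sigma / self.f0

    def validate(self) -> None:
        if self.n_frames < 1 or self.height < 1 or self.width < 1:
            raise ParameterError("movie dimensions must be positive")
        if self.f0 <= 0:
            raise ParameterError("f0 must be > 0")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.drift not in ("none", "linear", "exponential"):
            raise ParameterError(f"unknown drift model {self.drift!r}")


@dataclass
class FlickerTruth:
    """Manifest for a generated flicker movie."""

    events: list[FlickerEventSpec]
    params: FlickerMovieParams
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t_start": e.t_start,
                    "duration": e.duration,
                    "x": e.x,
                    "y": e.y,
                    "peak_dff": e.peak_dff,
                    "sigma": e.sigma,
                    "tau": e.tau,
                }
                for e in self.events
            ],
            columns=["t_start", "duration", "x", "y", "peak_dff", "sigma", "tau"],
        )

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(f"{prefix}events_truth.csv", index=False)
        meta = dataclasses.asdict(self.params)
        meta["seed"] = self.seed
        Path(f"{prefix}params.json").write_text(json.dumps(meta, indent=1))


def _render_flicker_events(
    params: FlickerMovieParams, events: list[FlickerEventSpec]
) -> np.ndarray:
    """Sum of event dF/F0 contributions, shape (T, H, W)."""
    dff = np.zeros((params.n_frames, params.height, params.width))
    yy, xx = np.mgrid[0 : params.height, 0 : params.width]
    for e in events:
        if not (0 <= e.x < params.width and 0 <= e.y < params.height):
            raise GeneratorError(f"event at ({e.x}, {e.y}) outside the field")
        t_end = e.t_start + e.duration
        if e.t_start < 0 or t_end > params.n_frames:
            raise GeneratorError(
                f"event frames [{e.t_start}, {t_end}) outside the movie"
            )
        spatial = np.exp(-((xx - e.x) ** 2 + (yy - e.y) ** 2) / (2 * e.sigma**2))
        t = np.arange(e.duration) * params.frame_interval
        kernel = e.peak_dff * np.exp(-t / e.tau)  # instant rise, exp decay
        dff[e.t_start : t_end] += kernel[:, None, None] * spatial
    return dff


def random_flicker_events(
    params: FlickerMovieParams,
    n_events: int,
    peak_z: float | tuple[float, float] = (8.0, 15.0),
    duration: int = 8,
    seed: int = 0,
    min_separation_px: float = 16.0,
    margin_px: float = 10.0,
) -> list[FlickerEventSpec]:
    """Draw non-overlapping event specs after the baseline window.

    Event start times avoid the first ``baseline-ish`` stretch (drawn in
    the second half of the movie by default is too restrictive; events
    start anywhere after frame 110 of the default 200-frame movie so the
    100-frame baseline stays clean). Positions keep a minimum pairwise
    spacing so ground-truth matching is unambiguous.
    """
    rng = np.random.default_rng(seed)
    t_lo = min(110, params.n_frames - duration)
    t_hi = params.n_frames - duration
    if t_hi < t_lo:
        raise GeneratorError("movie too short for the requested events")
    events: list[FlickerEventSpec] = []
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(events) < n_events:
        attempts += 1
        if attempts > 1000 * n_events:
            raise GeneratorError("could not place events with the requested spacing")
        x = rng.uniform(margin_px, params.width - 1 - margin_px)
        y = rng.uniform(margin_px, params.height - 1 - margin_px)
        if any((x - px) ** 2 + (y - py) ** 2 < min_separation_px**2 for px, py in placed):
            continue
        if isinstance(peak_z, tuple):
            z = rng.uniform(*peak_z)
        else:
            z = float(peak_z)
        t0 = int(rng.integers(t_lo, t_hi + 1))
        events.append(
            FlickerEventSpec(
                t_start=t0,
                duration=duration,
                x=x,
                y=y,
                peak_dff=params.peak_dff_for_z(z),
            )
        )
        placed.append((x, y))
    return events


def generate_flicker_movie(
    params: FlickerMovieParams | None = None,
    events: list[FlickerEventSpec] | None = None,
    seed: int = 0,
) -> tuple[Movie, FlickerTruth]:
    """Render a flicker movie: black + F0 * drift * (1 + sum events) + noise."""
    params = params or FlickerMovieParams()
    params.validate()
    events = events or []
    rng = np.random.default_rng(seed)
    dff = _render_flicker_events(params, events)
    t = np.arange(params.n_frames) / max(params.n_frames - 1, 1)
    if params.drift == "linear":
        drift = 1.0 + params.drift_amplitude * t
    elif params.drift == "exponential":
        drift = np.exp(np.log1p(params.drift_amplitude) * t)
    else:
        drift = np.ones_like(t)
    signal = params.f0 * drift[:, None, None] * (1.0 + dff)
    if params.poisson_noise:
        data = params.black_level + rng.poisson(signal).astype(float)
    else:
        data = params.black_level + signal
    if params.noise_sigma > 0:
        data = data + rng.normal(0.0, params.noise_sigma, size=data.shape)
    movie = Movie(
        data=data,
        frame_interval=params.frame_interval,
        pixel_size=params.pixel_size,
        black_level=params.black_level,
    )
    return movie, FlickerTruth(events=events, params=params, seed=seed)


# --------------------------------------------------------------------------
# Brownian puncta movies
# --------------------------------------------------------------------------

@dataclass
class DiffusionMovieParams:
    """Brownian puncta rendered as Gaussian PSFs.

    Acquisition constants default to the tracking rig (0.1 s/frame,
    0.16 um/px); the default ground-truth mobility is D = 0.067 um^2/s.
    ``snr`` is the PSF peak amplitude over the noise sigma.
    """

    n_particles: int = 40
    n_frames: int = 50
    height: int = 256
    width: int = 256
    frame_interval: float = TRACKING_FRAME_INTERVAL
    pixel_size: float = TRACKING_PIXEL_SIZE
    d_true: float = 0.067  # um^2/s
    psf_sigma: float = 1.3  # px
    snr: float = 10.0
    noise_sigma: float = 10.0  # counts
    background: float = 100.0
    margin_px: float = 8.0
    min_spacing_factor: float = 4.0  # min initial spacing in PSF sigmas

    def validate(self) -> None:
        if self.d_true < 0:
            raise ParameterError("d_true must be >= 0")
        if self.psf_sigma <= 0 or self.snr <= 0:
            raise ParameterError("psf_sigma and snr must be > 0")


@dataclass
class TrackTruth:
    """True per-particle trajectories (px) and the generator parameters."""

    tracks: list[dict]  # each: {'id', 'frames', 'x', 'y'} in px
    params: DiffusionMovieParams
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for f, x, y in zip(tr["frames"], tr["x"], tr["y"]):
                rows.append({"track_id": tr["id"], "frame": int(f), "x": x, "y": y})
        return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])

    def all_steps_px(self) -> np.ndarray:
        """Per-axis Brownian steps pooled over particles, in px."""
        steps = []
        for tr in self.tracks:
            if len(tr["x"]) >= 2:
                steps.append(np.diff(tr["x"]))
                steps.append(np.diff(tr["y"]))
        return np.concatenate(steps) if steps else np.zeros(0)

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(f"{prefix}tracks_truth.csv", index=False)
        meta = dataclasses.asdict(self.params)
        meta["seed"] = self.seed
        Path(f"{prefix}params.json").write_text(json.dumps(meta, indent=1))


def _initial_positions(params: DiffusionMovieParams, rng: np.random.Generator) -> np.ndarray:
    """Uniform initial positions with minimum pairwise spacing."""
    min_d = params.min_spacing_factor * params.psf_sigma
    pos = []
    attempts = 0
    while len(pos) < params.n_particles:
        attempts += 1
        if attempts > 2000 * params.n_particles:
            raise GeneratorError(
                "cannot place particles with the requested spacing; lower "
                "n_particles or min_spacing_factor"
            )
        p = rng.uniform(
            [params.margin_px, params.margin_px],
            [params.width - 1 - params.margin_px, params.height - 1 - params.margin_px],
        )
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_d**2 for q in pos):
            pos.append(p)
    return np.array(pos)  # (n, 2) of (x, y)


def _render_psf_frame(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitude: float,
    sigma: float,
) -> np.ndarray:
    """Sum of Gaussian PSFs at subpixel positions (windowed for speed)."""
    h, w = shape
    img = np.zeros((h, w))
    half = int(np.ceil(4 * sigma))
    for x, y in positions:
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
        )
    return img


def generate_diffusion_movie(
    params: DiffusionMovieParams | None = None,
    seed: int = 0,
) -> tuple[Movie, TrackTruth]:
    """Simulate Brownian puncta and render them with noise.

    Per-axis steps are i.i.d. N(0, 2*D*dt) in um (converted to px for
    rendering). A particle whose true position leaves the field is
    terminated: its manifest track ends and it is no longer rendered.
    """
    params = params or DiffusionMovieParams()
    params.validate()
    rng = np.random.default_rng(seed)
    step_sigma_px = np.sqrt(2 * params.d_true * params.frame_interval) / params.pixel_size
    pos = _initial_positions(params, rng)  # (n, 2)
    alive = np.ones(params.n_particles, dtype=bool)
    tracks = [
        {"id": i, "frames": [0], "x": [pos[i, 0]], "y": [pos[i, 1]]}
        for i in range(params.n_particles)
    ]
    amplitude = params.snr * params.noise_sigma
    frames = np.empty((params.n_frames, params.height, params.width))
    frames[0] = _render_psf_frame(
        (params.height, params.width), pos[alive], amplitude, params.psf_sigma
    )
    for t in range(1, params.n_frames):
        steps = rng.normal(0.0, step_sigma_px, size=pos.shape)
        pos = pos + np.where(alive[:, None], steps, 0.0)
        out = (
            (pos[:, 0] < 0)
            | (pos[:, 0] > params.width - 1)
            | (pos[:, 1] < 0)
            | (pos[:, 1] > params.height - 1)
        )
        alive &= ~out
        for i in np.flatnonzero(alive):
            tracks[i]["frames"].append(t)
            tracks[i]["x"].append(pos[i, 0])
            tracks[i]["y"].append(pos[i, 1])
        frames[t] = _render_psf_frame(
            (params.height, params.width), pos[alive], amplitude, params.psf_sigma
        )
    data = params.background + frames
    if params.noise_sigma > 0:
        data = data + rng.normal(0.0, params.noise_sigma, size=data.shape)
    movie = Movie(
        data=data,
        frame_interval=params.frame_interval,
        pixel_size=params.pixel_size,
    )
    for tr in tracks:
        tr["frames"] = np.array(tr["frames"], dtype=int)
        tr["x"] = np.array(tr["x"])
        tr["y"] = np.array(tr["y"])
    return movie, TrackTruth(tracks=tracks, params=params, seed=seed)


# --------------------------------------------------------------------------
# FRET pairs
# --------------------------------------------------------------------------

def synthetic_force_curve(
    max_force: float = 12.0,
    e_min: float = 0.05,
    e_max: float = 0.95,
    n_knots: int = 19,
) -> np.ndarray:
    """SYNTHETIC, non-physical efficiency->force table for testing only.

    Force decreases linearly from ``max_force`` pN at ``e_min`` to 0 at
    ``e_max``; it stands in for a real tension-sensor calibration curve
    solely so the force-map chain can be exercised with known truth.
    """
    eff = np.linspace(e_min, e_max, n_knots)
    force = max_force * (e_max - eff) / (e_max - e_min)
    return np.column_stack([eff, force])


@dataclass
class ForceSceneParams:
    """A cell with force hotspots near its periphery (adhesion-like)."""

    height: int = 128
    width: int = 128
    pixel_size: float = 0.1  # um/px
    cell_radius_px: float = 50.0
    n_hotspots: int = 6
    hotspot_sigma_px: float = 4.0
    hotspot_force: float = 8.0  # pN
    baseline_force: float = 0.5  # pN


@dataclass
class ForceTruth:
    """Ground-truth force map + the calibration used to invert it."""

    force: np.ndarray  # pN
    cell: CellMask
    calibration: FretCalibration
    hotspot_centers: np.ndarray  # (n, 2) of (x, y) px
    noise_sigma: float
    seed: int


def generate_force_scene(
    params: ForceSceneParams | None = None,
    cal: FretCalibration | None = None,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> ForceTruth:
    """Ground-truth force map: low baseline + Gaussian hotspots near the rim."""
    params = params or ForceSceneParams()
    cal = cal or FretCalibration(force_curve=synthetic_force_curve())
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cell = CellMask(
        mask=(xx - cx) ** 2 + (yy - cy) ** 2 <= params.cell_radius_px**2,
        pixel_size=params.pixel_size,
    )
    angles = rng.uniform(0, 2 * np.pi, size=params.n_hotspots)
    radii = rng.uniform(0.6, 0.85, size=params.n_hotspots) * params.cell_radius_px
    centers = np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
    force = np.full((h, w), params.baseline_force)
    for x0, y0 in centers:
        force += params.hotspot_force * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * params.hotspot_sigma_px**2)
        )
    force[~cell.mask] = params.baseline_force
    fmax = cal.force_curve[:, 1].max()
    force = np.clip(force, cal.force_curve[:, 1].min(), fmax)
    return ForceTruth(
        force=force,
        cell=cell,
        calibration=cal,
        hotspot_centers=centers,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _fret_index_from_efficiency(eff: np.ndarray, cal: FretCalibration) -> np.ndarray:
    """Closed-form inverse of the efficiency equation:
    FRETi = E*alpha*gamma / (1 - E*alpha + E*alpha*gamma)."""
    a, g = cal.alpha, cal.gamma
    return eff * a * g / (1.0 - eff * a + eff * a * g)


def generate_fret_pair(
    truth: ForceTruth,
    total_intensity: float = 1000.0,
    donor_background: float = 50.0,
    acceptor_background: float = 50.0,
    seed: int | None = None,
) -> tuple[FretPair, ForceTruth]:
    """Donor/acceptor images consistent with the ground-truth force map.

    force -> E (inverse calibration curve) -> FRETi (closed-form inverse
    of the efficiency equation) -> (A, D) = total * (FRETi, 1 - FRETi),
    plus backgrounds and Gaussian noise of sigma ``truth.noise_sigma``.
    """
    cal = truth.calibration
    eff = cal.efficiency_from_force(truth.force)
    index = _fret_index_from_efficiency(eff, cal)
    a = total_intensity * index
    d = total_intensity * (1.0 - index)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if truth.noise_sigma > 0:
        a = a + rng.normal(0.0, truth.noise_sigma, size=a.shape)
        d = d + rng.normal(0.0, truth.noise_sigma, size=d.shape)
    pair = FretPair(
        donor=d + donor_background,
        acceptor=a + acceptor_background,
        donor_background=donor_background,
        acceptor_background=acceptor_background,
    )
    return pair, truth
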