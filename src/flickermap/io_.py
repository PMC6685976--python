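"""Core data model and file I/O.

A :class:`Movie` is the unit every pipeline consumes: a (frame, row, col)
stack of fluorescence counts plus the three acquisition numbers the
analysis needs — frame interval, pixel size and camera black level.
TIFF tags are deliberately not trusted for metadata; acquisition software
writes unreliable tags, so metadata always comes from explicit arguments
or the run configuration.

Coordinate convention: 0-based pixel indices, x = column, y = row; a
subpixel localization (x, y) lives on the pixel-center continuum, so the
center of pixel (i, j) is (x=j, y=i). Physical coordinates are pixel
coordinates times ``pixel_size``. Frame k spans [k*dt, (k+1)*dt).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DegenerateInputError, FormatError, ParameterError

__all__ = [
    "Movie",
    "CellMask",
    "load_movie",
    "save_movie",
    "load_mask",
    "save_mask",
    "save_events_table",
    "load_events_table",
    "EVENT_COLUMNS",
]


@dataclass
class Movie:
    """A single-channel fluorescence time-lapse.

    Parameters
    ----------
    data
        3D array (frame, row, col) of fluorescence counts.
    frame_interval
        Seconds per frame.
    pixel_size
        Micrometres per pixel.
    black_level
        Camera offset in counts (added by the sensor, carried no photons).
    valid
        Optional 2D boolean mask of pixels usable downstream; ``None``
        means all pixels are valid.
    """

    data: np.ndarray
    frame_interval: float
    pixel_size: float
    black_level: float = 0.0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"movie data must be 3D (frame, row, col), got ndim={self.data.ndim}"
            )
        if self.data.shape[0] < 1 or self.data.shape[1] < 1 or self.data.shape[2] < 1:
            raise FormatError(f"movie must have >=1 frame and >=1 pixel, got {self.data.shape}")
        if not self.frame_interval > 0:
            raise ParameterError(f"frame_interval must be > 0, got {self.frame_interval}")
        if not self.pixel_size > 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.black_level < 0:
            raise ParameterError(f"black_level must be >= 0, got {self.black_level}")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape[1:]:
                raise FormatError(
                    f"valid mask shape {self.valid.shape} does not match frame shape "
                    f"{self.data.shape[1:]}"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration(self) -> float:
        """Total recording duration in seconds."""
        return self.n_frames * self.frame_interval

    def valid_mask(self) -> np.ndarray:
        """2D boolean mask of valid pixels (all-true if none was set)."""
        if self.valid is None:
            return np.ones(self.data.shape[1:], dtype=bool)
        return self.valid

    def with_data(self, data: np.ndarray, valid: np.ndarray | None = None) -> "Movie":
        """Copy of this movie with new voxel data, metadata preserved."""
        return Movie(
            data=data,
            frame_interval=self.frame_interval,
            pixel_size=self.pixel_size,
            black_level=self.black_level,
            valid=self.valid if valid is None else valid,
        )


@dataclass
class CellMask:
    """Binary mask of the pixels covered by a cell (or cells)."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise FormatError(f"cell mask must be 2D, got ndim={self.mask.ndim}")
        if not self.pixel_size > 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_um2(self) -> float:
        """Mask area in square micrometres."""
        return self.n_pixels * self.pixel_size**2

    def require_nonempty(self) -> None:
        if self.n_pixels == 0:
            raise DegenerateInputError("cell mask has no true pixels")


def _check_grayscale(arr: np.ndarray, path: str | Path) -> np.ndarray:
    """Coerce a TIFF array to (T, H, W), rejecting color/multi-channel pages."""
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected grayscale pages, got array of shape {arr.shape}")
    # A trailing axis of 3 or 4 on an otherwise-2D page is an RGB(A) page.
    if arr.shape[-1] in (3, 4) and arr.shape[-2] > 8 and arr.ndim == 3 and arr.shape[0] <= 8:
        raise FormatError(f"{path}: page 0 appears to be RGB/multi-channel (shape {arr.shape})")
    return arr


def load_movie(
    path: str | Path,
    frame_interval: float,
    pixel_size: float,
    black_level: float = 0.0,
) -> Movie:
    """Read a single- or multi-page grayscale TIFF as a :class:`Movie`.

    Frames are returned in acquisition (page) order. Metadata is taken from
    the arguments, never from TIFF tags.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read movie: {path} does not exist")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - tifffile error text varies
        raise IOError(f"cannot read movie {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 4:
        # (T, H, W, C) color stack: not supported
        raise FormatError(
            f"{path}: multi-channel TIFF (shape {arr.shape}); pages must be grayscale"
        )
    arr = _check_grayscale(arr, path)
    return Movie(
        data=arr,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        black_level=black_level,
    )


def save_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as a multi-page TIFF (one page per frame)."""
    data = movie.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    tifffile.imwrite(Path(path), data)


def load_mask(path: str | Path, pixel_size: float) -> CellMask:
    """Read a single-page mask image (TIFF or PNG); nonzero pixels are inside."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read mask: {path} does not exist")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be a single 2D page, got shape {arr.shape}")
    return CellMask(mask=arr != 0, pixel_size=pixel_size)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit TIFF (255 = inside)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


EVENT_COLUMNS = [
    "id",
    "t_start",
    "t_end",
    "duration_s",
    "x_px",
    "y_px",
    "x_um",
    "y_um",
    "peak_amplitude",
    "n_voxels",
    "fit_sigma",
    "fit_ok",
]


def save_events_table(events, path: str | Path) -> None:
    """Write detected flicker events as CSV, one row per event.

    ``events`` is a sequence of objects exposing the event attributes
    (see :class:`flickermap.detect.FlickerEvent`); an empty sequence
    produces a header-only file.
    """
    rows = []
    for i, ev in enumerate(events):
        rows.append(
            {
                "id": i,
                "t_start": ev.t_start,
                "t_end": ev.t_end,
                "duration_s": ev.duration,
                "x_px": ev.x,
                "y_px": ev.y,
                "x_um": ev.x_um,
                "y_um": ev.y_um,
                "peak_amplitude": ev.peak_amplitude,
                "n_voxels": ev.n_voxels,
                "fit_sigma": ev.fit_sigma,
                "fit_ok": ev.fit_ok,
            }
        )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(Path(path), index=False)


def load_events_table(path: str | Path) -> pd.DataFrame:
    """Read an events CSV written by :func:`save_events_table`."""
    return pd.read_csv(Path(path))
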