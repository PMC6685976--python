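"""Spatial statistics relating flicker locations to force-generating regions.

Three analyses:

* distance analysis — Euclidean distance from each flicker centroid to
  the nearest force-generating region (0 inside one), compared against a
  null of points drawn uniformly inside the cell outline, with a
  two-sample Kolmogorov-Smirnov test;
* square-geometry classification — flickers in micropatterned square
  cells labeled corner / edge / middle, with an area-normalized
  chi-square test against the uniform expectation (traction forces in
  square cells are highest at the vertices, so an excess of corner
  flickers is the mechanotransduction signature);
* flicker frequency per unit cell-covered area per second, which is
  robust to cells touching in the field of view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .errors import DegenerateInputError, ParameterError
from .fret import ForceRegionMask
from .io_ import CellMask

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceAnalysis",
    "SquareGeometry",
    "RegionCounts",
    "FrequencySummary",
    "distance_to_force_regions",
    "random_null_distances",
    "compare_distributions_ks",
    "analyze_distances",
    "classify_square_regions",
    "region_chi_square",
    "flicker_frequency",
]


@dataclass
class DistanceAnalysis:
    """Experimental vs random-null distances to the nearest force region."""

    experimental_distances: np.ndarray  # um, 0 inside a region
    null_distances: np.ndarray  # um
    n_null: int
    seed: int
    ks_statistic: float
    p_value: float
    mean_exp: float
    mean_null: float


@dataclass
class SquareGeometry:
    """A square micropattern island and its corner/edge/middle partition.

    With border width w = corner_fraction * side: the four w-by-w squares
    at the vertices are "corner", the rest of the border strip is
    "edge", and the interior is "middle". Areas sum to side^2.
    """

    side: float  # um
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) um of the square's corner
    corner_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ParameterError("side must be > 0")
        if not (0 < self.corner_fraction < 0.5):
            raise ParameterError("corner_fraction must be in (0, 0.5)")

    @property
    def border_width(self) -> float:
        return self.corner_fraction * self.side

    @property
    def areas(self) -> dict[str, float]:
        w, s = self.border_width, self.side
        corner = 4 * w * w
        middle = (s - 2 * w) ** 2
        edge = s * s - corner - middle
        return {"corner": corner, "edge": edge, "middle": middle}


@dataclass
class RegionCounts:
    observed: dict[str, int]
    expected: dict[str, float]
    chi2: float
    df: int
    p_value: float


@dataclass
class FrequencySummary:
    n_events: int
    cell_area_um2: float
    duration_s: float
    frequency: float  # events * um^-2 * s^-1
    amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def frequency_per_1e4(self) -> float:
        """Frequency scaled by 1e4 for readability."""
        return self.frequency * 1e4


def _edt_um(regions: ForceRegionMask, pixel_size: float) -> np.ndarray:
    """Distance transform of the region-mask complement, in pixels."""
    if not regions.mask.any():
        raise DegenerateInputError("force-region mask is empty")
    return ndimage.distance_transform_edt(~regions.mask)


def distance_to_force_regions(
    centroids: np.ndarray,
    regions: ForceRegionMask,
    pixel_size: float,
) -> np.ndarray:
    """Distance (um) from each (x, y) px centroid to the nearest region pixel.

    The Euclidean distance transform of the mask complement is sampled
    at the centroids with bilinear interpolation; a centroid whose
    containing pixel belongs to the mask gets exactly 0 (region
    membership is pixelwise, so anywhere inside a region pixel counts as
    inside). Centroids outside the image yield NaN with a warning.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if centroids.shape[1] != 2:
        raise ParameterError("centroids must be (n, 2) array of (x, y)")
    edt = _edt_um(regions, pixel_size)
    h, w = edt.shape
    x, y = centroids[:, 0], centroids[:, 1]
    inside = (x >= 0) & (x <= w - 1) & (y >= 0) & (y <= h - 1)
    dist = np.full(len(centroids), np.nan)
    if inside.any():
        dist[inside] = ndimage.map_coordinates(
            edt, [y[inside], x[inside]], order=1, mode="nearest"
        )
        ry = np.clip(np.round(y[inside]).astype(int), 0, h - 1)
        rx = np.clip(np.round(x[inside]).astype(int), 0, w - 1)
        d_in = dist[inside]
        d_in[regions.mask[ry, rx]] = 0.0
        dist[inside] = d_in
    if (~inside).any():
        logger.warning("%d centroid(s) outside the image; distance set to NaN",
                       int((~inside).sum()))
    return dist * pixel_size


def random_null_distances(
    cell: CellMask,
    regions: ForceRegionMask,
    n: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Distances (um) for n points uniform over the cell mask.

    Points are drawn per pixel with continuous jitter inside the chosen
    pixel, so the null is uniform over the cell area; reproducible given
    the seed.
    """
    cell.require_nonempty()
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pix = np.argwhere(cell.mask)  # (m, 2) of (y, x)
    choice = rng.integers(0, len(pix), size=n)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    pts_yx = pix[choice] + jitter
    # clip jittered points at the image border so sampling stays defined
    h, w = cell.mask.shape
    xs = np.clip(pts_yx[:, 1], 0, w - 1)
    ys = np.clip(pts_yx[:, 0], 0, h - 1)
    return distance_to_force_regions(
        np.column_stack([xs, ys]), regions, cell.pixel_size
    )


def compare_distributions_ks(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def analyze_distances(
    centroids: np.ndarray,
    cell: CellMask,
    regions: ForceRegionMask,
    n_null: int = 1000,
    seed: int = 0,
) -> DistanceAnalysis:
    """Experimental flicker distances vs the uniform-in-cell null + KS test."""
    exp = distance_to_force_regions(centroids, regions, cell.pixel_size)
    exp = exp[np.isfinite(exp)]
    if len(exp) == 0:
        raise DegenerateInputError("no in-image centroid to analyze")
    null = random_null_distances(cell, regions, n=n_null, seed=seed)
    ks, p = compare_distributions_ks(exp, null)
    return DistanceAnalysis(
        experimental_distances=exp,
        null_distances=null,
        n_null=n_null,
        seed=seed,
        ks_statistic=ks,
        p_value=p,
        mean_exp=float(exp.mean()),
        mean_null=float(null.mean()),
    )


def classify_square_regions(
    centroids_um: np.ndarray, geom: SquareGeometry
) -> np.ndarray:
    """Label (x, y) um points as 'corner' / 'edge' / 'middle' / 'outside'."""
    pts = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    x = pts[:, 0] - geom.origin[0]
    y = pts[:, 1] - geom.origin[1]
    s, w = geom.side, geom.border_width
    labels = np.full(len(pts), "middle", dtype=object)
    outside = (x < 0) | (x > s) | (y < 0) | (y > s)
    near_x = (x < w) | (x > s - w)
    near_y = (y < w) | (y > s - w)
    labels[near_x | near_y] = "edge"
    labels[near_x & near_y] = "corner"
    labels[outside] = "outside"
    return labels.astype(str)


def region_chi_square(
    labels: np.ndarray, geom: SquareGeometry, expectation: str = "area"
) -> RegionCounts:
    """Chi-square of observed region counts against chance.

    Default expectation is area-proportional (expected_r = N * area_r /
    side^2); ``expectation='equal'`` uses equal thirds instead, for
    sensitivity checks. df = 2. 'outside' labels are excluded.
    """
    labels = np.asarray(labels, dtype=str)
    labels = labels[labels != "outside"]
    n = len(labels)
    if n < 1:
        raise ParameterError("need at least one labeled point inside the square")
    areas = geom.areas
    total = sum(areas.values())
    names = ["corner", "edge", "middle"]
    observed = {r: int(np.sum(labels == r)) for r in names}
    if expectation == "area":
        expected = {r: n * areas[r] / total for r in names}
    elif expectation == "equal":
        expected = {r: n / 3.0 for r in names}
    else:
        raise ParameterError(f"unknown expectation model {expectation!r}")
    if any(e <= 0 for e in expected.values()):
        raise ParameterError("degenerate geometry: a region has zero expected count")
    obs = np.array([observed[r] for r in names], dtype=float)
    exp = np.array([expected[r] for r in names])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=2))
    return RegionCounts(observed=observed, expected=expected, chi2=chi2, df=2, p_value=p)


def flicker_frequency(
    events, cell: CellMask, duration: float
) -> FrequencySummary:
    """Events per um^2 of cell-covered area per second.

    ``events`` may be a count or a sequence of events carrying
    ``peak_amplitude`` attributes (collected into the summary).
    """
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    area = cell.area_um2
    if area <= 0:
        raise ParameterError("cell area must be > 0")
    if isinstance(events, (int, np.integer)):
        n = int(events)
        amplitudes = np.zeros(0)
    else:
        events = list(events)
        n = len(events)
        amplitudes = np.array(
            [getattr(e, "peak_amplitude", np.nan) for e in events], dtype=float
        )
    return FrequencySummary(
        n_events=n,
        cell_area_um2=area,
        duration_s=duration,
        frequency=n / (area * duration),
        amplitudes=amplitudes,
    )
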