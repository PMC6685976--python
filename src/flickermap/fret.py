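"""FRET tension-sensor force maps.

A molecular tension sensor (MTS) is an elastic peptide flanked by a FRET
pair and anchored to the coverslip; cell traction stretches it, which
lowers FRET. From registered donor (D) and acceptor (A) images:

    FRET index   FRETi = A / (A + D)          (backgrounds subtracted)
    efficiency   E = FRETi / (alpha * (gamma - FRETi*gamma + FRETi))
    force        monotone-decreasing calibration curve force(E)

alpha is the fraction of donor-labeled sensors carrying an acceptor and
gamma corrects for donor/acceptor quantum-yield differences; both are
experimentally determined per sensor batch and consumed here as
configuration. Force-generating regions are segmented by blurring the
index map and keeping pixels below 75% of the maximum blurred intensity
(low index = high force).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, FormatError, ParameterError
from .io_ import CellMask

logger = logging.getLogger(__name__)

__all__ = [
    "FretPair",
    "FretCalibration",
    "ForceMap",
    "ForceRegionMask",
    "compute_fret_index",
    "fret_index_to_efficiency",
    "efficiency_to_force",
    "segment_force_regions",
    "force_map_pipeline",
    "load_force_curve",
]


@dataclass
class FretPair:
    """Registered donor/acceptor image pair with backgrounds.

    ``registration_offset`` = (dx, dy) px translation applied to the
    acceptor channel (bilinear resampling) before any arithmetic.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    donor_background: float | np.ndarray = 0.0
    acceptor_background: float | np.ndarray = 0.0
    registration_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise FormatError(
                f"donor shape {self.donor.shape} != acceptor shape {self.acceptor.shape}"
            )
        if self.donor.ndim != 2:
            raise FormatError("donor/acceptor images must be 2D")
        if np.any(np.asarray(self.donor_background) < 0) or np.any(
            np.asarray(self.acceptor_background) < 0
        ):
            raise ParameterError("backgrounds must be non-negative")

    def registered_acceptor(self) -> np.ndarray:
        dx, dy = self.registration_offset
        if dx == 0 and dy == 0:
            return self.acceptor
        # ndimage.shift moves content by +shift along each axis (y, x)
        return ndimage.shift(self.acceptor, shift=(dy, dx), order=1, mode="nearest")


@dataclass
class FretCalibration:
    """Sensor calibration: alpha, gamma and the efficiency->force curve.

    ``force_curve`` is an (n, 2) array of (efficiency, force_pN) knots,
    strictly monotone in efficiency and decreasing in force (stretching
    the linker lowers FRET).
    """

    alpha: float = 1.0
    gamma: float = 1.0
    force_curve: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ParameterError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.gamma <= 0:
            raise ParameterError(f"gamma must be > 0, got {self.gamma}")
        if self.alpha == 1.0 and self.gamma == 1.0:
            logger.warning(
                "alpha = gamma = 1: uncalibrated defaults; FRET efficiency will "
                "equal the raw FRET index"
            )
        if self.force_curve is not None:
            self.force_curve = np.asarray(self.force_curve, dtype=float)
            self._validate_curve()

    def _validate_curve(self) -> None:
        curve = self.force_curve
        if curve.ndim != 2 or curve.shape[1] != 2 or len(curve) < 2:
            raise ParameterError("force_curve must be an (n>=2, 2) table")
        eff = curve[:, 0]
        order = np.argsort(eff)
        eff_s, force_s = eff[order], curve[order, 1]
        if np.any(np.diff(eff_s) <= 0):
            raise ParameterError("force_curve efficiencies must be strictly monotone")
        if np.any(np.diff(force_s) >= 0):
            raise ParameterError(
                "force_curve must be monotone decreasing: higher force means lower FRET"
            )
        self.force_curve = np.column_stack([eff_s, force_s])

    def force_from_efficiency(self, eff: np.ndarray) -> np.ndarray:
        """Interpolate the calibration curve; out-of-range clamped to end knots."""
        if self.force_curve is None:
            raise ParameterError("calibration has no force curve")
        knots_e, knots_f = self.force_curve[:, 0], self.force_curve[:, 1]
        eff = np.asarray(eff, dtype=float)
        n_clamped = int(np.sum((eff < knots_e[0]) | (eff > knots_e[-1])))
        if n_clamped:
            logger.warning(
                "%d pixel(s) outside the calibration efficiency range were clamped "
                "to the nearest knot", n_clamped,
            )
        return np.interp(eff, knots_e, knots_f)

    def efficiency_from_force(self, force: np.ndarray) -> np.ndarray:
        """Inverse of the (decreasing) calibration curve."""
        if self.force_curve is None:
            raise ParameterError("calibration has no force curve")
        # force decreases with efficiency; flip for np.interp's ascending x
        f_asc = self.force_curve[::-1, 1]
        e_asc = self.force_curve[::-1, 0]
        force = np.asarray(force, dtype=float)
        if np.any(force < f_asc[0]) or np.any(force > f_asc[-1]):
            raise ParameterError("force outside the calibration table range")
        return np.interp(force, f_asc, e_asc)


@dataclass
class ForceMap:
    """Per-pixel FRET index / efficiency / force plus the validity mask."""

    fret_index: np.ndarray
    valid: np.ndarray
    efficiency: np.ndarray | None = None
    force: np.ndarray | None = None
    cell_mask: CellMask | None = None

    def support(self) -> np.ndarray:
        """Pixels entering statistics: valid, intersected with the cell mask."""
        if self.cell_mask is not None:
            return self.valid & self.cell_mask.mask
        return self.valid


@dataclass
class ForceRegionMask:
    """Segmented force-generating regions (True = force generating)."""

    mask: np.ndarray
    blur_sigma: float
    threshold_fraction: float
    reference_max: float


def compute_fret_index(
    pair: FretPair,
    intensity_floor: float = 0.0,
    cell_mask: CellMask | None = None,
) -> ForceMap:
    """FRETi = a / (a + d) with backgrounds subtracted and negatives clamped.

    Pixels with a + d below ``intensity_floor`` are invalid and excluded
    from every downstream statistic (never NaN-poisoned).
    """
    if intensity_floor < 0:
        raise ParameterError("intensity_floor must be >= 0")
    a = np.clip(pair.registered_acceptor() - pair.acceptor_background, 0.0, None)
    d = np.clip(pair.donor - pair.donor_background, 0.0, None)
    total = a + d
    valid = total >= max(intensity_floor, np.finfo(float).tiny)
    index = np.divide(a, total, out=np.zeros_like(total), where=valid)
    return ForceMap(fret_index=index, valid=valid, cell_mask=cell_mask)


def fret_index_to_efficiency(fmap: ForceMap, cal: FretCalibration) -> ForceMap:
    """E = FRETi / (alpha * (gamma - FRETi*gamma + FRETi)), pixelwise.

    Pixels where the denominator is non-positive are flagged invalid and
    counted in the log. With alpha = gamma = 1 this reduces to E = FRETi.
    """
    idx = fmap.fret_index
    denom = cal.alpha * (cal.gamma - idx * cal.gamma + idx)
    ok = denom > 0
    n_bad = int(np.sum(fmap.valid & ~ok))
    if n_bad:
        logger.warning("%d pixel(s) outside the efficiency-equation domain", n_bad)
    fmap.valid = fmap.valid & ok
    fmap.efficiency = np.divide(idx, denom, out=np.zeros_like(idx), where=ok)
    return fmap


def efficiency_to_force(fmap: ForceMap, cal: FretCalibration) -> ForceMap:
    """Convert the efficiency map to pN per sensor via the calibration curve."""
    if fmap.efficiency is None:
        raise ParameterError("efficiency map not computed yet")
    force = cal.force_from_efficiency(fmap.efficiency)
    force[~fmap.valid] = 0.0
    fmap.force = force
    return fmap


def _masked_blur(img: np.ndarray, support: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur restricted to ``support`` (normalized convolution)."""
    sup = support.astype(float)
    num = ndimage.gaussian_filter(np.where(support, img, 0.0), sigma)
    den = ndimage.gaussian_filter(sup, sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = 0.0
    return out


def segment_force_regions(
    fmap: ForceMap,
    blur_sigma: float = 2.0,
    threshold_fraction: float = 0.75,
    source: str = "index",
) -> ForceRegionMask:
    """Segment force-generating regions from the blurred map.

    Default (``source='index'``): blur the FRET-index map within its
    support and keep pixels below ``threshold_fraction`` of the maximum
    blurred intensity — low index means high force, so dark wells in the
    index map are where the cell pulls. ``source='force'`` instead
    thresholds the blurred computed-force map *above* the fraction of
    its maximum. The threshold is relative to the observed maximum, so
    the mask is invariant to common gain applied to both channels.
    """
    if blur_sigma <= 0:
        raise ParameterError("blur_sigma must be > 0")
    if not (0 < threshold_fraction < 1):
        raise ParameterError("threshold_fraction must be in (0, 1)")
    support = fmap.support()
    if not support.any():
        raise DegenerateInputError("no valid pixels to segment")
    if source == "index":
        img = fmap.fret_index
    elif source == "force":
        if fmap.force is None:
            raise ParameterError("force map not computed; cannot segment on it")
        img = fmap.force
    else:
        raise ParameterError(f"unknown segmentation source {source!r}")
    blurred = _masked_blur(img, support, blur_sigma)
    ref_max = float(blurred[support].max())
    if source == "index":
        mask = support & (blurred < threshold_fraction * ref_max)
    else:
        mask = support & (blurred > threshold_fraction * ref_max)
    return ForceRegionMask(
        mask=mask,
        blur_sigma=blur_sigma,
        threshold_fraction=threshold_fraction,
        reference_max=ref_max,
    )


def force_map_pipeline(
    pair: FretPair,
    cal: FretCalibration,
    intensity_floor: float = 0.0,
    cell_mask: CellMask | None = None,
    blur_sigma: float = 2.0,
    threshold_fraction: float = 0.75,
) -> tuple[ForceMap, ForceRegionMask]:
    """Index -> efficiency -> force -> segmented force regions."""
    fmap = compute_fret_index(pair, intensity_floor, cell_mask)
    fmap = fret_index_to_efficiency(fmap, cal)
    if cal.force_curve is not None:
        fmap = efficiency_to_force(fmap, cal)
    regions = segment_force_regions(fmap, blur_sigma, threshold_fraction)
    return fmap, regions


def load_force_curve(path) -> np.ndarray:
    """Read a two-column efficiency,force_pN CSV (header required)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if "efficiency" not in cols or not any(c.startswith("force") for c in cols):
        raise FormatError(
            f"force curve CSV must have 'efficiency' and 'force_pN' columns, got {list(df.columns)}"
        )
    eff = df[df.columns[cols.index("efficiency")]].to_numpy(float)
    fcol = next(c for i, c in enumerate(df.columns) if cols[i].startswith("force"))
    return np.column_stack([eff, df[fcol].to_numpy(float)])
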