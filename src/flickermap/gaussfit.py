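"""Symmetric 2D Gaussian least-squares fitting shared by localization code.

Model: f(x, y) = A * exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2)) + B,
fitted over a rectangular pixel window. Coordinates follow the package
convention (x = column, y = row, pixel centers at integers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["GaussianFit", "fit_gaussian_2d"]


@dataclass
class GaussianFit:
    amplitude: float
    x0: float
    y0: float
    sigma: float
    offset: float
    ok: bool


def _model(coords, A, x0, y0, sigma, B):
    x, y = coords
    return A * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma**2)) + B


def fit_gaussian_2d(
    window: np.ndarray,
    x_offset: float = 0.0,
    y_offset: float = 0.0,
    init_xy: tuple[float, float] | None = None,
    init_sigma: float = 1.5,
) -> GaussianFit:
    """Fit a symmetric 2D Gaussian to ``window``.

    ``x_offset``/``y_offset`` place the window in image coordinates: the
    pixel window[j, i] is at image position (x_offset + i, y_offset + j),
    and the returned center is in image coordinates.

    Initial values: center = ``init_xy`` (image coords) or the window's
    intensity-weighted center of mass; A = max - median; B = median;
    sigma = ``init_sigma``. ``ok`` is False when the optimizer fails or
    the fitted center leaves the window, in which case the returned
    center is the initial guess.
    """
    window = np.asarray(window, dtype=float)
    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w]
    med = float(np.median(window))
    amp0 = float(window.max() - med)
    if init_xy is None:
        weights = np.clip(window - med, 0, None)
        total = weights.sum()
        if total > 0:
            cx = float((weights * xx).sum() / total)
            cy = float((weights * yy).sum() / total)
        else:
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    else:
        cx = float(init_xy[0]) - x_offset
        cy = float(init_xy[1]) - y_offset
    p0 = (max(amp0, 1e-12), cx, cy, init_sigma, med)
    try:
        popt, _ = curve_fit(
            _model,
            (xx.ravel().astype(float), yy.ravel().astype(float)),
            window.ravel(),
            p0=p0,
            maxfev=400,
        )
        A, x0, y0, sigma, B = popt
        ok = bool(-0.5 <= x0 <= w - 0.5 and -0.5 <= y0 <= h - 0.5 and np.isfinite([A, x0, y0, sigma, B]).all())
    except Exception:
        ok = False
    if not ok:
        return GaussianFit(
            amplitude=amp0,
            x0=cx + x_offset,
            y0=cy + y_offset,
            sigma=float(init_sigma),
            offset=med,
            ok=False,
        )
    return GaussianFit(
        amplitude=float(A),
        x0=float(x0) + x_offset,
        y0=float(y0) + y_offset,
        sigma=abs(float(sigma)),
        offset=float(B),
        ok=True,
    )
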