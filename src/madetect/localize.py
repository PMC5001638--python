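"""Candidate localization by directional second derivatives (the P map).

At the center of a round dark blob the 1-D intensity profile has a minimum in
every direction, so the second directional derivative is strictly positive in
all directions; on a ridge, the along-ridge profile is flat and at least one
direction yields a non-positive second derivative.  The localizer exploits
this: for directions theta sampled every 10 degrees,

    I'_theta  = cos(theta) dI/dx + sin(theta) dI/dy        (clipped at 0)
    I''_theta = u . grad( max(I'_theta, 0) ),  u = (cos theta, sin theta)
    P(x, y)   = prod_theta max(I''_theta, 0)

P is strictly positive only where every one of the 36 clipped directional
second derivatives is positive — in practice only at blob centers.  Clipping
the first derivative at zero discards the half-profile on which intensity
decreases away from the center, which sharpens the peak at the true center.

Derivatives come from a cubic facet model: each pixel's 7x7 neighborhood is
fit with a bivariate cubic polynomial by least squares and the derivatives of
the fitted surface are read off at the window center.  Because the fit is a
fixed linear functional of the window, it is implemented as a bank of
convolution kernels; the cubic facet reproduces planes and quadratics
exactly, so second derivatives are unbiased.

The detector input is the vessel-removal residual, in which lesions are
bright peaks; the residual is negated internally so that blob centers are
intensity minima as the machinery above assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .config import DEFAULT_CONFIG, DetectConfig
from .errors import InvalidInputError
from .image import IntensityImage

FACET_WINDOW = 7
P_FACTOR_FLOOR = 1e-12


@dataclass
class PMap:
    """Product-of-directional-second-derivative raster."""

    values: np.ndarray          # the raw product, >= 0
    n_directions: int = 36

    def root(self) -> np.ndarray:
        """Per-direction geometric mean, values ** (1 / n_directions).

        The raw product spans a dynamic range exponential in the direction
        count; the root is the natural scale on which blob strengths of
        different contrast are comparable.
        """
        return np.power(self.values, 1.0 / self.n_directions)


@dataclass(frozen=True)
class CandidateLocation:
    """A localized candidate center (0-based pixel coords, x = column)."""

    x: int
    y: int
    p_value: float


@lru_cache(maxsize=1)
def _facet_kernels() -> dict[str, np.ndarray]:
    """Correlation kernels for cubic-facet derivatives on a 7x7 window.

    Kernel entries are indexed [dy + 3, dx + 3]; applying them with
    ``ndimage.correlate`` evaluates the derivative of the least-squares cubic
    fit at the window center.
    """
    half = FACET_WINDOW // 2
    dys, dxs = np.mgrid[-half : half + 1, -half : half + 1]
    x = dxs.ravel().astype(np.float64)
    y = dys.ravel().astype(np.float64)
    # bivariate cubic basis: 1, x, y, x^2, xy, y^2, x^3, x^2 y, x y^2, y^3
    A = np.stack(
        [np.ones_like(x), x, y, x * x, x * y, y * y,
         x**3, x * x * y, x * y * y, y**3],
        axis=1,
    )
    pinv = np.linalg.pinv(A)            # (10, 49): coefficient = pinv @ window
    shape = (FACET_WINDOW, FACET_WINDOW)
    return {
        "dx": pinv[1].reshape(shape),
        "dy": pinv[2].reshape(shape),
        "dxx": 2.0 * pinv[3].reshape(shape),
        "dxy": pinv[4].reshape(shape),
        "dyy": 2.0 * pinv[5].reshape(shape),
    }


def facet_derivatives(img: IntensityImage | np.ndarray) -> dict[str, np.ndarray]:
    """First- and second-order facet-model derivative rasters.

    Returns a dict with keys ``dx, dy, dxx, dxy, dyy``; borders use
    nearest-neighbor extension of the image.
    """
    values = img.values if isinstance(img, IntensityImage) else np.asarray(img, float)
    if min(values.shape) < FACET_WINDOW:
        raise InvalidInputError("image must be at least 7x7 for the facet model")
    kernels = _facet_kernels()
    return {
        name: ndimage.correlate(values, k, mode="nearest")
        for name, k in kernels.items()
    }


def _facet_gradient(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    kernels = _facet_kernels()
    gx = ndimage.correlate(values, kernels["dx"], mode="nearest")
    gy = ndimage.correlate(values, kernels["dy"], mode="nearest")
    return gx, gy


def direction_vector(theta: float) -> tuple[float, float]:
    """(cos, sin) with components snapped to 0 at multiples of 90 degrees,
    so that axis-aligned directions are handled exactly."""
    c, s = float(np.cos(theta)), float(np.sin(theta))
    if abs(c) < 1e-12:
        c = 0.0
    if abs(s) < 1e-12:
        s = 0.0
    return c, s


def clipped_second_directional_derivative(
    derivs: dict[str, np.ndarray], theta: float
) -> np.ndarray:
    """Clipped second directional derivative raster for one direction.

    The first directional derivative is floored at zero before being
    differentiated again along the same direction with the facet scheme.
    """
    c, s = direction_vector(theta)
    first = np.maximum(c * derivs["dx"] + s * derivs["dy"], 0.0)
    gx, gy = _facet_gradient(first)
    return c * gx + s * gy


def p_map(
    img: IntensityImage | np.ndarray,
    n_directions: int = DEFAULT_CONFIG.n_directions,
    negate: bool = True,
) -> PMap:
    """P map of an image (by default of the negated residual).

    The product over directions is accumulated in the log domain with a
    zero-factor short-circuit so that pixels with any non-positive factor are
    exactly zero and the rest do not underflow prematurely.  Factors below
    1e-12 — the scale of floating-point dust left by the convolution pipeline
    on analytically flat profiles — count as zero; genuine blob responses are
    many orders of magnitude above this.
    """
    if n_directions < 4:
        raise InvalidInputError("need at least 4 directions for the P map")
    values = img.values if isinstance(img, IntensityImage) else np.asarray(img, float)
    if negate:
        values = -values
    derivs = facet_derivatives(values)
    log_p = np.zeros(values.shape, dtype=np.float64)
    positive = np.ones(values.shape, dtype=bool)
    for k in range(n_directions):
        theta = 2.0 * np.pi * k / n_directions
        second = clipped_second_directional_derivative(derivs, theta)
        positive &= second > P_FACTOR_FLOOR
        if not positive.any():
            break
        log_second = np.zeros_like(second)
        np.log(second, out=log_second, where=positive)
        log_p += np.where(positive, log_second, 0.0)
    p = np.zeros_like(log_p)
    p[positive] = np.exp(log_p[positive])
    return PMap(values=p, n_directions=n_directions)


def localize_candidates(
    pmap: PMap,
    rel_threshold: float = DEFAULT_CONFIG.p_rel_threshold,
    dedup_radius: float = DEFAULT_CONFIG.dedup_radius,
) -> list[CandidateLocation]:
    """Local maxima of the P map above a relative threshold.

    The threshold is ``rel_threshold`` times the image maximum applied on the
    per-direction geometric-mean scale (the n-th root of P), where blob
    strengths of different contrast are comparable; plateau maxima are
    reduced to their centroid and candidates closer than ``dedup_radius``
    keep only the higher P value.  Candidates are returned sorted by
    descending P.
    """
    if not (0.0 < rel_threshold < 1.0):
        raise InvalidInputError("rel_threshold must lie in (0, 1)")
    p = pmap.values
    if p.max() <= 0.0:
        return []
    root = pmap.root()
    cutoff = rel_threshold * root.max()
    is_max = (p == ndimage.maximum_filter(p, size=3, mode="nearest")) & (root > cutoff)
    if not is_max.any():
        return []
    # plateau handling: collapse connected equal-valued maxima to centroids
    labels, n_lab = ndimage.label(is_max, structure=np.ones((3, 3), dtype=bool))
    cys, cxs = np.array(
        ndimage.center_of_mass(is_max, labels, range(1, n_lab + 1))
    ).T.reshape(2, -1)
    peaks = []
    for cy, cx in zip(cys, cxs):
        iy, ix = int(round(cy)), int(round(cx))
        peaks.append((float(p[iy, ix]), ix, iy))
    peaks.sort(key=lambda t: (-t[0], t[2], t[1]))
    kept: list[CandidateLocation] = []
    for val, x, y in peaks:
        if all((x - c.x) ** 2 + (y - c.y) ** 2 > dedup_radius**2 for c in kept):
            kept.append(CandidateLocation(x=x, y=y, p_value=val))
    return kept
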