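"""Multi-scale log condition-number vesselness (the K map).

Retinal vessels are piecewise-linear dark ridges: within a circular support
region on a vessel, image gradient vectors point (with both signs) along the
ridge normal, so the 2x2 covariance matrix of the gradients has one dominant
eigenvalue.  At the center of a microaneurysm — a round dark blob — gradients
point radially in all directions and the two eigenvalues are comparable.  The
condition number kappa = lambda1 / lambda2 of the local gradient covariance
therefore discriminates vessel-like from blob-like structure: kappa ~ 1 for
blobs, kappa >> 1 for ridges.

To cover vessels and lesions of different calibers the condition number is
accumulated over integer support radii r = r_min .. r_max,

    K(x, y) = sum_r ln kappa(C(x, y, r)),

with r_min = round(2 rho), r_max = round(7 rho) and rho = width / 768: at the
reference resolution both vessels and microaneurysms have radii of roughly
1-6 px.  The logarithm keeps the multi-scale product from overflowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, DetectConfig
from .errors import ConfigError, InvalidInputError
from .image import IntensityImage


@dataclass
class GradientField:
    """Partial derivatives of an intensity image (central differences)."""

    dx: np.ndarray
    dy: np.ndarray


@dataclass
class KMap:
    """Multi-scale log condition-number raster."""

    values: np.ndarray
    r_min: int
    r_max: int
    rho: float = 1.0

    @property
    def n_scales(self) -> int:
        return self.r_max - self.r_min + 1


def gradient(img: IntensityImage) -> GradientField:
    """Central-difference gradient (one-sided at borders)."""
    if img.height < 3 or img.width < 3:
        raise InvalidInputError("image must be at least 3x3 for gradients")
    dy, dx = np.gradient(img.values)
    return GradientField(dx=dx, dy=dy)


def support_radii(rho: float) -> list[int]:
    """Integer support radii round(2 rho) .. round(7 rho)."""
    r_min = max(1, int(round(DEFAULT_CONFIG.r_min_factor * rho)))
    r_max = int(round(DEFAULT_CONFIG.r_max_factor * rho))
    if r_min > r_max:
        raise ConfigError(f"r_min {r_min} exceeds r_max {r_max}")
    return list(range(r_min, r_max + 1))


def gradient_covariance(
    field: GradientField, center: tuple[int, int], radius: float
) -> np.ndarray:
    """Population covariance of gradient vectors over a circular support.

    ``center`` is (x, y) with x the column.  Pixels whose centers lie within
    Euclidean distance ``radius`` and inside the image take part; the support
    is clipped at borders.
    """
    h, w = field.dx.shape
    cx, cy = center
    r = int(np.floor(radius))
    x0, x1 = max(0, cx - r), min(w - 1, cx + r)
    y0, y1 = max(0, cy - r), min(h - 1, cy + r)
    if x0 > x1 or y0 > y1:
        raise InvalidInputError("support region lies entirely outside the image")
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    if not inside.any():
        raise InvalidInputError("support region contains no pixels")
    gx = field.dx[y0 : y1 + 1, x0 : x1 + 1][inside]
    gy = field.dy[y0 : y1 + 1, x0 : x1 + 1][inside]
    mx, my = gx.mean(), gy.mean()
    cxx = np.mean((gx - mx) ** 2)
    cyy = np.mean((gy - my) ** 2)
    cxy = np.mean((gx - mx) * (gy - my))
    return np.array([[cxx, cxy], [cxy, cyy]])


def condition_number(cov: np.ndarray, eps: float = DEFAULT_CONFIG.cov_eps) -> float:
    """Regularized condition number (lambda1 + eps) / (lambda2 + eps) >= 1."""
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    half_tr = 0.5 * (a + c)
    d = np.sqrt((0.5 * (a - c)) ** 2 + b * b)
    lam1 = half_tr + d
    lam2 = max(half_tr - d, 0.0)
    return float((lam1 + eps) / (lam2 + eps))


def _disk_row_extents(radius: int) -> list[tuple[int, int]]:
    """(dy, half-width) pairs of the pixel disk of the given integer radius."""
    return [
        (dy, int(np.floor(np.sqrt(radius**2 - dy**2))))
        for dy in range(-radius, radius + 1)
    ]


def _disk_sums(values: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel sum of ``values`` over the disk support, clipped at borders.

    Uses row-wise cumulative sums: each disk row is a contiguous segment, so
    its sum is a difference of two cumsum entries.  Exact summation (no FFT),
    which keeps the map bit-comparable with a brute-force enumeration.
    """
    h, w = values.shape
    r = radius
    padded = np.zeros((h + 2 * r, w + 2 * r), dtype=np.float64)
    padded[r : r + h, r : r + w] = values
    csum = np.zeros((h + 2 * r, w + 2 * r + 1), dtype=np.float64)
    np.cumsum(padded, axis=1, out=csum[:, 1:])
    out = np.zeros((h, w), dtype=np.float64)
    for dy, hw in _disk_row_extents(r):
        rows = slice(r + dy, r + dy + h)
        out += csum[rows, r + hw + 1 : r + hw + 1 + w] - csum[rows, r - hw : r - hw + w]
    return out


def _disk_counts(shape: tuple[int, int], radius: int) -> np.ndarray:
    return _disk_sums(np.ones(shape, dtype=np.float64), radius)


def k_map(img: IntensityImage, config: DetectConfig = DEFAULT_CONFIG) -> KMap:
    """Multi-scale log condition-number map of a preprocessed image."""
    radii = support_radii(img.rho)
    field = gradient(img)
    gx, gy = field.dx, field.dy
    shape = gx.shape
    eps = config.cov_eps
    K = np.zeros(shape, dtype=np.float64)
    for r in radii:
        n = _disk_counts(shape, r)
        sx = _disk_sums(gx, r)
        sy = _disk_sums(gy, r)
        sxx = _disk_sums(gx * gx, r)
        syy = _disk_sums(gy * gy, r)
        sxy = _disk_sums(gx * gy, r)
        mx, my = sx / n, sy / n
        cxx = sxx / n - mx * mx
        cyy = syy / n - my * my
        cxy = sxy / n - mx * my
        half_tr = 0.5 * (cxx + cyy)
        d = np.sqrt((0.5 * (cxx - cyy)) ** 2 + cxy * cxy)
        lam1 = half_tr + d
        lam2 = np.maximum(half_tr - d, 0.0)
        K += np.log((lam1 + eps) / (lam2 + eps))
    K = np.maximum(K, 0.0)
    if img.fov_mask is not None:
        K[~img.fov_mask] = 0.0
    return KMap(values=K, r_min=radii[0], r_max=radii[-1], rho=img.rho)
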