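"""Hand-crafted patch descriptors: HOG (775), SURF-style (128), GIST (216).

All three operate on a 31x31 intensity patch centered at a candidate seed
(about 15 px radius — enough to cover a manually annotated microaneurysm and
its surroundings).  Sizes follow the classical descriptor layouts:

* HOG: 5 x 5 cells x 31 features per cell (18 contrast-sensitive + 9
  contrast-insensitive orientation channels + 4 normalization-energy
  features, each orientation channel averaged over the four neighboring
  block normalizations with truncation at 0.2);
* SURF: 4 x 4 cells x 8 sign-split Haar wavelet response sums;
* GIST: Gabor filter energy at 3 scales x 8 orientations averaged over a
  3 x 3 spatial grid.

A zero patch maps to the zero vector for every descriptor.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage

PATCH = 31
_EPS = 1e-12
_TRUNC = 0.2

HOG_SIZE = 775
SURF_SIZE = 128
GIST_SIZE = 216


def extract_patch(values: np.ndarray, x: int, y: int, size: int = PATCH) -> np.ndarray:
    """Square patch centered at (x, y), zero-padded at image borders."""
    half = size // 2
    h, w = values.shape
    patch = np.zeros((size, size), dtype=np.float64)
    y0, y1 = max(0, y - half), min(h, y + half + 1)
    x0, x1 = max(0, x - half), min(w, x + half + 1)
    patch[y0 - (y - half) : y1 - (y - half), x0 - (x - half) : x1 - (x - half)] = (
        values[y0:y1, x0:x1]
    )
    return patch


def _cell_bounds(n_cells: int, size: int = PATCH) -> np.ndarray:
    return np.round(np.linspace(0, size, n_cells + 1)).astype(int)


# ---------------------------------------------------------------------------
# HOG, 5x5 cells x 31 features
# ---------------------------------------------------------------------------

def hog_descriptor(patch: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(patch)
    mag = np.hypot(gx, gy)
    ori = np.mod(np.arctan2(gy, gx), 2.0 * np.pi)
    bins18 = np.minimum((ori / (2.0 * np.pi / 18.0)).astype(int), 17)

    bounds = _cell_bounds(5)
    hist18 = np.zeros((5, 5, 18))
    for i in range(5):
        for j in range(5):
            sub_m = mag[bounds[i] : bounds[i + 1], bounds[j] : bounds[j + 1]]
            sub_b = bins18[bounds[i] : bounds[i + 1], bounds[j] : bounds[j + 1]]
            hist18[i, j] = np.bincount(sub_b.ravel(), weights=sub_m.ravel(),
                                       minlength=18)
    hist9 = hist18[:, :, :9] + hist18[:, :, 9:]
    energy = np.sum(hist9**2, axis=2)                       # (5, 5)
    block = (energy[:-1, :-1] + energy[1:, :-1]
             + energy[:-1, 1:] + energy[1:, 1:])            # (4, 4)

    out = np.zeros((5, 5, 31))
    for i in range(5):
        for j in range(5):
            # four neighboring 2x2 blocks, clamped at the grid border
            norms = []
            for bi in (i - 1, i):
                for bj in (j - 1, j):
                    bi_c = min(max(bi, 0), 3)
                    bj_c = min(max(bj, 0), 3)
                    norms.append(np.sqrt(block[bi_c, bj_c]) + _EPS)
            h18, h9 = hist18[i, j], hist9[i, j]
            f18 = 0.5 * sum(np.minimum(h18 / n, _TRUNC) for n in norms)
            f9 = 0.5 * sum(np.minimum(h9 / n, _TRUNC) for n in norms)
            tex = np.array([np.minimum(h9 / n, _TRUNC).sum() for n in norms])
            out[i, j] = np.concatenate([f18, f9, 0.2357 * tex])
    return out.reshape(-1)


# ---------------------------------------------------------------------------
# SURF-style, 4x4 cells x 8 sign-split Haar sums
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _haar_kernels() -> tuple[np.ndarray, np.ndarray]:
    kx = np.zeros((4, 4))
    kx[:, :2], kx[:, 2:] = -1.0, 1.0
    return kx, kx.T.copy()


def surf_descriptor(patch: np.ndarray) -> np.ndarray:
    kx, ky = _haar_kernels()
    dx = ndimage.correlate(patch, kx, mode="constant")
    dy = ndimage.correlate(patch, ky, mode="constant")
    bounds = _cell_bounds(4)
    feats = np.zeros((4, 4, 8))
    for i in range(4):
        for j in range(4):
            sl = np.s_[bounds[i] : bounds[i + 1], bounds[j] : bounds[j + 1]]
            cdx, cdy = dx[sl], dy[sl]
            neg_y, pos_y = cdy < 0, cdy >= 0
            neg_x, pos_x = cdx < 0, cdx >= 0
            feats[i, j] = [
                cdx[neg_y].sum(), np.abs(cdx[neg_y]).sum(),
                cdx[pos_y].sum(), np.abs(cdx[pos_y]).sum(),
                cdy[neg_x].sum(), np.abs(cdy[neg_x]).sum(),
                cdy[pos_x].sum(), np.abs(cdy[pos_x]).sum(),
            ]
    vec = feats.reshape(-1)
    norm = np.linalg.norm(vec)
    return vec / norm if norm > _EPS else vec


# ---------------------------------------------------------------------------
# GIST, 3 scales x 8 orientations x 3x3 grid
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _gabor_bank(size: int = PATCH) -> np.ndarray:
    """Frequency-domain Gabor transfer functions, shape (24, size, size).

    One-sided log-polar Gaussians: radial center frequencies 0.25, 0.125 and
    0.0625 cycles/px with sigma 0.4 f0, angular sigma pi/8.
    """
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    radius = np.hypot(fx, fy)
    angle = np.arctan2(fy, fx)
    bank = []
    for f0 in (0.25, 0.125, 0.0625):
        radial = np.exp(-0.5 * ((radius - f0) / (0.4 * f0)) ** 2)
        radial[radius == 0] = 0.0
        for k in range(8):
            theta = np.pi * k / 8.0
            d = np.angle(np.exp(1j * (angle - theta)))
            angular = np.exp(-0.5 * (d / (np.pi / 8.0)) ** 2)
            bank.append(radial * angular)
    return np.stack(bank)


def gist_descriptor(patch: np.ndarray) -> np.ndarray:
    size = patch.shape[0]
    spectrum = np.fft.fft2(patch - patch.mean())
    bank = _gabor_bank(size)
    bounds = _cell_bounds(3, size)
    feats = np.zeros((24, 3, 3))
    for f, transfer in enumerate(bank):
        mag = np.abs(np.fft.ifft2(spectrum * transfer))
        for i in range(3):
            for j in range(3):
                feats[f, i, j] = mag[
                    bounds[i] : bounds[i + 1], bounds[j] : bounds[j + 1]
                ].mean()
    return feats.reshape(-1)


def region_descriptors(values: np.ndarray, x: int, y: int) -> np.ndarray:
    """Concatenated HOG + SURF + GIST features of the 31x31 patch at (x, y)."""
    patch = extract_patch(values, x, y)
    return np.concatenate(
        [hog_descriptor(patch), surf_descriptor(patch), gist_descriptor(patch)]
    )
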