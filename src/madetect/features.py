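"""Seven-family feature extraction for candidate regions (1247 slots).

For each segmented candidate region Omega the extractor assembles a fixed
1247-long named vector grouped into seven families:

====================  ====  =====================================================
family                size  content
====================  ====  =====================================================
geometric                6  axis ratio r1, diameter ratio r2, area, circularity,
                            eccentricity, compactness
contrast                10  max(inside) - min(outside) in I_p and the 9 channels
                            of RGB / LUV / HSI of the original color image
intensity               42  total intensity, area-normalized intensity and
                            FOV-mean-normalized mean in I_p and green (6), plus
                            mu_in, sigma_in, mu_out, sigma_out in the 9 color
                            channels (36)
edge                     1  mean gradient magnitude of I_p on the boundary
texture                 16  mean/std over Omega of Gaussian and LoG responses of
                            I_p at sigma = 1, 2, 4, 8
hog                    775  5x5-cell, 31-feature HOG of the 31x31 patch
surf                   128  4x4-cell, 8-feature Haar-response descriptor
gist                   216  3-scale x 8-orientation x 3x3-grid Gabor energies
other                   53  36 per-direction mean gradient-vs-ray angle
                            differences + their overall mean/std (2), in/out
                            mean/std in the condition-number, convergence-index
                            and divergence maps (12), isolated-index mean/std
                            over Omega (2), product-map mean (1)
====================  ====  =====================================================

The "outer" region used by contrast/intensity statistics is the morphological
dilation of Omega by a radius-2 disk minus Omega.  Undefined statistics
(empty outer region, zero gradients) are imputed as 0.  The per-image maps
(color channels, filter banks, condition-number / convergence-index /
divergence / isolated-index maps) are computed once per image by
``FeatureExtractor`` and shared across candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import ndimage
from skimage.color import rgb2luv
from skimage.measure import regionprops

from .config import DEFAULT_CONFIG, DetectConfig
from .descriptors import GIST_SIZE, HOG_SIZE, PATCH, SURF_SIZE, region_descriptors
from .image import FundusImage, IntensityImage
from .segment import CandidateRegion
from .vesselness import _disk_sums

_EPS = 1e-12

FEATURE_LAYOUT: tuple[tuple[str, int], ...] = (
    ("geometric", 6),
    ("contrast", 10),
    ("intensity", 42),
    ("edge", 1),
    ("texture", 16),
    ("hog", HOG_SIZE),
    ("surf", SURF_SIZE),
    ("gist", GIST_SIZE),
    ("other", 53),
)
N_FEATURES = sum(n for _, n in FEATURE_LAYOUT)          # 1247
FEATURE_LAYOUT_VERSION = "madetect-features-1"

COLOR_CHANNEL_NAMES = ("R", "G", "B", "L", "U", "V", "H", "S", "I")
TEXTURE_SIGMAS = (1.0, 2.0, 4.0, 8.0)


def feature_names() -> list[str]:
    """Stable column names ``grp__name`` for the full 1247-slot vector."""
    names: list[str] = []
    names += [f"geometric__{n}" for n in ("r1", "r2", "area", "circularity",
                                          "eccentricity", "compactness")]
    names += [f"contrast__xi__{c}" for c in ("Ip",) + COLOR_CHANNEL_NAMES]
    for c in ("Ip", "green"):
        names += [f"intensity__{n}__{c}" for n in ("total", "ni", "nm")]
    for c in COLOR_CHANNEL_NAMES:
        names += [f"intensity__{n}__{c}"
                  for n in ("mu_in", "sigma_in", "mu_out", "sigma_out")]
    names += ["edge__mu_e__Ip"]
    for s in TEXTURE_SIGMAS:
        names += [f"texture__{n}__s{s:g}"
                  for n in ("mu_gauss", "sigma_gauss", "mu_log", "sigma_log")]
    names += [f"hog__{i:03d}" for i in range(HOG_SIZE)]
    names += [f"surf__{i:03d}" for i in range(SURF_SIZE)]
    names += [f"gist__{i:03d}" for i in range(GIST_SIZE)]
    names += [f"other__angle_dir{k:02d}" for k in range(36)]
    names += ["other__mu_angle", "other__sigma_angle"]
    for m in ("cond", "ci", "div"):
        names += [f"other__{m}__{n}"
                  for n in ("mu_in", "sigma_in", "mu_out", "sigma_out")]
    names += ["other__mu_ii", "other__sigma_ii", "other__mu_wi"]
    assert len(names) == N_FEATURES
    return names


def hsi_channels(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hue/saturation/intensity under the standard conical model, all in [0, 1]."""
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    intensity = total / 3.0
    minimum = np.minimum(np.minimum(r, g), b)
    sat = np.where(total > _EPS, 1.0 - 3.0 * minimum / np.maximum(total, _EPS), 0.0)
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    theta = np.arccos(np.clip(np.divide(num, den, out=np.zeros_like(num),
                                        where=den > _EPS), -1.0, 1.0))
    hue = np.where(b > g, 2.0 * np.pi - theta, theta) / (2.0 * np.pi)
    hue = np.where(den > _EPS, hue, 0.0)
    return np.mod(hue, 1.0), np.clip(sat, 0.0, 1.0), np.clip(intensity, 0.0, 1.0)


def color_channels(img: FundusImage) -> dict[str, np.ndarray]:
    """The nine RGB / LUV / HSI channels of the color image, rescaled to [0, 1]."""
    rgb = img.as_float()
    luv = rgb2luv(rgb)
    # canonical sRGB gamut bounds for CIE L*u*v* (D65)
    chans = {
        "R": rgb[..., 0], "G": rgb[..., 1], "B": rgb[..., 2],
        "L": luv[..., 0] / 100.0,
        "U": np.clip((luv[..., 1] + 134.0) / 354.0, 0.0, 1.0),
        "V": np.clip((luv[..., 2] + 140.0) / 262.0, 0.0, 1.0),
    }
    chans["H"], chans["S"], chans["I"] = hsi_channels(rgb)
    return chans


# ---------------------------------------------------------------------------
# per-image context
# ---------------------------------------------------------------------------

@dataclass
class FeatureExtractor:
    """Per-image feature context shared across candidates."""

    ip: IntensityImage
    fundus: FundusImage
    config: DetectConfig = DEFAULT_CONFIG

    @cached_property
    def channels(self) -> dict[str, np.ndarray]:
        return color_channels(self.fundus)

    @cached_property
    def fov_mean(self) -> dict[str, float]:
        fov = self.ip.fov()
        return {
            "Ip": float(self.ip.values[fov].mean()),
            "green": float(self.channels["G"][fov].mean()),
        }

    @cached_property
    def grad(self) -> tuple[np.ndarray, np.ndarray]:
        gy, gx = np.gradient(self.ip.values)
        return gx, gy

    @cached_property
    def grad_mag(self) -> np.ndarray:
        gx, gy = self.grad
        return np.hypot(gx, gy)

    @cached_property
    def texture_bank(self) -> list[np.ndarray]:
        bank = []
        for s in TEXTURE_SIGMAS:
            bank.append(ndimage.gaussian_filter(self.ip.values, s))
            bank.append(ndimage.gaussian_laplace(self.ip.values, s))
        return bank

    @cached_property
    def cond_map(self) -> np.ndarray:
        """Single-scale log condition-number map at r = 4 rho."""
        r = max(1, int(round(self.config.cond_feature_radius_factor * self.ip.rho)))
        gx, gy = self.grad
        shape = gx.shape
        n = _disk_sums(np.ones(shape), r)
        sx, sy = _disk_sums(gx, r), _disk_sums(gy, r)
        sxx, syy = _disk_sums(gx * gx, r), _disk_sums(gy * gy, r)
        sxy = _disk_sums(gx * gy, r)
        mx, my = sx / n, sy / n
        cxx, cyy = sxx / n - mx * mx, syy / n - my * my
        cxy = sxy / n - mx * my
        half_tr = 0.5 * (cxx + cyy)
        d = np.sqrt((0.5 * (cxx - cyy)) ** 2 + cxy * cxy)
        lam1, lam2 = half_tr + d, np.maximum(half_tr - d, 0.0)
        eps = self.config.cov_eps
        return np.log((lam1 + eps) / (lam2 + eps))

    @cached_property
    def unit_grad(self) -> tuple[np.ndarray, np.ndarray]:
        gx, gy = self.grad
        mag = np.hypot(gx, gy)
        nx = np.divide(gx, mag, out=np.zeros_like(gx), where=mag > _EPS)
        ny = np.divide(gy, mag, out=np.zeros_like(gy), where=mag > _EPS)
        return nx, ny

    @cached_property
    def convergence_map(self) -> np.ndarray:
        """Mean cosine between the gradient and the outward radial direction.

        At a dark blob center the gradients of the surrounding pixels point
        radially outward (toward brighter), so the index peaks at +1 there.
        """
        r = self.config.convergence_radius
        size = 2 * r + 1
        dys, dxs = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
        dist = np.hypot(dxs, dys)
        inside = (dist <= r) & (dist > 0)
        count = inside.sum()
        kx = np.where(inside, dxs / np.maximum(dist, _EPS), 0.0) / count
        ky = np.where(inside, dys / np.maximum(dist, _EPS), 0.0) / count
        nx, ny = self.unit_grad
        return (ndimage.correlate(nx, kx, mode="constant")
                + ndimage.correlate(ny, ky, mode="constant"))

    @cached_property
    def divergence_map(self) -> np.ndarray:
        """Divergence of the unit gradient field (peaks at dark blob centers)."""
        nx, ny = self.unit_grad
        dnx = np.gradient(nx, axis=1)
        dny = np.gradient(ny, axis=0)
        return dnx + dny

    @cached_property
    def isolated_map(self) -> np.ndarray:
        """Ratio of ring mean to ring std (ring width 3 outside radius 7)."""
        cfg = self.config
        r_in = cfg.isolated_inner_radius
        r_out = r_in + cfg.isolated_ring_width
        v = self.ip.values
        ones = np.ones_like(v)
        n = _disk_sums(ones, r_out) - _disk_sums(ones, r_in)
        s1 = _disk_sums(v, r_out) - _disk_sums(v, r_in)
        s2 = _disk_sums(v * v, r_out) - _disk_sums(v * v, r_in)
        mean = s1 / n
        var = np.maximum(s2 / n - mean * mean, 0.0)
        # std floor 1e-3: far below sensor noise, keeps the index from
        # amplifying float dust on analytically flat rings
        return mean / (np.sqrt(var) + 1e-3)

    @cached_property
    def product_map(self) -> np.ndarray:
        return (self.cond_map * self.convergence_map
                * self.isolated_map * self.divergence_map)


# ---------------------------------------------------------------------------
# family extractors
# ---------------------------------------------------------------------------

def _region_masks(region: CandidateRegion, shape: tuple[int, int],
                  dilation_radius: int
                  ) -> tuple[tuple[slice, slice], np.ndarray, np.ndarray]:
    """Cropped (window, inside, outer-ring) masks for a candidate region.

    The window is the region bounding box expanded by the dilation radius and
    clipped to the image; ``inside``/``outer`` index into ``raster[window]``.
    """
    ys, xs = region.pixel_coords()
    keep = (ys >= 0) & (ys < shape[0]) & (xs >= 0) & (xs < shape[1])
    ys, xs = ys[keep], xs[keep]
    r = dilation_radius
    y0, y1 = max(0, ys.min() - r), min(shape[0], ys.max() + r + 1)
    x0, x1 = max(0, xs.min() - r), min(shape[1], xs.max() + r + 1)
    window = (slice(y0, y1), slice(x0, x1))
    inside = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    inside[ys - y0, xs - x0] = True
    dys, dxs = np.mgrid[-r : r + 1, -r : r + 1]
    footprint = dxs**2 + dys**2 <= r * r
    outer = ndimage.binary_dilation(inside, structure=footprint) & ~inside
    return window, inside, outer


def geometric_features(region: CandidateRegion) -> np.ndarray:
    """r1, r2, area, circularity, eccentricity, compactness."""
    area = region.area
    if area <= 1:
        return np.array([1.0, 1.0, float(area), 1.0, 0.0, 1.0])
    props = regionprops(region.mask.astype(np.uint8))[0]
    major = props.axis_major_length
    minor = props.axis_minor_length
    perimeter = props.perimeter
    equiv = props.equivalent_diameter_area
    if major < _EPS:                        # degenerate second moments
        r1, r2, ecc = 1.0, 1.0, 0.0
    else:
        r1, r2, ecc = minor / major, equiv / major, props.eccentricity
    if perimeter < _EPS:
        circ, comp = 1.0, 1.0
    else:
        circ = 4.0 * np.pi * area / perimeter**2
        comp = perimeter**2 / (4.0 * np.pi * area)
    return np.array([r1, r2, float(area), circ, ecc, comp])


def _mean_std(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return 0.0, 0.0
    return float(values.mean()), float(values.std())


def photometric_features(region: CandidateRegion, ctx: FeatureExtractor
                         ) -> np.ndarray:
    """Contrast (10) + intensity (42) + edge (1) features."""
    shape = ctx.ip.values.shape
    window, inside, outer = _region_masks(region, shape,
                                          ctx.config.outer_dilation_radius)
    rasters = {"Ip": ctx.ip.values, **ctx.channels}
    out: list[float] = []
    # contrast xi: max inside minus min outside, per channel
    for name in ("Ip",) + COLOR_CHANNEL_NAMES:
        v = rasters[name][window]
        if outer.any():
            out.append(float(v[inside].max() - v[outer].min()))
        else:
            out.append(0.0)
    # total / normalized intensity in I_p and green
    area = max(inside.sum(), 1)
    for name, raster in (("Ip", ctx.ip.values), ("green", ctx.channels["G"])):
        total = float(raster[window][inside].sum())
        mean = total / area
        fov_mean = ctx.fov_mean[name]
        out += [total, total / area, mean / fov_mean if fov_mean > _EPS else 0.0]
    # in/out mean and std per color channel
    for name in COLOR_CHANNEL_NAMES:
        v = rasters[name][window]
        mu_in, sd_in = _mean_std(v[inside])
        mu_out, sd_out = _mean_std(v[outer])
        out += [mu_in, sd_in, mu_out, sd_out]
    # boundary edge strength
    bys, bxs = region.boundary_coords()
    keep = (bys >= 0) & (bys < shape[0]) & (bxs >= 0) & (bxs < shape[1])
    edge = float(ctx.grad_mag[bys[keep], bxs[keep]].mean()) if keep.any() else 0.0
    out.append(edge)
    return np.array(out)


def texture_features(region: CandidateRegion, ctx: FeatureExtractor) -> np.ndarray:
    """Mean/std over Omega of Gaussian and LoG responses at four scales."""
    ys, xs = region.pixel_coords()
    shape = ctx.ip.values.shape
    keep = (ys >= 0) & (ys < shape[0]) & (xs >= 0) & (xs < shape[1])
    ys, xs = ys[keep], xs[keep]
    out: list[float] = []
    for i in range(len(TEXTURE_SIGMAS)):
        gauss, log = ctx.texture_bank[2 * i], ctx.texture_bank[2 * i + 1]
        out += [*_mean_std(gauss[ys, xs]), *_mean_std(log[ys, xs])]
    return np.array(out)


def gradient_field_features(region: CandidateRegion, ctx: FeatureExtractor
                            ) -> np.ndarray:
    """The 53 'other' features (ray-angle statistics + gradient-field maps)."""
    shape = ctx.ip.values.shape
    window, inside, outer = _region_masks(region, shape,
                                          ctx.config.outer_dilation_radius)
    gx, gy = ctx.grad
    seed = region.seed
    y0w, x0w = window[0].start, window[1].start

    def in_region(x: int, y: int) -> bool:
        iy, ix = y - y0w, x - x0w
        return (0 <= iy < inside.shape[0] and 0 <= ix < inside.shape[1]
                and inside[iy, ix])

    # per-direction mean angle difference between gradient and the ray direction
    n_dir = 36
    extent = int(np.ceil(np.sqrt(region.area / np.pi))) + 3
    per_dir = np.zeros(n_dir)
    all_diffs: list[float] = []
    for k in range(n_dir):
        theta = 2.0 * np.pi * k / n_dir
        c, s = np.cos(theta), np.sin(theta)
        diffs = []
        for t in range(1, extent + 1):
            # half-up rounding: translation-invariant (round-half-even is not)
            x = int(np.floor(seed.x + t * c + 0.5))
            y = int(np.floor(seed.y + t * s + 0.5))
            if not (0 <= x < shape[1] and 0 <= y < shape[0]) or not in_region(x, y):
                break
            g = np.hypot(gx[y, x], gy[y, x])
            if g < _EPS:
                diffs.append(0.0)          # zero gradient: flagged neutral
                continue
            ang = np.arctan2(gy[y, x], gx[y, x])
            d = np.angle(np.exp(1j * (ang - theta)))
            diffs.append(abs(d))
        per_dir[k] = np.degrees(np.mean(diffs)) if diffs else 0.0
        all_diffs += diffs
    mu_angle, sigma_angle = _mean_std(np.degrees(np.array(all_diffs)))

    out = list(per_dir) + [mu_angle, sigma_angle]
    for mp in (ctx.cond_map, ctx.convergence_map, ctx.divergence_map):
        crop = mp[window]
        out += [*_mean_std(crop[inside]), *_mean_std(crop[outer])]
    out += [*_mean_std(ctx.isolated_map[window][inside])]
    out.append(_mean_std(ctx.product_map[window][inside])[0])
    return np.array(out)


def extract_features(region: CandidateRegion, ctx: FeatureExtractor) -> np.ndarray:
    """Full 1247-slot feature vector for one candidate region."""
    vec = np.concatenate([
        geometric_features(region),
        photometric_features(region, ctx),
        texture_features(region, ctx),
        region_descriptors(ctx.ip.values, region.seed.x, region.seed.y),
        gradient_field_features(region, ctx),
    ])
    vec = np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)
    assert vec.shape[0] == N_FEATURES
    return vec
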