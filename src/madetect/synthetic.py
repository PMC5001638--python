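"""Synthetic fundus phantoms and labeled candidate sets.

The phantom generator renders the image structure the detector assumes, so
that every pipeline stage is testable without any database download:

* a smooth background with low-frequency shading and a linear illumination
  ramp;
* dark curvilinear vessels as quadratic Bezier curves with a Gaussian
  cross-profile of varying half-width (1-6 px at the reference width);
* dark microaneurysm pits as (an)isotropic Gaussians of radius ~1-6 px,
  covering the clinically observed taxonomy: regular, subtle low-contrast,
  irregular elongated (axis ratio kept >= 0.3), clustered pairs 4-8 px
  apart, and lesions adjacent to a vessel (2-4 px from its edge);
* additive i.i.d. Gaussian sensor noise.

Placement is by rejection sampling under the constraints above; the exact
center/radius list is returned as annotations, so the phantom doubles as
ground truth.  Regenerating from the same (params, seed) is bit-identical.

``generate_candidate_dataset`` instead emulates the *classification* stage's
statistics: a heavily imbalanced labeled feature table (e.g. 433 negatives
per positive, the imbalance level observed on real screening data) in which
the two classes are Gaussian clouds separated along 10 informative
coordinates embedded in the full 1247-dimensional feature space, the
remaining coordinates being nuisance noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .evaluate import Annotation
from .features import N_FEATURES
from .image import FundusImage


@dataclass(frozen=True)
class MACounts:
    regular: int = 4
    subtle: int = 1
    irregular: int = 1
    clustered_pairs: int = 1      # each pair contributes two lesions
    adjacent: int = 2

    @property
    def total(self) -> int:
        return (self.regular + self.subtle + self.irregular
                + 2 * self.clustered_pairs + self.adjacent)


@dataclass(frozen=True)
class PhantomParams:
    width: int = 768
    height: int = 576
    n_vessels: int = 6
    vessel_half_width: tuple[float, float] = (1.0, 6.0)
    vessel_contrast: tuple[float, float] = (0.08, 0.18)
    ma_counts: MACounts = field(default_factory=MACounts)
    ma_sigma: tuple[float, float] = (1.0, 2.5)          # radius ~ 1-6 px
    ma_contrast: tuple[float, float] = (0.10, 0.20)
    subtle_contrast: tuple[float, float] = (0.05, 0.08)
    cluster_gap: tuple[float, float] = (4.0, 8.0)       # center spacing, px
    adjacent_gap: tuple[float, float] = (2.0, 4.0)      # distance to vessel edge
    n_clutter: int = 450                                # unannotated dark specks
    clutter_contrast: tuple[float, float] = (0.02, 0.06)
    clutter_sigma: tuple[float, float] = (0.6, 1.4)
    background_level: float = 0.45
    ramp_amplitude: float = 0.1
    shading_amplitude: float = 0.05
    noise_sigma: float = 0.01
    fov_margin: int = 6
    min_separation: float = 14.0                        # generic MA spacing, px


@dataclass
class PhantomScene:
    image: FundusImage
    annotations: list[Annotation]
    vessel_centerlines: np.ndarray        # (N, 2) float (x, y) samples
    vessels: list[dict]                   # per-vessel pts / half_width / contrast
    noiseless_green: np.ndarray
    params: PhantomParams
    seed: int


def _bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _render_vessel(canvas: np.ndarray, pts: np.ndarray, half_width: float,
                   contrast: float) -> None:
    """Subtract a Gaussian-cross-profile ridge along a sampled centerline.

    ``half_width`` is the half-width at half maximum of the cross profile,
    so a 1-6 px half-width matches the 1-6 px vessel caliber the detector is
    scaled for; the Gaussian sigma is half_width / sqrt(2 ln 2).
    """
    sigma = half_width / np.sqrt(2.0 * np.log(2.0))
    h, w = canvas.shape
    margin = int(np.ceil(4 * sigma)) + 2
    x0 = max(0, int(pts[:, 0].min()) - margin)
    x1 = min(w, int(pts[:, 0].max()) + margin + 1)
    y0 = max(0, int(pts[:, 1].min()) - margin)
    y1 = min(h, int(pts[:, 1].max()) + margin + 1)
    if x0 >= x1 or y0 >= y1:
        return
    mask = np.ones((y1 - y0, x1 - x0), dtype=bool)
    ix = np.clip(np.round(pts[:, 0]).astype(int) - x0, 0, x1 - x0 - 1)
    iy = np.clip(np.round(pts[:, 1]).astype(int) - y0, 0, y1 - y0 - 1)
    mask[iy, ix] = False
    dist = ndimage.distance_transform_edt(mask)
    canvas[y0:y1, x0:x1] -= contrast * np.exp(-0.5 * (dist / sigma) ** 2)


def _render_ma(canvas: np.ndarray, cx: float, cy: float, depth: float,
               sigma_x: float, sigma_y: float, angle: float) -> None:
    h, w = canvas.shape
    margin = int(np.ceil(4 * max(sigma_x, sigma_y))) + 1
    x0, x1 = max(0, int(cx) - margin), min(w, int(cx) + margin + 1)
    y0, y1 = max(0, int(cy) - margin), min(h, int(cy) + margin + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1].astype(float)
    dx, dy = xs - cx, ys - cy
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    canvas[y0:y1, x0:x1] -= depth * np.exp(
        -0.5 * ((u / sigma_x) ** 2 + (v / sigma_y) ** 2)
    )


def generate_phantom(params: PhantomParams | None = None, seed: int = 0
                     ) -> PhantomScene:
    """Render one phantom scene with exact annotations."""
    if params is None:
        params = PhantomParams()
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width
    ys, xs = np.mgrid[0:h, 0:w].astype(float)

    # background: base level + linear ramp + smooth low-frequency shading
    green = np.full((h, w), params.background_level)
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (np.cos(theta) * xs / w + np.sin(theta) * ys / h)
    green += params.ramp_amplitude * (ramp - ramp.mean())
    for _ in range(3):
        bx, by = rng.uniform(0, w), rng.uniform(0, h)
        bs = rng.uniform(0.25, 0.5) * min(h, w)
        green += (params.shading_amplitude * rng.uniform(-1, 1)
                  * np.exp(-((xs - bx) ** 2 + (ys - by) ** 2) / (2 * bs**2)))

    # vessels: non-crossing quadratic Bezier arcs spanning the image.  Real
    # same-caliber vessels rarely cross; keeping the phantom arcade disjoint
    # also isolates the crossing failure mode (a crossing looks blob-like to
    # any shape-based vessel filter) from the suppression contract under test.
    vessels: list[dict] = []
    n_samples = int(2 * max(h, w))
    for _ in range(params.n_vessels):
        for _attempt in range(60):
            p0 = np.array([0.0, rng.uniform(0.08, 0.92) * h])
            p2 = np.array([w - 1.0, rng.uniform(0.08, 0.92) * h])
            mid_y = 0.5 * (p0[1] + p2[1]) + rng.uniform(-0.12, 0.12) * h
            p1 = np.array([rng.uniform(0.3, 0.7) * w,
                           np.clip(mid_y, 0.05 * h, 0.95 * h)])
            pts = _bezier(p0, p1, p2, n_samples)
            min_gap = min(
                (np.min(np.hypot(pts[::8, 0, None] - v["pts"][None, ::8, 0],
                                 pts[::8, 1, None] - v["pts"][None, ::8, 1]))
                 for v in vessels),
                default=np.inf,
            )
            if min_gap >= 14.0:
                break
        else:
            continue                         # could not fit another disjoint arc
        hw = rng.uniform(*params.vessel_half_width)
        contrast = rng.uniform(*params.vessel_contrast)
        _render_vessel(green, pts, hw, contrast)
        vessels.append({"pts": pts, "half_width": hw, "contrast": contrast})
    centerlines = (np.concatenate([v["pts"] for v in vessels]) if vessels
                   else np.empty((0, 2)))

    # FOV: inscribed circle (as in a fundus photograph)
    cx0, cy0 = (w - 1) / 2.0, (h - 1) / 2.0
    fov_r = min(w, h) / 2.0 - params.fov_margin
    fov = (xs - cx0) ** 2 + (ys - cy0) ** 2 <= fov_r**2

    def vessel_distance(x: float, y: float) -> float:
        if centerlines.size == 0:
            return np.inf
        return float(np.min(np.hypot(centerlines[:, 0] - x,
                                     centerlines[:, 1] - y)))

    margin = 24.0
    placed: list[tuple[float, float]] = []

    def sample_center(min_vessel_dist: float, max_vessel_dist: float = np.inf,
                      constraint: str = "") -> tuple[float, float]:
        for _ in range(1000):
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
            if (x - cx0) ** 2 + (y - cy0) ** 2 > (fov_r - margin) ** 2:
                continue
            d = vessel_distance(x, y)
            if not (min_vessel_dist <= d <= max_vessel_dist):
                continue
            if any(np.hypot(x - px, y - py) < params.min_separation
                   for px, py in placed):
                continue
            return x, y
        raise InvalidInputError(
            f"could not place a microaneurysm satisfying: {constraint or 'spacing'}"
        )

    annotations: list[Annotation] = []
    counts = params.ma_counts

    def add_ma(x: float, y: float, depth: float, sx: float, sy: float,
               angle: float) -> None:
        _render_ma(green, x, y, depth, sx, sy, angle)
        radius = float(max(3.0, 2.0 * max(sx, sy)))
        annotations.append(Annotation(x=x, y=y, radius=radius))
        placed.append((x, y))

    for _ in range(counts.regular):
        x, y = sample_center(12.0, constraint="regular MA clear of vessels")
        s = rng.uniform(*params.ma_sigma)
        add_ma(x, y, rng.uniform(*params.ma_contrast), s, s, 0.0)
    for _ in range(counts.subtle):
        x, y = sample_center(12.0, constraint="subtle MA clear of vessels")
        s = rng.uniform(*params.ma_sigma)
        add_ma(x, y, rng.uniform(*params.subtle_contrast), s, s, 0.0)
    for _ in range(counts.irregular):
        x, y = sample_center(12.0, constraint="irregular MA clear of vessels")
        s = rng.uniform(*params.ma_sigma)
        ratio = rng.uniform(0.45, 0.8)       # keeps segmented r1 >= 0.3
        add_ma(x, y, rng.uniform(*params.ma_contrast), s / np.sqrt(ratio),
               s * np.sqrt(ratio), rng.uniform(0, np.pi))
    for _ in range(counts.clustered_pairs):
        x, y = sample_center(14.0, constraint="clustered pair clear of vessels")
        gap = rng.uniform(*params.cluster_gap)
        ang = rng.uniform(0, 2 * np.pi)
        s1, s2 = rng.uniform(0.9, 1.5, size=2)   # compact, so each center stays
                                                  # a strict minimum of the pair
        d1, d2 = rng.uniform(*params.ma_contrast, size=2)
        x2, y2 = x + gap * np.cos(ang), y + gap * np.sin(ang)
        add_ma(x, y, d1, s1, s1, 0.0)
        _render_ma(green, x2, y2, d2, s2, s2, 0.0)
        annotations.append(Annotation(x=x2, y=y2, radius=float(max(3.0, 2 * s2))))
        placed.append((x2, y2))
    for _ in range(counts.adjacent):
        if not vessels:
            raise InvalidInputError(
                "cannot place a vessel-adjacent microaneurysm without vessels"
            )
        s = rng.uniform(1.0, 1.8)
        for _attempt in range(1000):
            v = vessels[rng.integers(0, len(vessels))]
            pts = v["pts"]
            i = rng.integers(n_samples // 10, 9 * n_samples // 10)
            tangent = pts[min(i + 1, n_samples - 1)] - pts[max(i - 1, 0)]
            normal = np.array([-tangent[1], tangent[0]])
            normal /= max(np.hypot(*normal), 1e-9)
            gap = rng.uniform(*params.adjacent_gap)
            # vessel "edge" ~ where the Gaussian profile falls to 20% contrast
            offset = 1.8 * v["half_width"] + gap + 1.5 * s
            x, y = pts[i] + rng.choice([-1.0, 1.0]) * offset * normal
            if (x - cx0) ** 2 + (y - cy0) ** 2 > (fov_r - margin) ** 2:
                continue
            if not (margin <= x <= w - margin and margin <= y <= h - margin):
                continue
            if any(np.hypot(x - px, y - py) < params.min_separation
                   for px, py in placed):
                continue
            if vessel_distance(x, y) < offset - 0.75:   # another vessel too close
                continue
            break
        else:
            raise InvalidInputError(
                "could not place a microaneurysm adjacent to a vessel"
            )
        add_ma(x, y, rng.uniform(*params.ma_contrast), s, s, 0.0)

    # unannotated faint dark specks: the background clutter that makes real
    # candidate classification a heavily imbalanced problem
    clutter_xy: list[tuple[float, float]] = []
    for _ in range(params.n_clutter):
        for _attempt in range(200):
            x = rng.uniform(params.fov_margin + 4, w - params.fov_margin - 4)
            y = rng.uniform(params.fov_margin + 4, h - params.fov_margin - 4)
            if (x - cx0) ** 2 + (y - cy0) ** 2 > (fov_r - 8.0) ** 2:
                continue
            if any(np.hypot(x - px, y - py) < 10.0 for px, py in placed):
                continue
            if vessel_distance(x, y) < 8.0:
                continue
            if any(np.hypot(x - qx, y - qy) < 5.0 for qx, qy in clutter_xy):
                continue
            break
        else:
            continue                       # skip a speck that will not fit
        s = rng.uniform(*params.clutter_sigma)
        _render_ma(green, x, y, rng.uniform(*params.clutter_contrast), s, s, 0.0)
        clutter_xy.append((x, y))

    noiseless = green.copy()
    noisy = green + rng.normal(0.0, params.noise_sigma, size=green.shape)
    noisy = np.clip(noisy, 0.0, 1.0)
    noiseless = np.clip(noiseless, 0.0, 1.0)

    # assemble an RGB image with the lesion structure in the green channel
    rgb = np.zeros((h, w, 3), dtype=np.uint16)
    red = np.clip(noisy * 1.3 + 0.15, 0.0, 1.0)
    blue = np.clip(noisy * 0.35, 0.0, 1.0)
    for k, chan in enumerate((red, noisy, blue)):
        arr = np.round(np.clip(chan, 0, 1) * 65535.0).astype(np.uint16)
        arr[~fov] = 0
        rgb[:, :, k] = arr
    noiseless[~fov] = 0.0

    return PhantomScene(
        image=FundusImage(pixels=rgb, fov_mask=fov),
        annotations=annotations,
        vessel_centerlines=centerlines,
        vessels=vessels,
        noiseless_green=noiseless,
        params=params,
        seed=seed,
    )


def generate_candidate_dataset(
    n_pos: int,
    ratio: float,
    overlap: float = 0.3,
    seed: int = 0,
    n_features: int = N_FEATURES,
    n_informative: int = 10,
    contamination: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Imbalanced labeled feature table emulating candidate classification.

    Positives and ``round(ratio * n_pos)`` negatives are drawn from two
    Gaussian mixtures whose means differ along ``n_informative`` embedded
    coordinates; the remaining coordinates are nuisance noise.  ``overlap``
    in [0, 1) moves the classes together (0 = wide separation).

    ``contamination`` draws that fraction of the negatives from the positive
    component, emulating the impure negative labels of real screening data
    (missed annotations, ambiguous multiple hits of one lesion); it also
    caps the sensitivity any classifier can reach at small false-positive
    budgets.  Returns (X, y), X float32.
    """
    if ratio < 1:
        raise InvalidInputError("ratio must be >= 1")
    if not (0 <= overlap < 1):
        raise InvalidInputError("overlap must lie in [0, 1)")
    if not (0 <= contamination < 1):
        raise InvalidInputError("contamination must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_neg = int(round(ratio * n_pos))
    n_total = n_pos + n_neg
    X = rng.standard_normal((n_total, n_features)).astype(np.float32)
    shift = (1.0 - overlap) * 6.0 / np.sqrt(n_informative)
    X[:n_pos, :n_informative] += shift
    n_cont = int(round(contamination * n_neg))
    X[n_pos : n_pos + n_cont, :n_informative] += shift
    y = np.zeros(n_total, dtype=int)
    y[:n_pos] = 1
    perm = rng.permutation(n_total)
    return X[perm], y[perm]
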