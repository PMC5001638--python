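"""Gradient-covariance condition-number vesselness (K map)."""

import numpy as np
import pytest
from scipy import ndimage

import madetect as md
from madetect.errors import InvalidInputError
from madetect.image import IntensityImage
from madetect.vesselness import (GradientField, condition_number, gradient,
                                 gradient_covariance, k_map, support_radii)

from conftest import gaussian_pit, vertical_ridge


def brute_force_k(img: IntensityImage,
                  eps: float = md.DEFAULT_CONFIG.cov_eps) -> np.ndarray:
    """Per-pixel double-loop K computation (the independent oracle)."""
    gy, gx = np.gradient(img.values)
    h, w = gx.shape
    K = np.zeros((h, w))
    for r in support_radii(img.rho):
        offsets = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)
                   if dx * dx + dy * dy <= r * r]
        for y in range(h):
            for x in range(w):
                pts = [(y + dy, x + dx) for dy, dx in offsets
                       if 0 <= y + dy < h and 0 <= x + dx < w]
                gxs = np.array([gx[p] for p in pts])
                gys = np.array([gy[p] for p in pts])
                mx, my = gxs.mean(), gys.mean()
                cxx = np.mean((gxs - mx) ** 2)
                cyy = np.mean((gys - my) ** 2)
                cxy = np.mean((gxs - mx) * (gys - my))
                tr = 0.5 * (cxx + cyy)
                d = np.sqrt((0.5 * (cxx - cyy)) ** 2 + cxy**2)
                K[y, x] += np.log((tr + d + eps) / (max(tr - d, 0.0) + eps))
    return K


class TestGradient:
    def test_constant_zero(self):
        f = gradient(IntensityImage(np.full((16, 16), 0.4)))
        assert np.all(f.dx == 0) and np.all(f.dy == 0)

    def test_linear_ramp(self):
        xx = np.tile(np.arange(32, dtype=float), (32, 1))
        f = gradient(IntensityImage(np.clip(0.01 * xx, 0, 1)))
        assert np.allclose(f.dx[:, 1:-1], 0.01)
        assert np.allclose(f.dy, 0.0, atol=1e-12)

    def test_gaussian_pit_matches_analytic(self):
        # gradient points radially outward (toward brighter) from the pit
        depth, sigma = 0.1, 4.0
        img = gaussian_pit(shape=(64, 64), center=(32, 32), depth=depth,
                           sigma=sigma)
        f = gradient(IntensityImage(img))
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.integers(10, 54, size=2)
            r2 = (x - 32.0) ** 2 + (y - 32.0) ** 2
            g = depth * np.exp(-r2 / (2 * sigma**2)) / sigma**2
            assert f.dx[y, x] == pytest.approx((x - 32.0) * g, abs=1e-3)
            assert f.dy[y, x] == pytest.approx((y - 32.0) * g, abs=1e-3)

    def test_too_small_image(self):
        with pytest.raises(InvalidInputError):
            gradient(IntensityImage(np.zeros((2, 2))))


class TestGradientCovariance:
    def test_constant_image_zero_matrix(self):
        f = gradient(IntensityImage(np.full((16, 16), 0.4)))
        cov = gradient_covariance(f, (8, 8), 4)
        assert np.allclose(cov, 0.0)

    def test_uniform_gradient_zero_matrix(self):
        f = GradientField(dx=np.full((16, 16), 0.3), dy=np.zeros((16, 16)))
        assert np.allclose(gradient_covariance(f, (8, 8), 4), 0.0)

    def test_ridge_principal_direction(self):
        img = vertical_ridge(shape=(48, 48), x0=24)
        f = gradient(IntensityImage(img))
        cov = gradient_covariance(f, (24, 24), 5)
        lam, vec = np.linalg.eigh(cov)
        principal = vec[:, np.argmax(lam)]
        angle = np.degrees(np.arctan2(abs(principal[1]), abs(principal[0])))
        assert angle < 5.0                       # along the x axis
        assert lam.min() / lam.max() < 0.05
        # brute-force covariance from explicitly enumerated support pixels
        pts = [(y, x) for y in range(48) for x in range(48)
               if (x - 24) ** 2 + (y - 24) ** 2 <= 25]
        gxs = np.array([f.dx[p] for p in pts])
        gys = np.array([f.dy[p] for p in pts])
        ref = np.cov(np.stack([gxs, gys]), bias=True)
        assert np.allclose(cov, ref, atol=1e-15)

    def test_support_outside_image(self):
        f = gradient(IntensityImage(np.full((16, 16), 0.4)))
        with pytest.raises(InvalidInputError):
            gradient_covariance(f, (100, 100), 3)


class TestConditionNumber:
    def test_identity_is_one(self):
        assert condition_number(np.eye(2)) == pytest.approx(1.0, rel=1e-5)

    def test_closed_form(self):
        assert condition_number(np.diag([4.0, 1.0]), eps=1e-15) == pytest.approx(4.0)

    def test_zero_matrix_regularized(self):
        assert condition_number(np.zeros((2, 2)), eps=1e-3) == 1.0


class TestKMap:
    def test_oracle_equivalence(self, ridge_pit_image):
        K = k_map(ridge_pit_image).values
        Kb = brute_force_k(ridge_pit_image)
        assert np.abs(K - Kb).max() < 1e-9

    def test_blob_low_ridge_high(self, ridge_pit_image):
        km = k_map(ridge_pit_image)
        k_pit = km.values[44, 44]
        k_ridge = km.values[20:44, 20].mean()
        assert k_pit < 0.5
        assert k_ridge > 5.0 * max(k_pit, 0.1)

    def test_scales_at_reference_resolution(self):
        assert support_radii(1.0) == [2, 3, 4, 5, 6, 7]
        km = k_map(IntensityImage(np.full((32, 32), 0.4)))
        assert (km.r_min, km.r_max, km.n_scales) == (2, 7, 6)

    def test_nonnegative(self, standard_extraction):
        assert standard_extraction["kmap"].values.min() >= 0.0

    def test_rotation_90_exact(self, ridge_pit_image):
        K1 = k_map(ridge_pit_image).values
        K2 = k_map(IntensityImage(np.rot90(ridge_pit_image.values).copy())).values
        assert np.abs(np.rot90(K1) - K2).max() < 1e-9

    def test_rotation_30_small_on_blob_phantom(self):
        # interpolation-compatible regime: smooth blobs only (near ridge
        # flanks K is not Lipschitz under resampling)
        params = md.PhantomParams(
            noise_sigma=0.0, n_clutter=0, n_vessels=0,
            ma_counts=md.MACounts(regular=6, subtle=2, irregular=0,
                                  clustered_pairs=0, adjacent=0))
        g = md.generate_phantom(params, seed=3).noiseless_green
        K1 = k_map(IntensityImage(g)).values
        rot = ndimage.rotate(g, 30, reshape=False, order=1, mode="nearest")
        K2 = k_map(IntensityImage(np.clip(rot, 0, 1))).values
        K1r = ndimage.rotate(K1, 30, reshape=False, order=1, mode="nearest")
        c = 170
        assert np.abs(K2 - K1r)[c:-c, c + 96 : -(c + 96)].mean() < 0.1
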