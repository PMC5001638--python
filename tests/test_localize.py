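"""Directional-second-derivative localization (facet model, P map)."""

import numpy as np
import pytest
from scipy import ndimage

import madetect as md
from madetect.errors import InvalidInputError
from madetect.image import IntensityImage
from madetect.localize import (FACET_WINDOW, CandidateLocation, PMap,
                               _facet_kernels,
                               clipped_second_directional_derivative,
                               facet_derivatives, localize_candidates, p_map)

from conftest import gaussian_pit


def brute_force_p(values: np.ndarray, n_directions: int = 36) -> np.ndarray:
    """Per-direction explicit-loop P computation (independent oracle)."""
    from madetect.localize import P_FACTOR_FLOOR, direction_vector

    kernels = _facet_kernels()
    v = -np.asarray(values, float)
    dx = ndimage.correlate(v, kernels["dx"], mode="nearest")
    dy = ndimage.correlate(v, kernels["dy"], mode="nearest")
    P = np.ones_like(v)
    for k in range(n_directions):
        c, s = direction_vector(2 * np.pi * k / n_directions)
        first = np.maximum(c * dx + s * dy, 0.0)
        gx = ndimage.correlate(first, kernels["dx"], mode="nearest")
        gy = ndimage.correlate(first, kernels["dy"], mode="nearest")
        second = c * gx + s * gy
        P *= np.where(second > P_FACTOR_FLOOR, second, 0.0)
    return P


def lstsq_facet_reference(values: np.ndarray, y: int, x: int) -> dict:
    """Per-pixel cubic facet fit via an explicit least-squares solve."""
    half = FACET_WINDOW // 2
    win = values[y - half : y + half + 1, x - half : x + half + 1]
    dys, dxs = np.mgrid[-half : half + 1, -half : half + 1]
    xs, ys2 = dxs.ravel().astype(float), dys.ravel().astype(float)
    A = np.stack([np.ones_like(xs), xs, ys2, xs**2, xs * ys2, ys2**2,
                  xs**3, xs**2 * ys2, xs * ys2**2, ys2**3], axis=1)
    coef, *_ = np.linalg.lstsq(A, win.ravel(), rcond=None)
    return {"dx": coef[1], "dy": coef[2], "dxx": 2 * coef[3],
            "dxy": coef[4], "dyy": 2 * coef[5]}


class TestFacetModel:
    def test_plane_reproduced_exactly(self):
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        d = facet_derivatives(0.3 + 0.02 * xx - 0.01 * yy)
        interior = np.s_[4:-4, 4:-4]
        assert np.allclose(d["dx"][interior], 0.02, atol=1e-12)
        assert np.allclose(d["dy"][interior], -0.01, atol=1e-12)
        for key in ("dxx", "dxy", "dyy"):
            assert np.abs(d[key][interior]).max() < 1e-12

    def test_quadratic_reproduced_exactly(self):
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        d = facet_derivatives(0.01 * xx**2)
        assert np.allclose(d["dxx"][4:-4, 4:-4], 0.02, atol=1e-10)

    def test_gaussian_hessian_accuracy(self):
        # the 7x7 cubic LS fit is a smoothing estimator: its curvature bias
        # is O((3 / sigma)^2), so the 5% band needs sigma well above the
        # window half-width; at sigma = 2 the bias is ~60% by construction
        depth, sigma = 0.2, 10.0
        img = gaussian_pit(shape=(61, 61), center=(30, 30), depth=depth,
                           sigma=sigma)
        d = facet_derivatives(img)
        analytic_dxx = depth / sigma**2          # at the pit center
        assert d["dxx"][30, 30] == pytest.approx(analytic_dxx, rel=0.05)
        assert d["dyy"][30, 30] == pytest.approx(analytic_dxx, rel=0.05)
        assert abs(d["dxy"][30, 30]) < 0.05 * analytic_dxx

    def test_matches_explicit_lstsq_fit(self):
        rng = np.random.default_rng(0)
        img = rng.random((24, 24))
        d = facet_derivatives(img)
        for y, x in [(5, 5), (10, 17), (15, 8), (18, 18)]:
            ref = lstsq_facet_reference(img, y, x)
            for key, val in ref.items():
                assert d[key][y, x] == pytest.approx(val, abs=1e-10)


class TestClippedSecondDerivative:
    def test_constant_zero(self):
        d = facet_derivatives(np.full((16, 16), 0.4))
        out = clipped_second_directional_derivative(d, 0.7)
        assert np.abs(out).max() < 1e-12

    def test_ramp_zero_in_interior(self):
        xx = np.tile(np.arange(32, dtype=float), (32, 1))
        d = facet_derivatives(0.01 * xx)
        out = clipped_second_directional_derivative(d, 0.0)
        assert np.abs(out[6:-6, 6:-6]).max() < 1e-12

    def test_pit_center_isotropic(self):
        # the pit center is an intensity minimum: second directional
        # derivatives are positive in every direction there
        img = gaussian_pit(shape=(33, 33), center=(16, 16), depth=0.2, sigma=2.5)
        d = facet_derivatives(img)
        v0 = clipped_second_directional_derivative(d, 0.0)[16, 16]
        v90 = clipped_second_directional_derivative(d, np.pi / 2)[16, 16]
        assert v0 > 0 and v90 > 0
        assert v0 == pytest.approx(v90, rel=0.02)


class TestPMap:
    def test_zero_factor_gives_zero(self):
        # a straight ridge: the along-ridge direction has ~zero second
        # derivative, so P = 0 on the whole centerline
        yy, xx = np.mgrid[0:48, 0:48].astype(float)
        residual = 0.2 * np.exp(-((xx - 24) ** 2) / (2 * 1.5**2))
        pm = p_map(residual)
        assert np.all(pm.values[10:-10, 24] == 0.0)

    def test_pit_center_unique_local_max(self):
        sigma = 2.0
        residual = 0.5 - gaussian_pit(shape=(33, 33), center=(16, 16),
                                      depth=0.2, sigma=sigma)
        pm = p_map(residual)
        region = pm.values[10:23, 10:23]         # radius 3 sigma
        iy, ix = np.unravel_index(np.argmax(region), region.shape)
        assert (iy + 10, ix + 10) == (16, 16)
        assert (region == region.max()).sum() == 1

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        residual = (0.15 * np.exp(-((xx - 44) ** 2 + (yy - 44) ** 2) / 8.0)
                    + 0.08 * np.exp(-((xx - 20) ** 2 + (yy - 24) ** 2) / 4.5)
                    + np.abs(rng.normal(0, 0.003, (64, 64))))
        pm = p_map(residual)
        oracle = brute_force_p(residual)
        mask = pm.values > 0
        assert mask.any()
        rel = np.abs(pm.values[mask] - oracle[mask]) / oracle[mask]
        assert rel.max() < 1e-6
        assert np.all((pm.values > 0) == (oracle > 0))

    def test_requires_four_directions(self):
        with pytest.raises(InvalidInputError):
            p_map(np.zeros((16, 16)), n_directions=3)


class TestLocalizeCandidates:
    def test_single_peak(self):
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        p = np.exp(-((xx - 12) ** 2 + (yy - 20) ** 2) / 4.0)
        cands = localize_candidates(PMap(values=p))
        assert len(cands) == 1
        assert (cands[0].x, cands[0].y) == (12, 20)

    def test_clustered_pits_resolved(self):
        residual = (0.5 - gaussian_pit(shape=(48, 48), center=(20, 24),
                                       depth=0.2, sigma=1.2)
                    + 0.5 - gaussian_pit(shape=(48, 48), center=(26, 24),
                                         depth=0.18, sigma=1.2))
        cands = localize_candidates(p_map(residual))
        found = {(c.x, c.y) for c in cands}
        assert any(abs(x - 20) <= 1 and abs(y - 24) <= 1 for x, y in found)
        assert any(abs(x - 26) <= 1 and abs(y - 24) <= 1 for x, y in found)

    def test_default_threshold(self):
        import inspect
        sig = inspect.signature(localize_candidates)
        assert sig.parameters["rel_threshold"].default == 0.1

    def test_zero_map_empty(self):
        assert localize_candidates(PMap(values=np.zeros((16, 16)))) == []

    def test_rotation_90_maps_candidates(self):
        residual = (0.5 - gaussian_pit(shape=(64, 64), center=(40, 22),
                                       depth=0.2, sigma=1.5)
                    + 0.5 - gaussian_pit(shape=(64, 64), center=(18, 50),
                                         depth=0.12, sigma=2.0))
        c1 = localize_candidates(p_map(residual))
        c2 = localize_candidates(p_map(np.rot90(residual).copy()))
        # np.rot90 maps (x, y) -> (y, N-1-x)
        mapped = {(c.y, 64 - 1 - c.x) for c in c1}
        assert {(c.x, c.y) for c in c2} == mapped

    def test_recovery_on_standard_phantom(self, standard_scene,
                                          standard_extraction):
        cands = standard_extraction["candidates"]
        hits = sum(
            any((c.x - a.x) ** 2 + (c.y - a.y) ** 2 <= 4.0 for c in cands)
            for a in standard_scene.annotations
        )
        assert hits >= 0.9 * len(standard_scene.annotations)
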