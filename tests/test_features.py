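"""Seven-family feature extraction (1247 slots)."""

import numpy as np
import pytest
from scipy import ndimage

import madetect as md
from madetect.descriptors import (extract_patch, gist_descriptor,
                                  hog_descriptor, surf_descriptor)
from madetect.features import (COLOR_CHANNEL_NAMES, N_FEATURES,
                               FeatureExtractor, color_channels,
                               extract_features, feature_names,
                               geometric_features, gradient_field_features,
                               photometric_features, texture_features)
from madetect.image import FundusImage, IntensityImage
from madetect.localize import CandidateLocation
from madetect.segment import CandidateRegion, segment_candidate

from conftest import gaussian_pit


def make_fundus(green: np.ndarray) -> FundusImage:
    px = np.zeros(green.shape + (3,), dtype=np.uint8)
    px[..., 0] = np.round(np.clip(green * 1.2 + 0.1, 0, 1) * 255)
    px[..., 1] = np.round(np.clip(green, 0, 1) * 255)
    px[..., 2] = np.round(np.clip(green * 0.4, 0, 1) * 255)
    return FundusImage(pixels=px)


def disk_region(center=(24, 24), radius=3.0, shape=(48, 48)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2
    return CandidateRegion(seed=CandidateLocation(center[0], center[1], 1.0),
                           mask=mask, offset=(0, 0))


@pytest.fixture(scope="module")
def pit_context():
    green = gaussian_pit(shape=(48, 48), center=(24, 24), depth=0.2, sigma=2.0)
    fundus = make_fundus(green)
    ip = IntensityImage(green)
    return FeatureExtractor(ip=ip, fundus=fundus)


def test_layout_is_1247():
    names = feature_names()
    assert len(names) == N_FEATURES == 1247
    assert len(set(names)) == 1247


class TestGeometric:
    def test_rasterized_disk(self):
        g = geometric_features(disk_region(radius=5.0))
        r1, r2, area, circ, ecc, comp = g
        assert 0.95 <= r1 <= 1.0
        assert 0.85 <= circ <= 1.2
        assert area == 81

    def test_thin_line(self):
        mask = np.zeros((5, 11), dtype=bool)
        mask[2, 1:10] = True
        region = CandidateRegion(seed=CandidateLocation(5, 2, 1.0), mask=mask,
                                 offset=(0, 0))
        assert geometric_features(region)[0] < 0.2

    def test_single_pixel_conventions(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        region = CandidateRegion(seed=CandidateLocation(1, 1, 1.0), mask=mask,
                                 offset=(0, 0))
        g = geometric_features(region)
        assert g[0] == 1.0 and g[2] == 1.0 and g[3] == 1.0


class TestPhotometric:
    def test_piecewise_constant_disk(self):
        green = np.full((48, 48), 0.7)
        yy, xx = np.mgrid[0:48, 0:48]
        inside = (xx - 24) ** 2 + (yy - 24) ** 2 <= 9.0
        green[inside] = 0.3
        ctx = FeatureExtractor(ip=IntensityImage(green),
                               fundus=make_fundus(green))
        out = photometric_features(disk_region(radius=3.0), ctx)
        xi_ip = out[0]
        assert xi_ip == pytest.approx(0.3 - 0.7, abs=1e-12)
        # mu_in/sigma_in/mu_out/sigma_out in the green channel (index 1)
        base = 10 + 6 + 4 * COLOR_CHANNEL_NAMES.index("G")
        mu_in, sd_in, mu_out, sd_out = out[base : base + 4]
        assert mu_in == pytest.approx(0.3, abs=1 / 255)
        assert mu_out == pytest.approx(0.7, abs=1 / 255)
        assert sd_in == pytest.approx(0.0, abs=1e-9)
        assert sd_out == pytest.approx(0.0, abs=1e-9)

    def test_constant_image(self):
        green = np.full((48, 48), 0.5)
        ctx = FeatureExtractor(ip=IntensityImage(green),
                               fundus=make_fundus(green))
        out = photometric_features(disk_region(radius=3.0), ctx)
        assert out[0] == pytest.approx(0.0, abs=1e-12)      # xi in I_p
        assert out[-1] == pytest.approx(0.0, abs=1e-12)     # mu_e

    def test_matches_brute_force_reference(self, pit_context):
        region = disk_region(radius=3.0)
        out = photometric_features(region, pit_context)
        ref = brute_force_photometric(region, pit_context)
        assert np.abs(out - ref).max() < 1e-9


def brute_force_photometric(region, ctx):
    """Independent straight-loop reference for the 53 photometric values."""
    shape = ctx.ip.values.shape
    mask = np.zeros(shape, dtype=bool)
    ys, xs = region.pixel_coords()
    mask[ys, xs] = True
    r = ctx.config.outer_dilation_radius
    outer = np.zeros(shape, dtype=bool)
    for y in range(shape[0]):
        for x in range(shape[1]):
            if mask[y, x]:
                continue
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if dx * dx + dy * dy <= r * r:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < shape[0] and 0 <= xx < shape[1] and mask[yy, xx]:
                            outer[y, x] = True
    rasters = {"Ip": ctx.ip.values, **ctx.channels}
    vals = []
    for name in ("Ip",) + COLOR_CHANNEL_NAMES:
        v = rasters[name]
        vals.append(v[mask].max() - v[outer].min())
    area = mask.sum()
    for name, raster in (("Ip", ctx.ip.values), ("green", ctx.channels["G"])):
        total = raster[mask].sum()
        vals += [total, total / area,
                 (total / area) / raster[ctx.ip.fov()].mean()]
    for name in COLOR_CHANNEL_NAMES:
        v = rasters[name]
        vals += [v[mask].mean(), v[mask].std(), v[outer].mean(), v[outer].std()]
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
    bys, bxs = np.nonzero(mask & ~interior)
    gy, gx = np.gradient(ctx.ip.values)
    vals.append(np.hypot(gx[bys, bxs], gy[bys, bxs]).mean())
    return np.array(vals)


class TestTexture:
    def test_constant_image(self):
        green = np.full((48, 48), 0.42)
        ctx = FeatureExtractor(ip=IntensityImage(green),
                               fundus=make_fundus(green))
        out = texture_features(disk_region(radius=3.0), ctx)
        gauss_means = out[0::4]
        log_means, log_stds = out[2::4], out[3::4]
        assert np.allclose(gauss_means, 0.42, atol=1e-9)
        # truncated LoG kernels leak a little DC; zero at image scale
        assert np.abs(log_means).max() < 1e-3
        assert np.abs(log_stds).max() < 1e-3

    def test_log_scale_matching(self, pit_context):
        out = texture_features(disk_region(radius=3.0), pit_context)
        mu_log_s2 = out[1 * 4 + 2]          # sigma = 2 block
        mu_log_s8 = out[3 * 4 + 2]          # sigma = 8 block
        assert abs(mu_log_s2) > abs(mu_log_s8)


class TestDescriptors:
    def test_zero_patch_all_zero(self):
        patch = np.zeros((31, 31))
        assert np.abs(hog_descriptor(patch)).max() == 0.0
        assert np.abs(surf_descriptor(patch)).max() == 0.0
        assert np.abs(gist_descriptor(patch)).max() == 0.0

    def test_descriptor_lengths(self):
        rng = np.random.default_rng(0)
        patch = rng.random((31, 31))
        assert hog_descriptor(patch).shape == (775,)
        assert surf_descriptor(patch).shape == (128,)
        assert gist_descriptor(patch).shape == (216,)

    def test_gist_rotation_permutation(self):
        rng = np.random.default_rng(1)
        patch = rng.random((31, 31))
        a = gist_descriptor(patch).reshape(24, 3, 3)
        b = gist_descriptor(patch[::-1, ::-1].copy()).reshape(24, 3, 3)
        assert np.allclose(b, a[:, ::-1, ::-1], atol=1e-10)

    def test_patch_zero_padding_at_border(self):
        values = np.ones((40, 40))
        patch = extract_patch(values, 0, 0)
        assert patch.shape == (31, 31)
        assert patch[0, 0] == 0.0 and patch[15, 15] == 1.0


class TestGradientFieldFeatures:
    def test_pit_gradients_near_radial(self, pit_context):
        out = gradient_field_features(disk_region(radius=3.0), pit_context)
        mu_angle = out[36]
        assert mu_angle < 10.0               # degrees
        # convergence index peaks at the pit center
        ci = pit_context.convergence_map
        assert ci[24, 24] == pytest.approx(ci.max(), abs=1e-9)
        assert ci[24, 24] > 0.9

    def test_constant_image_all_zero(self):
        green = np.full((48, 48), 0.5)
        ctx = FeatureExtractor(ip=IntensityImage(green),
                               fundus=make_fundus(green))
        out = gradient_field_features(disk_region(radius=3.0), ctx)
        assert np.abs(out[:38]).max() < 1e-9        # angle features

    def test_isolated_index_ring_parameters(self, pit_context):
        cfg = pit_context.config
        assert cfg.isolated_inner_radius == 7
        assert cfg.isolated_ring_width == 3


class TestFullVector:
    def test_length_and_finite(self, pit_context):
        vec = extract_features(disk_region(radius=3.0), pit_context)
        assert vec.shape == (1247,)
        assert np.all(np.isfinite(vec))

    def test_translation_invariance(self):
        green = gaussian_pit(shape=(64, 64), center=(26, 24), depth=0.2,
                             sigma=2.0)
        shifted = np.roll(np.roll(green, 7, axis=0), 5, axis=1)
        ctx_a = FeatureExtractor(ip=IntensityImage(green),
                                 fundus=make_fundus(green))
        ctx_b = FeatureExtractor(ip=IntensityImage(shifted),
                                 fundus=make_fundus(shifted))
        va = extract_features(disk_region(center=(26, 24), radius=3.0), ctx_a)
        vb = extract_features(disk_region(center=(31, 31), radius=3.0), ctx_b)
        # absolute for order-one features, relative for large-magnitude ones
        # (rolling changes float summation order)
        rel = np.abs(va - vb) / np.maximum(1.0, np.abs(va))
        assert rel.max() < 1e-9

    def test_finite_on_phantom_candidates(self, standard_scene,
                                          standard_extraction):
        ip = standard_extraction["ip"]
        ctx = FeatureExtractor(ip=ip, fundus=standard_scene.image)
        for seed in standard_extraction["candidates"][:25]:
            region = segment_candidate(ip, seed)
            vec = extract_features(region, ctx)
            assert vec.shape == (1247,)
            assert np.all(np.isfinite(vec))


def test_color_channels_in_unit_range(standard_scene):
    chans = color_channels(standard_scene.image)
    assert set(chans) == set(COLOR_CHANNEL_NAMES)
    for name, v in chans.items():
        assert v.min() >= 0.0 and v.max() <= 1.0
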