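"""Shared fixtures: analytic rasters and phantom scenes."""

from __future__ import annotations

import numpy as np
import pytest

import madetect as md
from madetect.image import IntensityImage


def gaussian_pit(shape=(64, 64), center=(32, 32), depth=0.15, sigma=2.0,
                 background=0.5):
    """Dark isotropic Gaussian pit on a constant background."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return background - depth * np.exp(
        -((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2.0 * sigma**2)
    )


def vertical_ridge(shape=(64, 64), x0=20, depth=0.12, sigma=1.5, background=0.5):
    """Dark vertical ridge with Gaussian cross-profile."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return background - depth * np.exp(-((xx - x0) ** 2) / (2.0 * sigma**2))


@pytest.fixture(scope="session")
def ridge_pit_image() -> IntensityImage:
    """64x64 raster with one vertical ridge and one isolated pit."""
    img = vertical_ridge() + gaussian_pit(center=(44, 44)) - 0.5
    return IntensityImage(np.clip(img, 0.0, 1.0))


@pytest.fixture(scope="session")
def standard_scene() -> md.PhantomScene:
    return md.generate_phantom(seed=1)


@pytest.fixture(scope="session")
def standard_extraction(standard_scene):
    """Preprocessing chain of the standard phantom, shared across tests."""
    ip = md.preprocess(standard_scene.image)
    km = md.k_map(ip)
    residual = md.remove_vessels(ip, km)
    pmap = md.p_map(residual)
    candidates = md.localize_candidates(pmap)
    return {"ip": ip, "kmap": km, "residual": residual, "pmap": pmap,
            "candidates": candidates}


@pytest.fixture(scope="session")
def phantom_fundus(standard_scene) -> md.FundusImage:
    return standard_scene.image
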