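"""Pipeline configuration.

Every numeric default used by the detection pipeline lives here so that a run
is fully described by (config, seed).  Scale-dependent parameters are written
as factors of ``rho = image_width / 768``, the resolution normalization used
throughout: the reference resolution has vessels and microaneurysms with radii
of roughly 1-6 pixels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass(frozen=True)
class DetectConfig:
    # --- preprocessing ---
    smooth_strength: float = 1.0         # median footprint radius = strength * rho
    bg_window_factor: float = 25.0       # shade-correction median radius = factor * rho

    # --- vesselness / vessel removal ---
    r_min_factor: float = 2.0            # smallest support radius = factor * rho
    r_max_factor: float = 7.0            # largest support radius = factor * rho
    cov_eps: float = 1e-8                # eigenvalue regularization for kappa
    k_threshold: float = 14.5            # K-map threshold at six ln-kappa terms
    k_threshold_scales: int = 6          # scale count the threshold was tuned for

    # --- localization ---
    n_directions: int = 36               # directions for the P map (10 degree step)
    p_rel_threshold: float = 0.1         # relative cut on the per-direction root of P
    dedup_radius: float = 2.0            # min spacing between candidates, px

    # --- segmentation ---
    seg_local_radius_factor: float = 8.0 # localized Chan-Vese ball = factor * rho
    seg_init_radius: float = 2.0
    seg_max_iters: int = 100

    # --- features ---
    patch_size: int = 31                 # descriptor patch edge, px
    outer_dilation_radius: int = 2       # outer ring for in/out statistics
    cond_feature_radius_factor: float = 4.0  # single-scale condition-number map
    convergence_radius: int = 5
    isolated_inner_radius: int = 7
    isolated_ring_width: int = 3

    # --- classification ---
    n_rounds: int = 500                  # RUSBoost rounds T
    tree_max_depth: int = 3
    tree_max_features: int | None = None
    area_min: float = 2.0                # exclusion bounds at rho = 1 (scaled by rho^2)
    area_max: float = 150.0
    r1_min: float = 0.3

    # --- evaluation ---
    fp_levels: tuple[float, ...] = field(
        default=(1 / 8, 1 / 4, 1 / 2, 1.0, 2.0, 4.0, 8.0)
    )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the effective configuration (logged into outputs)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


DEFAULT_CONFIG = DetectConfig()
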