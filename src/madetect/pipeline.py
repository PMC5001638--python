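"""End-to-end orchestration: candidate extraction, training and detection.

The detection path runs, per image:

    preprocess -> K map -> vessel removal -> P map -> localization
    -> localized Chan-Vese segmentation -> 1247-slot feature extraction
    -> geometric exclusion -> RUSBoost scoring

The training path runs the same extraction on annotated images, labels each
surviving candidate positive when it hits an annotation (all hits are kept
as positives — with several candidates inside one lesion one cannot tell
which is "the" true one) and negative otherwise, and fits the RUSBoost
ensemble on the resulting heavily imbalanced feature table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classify import (RUSBoostModel, exclusion_filter, rusboost_score,
                       rusboost_train)
from .config import DEFAULT_CONFIG, DetectConfig
from .errors import InvalidInputError
from .evaluate import Annotation, Finding, match_findings
from .features import (FEATURE_LAYOUT_VERSION, FeatureExtractor,
                       extract_features, geometric_features)
from .image import FundusImage, IntensityImage
from .localize import CandidateLocation, localize_candidates, p_map
from .preprocess import preprocess
from .segment import CandidateRegion, segment_candidate
from .vessel_removal import remove_vessels
from .vesselness import k_map

logger = logging.getLogger("madetect")


@dataclass
class ExtractionResult:
    """Per-image extraction output: surviving candidates and their features."""

    ip: IntensityImage
    candidates: list[CandidateRegion]
    features: np.ndarray                 # (n_candidates, 1247)

    def seeds(self) -> list[CandidateLocation]:
        return [r.seed for r in self.candidates]


def extract_candidates(
    img: FundusImage,
    config: DetectConfig = DEFAULT_CONFIG,
    remove_vessel_stage: bool = True,
) -> ExtractionResult:
    """Run the candidate-extraction stage on one image.

    ``remove_vessel_stage=False`` bypasses vessel suppression (used to
    verify that the stage actually reduces the candidate load).
    """
    ip = preprocess(img, config)
    if remove_vessel_stage:
        km = k_map(ip, config)
        residual = remove_vessels(ip, km, config=config)
    else:
        residual = ip.with_values(1.0 - ip.values)
    pm = p_map(residual, n_directions=config.n_directions)
    seeds = localize_candidates(pm, rel_threshold=config.p_rel_threshold,
                                dedup_radius=config.dedup_radius)
    logger.info("localized %d candidate seeds", len(seeds))

    regions = [segment_candidate(ip, s, config=config) for s in seeds]
    if regions:
        geom = np.stack([geometric_features(r) for r in regions])
        keep = exclusion_filter(geom[:, 2], geom[:, 0], rho=img.rho, config=config)
        regions = [r for r, k in zip(regions, keep) if k]
    logger.info("%d candidates survive the exclusion criterion", len(regions))

    ctx = FeatureExtractor(ip=ip, fundus=img, config=config)
    feats = (np.stack([extract_features(r, ctx) for r in regions])
             if regions else np.empty((0, 0)))
    return ExtractionResult(ip=ip, candidates=regions, features=feats)


def detect(
    img: FundusImage,
    model: RUSBoostModel,
    config: DetectConfig = DEFAULT_CONFIG,
) -> list[Finding]:
    """Detect microaneurysms in one image with a trained model."""
    if (model.feature_layout_version
            and model.feature_layout_version != FEATURE_LAYOUT_VERSION):
        raise InvalidInputError(
            "model was trained with a different feature layout "
            f"({model.feature_layout_version!r} != {FEATURE_LAYOUT_VERSION!r})"
        )
    res = extract_candidates(img, config)
    if not res.candidates:
        return []
    scores = rusboost_score(model, res.features)
    return [
        Finding(x=r.seed.x, y=r.seed.y, score=float(s))
        for r, s in zip(res.candidates, scores)
    ]


def label_candidates(
    result: ExtractionResult, annotations: list[Annotation]
) -> np.ndarray:
    """Binary labels: 1 for every candidate that hits an annotation."""
    findings = [Finding(x=r.seed.x, y=r.seed.y, score=0.0)
                for r in result.candidates]
    res = match_findings(findings, annotations)
    return (res.hit_index >= 0).astype(int)


def train_pipeline(
    images: list[FundusImage],
    annotations: list[list[Annotation]],
    config: DetectConfig = DEFAULT_CONFIG,
    seed: int = 0,
    T: int | None = None,
) -> RUSBoostModel:
    """Train the RUSBoost classifier from annotated images."""
    if len(images) == 0 or len(images) != len(annotations):
        raise InvalidInputError("need one annotation list per image")
    feats, labels = [], []
    for img, anns in zip(images, annotations):
        res = extract_candidates(img, config)
        if not res.candidates:
            continue
        feats.append(res.features)
        labels.append(label_candidates(res, anns))
    if not feats:
        raise InvalidInputError("no candidates extracted from the training images")
    X = np.concatenate(feats)
    y = np.concatenate(labels)
    if y.sum() == 0:
        raise InvalidInputError(
            "no positive candidates: increase phantom lesion contrast or "
            "check the annotations"
        )
    logger.info("training on %d candidates (%d positive, imbalance %.0f:1)",
                len(y), int(y.sum()), (len(y) - y.sum()) / max(y.sum(), 1))
    return rusboost_train(
        X, y,
        T=T if T is not None else config.n_rounds,
        seed=seed,
        max_depth=config.tree_max_depth,
        max_features=config.tree_max_features,
        feature_layout_version=FEATURE_LAYOUT_VERSION,
        config_hash=config.config_hash(),
    )
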