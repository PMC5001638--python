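"""Lesion-detection evaluation: hit matching, FROC, CPM, partial AUC.

Matching follows the free-response protocol used by the Retinopathy Online
Challenge: a finding *hits* the annotation closest to it if their center
distance is strictly smaller than that annotation's radius.  Each annotation
contributes at most one true positive — its highest-scoring hit — and every
other finding (extra hits and hit-misses) is a false positive.  Sweeping the
score threshold over all operating points yields the FROC curve (pooled
sensitivity versus mean false positives per image); the competition
performance metric (CPM) is the average sensitivity at the seven standard
levels 1/8, 1/4, 1/2, 1, 2, 4 and 8 FPs/image, and the partial AUC is the
area under the FROC curve between 1/8 and 8 FPs/image normalized by the
interval width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG
from .errors import InvalidInputError

STANDARD_FP_LEVELS: tuple[float, ...] = DEFAULT_CONFIG.fp_levels


@dataclass(frozen=True)
class Annotation:
    """A labeled MA center with its acceptance radius."""

    x: float
    y: float
    radius: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidInputError("annotation radius must be positive")


@dataclass(frozen=True)
class Finding:
    """A scored detection."""

    x: float
    y: float
    score: float


@dataclass
class MatchResult:
    is_tp: np.ndarray            # per finding
    hit_index: np.ndarray        # annotation index hit by each finding, -1 if miss
    detected: np.ndarray         # per annotation

    @property
    def n_tp(self) -> int:
        return int(self.is_tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.is_tp).sum())


@dataclass
class FROCCurve:
    """Operating points (FPs/image, pooled sensitivity), plus curve summaries."""

    fps_per_image: np.ndarray
    sensitivity: np.ndarray
    n_images: int
    n_annotations: int

    def sensitivity_at(self, level: float) -> float:
        """Right-continuous step convention: the sensitivity of the last
        operating point whose FPs/image does not exceed ``level``."""
        ok = self.fps_per_image <= level + 1e-12
        return float(self.sensitivity[ok].max()) if ok.any() else 0.0

    def sensitivities(self, levels=STANDARD_FP_LEVELS) -> np.ndarray:
        return np.array([self.sensitivity_at(lv) for lv in levels])


def match_findings(findings: list[Finding], annotations: list[Annotation]
                   ) -> MatchResult:
    """Label one image's findings as TP/FP against its annotations.

    A finding hits the *closest* annotation when the distance is strictly
    smaller than that annotation's radius (ties on closest broken by lower
    annotation index); among multiple hits of one annotation only the
    highest-scoring is the true positive.
    """
    n_f, n_a = len(findings), len(annotations)
    hit_index = np.full(n_f, -1, dtype=int)
    for i, f in enumerate(findings):
        best_j, best_d = -1, np.inf
        for j, a in enumerate(annotations):
            d = np.hypot(f.x - a.x, f.y - a.y)
            if d < best_d - 1e-12:
                best_j, best_d = j, d
        if best_j >= 0 and best_d < annotations[best_j].radius:
            hit_index[i] = best_j
    is_tp = np.zeros(n_f, dtype=bool)
    detected = np.zeros(n_a, dtype=bool)
    for j in range(n_a):
        hits = np.flatnonzero(hit_index == j)
        if hits.size:
            best = hits[np.argmax([findings[i].score for i in hits])]
            is_tp[best] = True
            detected[j] = True
    return MatchResult(is_tp=is_tp, hit_index=hit_index, detected=detected)


def froc(
    findings_per_image: list[list[Finding]],
    annotations_per_image: list[list[Annotation]],
) -> FROCCurve:
    """FROC curve pooled over images, sweeping all distinct scores."""
    if len(findings_per_image) != len(annotations_per_image):
        raise InvalidInputError("findings and annotations must align per image")
    n_images = len(findings_per_image)
    if n_images == 0:
        raise InvalidInputError("need at least one image")
    n_annotations = sum(len(a) for a in annotations_per_image)

    # per-finding annotation assignment; global identifiers per annotation
    rows = []            # (score, image, annotation_gid or -1)
    gid0 = 0
    for img, (fs, anns) in enumerate(zip(findings_per_image, annotations_per_image)):
        res = match_findings(fs, anns)
        for f, j in zip(fs, res.hit_index):
            rows.append((f.score, img, gid0 + j if j >= 0 else -1))
        gid0 += len(anns)

    if not rows or n_annotations == 0:
        return FROCCurve(np.array([0.0]), np.array([0.0]), n_images,
                         max(n_annotations, 1))

    scores = np.array([r[0] for r in rows])
    gids = np.array([r[2] for r in rows])
    order = np.argsort(-scores, kind="stable")
    scores, gids = scores[order], gids[order]

    fps_list, sens_list = [0.0], [0.0]
    seen: set[int] = set()
    n_tp = 0
    n_fp = 0
    for i in range(len(scores)):
        g = gids[i]
        if g >= 0 and g not in seen:
            seen.add(g)
            n_tp += 1
        else:
            n_fp += 1
        # emit an operating point after the last finding of each score value
        if i + 1 == len(scores) or scores[i + 1] < scores[i]:
            fps_list.append(n_fp / n_images)
            sens_list.append(n_tp / n_annotations)
    return FROCCurve(np.array(fps_list), np.array(sens_list), n_images,
                     n_annotations)


def cpm(curve: FROCCurve, levels=STANDARD_FP_LEVELS) -> float:
    """Competition performance metric: mean sensitivity at the 7 levels."""
    return float(np.mean(curve.sensitivities(levels)))


def cpm_from_sensitivities(sensitivities) -> float:
    """CPM directly from per-level sensitivities (e.g. a published table row)."""
    sens = np.asarray(sensitivities, dtype=float)
    if sens.size != len(STANDARD_FP_LEVELS):
        raise InvalidInputError("expected one sensitivity per standard level")
    return float(sens.mean())


def partial_auc(curve: FROCCurve, lo: float = 1 / 8, hi: float = 8.0) -> float:
    """Normalized area under the FROC step curve over [lo, hi]."""
    grid = np.unique(np.concatenate([
        [lo, hi], curve.fps_per_image[(curve.fps_per_image > lo)
                                      & (curve.fps_per_image < hi)]
    ]))
    area = 0.0
    for a, b in zip(grid[:-1], grid[1:]):
        area += curve.sensitivity_at(a) * (b - a)
    return area / (hi - lo)


# ---------------------------------------------------------------------------
# annotation / finding I/O (CSV dialect: image,x,y,radius[,confidence])
# ---------------------------------------------------------------------------

def load_annotations(path: str | Path) -> dict[str, list[Annotation]]:
    """Read annotations from the CSV dialect or a JSON list of records."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path)
    required = {"image", "x", "y", "radius"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"annotation table needs columns {sorted(required)}")
    out: dict[str, list[Annotation]] = {}
    for _, row in df.iterrows():
        conf = float(row["confidence"]) if "confidence" in df.columns else None
        out.setdefault(str(row["image"]), []).append(
            Annotation(float(row["x"]), float(row["y"]), float(row["radius"]), conf)
        )
    return out


def save_findings(path: str | Path, findings: dict[str, list[Finding]]) -> None:
    rows = [
        {"image": img, "x": f.x, "y": f.y, "score": f.score}
        for img, fs in findings.items() for f in fs
    ]
    pd.DataFrame(rows, columns=["image", "x", "y", "score"]).to_csv(path, index=False)


def load_findings(path: str | Path) -> dict[str, list[Finding]]:
    df = pd.read_csv(path)
    required = {"image", "x", "y", "score"}
    if not required.issubset(df.columns):
        raise InvalidInputError(
            f"findings table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    out: dict[str, list[Finding]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["image"]), []).append(
            Finding(float(row["x"]), float(row["y"]), float(row["score"]))
        )
    return out


def consensus_fusion(
    expert_annotations: list[list[Annotation]],
    min_agreement: float = 0.75,
    max_radius: float = 10.0,
) -> list[Annotation]:
    """Merge expert annotation lists by greedy center clustering.

    Annotations from different experts within ``max_radius`` of a cluster
    center are grouped; clusters supported by at least ``min_agreement`` of
    the experts are kept, with the member mean center and radius.
    """
    n_experts = len(expert_annotations)
    if n_experts == 0:
        return []
    pool = [(e, a) for e, anns in enumerate(expert_annotations) for a in anns]
    used = [False] * len(pool)
    fused = []
    for i, (e_i, a_i) in enumerate(pool):
        if used[i]:
            continue
        members = [(e_i, a_i)]
        used[i] = True
        for j in range(i + 1, len(pool)):
            if used[j]:
                continue
            e_j, a_j = pool[j]
            if e_j in {e for e, _ in members}:
                continue
            if np.hypot(a_i.x - a_j.x, a_i.y - a_j.y) <= max_radius:
                members.append((e_j, a_j))
                used[j] = True
        if len(members) / n_experts >= min_agreement:
            xs = np.mean([a.x for _, a in members])
            ys = np.mean([a.y for _, a in members])
            rs = np.mean([a.radius for _, a in members])
            fused.append(Annotation(float(xs), float(ys), float(rs)))
    return fused
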