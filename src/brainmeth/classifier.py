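"""The three-step hierarchical brain-tumor methylation caller.

Step A separates primary CNS tumors from metastases by thresholding the
BM score (metastasis minus glioblastoma region levels); step B assigns the
tissue of origin (melanoma / lung / breast) by argmax of the three origin
scores; step C, run only for breast-cancer metastases, assigns the
therapeutic subtype (HR+/HER2-, HER2+, HR-/HER2-) by argmax of the
subtype scores computed from a six-region panel (two regions per subtype).

Deployment thresholds are calibrated from labeled data (Youden-J optimum),
not hard-coded.  Ties and sub-margin gaps abstain rather than guess; a
malformed panel produces a structured error and no partial call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import PanelError
from .qmsp import (
    BUILTIN_SCORES,
    ORIGIN_SCORES,
    SUBTYPE_SCORES,
    ScoreDefinition,
    composite_score,
    roc_auc,
)

__all__ = [
    "ThresholdCalibration",
    "BrainMethModel",
    "BrainMethCall",
    "calibrate_threshold",
    "classify_step_a",
    "classify_step_b",
    "classify_step_c",
    "run_brainmeth",
]

PRIMARY_CNS = "primary_CNS"
METASTASIS = "metastasis"
ABSTAIN = "abstain"
NOT_APPLICABLE = "not_applicable"

#: score name -> class-B origin call
_ORIGIN_BY_SCORE = {"MBMscore": "MBM", "LCBMscore": "LCBM", "BCBMscore": "BCBM"}
#: score name -> class-C subtype call
_SUBTYPE_BY_SCORE = {
    "HR+/HER2-score": "HR+/HER2-",
    "HER2+score": "HER2+",
    "HR-/HER2-score": "HR-/HER2-",
}


@dataclass(frozen=True)
class ThresholdCalibration:
    """A calibrated operating threshold with its diagnostics."""

    threshold: float
    youden_j: float
    auc: float
    informative: bool  # False when the score does not separate the classes


def calibrate_threshold(scores, labels, seed: int = 0) -> ThresholdCalibration:
    """Youden-J-optimal threshold from a labeled calibration set.

    For perfectly separated scores the midpoint of the gap between the
    classes is returned; a score with no discriminating power (J = 0) is
    flagged non-informative.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    roc = roc_auc(scores, y, n_bootstrap=100, seed=seed)
    j = roc.sensitivity - (1.0 - roc.specificity)
    best = int(np.argmax(j))
    youden_j = float(j[best])
    min_pos = scores[y == 1].min()
    max_neg = scores[y == 0].max()
    if min_pos > max_neg:
        threshold = float((min_pos + max_neg) / 2.0)
    else:
        threshold = float(roc.thresholds[best])
    return ThresholdCalibration(
        threshold=threshold,
        youden_j=youden_j,
        auc=roc.auc,
        informative=youden_j > 0.0,
    )


def classify_step_a(bm_score: float, threshold: float) -> str:
    """Metastasis iff BM score >= threshold (equality calls metastasis)."""
    return METASTASIS if bm_score >= threshold else PRIMARY_CNS


def _argmax_call(scores: dict, call_by_score: dict, margin: float) -> tuple[str, float]:
    names = sorted(scores)
    values = np.array([scores[n] for n in names])
    order = np.argsort(-values)
    gap = float(values[order[0]] - values[order[1]])
    if gap == 0.0 or gap < margin:
        return ABSTAIN, gap
    return call_by_score[names[order[0]]], gap


def classify_step_b(
    mbm_score: float, lcbm_score: float, bcbm_score: float, margin: float = 0.0
) -> str:
    """Tissue-of-origin call: argmax of the three origin scores.

    Abstains on an exact tie or when the top-two gap is below ``margin``
    (default 0, i.e. pure argmax with tie-abstention).
    """
    call, _ = _argmax_call(
        {"MBMscore": mbm_score, "LCBMscore": lcbm_score, "BCBMscore": bcbm_score},
        _ORIGIN_BY_SCORE,
        margin,
    )
    return call


def classify_step_c(subtype_scores: dict, margin: float = 0.0) -> str:
    """Subtype call from the three subtype scores, abstaining on ties."""
    missing = [n for n in SUBTYPE_SCORES if n not in subtype_scores]
    if missing:
        raise PanelError(f"missing subtype scores: {missing}")
    call, _ = _argmax_call(
        {n: subtype_scores[n] for n in SUBTYPE_SCORES}, _SUBTYPE_BY_SCORE, margin
    )
    return call


@dataclass
class BrainMethModel:
    """Score definitions plus calibrated thresholds/margins of the caller."""

    class_a_threshold: float
    origin_margin: float = 0.0
    subtype_margin: float = 0.0
    scores: dict = field(default_factory=lambda: dict(BUILTIN_SCORES))

    def to_json(self) -> str:
        payload = {
            "class_a_threshold": self.class_a_threshold,
            "origin_margin": self.origin_margin,
            "subtype_margin": self.subtype_margin,
            "scores": {
                name: {"positive": list(d.positive), "negative_groups": [list(g) for g in d.negative_groups]}
                for name, d in self.scores.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BrainMethModel":
        payload = json.loads(text)
        scores = {
            name: ScoreDefinition(
                name,
                tuple(d["positive"]),
                tuple(tuple(g) for g in d["negative_groups"]),
            )
            for name, d in payload["scores"].items()
        }
        return cls(
            class_a_threshold=payload["class_a_threshold"],
            origin_margin=payload.get("origin_margin", 0.0),
            subtype_margin=payload.get("subtype_margin", 0.0),
            scores=scores,
        )


@dataclass
class BrainMethCall:
    """A full hierarchical call for one sample, with provenance.

    ``class_b`` is populated only when class A calls a metastasis, and
    ``class_c`` only when class B calls a breast-cancer metastasis.
    """

    sample_id: str
    class_a: str
    bm_score: float
    class_a_threshold: float
    class_b: str | None = None
    origin_scores: dict | None = None
    class_c: str | None = None
    subtype_scores: dict | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def run_brainmeth(
    sample_id: str, panel_levels: dict, model: BrainMethModel
) -> BrainMethCall:
    """Execute the A → (B) → (C) cascade on a sample's panel levels.

    ``panel_levels`` maps region id → methylation level.  The class-A
    regions are always required; class-B regions are required as soon as
    class A calls a metastasis, and the six class-C regions as soon as
    class B calls BCBM.  Any missing region raises :class:`PanelError`
    before a partial call is produced.
    """
    bm_def = model.scores["BMscore"]
    bm_score = composite_score(panel_levels, bm_def)
    class_a = classify_step_a(bm_score, model.class_a_threshold)
    call = BrainMethCall(
        sample_id=sample_id,
        class_a=class_a,
        bm_score=bm_score,
        class_a_threshold=model.class_a_threshold,
        provenance={
            "origin_margin": model.origin_margin,
            "subtype_margin": model.subtype_margin,
            "score_regions": {n: list(model.scores[n].regions) for n in model.scores},
        },
    )
    if class_a != METASTASIS:
        return call

    origin_scores = {n: composite_score(panel_levels, model.scores[n]) for n in ORIGIN_SCORES}
    call.origin_scores = origin_scores
    call.class_b = classify_step_b(
        origin_scores["MBMscore"],
        origin_scores["LCBMscore"],
        origin_scores["BCBMscore"],
        margin=model.origin_margin,
    )
    if call.class_b != "BCBM":
        call.class_c = NOT_APPLICABLE if call.class_b != ABSTAIN else None
        return call

    subtype_scores = {n: composite_score(panel_levels, model.scores[n]) for n in SUBTYPE_SCORES}
    call.subtype_scores = subtype_scores
    call.class_c = classify_step_c(subtype_scores, margin=model.subtype_margin)
    return call
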