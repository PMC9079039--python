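"""Template selection: pick the atlas whose shape best matches a subject.

All five dimensions are first normalized by the ML width, removing overall
joint size so templates are compared by shape. The score against each atlas
is the RMSE over the four remaining ratios (AP medial/lateral, JSW
medial/lateral); the atlas with the minimal score wins. A sum-of-absolute-
differences score is available as an alternative reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from kneefe.anatomy import AnatomicalDimensions, ValidationError
from kneefe.atlas import AtlasRecord

__all__ = ["NormalizedDimensions", "MatchResult", "normalize", "rmse", "select_template"]


@dataclass(frozen=True)
class NormalizedDimensions:
    """The four ML-normalized shape ratios (dimension / ml_width)."""

    r_ap_medial: float
    r_ap_lateral: float
    r_jsw_medial: float
    r_jsw_lateral: float

    def __post_init__(self) -> None:
        for name in ("r_ap_medial", "r_ap_lateral", "r_jsw_medial", "r_jsw_lateral"):
            v = getattr(self, name)
            if not (0 < v < 2):
                raise ValidationError(f"{name}={v!r} outside (0, 2)")
        if self.r_jsw_medial >= self.r_ap_medial or self.r_jsw_lateral >= self.r_ap_lateral:
            raise ValidationError("JSW ratios must be smaller than AP ratios")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.r_ap_medial, self.r_ap_lateral, self.r_jsw_medial, self.r_jsw_lateral]
        )


@dataclass(frozen=True)
class MatchResult:
    subject_id: str
    best_atlas_id: str
    scores: dict[str, float]  # atlas_id -> score, whole library

    def __post_init__(self) -> None:
        if self.best_atlas_id not in self.scores:
            raise ValidationError("best atlas missing from score table")
        if self.scores[self.best_atlas_id] > min(self.scores.values()) + 1e-15:
            raise ValidationError("best atlas does not have the minimal score")


def normalize(dims: AnatomicalDimensions) -> NormalizedDimensions:
    """Divide the four AP/JSW dimensions by the ML width."""
    w = dims.ml_width
    return NormalizedDimensions(
        r_ap_medial=dims.ap_medial / w,
        r_ap_lateral=dims.ap_lateral / w,
        r_jsw_medial=dims.jsw_medial / w,
        r_jsw_lateral=dims.jsw_lateral / w,
    )


def rmse(a: NormalizedDimensions, b: NormalizedDimensions) -> float:
    """Root-mean-square difference over the four shape ratios."""
    d = a.as_array() - b.as_array()
    return float(np.sqrt(np.mean(d * d)))


def sum_abs(a: NormalizedDimensions, b: NormalizedDimensions) -> float:
    """Sum of absolute ratio differences (alternative matching score)."""
    return float(np.abs(a.as_array() - b.as_array()).sum())


_SCORES = {"rmse4": rmse, "sum_abs": sum_abs}

#: Score differences below this are treated as ties (broken by atlas_id).
TIE_TOL = 1e-12


def select_template(
    subject_dims: AnatomicalDimensions,
    library: list[AtlasRecord],
    subject_id: str = "subject",
    score: str = "rmse4",
) -> MatchResult:
    """Score the subject against every atlas and return the argmin.

    Ties within ``TIE_TOL`` are broken by lexicographic atlas id so the
    result never depends on library ordering.
    """
    if not library:
        raise ValueError("empty atlas library")
    score_fn = _SCORES[score]
    target = normalize(subject_dims)
    scores = {rec.atlas_id: score_fn(target, normalize(rec.dimensions)) for rec in library}
    lowest = min(scores.values())
    best = min(aid for aid, s in scores.items() if s <= lowest + TIE_TOL)
    return MatchResult(subject_id=subject_id, best_atlas_id=best, scores=scores)
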