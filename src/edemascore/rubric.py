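"""Weighted ordinal rubric for pulmonary-edema findings on bedside chest radiographs.

Nine radiographic indicators are each graded on an ordinal scale whose
level 0 always means "finding absent" and scores zero. The remaining
levels carry increasing point values that weight how specifically the
finding reflects extravascular lung water: hilar-vessel changes are weak
indicators (max 3-9 points), while extensive perihilar haze and a diffuse
increase in density directly represent lung water (max 15 points each).
The per-item points are summed; a total strictly above the threshold
(default 15) classifies the radiograph as showing pulmonary edema.

Seven of the indicators use a four-level scale (absent/mild/moderate/
severe); Kerley B lines and micronoduli use a three-level scale whose
two present grades are stored positionally (lower/higher severity).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import RubricError, ValidationError

EDEMA = "edema"
NO_EDEMA = "no_edema"

#: Canonical indicator order and point vectors of the default rubric.
DEFAULT_POINTS: dict[str, tuple[int, ...]] = {
    "hilar_enlarged": (0, 1, 2, 3),
    "hilar_density": (0, 2, 4, 6),
    "hilar_blurred": (0, 3, 6, 9),
    "kerley_b": (0, 4, 8),
    "micronoduli": (0, 4, 8),
    "fissure_widening": (0, 4, 8, 12),
    "cuffs": (0, 4, 8, 12),
    "perihilar_haze": (0, 5, 10, 15),
    "diffuse_density": (0, 5, 10, 15),
}

DEFAULT_THRESHOLD = 15

#: Human-readable level labels, cosmetic only; scoring is positional.
LEVEL_LABELS_4 = ("missing", "mild", "moderate", "severe")
LEVEL_LABELS_3 = ("missing", "lower", "higher")


@dataclass(frozen=True)
class Indicator:
    """One scoreable radiographic finding.

    ``points_by_level[0]`` is the score of an absent finding and must be 0;
    the points of present levels must be strictly increasing so a more
    severe grade never scores less.
    """

    id: str
    points_by_level: tuple[int, ...]

    def __post_init__(self) -> None:
        pts = tuple(int(p) for p in self.points_by_level)
        object.__setattr__(self, "points_by_level", pts)
        if len(pts) < 2:
            raise RubricError(f"indicator {self.id!r} needs at least one present level")
        if pts[0] != 0:
            raise RubricError(f"indicator {self.id!r}: level 0 (missing) must score 0")
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise RubricError(
                f"indicator {self.id!r}: points must be strictly increasing, got {pts}"
            )

    @property
    def scale_size(self) -> int:
        return len(self.points_by_level)

    @property
    def max_points(self) -> int:
        return self.points_by_level[-1]


@dataclass(frozen=True)
class Rubric:
    """A full scoring rubric: ordered indicators plus the decision threshold."""

    indicators: tuple[Indicator, ...]
    threshold: int = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.indicators]
        if len(set(ids)) != len(ids):
            raise RubricError(f"duplicate indicator ids: {ids}")
        if not 0 < self.threshold < self.max_total:
            raise RubricError(
                f"threshold {self.threshold} must lie strictly between 0 and "
                f"the maximum total {self.max_total}"
            )

    @property
    def max_total(self) -> int:
        return sum(ind.max_points for ind in self.indicators)

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.indicators)

    def __getitem__(self, indicator_id: str) -> Indicator:
        for ind in self.indicators:
            if ind.id == indicator_id:
                return ind
        raise RubricError(f"unknown indicator {indicator_id!r}")

    def __contains__(self, indicator_id: str) -> bool:
        return any(ind.id == indicator_id for ind in self.indicators)

    def checksum(self) -> str:
        """Short stable digest of weights and threshold, for report provenance."""
        canon = ";".join(
            f"{ind.id}:{','.join(map(str, ind.points_by_level))}" for ind in self.indicators
        )
        canon += f";threshold:{self.threshold}"
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RatingSheet:
    """One reader's per-indicator severity levels for one radiograph."""

    case_id: str
    reader_id: str
    levels: Mapping[str, int] = field(default_factory=dict)

    def validate(self, rubric: Rubric) -> None:
        missing = [i for i in rubric.indicator_ids if i not in self.levels]
        extra = [i for i in self.levels if i not in rubric]
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"missing indicators {missing}")
            if extra:
                parts.append(f"unknown indicators {extra}")
            raise ValidationError(
                f"sheet (case={self.case_id}, reader={self.reader_id}): " + "; ".join(parts)
            )
        for ind_id, level in self.levels.items():
            ind = rubric[ind_id]
            if not (isinstance(level, (int,)) and 0 <= level < ind.scale_size):
                raise ValidationError(
                    f"sheet (case={self.case_id}, reader={self.reader_id}): level {level!r} "
                    f"out of range for indicator {ind_id!r} (scale size {ind.scale_size})"
                )


@dataclass(frozen=True)
class ScoreResult:
    per_item_points: Mapping[str, int]
    total: int
    classification: str  # EDEMA or NO_EDEMA


def default_rubric() -> Rubric:
    """The nine-indicator rubric with its published weights (max total 88)."""
    return Rubric(
        indicators=tuple(Indicator(i, p) for i, p in DEFAULT_POINTS.items()),
        threshold=DEFAULT_THRESHOLD,
    )


def item_points(rubric: Rubric, indicator: str, level: int) -> int:
    """Points scored by one indicator at one severity level."""
    ind = rubric[indicator]
    if not 0 <= level < ind.scale_size:
        raise ValidationError(
            f"level {level} out of range for indicator {indicator!r} "
            f"(valid: 0..{ind.scale_size - 1})"
        )
    return ind.points_by_level[level]


def classify_score(total: int, threshold: int = DEFAULT_THRESHOLD) -> str:
    """Edema iff the total is strictly above the threshold.

    The boundary is inclusive on the no-edema side: a total equal to the
    threshold is rated as no pulmonary edema. This is the single
    comparison site for the decision rule.
    """
    if total < 0:
        raise ValidationError(f"total score must be non-negative, got {total}")
    return EDEMA if total > threshold else NO_EDEMA


def total_score(rubric: Rubric, sheet: RatingSheet) -> ScoreResult:
    """Score a rating sheet: per-item points, their sum, and the classification."""
    sheet.validate(rubric)
    per_item = {i: item_points(rubric, i, sheet.levels[i]) for i in rubric.indicator_ids}
    total = sum(per_item.values())
    return ScoreResult(
        per_item_points=per_item,
        total=total,
        classification=classify_score(total, rubric.threshold),
    )


def load_rubric(path: str) -> Rubric:
    """Load a rubric from YAML: ``indicators: {id: [points...]}, threshold: int``.

    The default rubric is frozen in code; this hook exists so
    sensitivity-to-weights experiments can swap in alternative weightings.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "indicators" not in cfg:
        raise RubricError(f"rubric file {path}: expected mapping with 'indicators' key")
    indicators = tuple(
        Indicator(name, tuple(pts)) for name, pts in cfg["indicators"].items()
    )
    return Rubric(indicators=indicators, threshold=int(cfg.get("threshold", DEFAULT_THRESHOLD)))
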