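"""Synthetic multi-reader reading studies for end-to-end pipeline testing.

No radiographs are involved: a cohort of cases gets integer EVLW values
drawn uniformly within the no-edema (4-8 mL/kg) and edema (15-21 mL/kg)
bands, each case gets latent per-indicator severities drawn from a
configurable severity model conditional on its true status, and each
simulated reader produces (a) a rating sheet — the latent severities
perturbed by the reader's ordinal mis-grading noise — and (b) an unaided
binary call drawn from the reader's configured standard-approach
operating point (sensitivity / specificity).

Two severity presets ship with the package:

``separable``
    Degenerate: edema cases show every finding at its top grade, no-edema
    cases show none. The score arm is then a perfect classifier — useful
    for contract tests.

``paper_like``
    Calibrated so that, noise-free, the probability that an edema case
    scores above the decision threshold is ~0.77 while a no-edema case
    essentially never does — i.e. the score arm operates near
    sensitivity 77% / specificity 100%. No biological claim is attached
    to the individual level probabilities.

All randomness flows through one seeded generator per operation;
identical seeds give bit-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError, ValidationError
from .rubric import (
    EDEMA,
    NO_EDEMA,
    RatingSheet,
    Rubric,
    default_rubric,
    total_score,
)
from .stats import (
    BORDERLINE,
    CallMatrix,
    ReferenceStandard,
    StudyReport,
    evaluate_study,
)

DEFAULT_EVLW_RANGES = {
    NO_EDEMA: (4, 8),
    EDEMA: (15, 21),
    BORDERLINE: (9, 14),
}


@dataclass(frozen=True)
class CohortParams:
    """Two-group (plus optional borderline) cohort composition."""

    n_edema: int = 10
    n_no_edema: int = 10
    n_borderline: int = 0
    evlw_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_EVLW_RANGES)
    )

    def __post_init__(self) -> None:
        if min(self.n_edema, self.n_no_edema, self.n_borderline) < 0:
            raise InputError("cohort counts must be non-negative")
        if self.n_edema + self.n_no_edema + self.n_borderline == 0:
            raise InputError("cohort is empty")
        bands = {NO_EDEMA: (1, 8), BORDERLINE: (9, 14), EDEMA: (15, 10**6)}
        for status, (lo, hi) in self.evlw_ranges.items():
            blo, bhi = bands[status]
            if not (blo <= lo <= hi <= bhi):
                raise InputError(
                    f"EVLW range {lo}-{hi} for {status!r} violates the "
                    f"{blo}-{bhi} mL/kg band"
                )


@dataclass(frozen=True)
class ReaderProfile:
    """Per-reader noise parameters.

    ``rating_noise`` is the probability that the reader mis-grades any
    single indicator by one ordinal level (direction uniform, clamped to
    the valid range). ``standard_sens`` / ``standard_spec`` are the
    operating point of the reader's unaided binary call.
    """

    reader_id: str
    rating_noise: float = 0.05
    standard_sens: float = 0.57
    standard_spec: float = 0.90

    def __post_init__(self) -> None:
        for name in ("rating_noise", "standard_sens", "standard_spec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SeverityModel:
    """Per-indicator level distributions conditional on true edema status."""

    edema: Mapping[str, tuple[float, ...]]
    no_edema: Mapping[str, tuple[float, ...]]

    def validate(self, rubric: Rubric) -> None:
        for status, table in (("edema", self.edema), ("no_edema", self.no_edema)):
            if set(table) != set(rubric.indicator_ids):
                raise ValidationError(
                    f"severity model ({status}) indicators do not match the rubric: "
                    f"{sorted(set(table) ^ set(rubric.indicator_ids))}"
                )
            for ind_id, probs in table.items():
                ind = rubric[ind_id]
                if len(probs) != ind.scale_size:
                    raise ValidationError(
                        f"severity model ({status}, {ind_id}): {len(probs)} "
                        f"probabilities for a {ind.scale_size}-level scale"
                    )
                if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                    raise ValidationError(
                        f"severity model ({status}, {ind_id}): probabilities "
                        f"must be non-negative and sum to 1, got {probs}"
                    )

    def table(self, status: str) -> Mapping[str, tuple[float, ...]]:
        if status == EDEMA:
            return self.edema
        if status == NO_EDEMA:
            return self.no_edema
        # Borderline cases have no modelled radiographic phenotype; they are
        # excluded by the evaluation stage. Rate them like no-edema cases.
        return self.no_edema

    def threshold_exceedance(self, rubric: Rubric, status: str) -> float:
        """Exact P(total > threshold | status) by convolving the level PMFs."""
        pmf = {0: 1.0}
        for ind in rubric.indicators:
            probs = self.table(status)[ind.id]
            nxt: dict[int, float] = {}
            for tot, p in pmf.items():
                for pts, q in zip(ind.points_by_level, probs):
                    if q:
                        nxt[tot + pts] = nxt.get(tot + pts, 0.0) + p * q
            pmf = nxt
        return sum(p for tot, p in pmf.items() if tot > rubric.threshold)


def separable_model(rubric: Rubric | None = None) -> SeverityModel:
    """Degenerate preset: edema -> all findings severe, no edema -> none."""
    rubric = rubric or default_rubric()
    edema, clean = {}, {}
    for ind in rubric.indicators:
        top = [0.0] * ind.scale_size
        top[-1] = 1.0
        none = [0.0] * ind.scale_size
        none[0] = 1.0
        edema[ind.id] = tuple(top)
        clean[ind.id] = tuple(none)
    return SeverityModel(edema=edema, no_edema=clean)


#: Calibrated so P(total > 15 | edema) ~= 0.77 and P(total > 15 | no edema)
#: is negligible under the default rubric (checked exactly by convolution).
_PAPER_LIKE_EDEMA = {
    "hilar_enlarged": (0.31, 0.35, 0.24, 0.10),
    "hilar_density": (0.37, 0.35, 0.19, 0.09),
    "hilar_blurred": (0.36, 0.35, 0.19, 0.10),
    "kerley_b": (0.57, 0.33, 0.10),
    "micronoduli": (0.61, 0.29, 0.10),
    "fissure_widening": (0.56, 0.29, 0.10, 0.05),
    "cuffs": (0.52, 0.29, 0.14, 0.05),
    "perihilar_haze": (0.46, 0.35, 0.14, 0.05),
    "diffuse_density": (0.52, 0.34, 0.10, 0.04),
}
_PAPER_LIKE_NO_EDEMA = {
    "hilar_enlarged": (0.70, 0.25, 0.05, 0.00),
    "hilar_density": (0.80, 0.18, 0.02, 0.00),
    "hilar_blurred": (0.80, 0.18, 0.02, 0.00),
    "kerley_b": (0.92, 0.08, 0.00),
    "micronoduli": (0.92, 0.08, 0.00),
    "fissure_widening": (0.88, 0.12, 0.00, 0.00),
    "cuffs": (0.88, 0.12, 0.00, 0.00),
    "perihilar_haze": (0.94, 0.06, 0.00, 0.00),
    "diffuse_density": (0.94, 0.06, 0.00, 0.00),
}


def paper_like_model() -> SeverityModel:
    """Preset operating near sensitivity 77% / specificity 100% on the score arm."""
    return SeverityModel(edema=dict(_PAPER_LIKE_EDEMA), no_edema=dict(_PAPER_LIKE_NO_EDEMA))


PRESETS = {"separable": separable_model, "paper_like": paper_like_model}


def default_reader_profiles(n_readers: int = 7) -> tuple[ReaderProfile, ...]:
    """Readers at the pooled standard-approach operating point (57% / 90%)."""
    return tuple(ReaderProfile(reader_id=f"R{i + 1}") for i in range(n_readers))


# ---------------------------------------------------------------------------


def simulate_cohort(params: CohortParams, seed: int) -> list[ReferenceStandard]:
    """Draw integer EVLW values uniformly within each group's band."""
    rng = np.random.default_rng(seed)
    refs: list[ReferenceStandard] = []
    groups = (
        (EDEMA, "E", params.n_edema),
        (NO_EDEMA, "N", params.n_no_edema),
        (BORDERLINE, "B", params.n_borderline),
    )
    for status, prefix, n in groups:
        lo, hi = params.evlw_ranges.get(status, DEFAULT_EVLW_RANGES[status])
        values = rng.integers(lo, hi + 1, size=n)
        for i, v in enumerate(values):
            refs.append(ReferenceStandard(case_id=f"{prefix}{i + 1:03d}", evlw=int(v)))
    return refs


def _latent_severities(
    refs: Sequence[ReferenceStandard],
    model: SeverityModel,
    rubric: Rubric,
    rng: np.random.Generator,
) -> dict[str, dict[str, int]]:
    latent: dict[str, dict[str, int]] = {}
    for ref in refs:
        table = model.table(ref.status)
        latent[ref.case_id] = {
            ind.id: int(rng.choice(ind.scale_size, p=table[ind.id]))
            for ind in rubric.indicators
        }
    return latent


def simulate_ratings(
    refs: Sequence[ReferenceStandard],
    severity_model: SeverityModel,
    profiles: Sequence[ReaderProfile],
    seed: int,
    rubric: Rubric | None = None,
) -> list[RatingSheet]:
    """One rating sheet per reader x case.

    Latent severities are drawn once per case; each reader then sees them
    through their own ordinal noise (+-1 level with probability
    ``rating_noise``, clamped to the scale).
    """
    rubric = rubric or default_rubric()
    severity_model.validate(rubric)
    if not profiles:
        raise InputError("need at least one reader profile")
    rng = np.random.default_rng(seed)
    latent = _latent_severities(refs, severity_model, rubric, rng)
    sheets: list[RatingSheet] = []
    for profile in profiles:
        for ref in refs:
            levels = {}
            for ind in rubric.indicators:
                lvl = latent[ref.case_id][ind.id]
                if profile.rating_noise and rng.random() < profile.rating_noise:
                    lvl += 1 if rng.random() < 0.5 else -1
                    lvl = min(max(lvl, 0), ind.scale_size - 1)
                levels[ind.id] = lvl
            sheets.append(
                RatingSheet(case_id=ref.case_id, reader_id=profile.reader_id, levels=levels)
            )
    return sheets


def _standard_calls(
    refs: Sequence[ReferenceStandard],
    profiles: Sequence[ReaderProfile],
    rng: np.random.Generator,
) -> CallMatrix:
    records = []
    for profile in profiles:
        for ref in refs:
            if ref.status == EDEMA:
                p_edema = profile.standard_sens
            elif ref.status == NO_EDEMA:
                p_edema = 1.0 - profile.standard_spec
            else:  # borderline: coin flip; excluded downstream anyway
                p_edema = 0.5
            call = EDEMA if rng.random() < p_edema else NO_EDEMA
            records.append((profile.reader_id, ref.case_id, call))
    return CallMatrix.from_long(records)


def score_calls(
    sheets: Iterable[RatingSheet], rubric: Rubric | None = None
) -> CallMatrix:
    """Binary calls obtained by scoring rating sheets against the rubric."""
    rubric = rubric or default_rubric()
    records = [
        (s.reader_id, s.case_id, total_score(rubric, s).classification) for s in sheets
    ]
    return CallMatrix.from_long(records)


def run_virtual_study(
    cohort: Sequence[ReferenceStandard] | CohortParams,
    severity_model: SeverityModel | None = None,
    profiles: Sequence[ReaderProfile] | None = None,
    seed: int = 0,
    rubric: Rubric | None = None,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> tuple[CallMatrix, CallMatrix, StudyReport]:
    """Simulate both reading arms and evaluate them.

    Returns ``(score_based_calls, standard_calls, report)``. The score
    arm classifies each simulated rating sheet with the rubric; the
    standard arm draws unaided calls from each reader's operating point.
    Sub-seeds for the cohort, ratings, and standard calls are split off a
    single seed sequence, so the whole study is reproducible.
    """
    rubric = rubric or default_rubric()
    severity_model = severity_model or paper_like_model()
    profiles = tuple(profiles) if profiles is not None else default_reader_profiles()

    ss = np.random.SeedSequence(seed)
    seed_cohort, seed_ratings, seed_std = (int(s) for s in ss.generate_state(3) % (2**31))

    refs = (
        simulate_cohort(cohort, seed_cohort)
        if isinstance(cohort, CohortParams)
        else list(cohort)
    )
    sheets = simulate_ratings(refs, severity_model, profiles, seed_ratings, rubric)
    calls_score = score_calls(sheets, rubric)
    calls_std = _standard_calls(refs, profiles, np.random.default_rng(seed_std))

    report = evaluate_study(
        calls_std,
        calls_score,
        refs,
        ci_method=ci_method,
        level=level,
        provenance={"seed": seed, "rubric_checksum": rubric.checksum(), "simulated": True},
    )
    return calls_score, calls_std, report
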