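"""Multi-reader diagnostic-accuracy evaluation against an EVLW reference standard.

Extravascular lung water (EVLW, mL/kg, measured by transpulmonary
thermodilution) is the reference: <= 8 mL/kg means no pulmonary edema,
>= 15 mL/kg means pulmonary edema, and the 9-14 mL/kg band is borderline
and excluded from accuracy computations. Reader calls are pooled over
reader x case readings into confusion counts, from which sensitivity,
specificity, PPV and NPV are computed with binomial confidence intervals
(Clopper-Pearson by default, Wilson optionally).

Inter-reader agreement is summarized by the mean per-case proportion of
concordant reader pairs (the observed-agreement component of Fleiss-style
statistics) and by the free-marginal multirater kappa
``(P0 - 1/k) / (1 - 1/k)``, appropriate when readers are not constrained
to assign fixed numbers of cases to each category; for two categories it
reduces to ``2*P0 - 1``.

The improvement of one binary reading approach over another on the same
readings is measured by the binary net reclassification index (NRI): the
net proportion of event readings reclassified correctly plus the net
proportion of nonevent readings reclassified correctly, algebraically
equal to delta-sensitivity + delta-specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError, PairingError
from .rubric import EDEMA, NO_EDEMA

BORDERLINE = "borderline"

CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson"}


# ---------------------------------------------------------------------------
# Reference standard


@dataclass(frozen=True)
class ReferenceStandard:
    """Per-case EVLW value (mL/kg) and the edema status derived from it."""

    case_id: str
    evlw: float
    status: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", classify_evlw(self.evlw))


def classify_evlw(evlw: float) -> str:
    """Map an EVLW value (mL/kg) onto {no_edema, borderline, edema}.

    Values are rounded half-up to the nearest integer before banding
    (EVLW is reported clinically in integer mL/kg), so the bands
    <=8 / 9-14 / >=15 tile the positive axis without gaps.
    """
    if not math.isfinite(evlw) or evlw <= 0:
        raise InputError(f"EVLW must be a positive finite value in mL/kg, got {evlw!r}")
    rounded = math.floor(evlw + 0.5)  # round half-up
    if rounded <= 8:
        return NO_EDEMA
    if rounded <= 14:
        return BORDERLINE
    return EDEMA


def reference_frame(refs: Iterable[ReferenceStandard]) -> pd.DataFrame:
    """Tabulate a reference collection; raises on duplicate case ids."""
    rows = [(r.case_id, r.evlw, r.status) for r in refs]
    df = pd.DataFrame(rows, columns=["case_id", "evlw", "status"]).set_index("case_id")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise InputError(f"duplicate case ids in reference standard: {dupes}")
    return df


# ---------------------------------------------------------------------------
# Call matrices


class CallMatrix:
    """Readers x cases binary edema calls for one reading approach.

    Stored as a boolean DataFrame (True = edema call) with reader ids as
    the index and case ids as the columns; complete (no missing calls).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.empty:
            raise InputError("call matrix must have at least one reader and one case")
        if frame.isna().any().any():
            raise InputError("call matrix is incomplete (missing calls)")
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise InputError("duplicate reader or case ids in call matrix")
        self._frame = frame.astype(bool)

    @classmethod
    def from_long(cls, records: Iterable[tuple[str, str, str]]) -> "CallMatrix":
        """Build from (reader_id, case_id, call) triples, call in {edema, no_edema}."""
        rows = list(records)
        if not rows:
            raise InputError("no calls provided")
        df = pd.DataFrame(rows, columns=["reader_id", "case_id", "call"])
        bad = sorted(set(df["call"]) - {EDEMA, NO_EDEMA})
        if bad:
            raise InputError(f"calls must be 'edema' or 'no_edema', got {bad}")
        dup = df.duplicated(subset=["reader_id", "case_id"])
        if dup.any():
            pairs = df.loc[dup, ["reader_id", "case_id"]].values.tolist()
            raise InputError(f"duplicate (reader, case) calls: {pairs}")
        wide = df.pivot(index="reader_id", columns="case_id", values="call")
        if wide.isna().any().any():
            missing = [
                (r, c) for r in wide.index for c in wide.columns if pd.isna(wide.at[r, c])
            ]
            raise InputError(f"incomplete call matrix; missing calls: {missing}")
        return cls(wide == EDEMA)

    @property
    def readers(self) -> tuple[str, ...]:
        return tuple(self._frame.index)

    @property
    def cases(self) -> tuple[str, ...]:
        return tuple(self._frame.columns)

    @property
    def values(self) -> np.ndarray:
        """Boolean readers x cases array; True = edema call."""
        return self._frame.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def call(self, reader_id: str, case_id: str) -> str:
        return EDEMA if bool(self._frame.at[reader_id, case_id]) else NO_EDEMA

    def restrict_cases(self, case_ids: Sequence[str]) -> "CallMatrix":
        keep = [c for c in self.cases if c in set(case_ids)]
        if not keep:
            raise InputError("no cases left after restriction")
        return CallMatrix(self._frame[keep])

    def to_long(self) -> pd.DataFrame:
        long = self._frame.stack().rename("is_edema").reset_index()
        long.columns = ["reader_id", "case_id", "is_edema"]
        long["call"] = np.where(long["is_edema"], EDEMA, NO_EDEMA)
        return long[["reader_id", "case_id", "call"]]


def _split_cases(calls: CallMatrix, refs: Iterable[ReferenceStandard]):
    """Return (event case mask, nonevent case mask) aligned to calls.cases."""
    ref_df = reference_frame(refs)
    missing = [c for c in calls.cases if c not in ref_df.index]
    if missing:
        raise PairingError(f"cases without a reference EVLW value: {missing}")
    status = ref_df.loc[list(calls.cases), "status"].to_numpy()
    if (status == BORDERLINE).any():
        borderline = [c for c, s in zip(calls.cases, status) if s == BORDERLINE]
        raise InputError(
            f"borderline cases must be excluded before computing accuracy: {borderline}"
        )
    return status == EDEMA, status == NO_EDEMA


def exclude_borderline(
    calls: CallMatrix, refs: Iterable[ReferenceStandard]
) -> tuple[CallMatrix, list[str]]:
    """Drop borderline-EVLW cases from a call matrix; returns (matrix, dropped ids)."""
    refs = list(refs)
    ref_df = reference_frame(refs)
    missing = [c for c in calls.cases if c not in ref_df.index]
    if missing:
        raise PairingError(f"cases without a reference EVLW value: {missing}")
    dropped = [c for c in calls.cases if ref_df.at[c, "status"] == BORDERLINE]
    keep = [c for c in calls.cases if c not in dropped]
    if not keep:
        raise InputError("all cases are borderline; nothing to evaluate")
    return calls.restrict_cases(keep), dropped


# ---------------------------------------------------------------------------
# Confusion counts and diagnostic metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_events(self) -> int:
        return self.tp + self.fn

    @property
    def n_nonevents(self) -> int:
        return self.tn + self.fp


def _confusion(values: np.ndarray, is_event: np.ndarray, is_nonevent: np.ndarray) -> ConfusionCounts:
    ev, nev = values[:, is_event], values[:, is_nonevent]
    return ConfusionCounts(
        tp=int(ev.sum()),
        fn=int((~ev).sum()),
        fp=int(nev.sum()),
        tn=int((~nev).sum()),
    )


def pooled_confusion(calls: CallMatrix, refs: Iterable[ReferenceStandard]) -> ConfusionCounts:
    """Confusion counts pooled over all reader x case readings."""
    is_event, is_nonevent = _split_cases(calls, refs)
    return _confusion(calls.values, is_event, is_nonevent)


def per_reader_confusion(
    calls: CallMatrix, refs: Iterable[ReferenceStandard]
) -> dict[str, ConfusionCounts]:
    is_event, is_nonevent = _split_cases(calls, refs)
    return {
        reader: _confusion(calls.values[i : i + 1], is_event, is_nonevent)
        for i, reader in enumerate(calls.readers)
    }


@dataclass(frozen=True)
class ProportionEstimate:
    """A percentage with its CI; ``defined`` is False when the denominator is 0."""

    numerator: int
    denominator: int
    value: float | None
    ci: tuple[float, float] | None
    level: float
    method: str
    defined: bool = True


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate
    counts: ConfusionCounts
    ci_method: str
    level: float


def proportion_ci(
    successes: int, trials: int, method: str = "clopper_pearson", level: float = 0.95
) -> tuple[float, float]:
    """Two-sided binomial CI for ``successes/trials`` on the percentage scale."""
    if trials <= 0:
        raise InputError(f"trials must be positive, got {trials}")
    if not 0 <= successes <= trials:
        raise InputError(f"successes {successes} outside [0, {trials}]")
    if method not in CI_METHODS:
        raise InputError(f"unknown CI method {method!r}; choose from {sorted(CI_METHODS)}")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method=CI_METHODS[method])
    return 100.0 * float(lo), 100.0 * float(hi)


def _estimate(num: int, den: int, method: str, level: float) -> ProportionEstimate:
    if den == 0:
        return ProportionEstimate(num, den, None, None, level, method, defined=False)
    return ProportionEstimate(
        numerator=num,
        denominator=den,
        value=100.0 * num / den,
        ci=proportion_ci(num, den, method, level),
        level=level,
        method=method,
    )


def diagnostic_metrics(
    counts: ConfusionCounts, ci_method: str = "clopper_pearson", level: float = 0.95
) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV (percent) with binomial CIs.

    PPV or NPV with a zero denominator (no positive or no negative calls)
    is reported as undefined rather than forced to 0 or 100.
    """
    if counts.n_events == 0 or counts.n_nonevents == 0:
        raise InputError("need at least one event and one nonevent reading")
    return DiagnosticMetrics(
        sensitivity=_estimate(counts.tp, counts.n_events, ci_method, level),
        specificity=_estimate(counts.tn, counts.n_nonevents, ci_method, level),
        ppv=_estimate(counts.tp, counts.tp + counts.fp, ci_method, level),
        npv=_estimate(counts.tn, counts.tn + counts.fn, ci_method, level),
        counts=counts,
        ci_method=ci_method,
        level=level,
    )


# ---------------------------------------------------------------------------
# Agreement


@dataclass(frozen=True)
class AgreementStats:
    p_overall: float
    kappa_free: float
    n_categories: int


def pairwise_agreement(calls: CallMatrix) -> float:
    """Mean per-case proportion of concordant reader pairs (observed agreement)."""
    values = calls.values
    n_readers = values.shape[0]
    if n_readers < 2:
        raise InputError("pairwise agreement requires at least two readers")
    n_pairs = n_readers * (n_readers - 1) / 2
    pos = values.sum(axis=0)  # edema calls per case
    neg = n_readers - pos
    concordant = pos * (pos - 1) / 2 + neg * (neg - 1) / 2
    return float(np.mean(concordant / n_pairs))


def free_marginal_kappa(p_overall: float, k: int = 2) -> float:
    """Chance-corrected multirater agreement for unconstrained category margins."""
    if k < 2:
        raise InputError(f"need at least two categories, got k={k}")
    if not 0.0 <= p_overall <= 1.0:
        raise InputError(f"p_overall must be in [0, 1], got {p_overall}")
    return (p_overall - 1.0 / k) / (1.0 - 1.0 / k)


def agreement_stats(calls: CallMatrix, k: int = 2) -> AgreementStats:
    p0 = pairwise_agreement(calls)
    return AgreementStats(p_overall=p0, kappa_free=free_marginal_kappa(p0, k), n_categories=k)


# ---------------------------------------------------------------------------
# Net reclassification index


@dataclass(frozen=True)
class NRIResult:
    nri: float
    up_events: int
    down_events: int
    up_nonevents: int
    down_nonevents: int
    n_event_readings: int
    n_nonevent_readings: int
    se: float
    ci: tuple[float, float] | None
    p_value: float | None
    level: float

    @property
    def p_defined(self) -> bool:
        return self.p_value is not None


def _nri_from_counts(
    up_ev: int, down_ev: int, up_nev: int, down_nev: int,
    n_ev: int, n_nev: int, level: float,
) -> NRIResult:
    p_up_ev, p_down_ev = up_ev / n_ev, down_ev / n_ev
    p_up_nev, p_down_nev = up_nev / n_nev, down_nev / n_nev
    nri = (p_up_ev - p_down_ev) + (p_down_nev - p_up_nev)
    # Asymptotic variance of each net-move proportion: E[d^2] - E[d]^2 over
    # readings, where d is +1 for an up-move, -1 for a down-move, 0 otherwise.
    var = ((p_up_ev + p_down_ev) - (p_up_ev - p_down_ev) ** 2) / n_ev
    var += ((p_up_nev + p_down_nev) - (p_down_nev - p_up_nev) ** 2) / n_nev
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        return NRIResult(nri, up_ev, down_ev, up_nev, down_nev, n_ev, n_nev,
                         se=0.0, ci=None, p_value=None, level=level)
    z = sps.norm.ppf(0.5 + level / 2)
    p = 2.0 * float(sps.norm.sf(abs(nri) / se))
    return NRIResult(nri, up_ev, down_ev, up_nev, down_nev, n_ev, n_nev,
                     se=se, ci=(nri - z * se, nri + z * se), p_value=p, level=level)


def binary_nri(
    calls_old: CallMatrix,
    calls_new: CallMatrix,
    refs: Iterable[ReferenceStandard],
    scope: str = "pooled",
    level: float = 0.95,
) -> NRIResult | dict[str, NRIResult]:
    """Paired binary NRI of the new reading approach versus the old.

    Up-moves are readings reclassified from a no-edema call to an edema
    call; among event readings an up-move is a correction, among nonevent
    readings a degradation. The point estimate equals
    delta-sensitivity + delta-specificity of the two approaches.

    ``scope='pooled'`` pools all reader x case readings; ``'per_reader'``
    returns one result per reader.
    """
    refs = list(refs)
    if calls_old.readers != calls_new.readers or calls_old.cases != calls_new.cases:
        raise PairingError(
            "paired call matrices must share identical reader and case sets "
            f"(old: {len(calls_old.readers)}x{len(calls_old.cases)}, "
            f"new: {len(calls_new.readers)}x{len(calls_new.cases)})"
        )
    is_event, is_nonevent = _split_cases(calls_old, refs)
    if not is_event.any() or not is_nonevent.any():
        raise InputError("need at least one event case and one nonevent case")
    if scope not in {"pooled", "per_reader"}:
        raise InputError(f"scope must be 'pooled' or 'per_reader', got {scope!r}")

    old, new = calls_old.values, calls_new.values
    up = ~old & new
    down = old & ~new

    def result(rows: slice | list[int]) -> NRIResult:
        u, d = up[rows], down[rows]
        n_rows = u.shape[0]
        return _nri_from_counts(
            up_ev=int(u[:, is_event].sum()),
            down_ev=int(d[:, is_event].sum()),
            up_nev=int(u[:, is_nonevent].sum()),
            down_nev=int(d[:, is_nonevent].sum()),
            n_ev=int(is_event.sum()) * n_rows,
            n_nev=int(is_nonevent.sum()) * n_rows,
            level=level,
        )

    if scope == "pooled":
        return result(slice(None))
    return {reader: result([i]) for i, reader in enumerate(calls_old.readers)}


# ---------------------------------------------------------------------------
# Full study report


@dataclass(frozen=True)
class ArmSummary:
    """Evaluation of one reading approach: confusion, metrics, agreement."""

    name: str
    pooled: ConfusionCounts
    per_reader: Mapping[str, ConfusionCounts]
    metrics: DiagnosticMetrics
    agreement: AgreementStats


@dataclass(frozen=True)
class StudyReport:
    old_arm: ArmSummary
    new_arm: ArmSummary
    nri_pooled: NRIResult
    nri_per_reader: Mapping[str, NRIResult]
    excluded_borderline: tuple[str, ...]
    provenance: Mapping[str, object]


def evaluate_study(
    calls_old: CallMatrix,
    calls_new: CallMatrix,
    refs: Iterable[ReferenceStandard],
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
    provenance: Mapping[str, object] | None = None,
    old_name: str = "standard",
    new_name: str = "score_based",
) -> StudyReport:
    """Run the complete paired two-arm evaluation.

    Borderline-EVLW cases are excluded up front (and recorded in the
    report); everything downstream sees a clean two-group case set.
    """
    refs = list(refs)
    calls_old, dropped_old = exclude_borderline(calls_old, refs)
    calls_new, dropped_new = exclude_borderline(calls_new, refs)
    if dropped_old != dropped_new:
        raise PairingError("paired matrices disagree on borderline cases")

    def arm(calls: CallMatrix, name: str) -> ArmSummary:
        pooled = pooled_confusion(calls, refs)
        return ArmSummary(
            name=name,
            pooled=pooled,
            per_reader=per_reader_confusion(calls, refs),
            metrics=diagnostic_metrics(pooled, ci_method, level),
            agreement=agreement_stats(calls),
        )

    prov = dict(provenance or {})
    prov.setdefault("ci_method", ci_method)
    prov.setdefault("confidence_level", level)
    return StudyReport(
        old_arm=arm(calls_old, old_name),
        new_arm=arm(calls_new, new_name),
        nri_pooled=binary_nri(calls_old, calls_new, refs, "pooled", level),
        nri_per_reader=binary_nri(calls_old, calls_new, refs, "per_reader", level),
        excluded_borderline=tuple(dropped_old),
        provenance=prov,
    )
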