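"""CSV/JSON input and output with strict schema validation.

Three plain-text schemas are understood:

* rating sheets — ``case_id,reader_id,indicator,level``, one row per
  (case, reader, indicator);
* call matrices — ``reader_id,case_id,call`` with call in
  {edema, no_edema};
* reference standard — ``case_id,evlw`` with EVLW in mL/kg.

Reports serialize to JSON (full precision, deterministic field order,
lossless round-trip) or to a display-rounded TSV summary.
"""

from __future__ import annotations

import csv
import json
import logging
from typing import Iterable, Sequence

from . import __version__
from .errors import InputError, ReportIOError, ValidationError
from .rubric import RatingSheet, Rubric, default_rubric
from .stats import (
    AgreementStats,
    ArmSummary,
    CallMatrix,
    ConfusionCounts,
    DiagnosticMetrics,
    NRIResult,
    ProportionEstimate,
    ReferenceStandard,
    StudyReport,
)

logger = logging.getLogger("edemascore")

RATINGS_HEADER = ["case_id", "reader_id", "indicator", "level"]
CALLS_HEADER = ["reader_id", "case_id", "call"]
REFERENCE_HEADER = ["case_id", "evlw"]


def _open_rows(path: str, expected_header: list[str]):
    try:
        fh = open(path, newline="")
    except OSError as exc:
        raise ReportIOError(f"cannot read {path}: {exc}") from exc
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        fh.close()
        raise InputError(f"{path}: empty file (expected header {expected_header})")
    if [h.strip() for h in header] != expected_header:
        fh.close()
        raise ValidationError(f"{path}: header {header} != expected {expected_header}")
    return fh, reader


def read_ratings(
    path: str, rubric: Rubric | None = None, strict: bool = True
) -> list[RatingSheet]:
    """Load and validate rating sheets from CSV.

    In strict mode duplicate (case, reader, indicator) rows and unknown
    indicators are rejected; in lenient mode the last duplicate wins and
    unknown indicators are dropped with a warning. Every sheet must cover
    every rubric indicator exactly once.
    """
    rubric = rubric or default_rubric()
    fh, rows = _open_rows(path, RATINGS_HEADER)
    levels: dict[tuple[str, str], dict[str, int]] = {}
    with fh:
        for lineno, row in enumerate(rows, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            case_id, reader_id, indicator, level_s = (c.strip() for c in row)
            if indicator not in rubric:
                if strict:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown indicator {indicator!r}"
                    )
                logger.warning("%s:%d: dropping unknown indicator %r", path, lineno, indicator)
                continue
            try:
                level = int(level_s)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: level must be an integer, got {level_s!r}"
                ) from None
            key = (case_id, reader_id)
            if strict and indicator in levels.get(key, {}):
                raise ValidationError(
                    f"{path}:{lineno}: duplicate row for "
                    f"(case={case_id}, reader={reader_id}, indicator={indicator})"
                )
            levels.setdefault(key, {})[indicator] = level
    if not levels:
        raise InputError(f"{path}: no rating rows")
    sheets = []
    for (case_id, reader_id), lv in levels.items():
        sheet = RatingSheet(case_id=case_id, reader_id=reader_id, levels=lv)
        sheet.validate(rubric)
        sheets.append(sheet)
    logger.info("read %d rating sheets from %s", len(sheets), path)
    return sheets


def write_ratings(sheets: Iterable[RatingSheet], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RATINGS_HEADER)
        for s in sheets:
            for indicator, level in s.levels.items():
                w.writerow([s.case_id, s.reader_id, indicator, level])


def read_calls(path: str) -> CallMatrix:
    """Load a complete readers x cases binary call matrix from long CSV."""
    fh, rows = _open_rows(path, CALLS_HEADER)
    records = []
    with fh:
        for lineno, row in enumerate(rows, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            records.append(tuple(c.strip() for c in row))
    if not records:
        raise InputError(f"{path}: no call rows")
    matrix = CallMatrix.from_long(records)
    logger.info(
        "read calls from %s: %d readers x %d cases",
        path, len(matrix.readers), len(matrix.cases),
    )
    return matrix


def write_calls(matrix: CallMatrix, path: str) -> None:
    matrix.to_long().to_csv(path, index=False)


def read_reference(path: str) -> list[ReferenceStandard]:
    """Load the EVLW reference standard.

    Borderline rows (9-14 mL/kg) are loaded with their borderline status
    — the evaluation stage excludes them explicitly, never silently.
    """
    fh, rows = _open_rows(path, REFERENCE_HEADER)
    refs = []
    with fh:
        for lineno, row in enumerate(rows, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
            case_id, evlw_s = (c.strip() for c in row)
            try:
                evlw = float(evlw_s)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: EVLW must be numeric, got {evlw_s!r}"
                ) from None
            refs.append(ReferenceStandard(case_id=case_id, evlw=evlw))
    if not refs:
        raise InputError(f"{path}: no reference rows")
    n_border = sum(r.status == "borderline" for r in refs)
    logger.info("read %d reference cases from %s (%d borderline)", len(refs), path, n_border)
    return refs


def write_reference(refs: Iterable[ReferenceStandard], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(REFERENCE_HEADER)
        for r in refs:
            w.writerow([r.case_id, r.evlw])


# ---------------------------------------------------------------------------
# Report serialization


def _estimate_dict(e: ProportionEstimate) -> dict:
    return {
        "numerator": e.numerator,
        "denominator": e.denominator,
        "value_percent": e.value,
        "ci_percent": list(e.ci) if e.ci is not None else None,
        "level": e.level,
        "method": e.method,
        "defined": e.defined,
    }


def _counts_dict(c: ConfusionCounts) -> dict:
    return {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}


def _nri_dict(r: NRIResult) -> dict:
    return {
        "nri": r.nri,
        "up_events": r.up_events,
        "down_events": r.down_events,
        "up_nonevents": r.up_nonevents,
        "down_nonevents": r.down_nonevents,
        "n_event_readings": r.n_event_readings,
        "n_nonevent_readings": r.n_nonevent_readings,
        "se": r.se,
        "ci": list(r.ci) if r.ci is not None else None,
        "p_value": r.p_value,
        "level": r.level,
    }


def _arm_dict(a: ArmSummary) -> dict:
    m = a.metrics
    return {
        "name": a.name,
        "pooled_confusion": _counts_dict(a.pooled),
        "per_reader_confusion": {k: _counts_dict(v) for k, v in sorted(a.per_reader.items())},
        "metrics": {
            "sensitivity": _estimate_dict(m.sensitivity),
            "specificity": _estimate_dict(m.specificity),
            "ppv": _estimate_dict(m.ppv),
            "npv": _estimate_dict(m.npv),
        },
        "agreement": {
            "p_overall": a.agreement.p_overall,
            "kappa_free": a.agreement.kappa_free,
            "n_categories": a.agreement.n_categories,
        },
    }


def report_to_dict(report: StudyReport) -> dict:
    """Serialize a study report with deterministic field ordering."""
    prov = dict(report.provenance)
    prov.setdefault("tool_version", __version__)
    return {
        "arms": {
            "old": _arm_dict(report.old_arm),
            "new": _arm_dict(report.new_arm),
        },
        "nri": {
            "pooled": _nri_dict(report.nri_pooled),
            "per_reader": {k: _nri_dict(v) for k, v in sorted(report.nri_per_reader.items())},
        },
        "excluded_borderline": list(report.excluded_borderline),
        "provenance": {k: prov[k] for k in sorted(prov)},
    }


def _estimate_from(d: dict) -> ProportionEstimate:
    return ProportionEstimate(
        numerator=d["numerator"],
        denominator=d["denominator"],
        value=d["value_percent"],
        ci=tuple(d["ci_percent"]) if d["ci_percent"] is not None else None,
        level=d["level"],
        method=d["method"],
        defined=d["defined"],
    )


def _nri_from(d: dict) -> NRIResult:
    return NRIResult(
        nri=d["nri"],
        up_events=d["up_events"],
        down_events=d["down_events"],
        up_nonevents=d["up_nonevents"],
        down_nonevents=d["down_nonevents"],
        n_event_readings=d["n_event_readings"],
        n_nonevent_readings=d["n_nonevent_readings"],
        se=d["se"],
        ci=tuple(d["ci"]) if d["ci"] is not None else None,
        p_value=d["p_value"],
        level=d["level"],
    )


def _arm_from(d: dict) -> ArmSummary:
    m = d["metrics"]
    counts = ConfusionCounts(**d["pooled_confusion"])
    metrics = DiagnosticMetrics(
        sensitivity=_estimate_from(m["sensitivity"]),
        specificity=_estimate_from(m["specificity"]),
        ppv=_estimate_from(m["ppv"]),
        npv=_estimate_from(m["npv"]),
        counts=counts,
        ci_method=m["sensitivity"]["method"],
        level=m["sensitivity"]["level"],
    )
    return ArmSummary(
        name=d["name"],
        pooled=counts,
        per_reader={k: ConfusionCounts(**v) for k, v in d["per_reader_confusion"].items()},
        metrics=metrics,
        agreement=AgreementStats(**d["agreement"]),
    )


def report_from_dict(d: dict) -> StudyReport:
    """Inverse of :func:`report_to_dict`."""
    return StudyReport(
        old_arm=_arm_from(d["arms"]["old"]),
        new_arm=_arm_from(d["arms"]["new"]),
        nri_pooled=_nri_from(d["nri"]["pooled"]),
        nri_per_reader={k: _nri_from(v) for k, v in d["nri"]["per_reader"].items()},
        excluded_borderline=tuple(d["excluded_borderline"]),
        provenance=d["provenance"],
    )


def _fmt(x: float | None, nd: int = 2) -> str:
    return "NA" if x is None else f"{x:.{nd}f}"


def report_to_tsv(report: StudyReport) -> str:
    """Display-rounded TSV summary (percentages and indices to 2 decimals)."""
    lines = ["metric\t" + report.old_arm.name + "\t" + report.new_arm.name]
    for attr, label in [
        ("sensitivity", "sensitivity_percent"),
        ("specificity", "specificity_percent"),
        ("ppv", "ppv_percent"),
        ("npv", "npv_percent"),
    ]:
        old_e = getattr(report.old_arm.metrics, attr)
        new_e = getattr(report.new_arm.metrics, attr)
        lines.append(f"{label}\t{_fmt(old_e.value)}\t{_fmt(new_e.value)}")
    lines.append(
        "overall_agreement_percent\t"
        f"{_fmt(100 * report.old_arm.agreement.p_overall)}\t"
        f"{_fmt(100 * report.new_arm.agreement.p_overall)}"
    )
    lines.append(
        "kappa_free\t"
        f"{_fmt(report.old_arm.agreement.kappa_free)}\t"
        f"{_fmt(report.new_arm.agreement.kappa_free)}"
    )
    lines.append(f"nri_pooled\t{_fmt(report.nri_pooled.nri)}\t")
    for reader in sorted(report.nri_per_reader):
        lines.append(f"nri_{reader}\t{_fmt(report.nri_per_reader[reader].nri)}\t")
    return "\n".join(lines) + "\n"


def emit_report(report: StudyReport, path: str, format: str = "json") -> None:
    """Write a report as JSON (full precision) or TSV summary (rounded)."""
    if format == "json":
        payload = json.dumps(report_to_dict(report), indent=2) + "\n"
    elif format == "tsv-summary":
        payload = report_to_tsv(report)
    else:
        raise InputError(f"unknown report format {format!r}")
    try:
        with open(path, "w") as fh:
            fh.write(payload)
    except OSError as exc:
        raise ReportIOError(f"cannot write {path}: {exc}") from exc
    logger.info("wrote %s report to %s", format, path)
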