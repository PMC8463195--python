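"""Cohort CSV contract: one row per procedure, booleans as 0/1.

Schema (header mandatory, UTF-8): case_id, operator_id, years_performing,
annual_volume, last_year_success_rate, age_years, prior_mi,
prior_failed_attempt, prior_cabg_target_vessel, target_vessel, blunt_stump,
calcification, calcification_severe, bend_ge45, severe_angulation,
occlusion_length_mm, distal_disease, rentrop_grade, in_stent, ostial,
technical_success, procedural_success.

Validation is row-level and exhaustive: every violation is collected and
reported with its (1-based, data) row number before the read fails.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .scoring import CaseFeatures, OperatorProfile, TargetVessel, score_all
from .simulate import Cohort, ProcedureRecord

__all__ = ["COHORT_COLUMNS", "CohortValidationError", "read_cohort", "write_cohort"]

BOOL_COLUMNS = [
    "prior_mi",
    "prior_failed_attempt",
    "prior_cabg_target_vessel",
    "blunt_stump",
    "calcification",
    "calcification_severe",
    "bend_ge45",
    "severe_angulation",
    "distal_disease",
    "in_stent",
    "ostial",
    "technical_success",
    "procedural_success",
]

COHORT_COLUMNS = [
    "case_id",
    "operator_id",
    "years_performing",
    "annual_volume",
    "last_year_success_rate",
    "age_years",
    "prior_mi",
    "prior_failed_attempt",
    "prior_cabg_target_vessel",
    "target_vessel",
    "blunt_stump",
    "calcification",
    "calcification_severe",
    "bend_ge45",
    "severe_angulation",
    "occlusion_length_mm",
    "distal_disease",
    "rentrop_grade",
    "in_stent",
    "ostial",
    "technical_success",
    "procedural_success",
]


class CohortValidationError(ValueError):
    """Raised when a cohort CSV violates the schema; carries every
    row-level message."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("cohort validation failed:\n" + "\n".join(errors))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Serialize a cohort to the CSV contract (scores are recomputable and
    not stored)."""
    rows = []
    for r in cohort:
        f, op = r.features, r.operator
        rows.append(
            {
                "case_id": r.case_id,
                "operator_id": op.operator_id,
                "years_performing": op.years_performing,
                "annual_volume": op.annual_volume,
                "last_year_success_rate": op.last_year_success_rate,
                "age_years": f.age_years,
                "prior_mi": int(f.prior_mi),
                "prior_failed_attempt": int(f.prior_failed_attempt),
                "prior_cabg_target_vessel": int(f.prior_cabg_target_vessel),
                "target_vessel": f.target_vessel.value,
                "blunt_stump": int(f.blunt_stump),
                "calcification": int(f.calcification),
                "calcification_severe": int(f.calcification_severe),
                "bend_ge45": int(f.bend_ge45),
                "severe_angulation": int(f.severe_angulation),
                "occlusion_length_mm": f.occlusion_length_mm,
                "distal_disease": int(f.distal_disease),
                "rentrop_grade": f.rentrop_grade,
                "in_stent": int(f.in_stent),
                "ostial": int(f.ostial),
                "technical_success": int(r.technical_success),
                "procedural_success": int(r.procedural_success),
            }
        )
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_cohort(path: str | Path, score: bool = True) -> Cohort:
    """Read and validate a cohort CSV; optionally fill in score panels.

    Raises :class:`CohortValidationError` listing every offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing columns: {', '.join(missing)}"])
    errors: list[str] = []
    records: list[ProcedureRecord] = []
    vessel_values = {v.value for v in TargetVessel}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_errors: list[str] = []
        d = row._asdict()
        for col in BOOL_COLUMNS:
            if d[col] not in (0, 1):
                row_errors.append(f"row {i}: {col}={d[col]!r} is not 0/1")
        if d["rentrop_grade"] not in (0, 1, 2, 3):
            row_errors.append(f"row {i}: rentrop_grade={d['rentrop_grade']!r} outside 0-3")
        if d["target_vessel"] not in vessel_values:
            row_errors.append(f"row {i}: target_vessel={d['target_vessel']!r} unknown")
        if not row_errors and d["procedural_success"] == 1 and d["technical_success"] == 0:
            row_errors.append(
                f"row {i}: procedural_success=1 with technical_success=0 "
                "violates endpoint nesting"
            )
        if row_errors:
            errors.extend(row_errors)
            continue
        try:
            features = CaseFeatures(
                age_years=int(d["age_years"]),
                prior_mi=bool(d["prior_mi"]),
                prior_failed_attempt=bool(d["prior_failed_attempt"]),
                prior_cabg_target_vessel=bool(d["prior_cabg_target_vessel"]),
                target_vessel=TargetVessel(d["target_vessel"]),
                blunt_stump=bool(d["blunt_stump"]),
                calcification=bool(d["calcification"]),
                calcification_severe=bool(d["calcification_severe"]),
                bend_ge45=bool(d["bend_ge45"]),
                severe_angulation=bool(d["severe_angulation"]),
                occlusion_length_mm=float(d["occlusion_length_mm"]),
                distal_disease=bool(d["distal_disease"]),
                rentrop_grade=int(d["rentrop_grade"]),
                in_stent=bool(d["in_stent"]),
                ostial=bool(d["ostial"]),
            )
            operator = OperatorProfile(
                operator_id=str(d["operator_id"]),
                years_performing=int(d["years_performing"]),
                annual_volume=int(d["annual_volume"]),
                last_year_success_rate=float(d["last_year_success_rate"]),
            )
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
            continue
        records.append(
            ProcedureRecord(
                case_id=str(d["case_id"]),
                features=features,
                operator=operator,
                technical_success=bool(d["technical_success"]),
                procedural_success=bool(d["procedural_success"]),
                scores=score_all(features, operator) if score else None,
            )
        )
    if errors:
        raise CohortValidationError(errors)
    try:
        return Cohort(records=tuple(records), provenance=f"loaded from {path}")
    except ValueError as exc:
        raise CohortValidationError([str(exc)]) from exc
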