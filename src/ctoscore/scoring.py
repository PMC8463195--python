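"""Additive difficulty scores for chronic-total-occlusion PCI.

Implements the operator-CTO score — an additive model combining one clinical
variable (prior target-vessel CABG), eight angiographic lesion variables, and
three operator-experience credits — together with the five published
comparator scores (J-CTO, PROGRESS, ORA, RECHARGE, CL) computed from the same
adjudicated case features.

All scores are deterministic functions of a :class:`CaseFeatures` record and,
for the operator-CTO score, an :class:`OperatorProfile`.  Threshold
comparisons follow the printed inequality symbols exactly: the operator-CTO
length variable is ``>= 20`` mm while J-CTO/RECHARGE/CL use ``> 20`` mm, and
no tolerance is applied to the operator success-rate boundary (0.8999 does
not earn the >=90% credit).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "TargetVessel",
    "DifficultyTier",
    "OperatorGroup",
    "CaseFeatures",
    "OperatorProfile",
    "ScorePanel",
    "operator_credit",
    "score_operator_cto",
    "classify_difficulty",
    "score_jcto",
    "score_progress",
    "score_ora",
    "score_recharge",
    "score_cl",
    "classify_operator_group",
    "GroupAssignment",
    "score_all",
]


class TargetVessel(str, enum.Enum):
    """Coronary vessel harbouring the occlusion."""

    LAD = "LAD"
    LCX = "LCX"
    RCA = "RCA"
    LM = "LM"


class DifficultyTier(enum.IntEnum):
    """Ordered procedure-difficulty tiers derived from the operator-CTO score."""

    SIMPLE = 0
    MEDIUM = 1
    DIFFICULT = 2
    EXTREMELY_DIFFICULT = 3

    @property
    def label(self) -> str:
        return _TIER_LABELS[self]


_TIER_LABELS = {
    DifficultyTier.SIMPLE: "simple",
    DifficultyTier.MEDIUM: "medium",
    DifficultyTier.DIFFICULT: "difficult",
    DifficultyTier.EXTREMELY_DIFFICULT: "extremely_difficult",
}


class OperatorGroup(str, enum.Enum):
    """Experience strata for operators (years performing, annual volume,
    previous-year technical success rate)."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"


@dataclass(frozen=True)
class CaseFeatures:
    """Pre-adjudicated clinical and angiographic inputs for one lesion.

    Attributes
    ----------
    age_years : int
        Patient age, >= 18.
    prior_mi : bool
        History of acute myocardial infarction before this procedure.
    prior_failed_attempt : bool
        A previously failed PCI attempt on this lesion.
    prior_cabg_target_vessel : bool
        Bypass graft surgery on the target vessel >= 3 months earlier.
    target_vessel : TargetVessel
    blunt_stump : bool
        Occlusion entry ends abruptly ("knife cut") rather than tapering.
    calcification : bool
        Any calcification in the occluded entrance or body segment.
    calcification_severe : bool
        Severe calcification (implies ``calcification``); only the CL score
        distinguishes severity.
    bend_ge45 : bool
        Any bend >= 45 degrees in the occluded segment (J-CTO/RECHARGE
        tortuosity definition).
    severe_angulation : bool
        At least two bends > 70 degrees or one > 90 degrees (PROGRESS-style
        tortuosity; implies ``bend_ge45``).
    occlusion_length_mm : float
        Occlusion length in millimetres, >= 0.
    distal_disease : bool
        Significant disease beyond the occlusion and/or distal lumen < 2 mm.
    rentrop_grade : int
        Collateral filling grade 0-3; < 2 denotes poor collaterals.
    in_stent : bool
        Occlusion within a previously implanted stent.
    ostial : bool
        Occluded segment at the proximal vessel opening.
    """

    age_years: int
    prior_mi: bool
    prior_failed_attempt: bool
    prior_cabg_target_vessel: bool
    target_vessel: TargetVessel
    blunt_stump: bool
    calcification: bool
    calcification_severe: bool
    bend_ge45: bool
    severe_angulation: bool
    occlusion_length_mm: float
    distal_disease: bool
    rentrop_grade: int
    in_stent: bool
    ostial: bool

    def __post_init__(self) -> None:
        if self.age_years < 18:
            raise ValueError(f"age_years must be >= 18, got {self.age_years}")
        if self.calcification_severe and not self.calcification:
            raise ValueError("calcification_severe requires calcification")
        if self.severe_angulation and not self.bend_ge45:
            raise ValueError("severe_angulation requires bend_ge45")
        if self.occlusion_length_mm < 0:
            raise ValueError("occlusion_length_mm must be >= 0")
        if self.rentrop_grade not in (0, 1, 2, 3):
            raise ValueError(
                f"rentrop_grade must be in {{0,1,2,3}}, got {self.rentrop_grade}"
            )
        if not isinstance(self.target_vessel, TargetVessel):
            object.__setattr__(
                self, "target_vessel", TargetVessel(self.target_vessel)
            )


@dataclass(frozen=True)
class OperatorProfile:
    """One operator's experience variables.

    ``years_performing`` counts whole years as the main CTO-PCI operator
    (more than six months rounds up to one year, applied upstream).
    ``last_year_success_rate`` is the previous year's technical success
    proportion in [0, 1].
    """

    operator_id: str
    years_performing: int
    annual_volume: int
    last_year_success_rate: float

    def __post_init__(self) -> None:
        if self.years_performing < 0:
            raise ValueError("years_performing must be >= 0")
        if self.annual_volume < 0:
            raise ValueError("annual_volume must be >= 0")
        if not 0.0 <= self.last_year_success_rate <= 1.0:
            raise ValueError("last_year_success_rate must be in [0, 1]")


@dataclass(frozen=True)
class ScorePanel:
    """All six scores plus the difficulty tier for one case."""

    operator_cto: int
    jcto: int
    progress: int
    ora: int
    recharge: int
    cl: float
    tier: DifficultyTier

    def __post_init__(self) -> None:
        checks = (
            ("operator_cto", self.operator_cto, -4, 9),
            ("jcto", self.jcto, 0, 5),
            ("progress", self.progress, 0, 4),
            ("ora", self.ora, 0, 3),
            ("recharge", self.recharge, 0, 6),
            ("cl", self.cl, 0.0, 8.0),
        )
        for name, value, lo, hi in checks:
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if self.tier is not classify_difficulty(self.operator_cto):
            raise ValueError("tier inconsistent with operator_cto score")


def operator_credit(operator: OperatorProfile) -> int:
    """Experience credit subtracted from the lesion score.

    -1 for annual volume >= 60 cases, -1 for >= 5 years performing, and -2
    for a previous-year success rate >= 90%; each criterion is independent
    and boundaries are inclusive.  Result is in {0, -1, -2, -3, -4}.
    """
    credit = 0
    if operator.annual_volume >= 60:
        credit -= 1
    if operator.years_performing >= 5:
        credit -= 1
    if operator.last_year_success_rate >= 0.90:
        credit -= 2
    return credit


def score_operator_cto(features: CaseFeatures, operator: OperatorProfile) -> int:
    """Operator-CTO score: nine 1-point adverse variables plus the operator
    credit; range [-4, 9].

    The adverse variables are prior target-vessel CABG, blunt stump, any
    calcification, severe angulation (the curvature variable), occlusion
    length >= 20 mm, distal disease, Rentrop grade < 2, in-stent occlusion,
    and ostial occlusion.
    """
    adverse = (
        features.prior_cabg_target_vessel
        + features.blunt_stump
        + features.calcification
        + features.severe_angulation
        + (features.occlusion_length_mm >= 20.0)
        + features.distal_disease
        + (features.rentrop_grade < 2)
        + features.in_stent
        + features.ostial
    )
    return int(adverse) + operator_credit(operator)


def classify_difficulty(score: int) -> DifficultyTier:
    """Map an operator-CTO score to its difficulty tier.

    <=2 simple, 3 medium, 4 difficult, >=5 extremely difficult.
    """
    if not -4 <= score <= 9:
        raise ValueError(f"operator-CTO score {score} outside [-4, 9]")
    if score <= 2:
        return DifficultyTier.SIMPLE
    if score == 3:
        return DifficultyTier.MEDIUM
    if score == 4:
        return DifficultyTier.DIFFICULT
    return DifficultyTier.EXTREMELY_DIFFICULT


def score_jcto(features: CaseFeatures) -> int:
    """J-CTO score: blunt stump, length > 20 mm, calcification, bend >= 45
    degrees, previously failed attempt; one point each, range [0, 5]."""
    return int(
        features.blunt_stump
        + (features.occlusion_length_mm > 20.0)
        + features.calcification
        + features.bend_ge45
        + features.prior_failed_attempt
    )


def score_progress(features: CaseFeatures) -> int:
    """PROGRESS score: blunt stump, moderate/severe tortuosity, poor
    collaterals (Rentrop < 2), circumflex occlusion; range [0, 4]."""
    return int(
        features.blunt_stump
        + features.severe_angulation
        + (features.rentrop_grade < 2)
        + (features.target_vessel is TargetVessel.LCX)
    )


def score_ora(features: CaseFeatures) -> int:
    """ORA score: age >= 75, ostial location, Rentrop < 2; range [0, 3]."""
    return int(
        (features.age_years >= 75)
        + features.ostial
        + (features.rentrop_grade < 2)
    )


def score_recharge(features: CaseFeatures) -> int:
    """RECHARGE score: blunt stump, length > 20 mm, calcification, bend >= 45
    degrees, distal disease, prior target-vessel CABG; range [0, 6]."""
    return int(
        features.blunt_stump
        + (features.occlusion_length_mm > 20.0)
        + features.calcification
        + features.bend_ge45
        + features.distal_disease
        + features.prior_cabg_target_vessel
    )


def score_cl(features: CaseFeatures) -> float:
    """CL score with fractional weights; range [0, 8] in 0.5 steps.

    Blunt stump 1, length > 20 mm 1.5, severe calcification 2, non-LAD
    vessel 1, prior target-vessel CABG 1.5, prior MI 1.
    """
    return (
        1.0 * features.blunt_stump
        + 1.5 * (features.occlusion_length_mm > 20.0)
        + 2.0 * features.calcification_severe
        + 1.0 * (features.target_vessel is not TargetVessel.LAD)
        + 1.5 * features.prior_cabg_target_vessel
        + 1.0 * features.prior_mi
    )


class GroupAssignment(NamedTuple):
    group: OperatorGroup
    extrapolated: bool


def classify_operator_group(operator: OperatorProfile) -> OperatorGroup:
    """Assign an operator to experience group I-V.

    I: <5 y, <60 cases, <90%; II: <5 y, >=60, <90%; III: >=5 y, <60, <90%;
    IV: >=5 y, >=60, <90%; V: >=5 y, >=60, >=90%.  Combinations outside the
    five defined strata (a >=90% operator lacking the years or volume
    criterion) resolve by the success-rate criterion first; use
    :func:`classify_operator_group_flagged` to see when this extrapolation
    fired.
    """
    return classify_operator_group_flagged(operator).group


def classify_operator_group_flagged(operator: OperatorProfile) -> GroupAssignment:
    """As :func:`classify_operator_group`, also reporting whether the
    operator fell outside the five enumerated strata."""
    senior = operator.years_performing >= 5
    high_volume = operator.annual_volume >= 60
    expert_rate = operator.last_year_success_rate >= 0.90
    if expert_rate:
        # success-rate criterion dominates; flag when years/volume fall short
        return GroupAssignment(OperatorGroup.V, not (senior and high_volume))
    if senior and high_volume:
        return GroupAssignment(OperatorGroup.IV, False)
    if senior:
        return GroupAssignment(OperatorGroup.III, False)
    if high_volume:
        return GroupAssignment(OperatorGroup.II, False)
    return GroupAssignment(OperatorGroup.I, False)


def score_all(features: CaseFeatures, operator: OperatorProfile) -> ScorePanel:
    """Compute every score and the difficulty tier for one case."""
    op_cto = score_operator_cto(features, operator)
    return ScorePanel(
        operator_cto=op_cto,
        jcto=score_jcto(features),
        progress=score_progress(features),
        ora=score_ora(features),
        recharge=score_recharge(features),
        cl=score_cl(features),
        tier=classify_difficulty(op_cto),
    )
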