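import numpy as np
import pytest
from hypothesis import settings
from hypothesis import strategies as st

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from ctoscore.scoring import (
    CaseFeatures,
    OperatorProfile,
    ScorePanel,
    TargetVessel,
    classify_difficulty,
)
from ctoscore.simulate import Cohort, ProcedureRecord


@st.composite
def case_features(draw) -> CaseFeatures:
    """Random valid CaseFeatures respecting the implication invariants."""
    calcification = draw(st.booleans())
    bend = draw(st.booleans())
    return CaseFeatures(
        age_years=draw(st.integers(18, 95)),
        prior_mi=draw(st.booleans()),
        prior_failed_attempt=draw(st.booleans()),
        prior_cabg_target_vessel=draw(st.booleans()),
        target_vessel=draw(st.sampled_from(list(TargetVessel))),
        blunt_stump=draw(st.booleans()),
        calcification=calcification,
        calcification_severe=calcification and draw(st.booleans()),
        bend_ge45=bend,
        severe_angulation=bend and draw(st.booleans()),
        occlusion_length_mm=draw(st.floats(0, 120, allow_nan=False)),
        distal_disease=draw(st.booleans()),
        rentrop_grade=draw(st.integers(0, 3)),
        in_stent=draw(st.booleans()),
        ostial=draw(st.booleans()),
    )


@st.composite
def operator_profiles(draw) -> OperatorProfile:
    return OperatorProfile(
        operator_id="op",
        years_performing=draw(st.integers(0, 20)),
        annual_volume=draw(st.integers(0, 200)),
        last_year_success_rate=draw(st.floats(0, 1, allow_nan=False)),
    )


BENIGN_FEATURES = CaseFeatures(
    age_years=60,
    prior_mi=False,
    prior_failed_attempt=False,
    prior_cabg_target_vessel=False,
    target_vessel=TargetVessel.LAD,
    blunt_stump=False,
    calcification=False,
    calcification_severe=False,
    bend_ge45=False,
    severe_angulation=False,
    occlusion_length_mm=10.0,
    distal_disease=False,
    rentrop_grade=3,
    in_stent=False,
    ostial=False,
)

ADVERSE_FEATURES = CaseFeatures(
    age_years=80,
    prior_mi=True,
    prior_failed_attempt=True,
    prior_cabg_target_vessel=True,
    target_vessel=TargetVessel.LCX,
    blunt_stump=True,
    calcification=True,
    calcification_severe=True,
    bend_ge45=True,
    severe_angulation=True,
    occlusion_length_mm=40.0,
    distal_disease=True,
    rentrop_grade=1,
    in_stent=True,
    ostial=True,
)

NOVICE_OPERATOR = OperatorProfile("nov", 3, 40, 0.85)
EXPERT_OPERATOR = OperatorProfile("exp", 6, 70, 0.92)


def make_tier_record(case_id: str, score: int, technical: bool, procedural: bool | None = None) -> ProcedureRecord:
    """A record with a forced operator-CTO score (for tier-table fixtures)."""
    panel = ScorePanel(
        operator_cto=score,
        jcto=0,
        progress=0,
        ora=0,
        recharge=0,
        cl=0.0,
        tier=classify_difficulty(score),
    )
    return ProcedureRecord(
        case_id=case_id,
        features=BENIGN_FEATURES,
        operator=NOVICE_OPERATOR,
        technical_success=technical,
        procedural_success=technical if procedural is None else procedural,
        scores=panel,
    )


def tier_fixture_cohort() -> Cohort:
    """Cohort with per-tier (n, technical successes) =
    (103, 102), (24, 21), (13, 7), (4, 1) — total 144 cases, 131 successes."""
    spec = [(0, 103, 102), (3, 24, 21), (4, 13, 7), (5, 4, 1)]
    records = []
    i = 0
    for score, n, successes in spec:
        for j in range(n):
            records.append(make_tier_record(f"c{i:04d}", score, j < successes))
            i += 1
    return Cohort(records=tuple(records))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
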