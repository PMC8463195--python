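"""Synthetic CTO-PCI cohort generation.

Generates cohorts with the marginal structure of a 144-procedure,
10-operator registry: configurable lesion-feature prevalences, an operator
pool stratified into five experience groups, and technical-success outcomes
drawn conditionally on the operator-CTO difficulty tier (default tier success
probabilities 99.0%, 87.5%, 53.8%, 25.0%).

Features are drawn independently at their marginal prevalences — the source
registry reports only marginals, so no joint feature structure is imposed.
One root seed is split into independent substreams per generation stage
(operators, features, operator assignment, outcomes) so adding a stage never
perturbs earlier draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
from scipy import stats as sps

from .scoring import (
    CaseFeatures,
    OperatorGroup,
    OperatorProfile,
    ScorePanel,
    TargetVessel,
    classify_operator_group,
    score_all,
)

__all__ = [
    "GeneratorConfig",
    "ProcedureRecord",
    "Cohort",
    "generate_operators",
    "generate_case_features",
    "generate_outcomes",
    "generate_cohort",
    "generate_auc_benchmark",
    "expected_benchmark_auc",
    "generate_rating_pairs",
    "BENCHMARK_TIER_WEIGHTS",
    "BENCHMARK_FAILURE_PROBS",
    "BENCHMARK_SCORE_SUPPORT",
]

#: Default marginal prevalences of the binary lesion features.
DEFAULT_FEATURE_PREVALENCES: dict[str, float] = {
    "prior_mi": 0.308,
    "prior_failed_attempt": 0.40,
    "prior_cabg_target_vessel": 0.007,
    "blunt_stump": 0.576,
    "calcification": 0.333,
    "calcification_severe": 0.167,
    "bend_ge45": 0.910,
    "severe_angulation": 0.333,
    "distal_disease": 0.542,
    "in_stent": 0.139,
    "ostial": 0.479,
}

#: Target-vessel distribution (LAD, LCX, RCA, LM).
DEFAULT_VESSEL_PROBS: dict[TargetVessel, float] = {
    TargetVessel.LAD: 0.424,
    TargetVessel.LCX: 0.097,
    TargetVessel.RCA: 0.472,
    TargetVessel.LM: 0.007,
}

#: Operator-group procedure-volume weights (groups I..V), proportional to
#: per-group procedure counts 5, 6, 13, 75, 45 out of 144.
DEFAULT_GROUP_WEIGHTS = (5 / 144, 6 / 144, 13 / 144, 75 / 144, 45 / 144)

#: Number of operators per group I..V in the simulated 10-operator pool.
GROUP_OPERATOR_COUNTS = (2, 1, 2, 3, 2)

#: (years, volume, success-rate) sampling boxes defining each group.
GROUP_BOXES: dict[OperatorGroup, tuple[tuple[int, int], tuple[int, int], tuple[float, float]]] = {
    OperatorGroup.I: ((1, 4), (20, 59), (0.70, 0.90)),
    OperatorGroup.II: ((1, 4), (60, 120), (0.70, 0.90)),
    OperatorGroup.III: ((5, 15), (20, 59), (0.70, 0.90)),
    OperatorGroup.IV: ((5, 15), (60, 120), (0.70, 0.90)),
    OperatorGroup.V: ((5, 15), (60, 120), (0.90, 0.99)),
}

#: Tier mix of the discrimination benchmark (simple..extremely difficult).
BENCHMARK_TIER_WEIGHTS = (103 / 144, 24 / 144, 13 / 144, 4 / 144)
#: Per-tier technical-failure probabilities of the benchmark.
BENCHMARK_FAILURE_PROBS = (0.010, 0.125, 0.462, 0.750)
#: Within-tier score supports (uniform over each tuple).
BENCHMARK_SCORE_SUPPORT = ((0, 1, 2), (3,), (4,), (5, 6))


@dataclass(frozen=True)
class LengthDistribution:
    """Occlusion-length model: a normal truncated at 0, location calibrated
    so the untruncated probability of >= 20 mm equals ``p_ge20``."""

    mean_mm: float = 35.0
    sd_mm: float = 13.0
    p_ge20: float | None = 0.882

    @property
    def loc(self) -> float:
        if self.p_ge20 is None:
            return self.mean_mm
        return 20.0 + self.sd_mm * sps.norm.ppf(self.p_ge20)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the cohort generator; defaults emulate the 144-procedure
    registry the scores were developed on."""

    n_cases: int = 144
    seed: int = 0
    feature_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_PREVALENCES)
    )
    vessel_probs: dict[TargetVessel, float] = field(
        default_factory=lambda: dict(DEFAULT_VESSEL_PROBS)
    )
    operator_group_weights: tuple[float, ...] = DEFAULT_GROUP_WEIGHTS
    tier_success_probs: tuple[float, float, float, float] = (0.990, 0.875, 0.538, 0.250)
    procedural_given_technical: float = 128 / 131
    rentrop_lt2_prob: float = 0.319
    length_distribution: LengthDistribution = LengthDistribution()
    age_mean: float = 62.81
    age_sd: float = 11.27

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        probs = list(self.feature_prevalences.values())
        probs += [self.procedural_given_technical, self.rentrop_lt2_prob]
        probs += list(self.tier_success_probs)
        probs += list(self.vessel_probs.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        w = self.operator_group_weights
        if len(w) != 5 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("operator_group_weights must be 5 non-negative reals summing to 1")
        fp = self.feature_prevalences
        if fp["calcification_severe"] > fp["calcification"] + 1e-12:
            raise ValueError("severe calcification prevalence exceeds any-calcification")
        if fp["severe_angulation"] > fp["bend_ge45"] + 1e-12:
            raise ValueError("severe angulation prevalence exceeds bend_ge45")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["vessel_probs"] = {k.value: v for k, v in self.vessel_probs.items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class ProcedureRecord:
    """One procedure: features, operator, outcomes, and the score panel."""

    case_id: str
    features: CaseFeatures
    operator: OperatorProfile
    technical_success: bool
    procedural_success: bool
    scores: ScorePanel | None = None

    def __post_init__(self) -> None:
        if self.procedural_success and not self.technical_success:
            raise ValueError("procedural_success requires technical_success")


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of procedure records with generation provenance."""

    records: tuple[ProcedureRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.case_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("case_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProcedureRecord]:
        return iter(self.records)


def generate_operators(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[OperatorProfile]:
    """Draw the 10-operator pool: group counts (2, 1, 2, 3, 2) for groups
    I..V, each operator's variables uniform within its group's defining box."""
    operators: list[OperatorProfile] = []
    idx = 1
    for group, count in zip(OperatorGroup, GROUP_OPERATOR_COUNTS):
        (ylo, yhi), (vlo, vhi), (rlo, rhi) = GROUP_BOXES[group]
        for _ in range(count):
            operators.append(
                OperatorProfile(
                    operator_id=f"op{idx:02d}",
                    years_performing=int(rng.integers(ylo, yhi + 1)),
                    annual_volume=int(rng.integers(vlo, vhi + 1)),
                    last_year_success_rate=float(rng.uniform(rlo, rhi)),
                )
            )
            idx += 1
    return operators


def generate_case_features(
    config: GeneratorConfig, rng: np.random.Generator
) -> CaseFeatures:
    """Draw one case's features: independent Bernoulli flags at configured
    prevalences, with the severe ⇒ any implications enforced by drawing the
    severe variant conditionally inside its parent."""
    fp = config.feature_prevalences

    def bern(p: float) -> bool:
        return bool(rng.random() < p)

    calcification = bern(fp["calcification"])
    calc_severe = calcification and bern(
        fp["calcification_severe"] / fp["calcification"]
        if fp["calcification"] > 0
        else 0.0
    )
    bend = bern(fp["bend_ge45"])
    severe_ang = bend and bern(
        fp["severe_angulation"] / fp["bend_ge45"] if fp["bend_ge45"] > 0 else 0.0
    )
    vessels = list(config.vessel_probs)
    vessel = vessels[
        int(rng.choice(len(vessels), p=np.asarray(list(config.vessel_probs.values()))))
    ]
    if bern(config.rentrop_lt2_prob):
        rentrop = int(rng.integers(0, 2))  # sub-grades 0/1 split evenly
    else:
        rentrop = int(rng.integers(2, 4))
    ld = config.length_distribution
    a = (0.0 - ld.loc) / ld.sd_mm
    length = float(sps.truncnorm.ppf(rng.random(), a, np.inf, loc=ld.loc, scale=ld.sd_mm))
    age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 18, 100))
    return CaseFeatures(
        age_years=age,
        prior_mi=bern(fp["prior_mi"]),
        prior_failed_attempt=bern(fp["prior_failed_attempt"]),
        prior_cabg_target_vessel=bern(fp["prior_cabg_target_vessel"]),
        target_vessel=vessel,
        blunt_stump=bern(fp["blunt_stump"]),
        calcification=calcification,
        calcification_severe=calc_severe,
        bend_ge45=bend,
        severe_angulation=severe_ang,
        occlusion_length_mm=length,
        distal_disease=bern(fp["distal_disease"]),
        rentrop_grade=rentrop,
        in_stent=bern(fp["in_stent"]),
        ostial=bern(fp["ostial"]),
    )


def generate_outcomes(
    panel: ScorePanel, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[bool, bool]:
    """Draw (technical_success, procedural_success) conditionally on the
    difficulty tier; procedural success nests inside technical success."""
    p_tech = config.tier_success_probs[int(panel.tier)]
    technical = bool(rng.random() < p_tech)
    procedural = technical and bool(rng.random() < config.procedural_given_technical)
    return technical, procedural


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full scored cohort, deterministic given the config.

    Independent substreams: operators, features, operator assignment and
    outcomes each consume their own child of the root seed.
    """
    root = np.random.SeedSequence(config.seed)
    op_ss, feat_ss, assign_ss, out_ss = root.spawn(4)
    op_rng = np.random.default_rng(op_ss)
    feat_rng = np.random.default_rng(feat_ss)
    assign_rng = np.random.default_rng(assign_ss)
    out_rng = np.random.default_rng(out_ss)

    operators = generate_operators(config, op_rng)
    by_group: dict[OperatorGroup, list[OperatorProfile]] = {g: [] for g in OperatorGroup}
    for op in operators:
        by_group[classify_operator_group(op)].append(op)

    groups = list(OperatorGroup)
    weights = np.asarray(config.operator_group_weights)
    records = []
    for i in range(config.n_cases):
        features = generate_case_features(config, feat_rng)
        group = groups[int(assign_rng.choice(5, p=weights))]
        members = by_group[group]
        operator = members[int(assign_rng.integers(len(members)))]
        panel = score_all(features, operator)
        technical, procedural = generate_outcomes(panel, config, out_rng)
        records.append(
            ProcedureRecord(
                case_id=f"case{i + 1:05d}",
                features=features,
                operator=operator,
                technical_success=technical,
                procedural_success=procedural,
                scores=panel,
            )
        )
    provenance = f"seed={config.seed} config={config.config_hash()} n={config.n_cases}"
    return Cohort(records=tuple(records), provenance=provenance)


def generate_auc_benchmark(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Tier-based discrimination benchmark.

    Each case draws a difficulty tier with probabilities (103, 24, 13, 4)/144,
    an operator-CTO score uniform over that tier's support ({0,1,2}, {3},
    {4}, {5,6}), and a technical failure ~ Bernoulli of the tier's failure
    probability (0.010, 0.125, 0.462, 0.750).

    Returns
    -------
    scores, failures : ndarray
        Parallel arrays; ``failures`` is 1 for technical failure (the
        positive class a difficulty score should rank highly).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    tiers = rng.choice(4, size=n, p=np.asarray(BENCHMARK_TIER_WEIGHTS))
    scores = np.empty(n, dtype=int)
    for t, support in enumerate(BENCHMARK_SCORE_SUPPORT):
        mask = tiers == t
        scores[mask] = rng.choice(support, size=int(mask.sum()))
    fail_p = np.asarray(BENCHMARK_FAILURE_PROBS)[tiers]
    failures = (rng.random(n) < fail_p).astype(int)
    return scores, failures


def expected_benchmark_auc(
    tier_weights: Sequence[float] = BENCHMARK_TIER_WEIGHTS,
    failure_probs: Sequence[float] = BENCHMARK_FAILURE_PROBS,
    score_support: Sequence[Sequence[int]] = BENCHMARK_SCORE_SUPPORT,
) -> float:
    """Closed-form expected AUC of the benchmark generator.

    Builds the exact joint distribution of (score, failure) over the discrete
    supports and evaluates P(S_fail > S_succ) + 0.5 P(S_fail = S_succ).
    """
    pf: dict[int, float] = {}
    ps: dict[int, float] = {}
    for w, q, support in zip(tier_weights, failure_probs, score_support):
        for s in support:
            p = w / len(support)
            pf[s] = pf.get(s, 0.0) + p * q
            ps[s] = ps.get(s, 0.0) + p * (1.0 - q)
    total_f = sum(pf.values())
    total_s = sum(ps.values())
    auc = 0.0
    for sf, a in pf.items():
        for ss, b in ps.items():
            if sf > ss:
                auc += a * b
            elif sf == ss:
                auc += 0.5 * a * b
    return auc / (total_f * total_s)


def generate_rating_pairs(
    n: int, agreement: float, n_categories: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two parallel categorical rating sequences for agreement studies.

    Rater 1 is uniform over categories; rater 2 copies rater 1 with
    probability ``agreement`` and otherwise re-draws uniformly over the
    remaining categories.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, n_categories, size=n)
    copy = rng.random(n) < agreement
    shift = rng.integers(1, n_categories, size=n)
    b = np.where(copy, a, (a + shift) % n_categories)
    return a, b
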