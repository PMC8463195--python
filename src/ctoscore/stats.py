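"""Calibration, discrimination, and agreement statistics for score validation.

Discrimination uses the Mann–Whitney AUC estimator (midrank tie handling,
identical to the trapezoidal ROC area) with a DeLong normal-approximation
confidence interval.  Calibration recalibrates an integer score to event
probabilities through a univariate logistic fit and applies the
Hosmer–Lemeshow goodness-of-fit test on decile groups.  Inter-rater
agreement uses unweighted Cohen's kappa.  Classical group-comparison tests
(chi-square, Fisher exact, one-way ANOVA, Kruskal–Wallis) round out the
toolbox; the chi-square/Fisher/Kruskal paths delegate to scipy after
degenerate-input checks.

AUC orientation convention: the positive class is technical *failure* and
higher scores predict it, so a well-behaved difficulty score has AUC > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import DifficultyTier
from .simulate import Cohort

__all__ = [
    "percent",
    "RocResult",
    "HLResult",
    "KappaResult",
    "TierTable",
    "LogisticFit",
    "tier_success_table",
    "auc_mann_whitney",
    "roc_points",
    "auc_ci",
    "logistic_recalibration",
    "hosmer_lemeshow",
    "cohen_kappa",
    "chi_square_test",
    "fisher_exact_2x2",
    "one_way_anova",
    "kruskal_wallis",
]


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (display convention for
    cohort tables)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TierRow:
    tier: DifficultyTier
    n: int
    technical_successes: int
    procedural_successes: int
    technical_pct: float | None
    procedural_pct: float | None


@dataclass(frozen=True)
class TierTable:
    """Per-difficulty-tier success counts and percentages.

    Empty tiers carry ``n=0`` and ``None`` percentages rather than 0.0.
    """

    rows: tuple[TierRow, ...]

    @property
    def total_n(self) -> int:
        return sum(r.n for r in self.rows)

    @property
    def total_technical(self) -> int:
        return sum(r.technical_successes for r in self.rows)


def tier_success_table(cohort: Cohort) -> TierTable:
    """Group a scored cohort by difficulty tier and tabulate success rates."""
    rows = []
    for tier in DifficultyTier:
        recs = [r for r in cohort if r.scores is not None and r.scores.tier is tier]
        n = len(recs)
        tech = sum(r.technical_success for r in recs)
        proc = sum(r.procedural_success for r in recs)
        rows.append(
            TierRow(
                tier=tier,
                n=n,
                technical_successes=tech,
                procedural_successes=proc,
                technical_pct=percent(tech, n) if n else None,
                procedural_pct=percent(proc, n) if n else None,
            )
        )
    unscored = sum(r.scores is None for r in cohort)
    if unscored:
        raise ValueError(f"{unscored} records lack a score panel")
    return TierTable(rows=tuple(rows))


def _check_binary(outcomes: np.ndarray) -> tuple[int, int]:
    n_pos = int(outcomes.sum())
    n_neg = int(len(outcomes) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("outcomes are degenerate: need both classes present")
    return n_pos, n_neg


def auc_mann_whitney(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """AUC via the Mann–Whitney U statistic with midrank ties.

    Equals the trapezoidal area under the ROC curve.  ``outcomes`` is 0/1
    with 1 the positive class (technical failure); higher scores should
    predict the positive class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    n_pos, n_neg = _check_binary(y)
    ranks = sps.rankdata(s)
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_points(
    scores: Sequence[float], outcomes: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve points at every distinct threshold, descending.

    Returns (thresholds, sensitivity, specificity); includes the (0, 1) and
    (1, 0) endpoints via +inf/-inf thresholds.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n_pos, n_neg = _check_binary(y)
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    sens = np.array([(s[y == 1] >= t).sum() / n_pos for t in thresholds])
    spec = np.array([(s[y == 0] < t).sum() / n_neg for t in thresholds])
    return thresholds, sens, spec


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def auc_ci(
    scores: Sequence[float],
    outcomes: Sequence[int],
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the Mann–Whitney AUC.

    ``method='delong'`` uses the DeLong placement-variance estimate with a
    normal interval truncated to [0, 1]; ``method='bootstrap'`` resamples
    cases (stratified draws not enforced; degenerate resamples are redrawn).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n_pos, n_neg = _check_binary(y)
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 cases in each outcome class")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    auc = auc_mann_whitney(s, y)
    z = sps.norm.ppf(0.5 + level / 2)
    if method == "delong":
        pos = s[y == 1]
        neg = s[y == 0]
        # placements: V10_i = P-hat(pos_i outranks a random negative)
        v10 = np.array([np.mean((x > neg) + 0.5 * (x == neg)) for x in pos])
        v01 = np.array([np.mean((pos > x) + 0.5 * (pos == x)) for x in neg])
        var = v10.var(ddof=1) / n_pos + v01.var(ddof=1) / n_neg
        se = np.sqrt(var)
        return float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(s)
        aucs = []
        while len(aucs) < n_boot:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.sum() in (0, n):
                continue
            aucs.append(auc_mann_whitney(s[idx], yb))
        lo, hi = np.quantile(aucs, [(1 - level) / 2, 0.5 + level / 2])
        return float(lo), float(hi)
    raise ValueError(f"unknown method {method!r}")


def roc_analysis(
    scores: Sequence[float], outcomes: Sequence[int], level: float = 0.95
) -> RocResult:
    """Full ROC summary: curve points, AUC, and DeLong interval."""
    thresholds, sens, spec = roc_points(scores, outcomes)
    auc = auc_mann_whitney(scores, outcomes)
    lo, hi = auc_ci(scores, outcomes, level=level)
    y = np.asarray(outcomes, dtype=int)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
    )


@dataclass(frozen=True)
class LogisticFit:
    """Univariate logistic recalibration P(event) = expit(a + b*score)."""

    intercept: float
    slope: float
    probabilities: np.ndarray
    converged: bool
    separated: bool
    n_iter: int
    log_likelihood: float


def logistic_recalibration(
    scores: Sequence[float],
    outcomes: Sequence[int],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of outcome on score by Newton–Raphson.

    Convergence: log-likelihood change below ``tol`` or ``max_iter``
    iterations.  Complete separation (all positive scores strictly above all
    negative scores, or vice versa) is detected up front and flagged — the
    returned coefficients are then the state at the iteration cap, not an
    MLE (none exists).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_binary(y.astype(int))
    pos, neg = s[y == 1], s[y == 0]
    separated = bool(pos.min() > neg.max() or pos.max() < neg.min())

    X = np.column_stack([np.ones_like(s), s])
    beta = np.zeros(2)
    # start intercept at the logit of the event rate
    rate = y.mean()
    beta[0] = np.log(rate / (1 - rate))
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * np.log(p + 1e-300) + (1 - y) * np.log(1 - p + 1e-300)))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * np.log(p + 1e-300) + (1 - y) * np.log(1 - p + 1e-300)))
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        probabilities=p,
        converged=converged and not separated,
        separated=separated,
        n_iter=it,
        log_likelihood=ll,
    )


@dataclass(frozen=True)
class HLResult:
    """Hosmer–Lemeshow goodness-of-fit result.

    ``group_table`` columns: n, observed, expected.  ``df_degenerate`` marks
    fits where fewer than 3 distinct groups survived (p undefined).
    """

    statistic: float
    df: int
    p_value: float
    group_table: pd.DataFrame
    df_degenerate: bool = False


def hosmer_lemeshow(
    probabilities: Sequence[float],
    outcomes: Sequence[int],
    n_groups: int = 10,
    group_values: Sequence[float] | None = None,
) -> HLResult:
    """Hosmer–Lemeshow chi-square test on near-equal-size risk groups.

    Cases are sorted by predicted probability (or by ``group_values`` if
    given — any strictly increasing transform yields identical groups) and
    split into ``n_groups`` quantile groups; tied values stay together and
    duplicate cut-points collapse.  Statistic: sum over groups of
    (O-E)^2 / (E (1 - E/n)); df = realized groups - 2.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and outcomes must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_groups < 3:
        raise ValueError("n_groups must be >= 3")
    gv = p if group_values is None else np.asarray(group_values, dtype=float)
    bins = pd.qcut(gv, q=n_groups, duplicates="drop")
    table = (
        pd.DataFrame({"bin": bins, "p": p, "y": y})
        .groupby("bin", observed=True)
        .agg(n=("y", "size"), observed=("y", "sum"), expected=("p", "sum"))
        .reset_index(drop=True)
    )
    for g, row in table.iterrows():
        if row["expected"] <= 0 or row["expected"] >= row["n"]:
            raise ValueError(
                f"group {g}: expected events {row['expected']:.3f} out of "
                f"{int(row['n'])} leave zero variance; cannot form the statistic"
            )
    o = table["observed"].to_numpy(dtype=float)
    e = table["expected"].to_numpy(dtype=float)
    n = table["n"].to_numpy(dtype=float)
    stat = float(np.sum((o - e) ** 2 / (e * (1 - e / n))))
    g_count = len(table)
    df = g_count - 2
    if df < 1:
        return HLResult(stat, df, float("nan"), table, df_degenerate=True)
    p_value = float(sps.chi2.sf(stat, df))
    return HLResult(stat, df, p_value, table)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    n: int
    degenerate: bool = False


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> KappaResult:
    """Unweighted Cohen's kappa for two categorical raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products.
    When both raters are constant and identical (p_e = 1, p_o = 1) kappa is
    defined as 1 with the ``degenerate`` flag set.
    """
    a = pd.Series(list(ratings_a))
    b = pd.Series(list(ratings_b))
    if len(a) != len(b):
        raise ValueError("rating sequences must have equal length")
    if len(a) == 0:
        raise ValueError("need at least one rating pair")
    n = len(a)
    p_o = float((a.to_numpy() == b.to_numpy()).mean())
    cats = pd.unique(pd.concat([a, b]))
    pa = a.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    pb = b.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    p_e = float((pa * pb).sum())
    if p_e >= 1.0 - 1e-15:
        return KappaResult(1.0, p_o, p_e, n, degenerate=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(float(kappa), p_o, p_e, n)


def chi_square_test(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table
    (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal; expected counts undefined")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 non-negative integers")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df_between, df_within, p).

    Degenerate inputs: zero within-group variance with equal means gives
    F = 0, p = 1; with unequal means gives F = inf, p = 0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 1 for g in gs):
        raise ValueError("need >= 2 groups, each non-empty")
    k = len(gs)
    n = sum(len(g) for g in gs)
    if n <= k:
        raise ValueError("total observations must exceed the group count")
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df1, df2, 1.0
        return float("inf"), df1, df2, 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), df1, df2, float(sps.f.sf(f, df1, df2))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal–Wallis rank test with tie correction: (H, df, p)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    df = len(gs) - 1
    flat = np.concatenate(gs)
    if np.all(flat == flat[0]):
        return 0.0, df, 1.0
    h, p = sps.kruskal(*gs)
    return float(h), df, float(p)
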