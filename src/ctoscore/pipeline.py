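"""End-to-end evaluation pipeline.

Generate or load a cohort, score every case with all six models, then
evaluate each selected score's calibration (logistic recalibration +
Hosmer–Lemeshow) and discrimination (Mann–Whitney AUC with DeLong CI)
against technical failure, plus the operator-CTO difficulty-tier success
table and cohort summary percentages.  The report is deterministic given
(config, seed); degenerate cohorts (a single outcome class) yield a partial
report with explicit skip reasons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .simulate import Cohort, GeneratorConfig, generate_cohort
from .io import read_cohort
from .stats import (
    auc_ci,
    auc_mann_whitney,
    hosmer_lemeshow,
    logistic_recalibration,
    percent,
    tier_success_table,
)

__all__ = ["RunConfig", "run_pipeline", "emit_report", "ALL_COMPARATORS"]

logger = logging.getLogger("ctoscore")

ALL_COMPARATORS = ("jcto", "progress", "ora", "recharge", "cl")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``generator`` (generate mode) or ``cohort_path`` (load
    mode) must be set.
    """

    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    comparators: tuple[str, ...] = ALL_COMPARATORS
    confidence_level: float = 0.95
    hl_groups: int = 10
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.cohort_path is None):
            raise ValueError("exactly one of generator / cohort_path must be set")
        if not self.comparators:
            raise ValueError("comparator set must be non-empty")
        unknown = set(self.comparators) - set(ALL_COMPARATORS)
        if unknown:
            raise ValueError(f"unknown comparators: {sorted(unknown)}")


def _score_column(cohort: Cohort, name: str) -> np.ndarray:
    return np.array([getattr(r.scores, name) for r in cohort], dtype=float)


def _evaluate_score(
    scores: np.ndarray, failures: np.ndarray, level: float, hl_groups: int
) -> dict:
    """HL calibration and ROC/AUC for one score against technical failure."""
    out: dict = {}
    auc = auc_mann_whitney(scores, failures)
    lo, hi = auc_ci(scores, failures, level=level)
    out["auc"] = round(auc, 3)
    out["auc_ci"] = [round(lo, 3), round(hi, 3)]
    fit = logistic_recalibration(scores, failures)
    out["recalibration"] = {
        "intercept": round(fit.intercept, 4),
        "slope": round(fit.slope, 4),
        "converged": fit.converged,
        "separated": fit.separated,
    }
    if fit.separated:
        out["hosmer_lemeshow"] = {"skipped": "complete separation in recalibration"}
        return out
    try:
        hl = hosmer_lemeshow(fit.probabilities, failures, n_groups=hl_groups)
    except ValueError as exc:
        out["hosmer_lemeshow"] = {"skipped": str(exc)}
        return out
    out["hosmer_lemeshow"] = {
        "statistic": round(hl.statistic, 3),
        "df": hl.df,
        "p_value": None if np.isnan(hl.p_value) else round(hl.p_value, 3),
        "df_degenerate": hl.df_degenerate,
    }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the evaluation report as a
    JSON-serializable dict."""
    if config.generator is not None:
        gen = config.generator
        logger.info("generating cohort: n=%d seed=%d hash=%s", gen.n_cases, gen.seed, gen.config_hash())
        cohort = generate_cohort(gen)
        source = {"mode": "generate", "config_hash": gen.config_hash(), "seed": gen.seed}
    else:
        logger.info("loading cohort from %s", config.cohort_path)
        cohort = read_cohort(config.cohort_path)
        source = {"mode": "load", "path": str(config.cohort_path)}

    n = len(cohort)
    report: dict = {
        "meta": {
            "package_version": __version__,
            "seed": config.seed,
            "source": source,
            "n_cases": n,
            "comparators": list(config.comparators),
            "confidence_level": config.confidence_level,
            "hl_groups": config.hl_groups,
        },
        "partial": False,
        "skip_reasons": [],
    }
    if n == 0:
        report["partial"] = True
        report["skip_reasons"].append("empty cohort")
        return report

    tech = np.array([r.technical_success for r in cohort], dtype=int)
    proc = np.array([r.procedural_success for r in cohort], dtype=int)
    failures = 1 - tech
    report["summary"] = {
        "n": n,
        "technical_successes": int(tech.sum()),
        "technical_success_pct": percent(int(tech.sum()), n),
        "technical_success_raw": float(tech.mean()),
        "procedural_successes": int(proc.sum()),
        "procedural_success_pct": percent(int(proc.sum()), n),
    }

    table = tier_success_table(cohort)
    report["tier_table"] = [
        {
            "tier": row.tier.label,
            "n": row.n,
            "technical_successes": row.technical_successes,
            "procedural_successes": row.procedural_successes,
            "technical_pct": row.technical_pct,
            "procedural_pct": row.procedural_pct,
        }
        for row in table.rows
    ]

    if failures.sum() == 0 or failures.sum() == n:
        report["partial"] = True
        report["skip_reasons"].append(
            "single outcome class: discrimination/calibration skipped"
        )
        return report

    report["scores"] = {}
    for name in ("operator_cto",) + tuple(config.comparators):
        scores = _score_column(cohort, name)
        logger.info("evaluating score %s", name)
        report["scores"][name] = _evaluate_score(
            scores, failures, config.confidence_level, config.hl_groups
        )
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# Cohort evaluation report", ""]
    meta = report["meta"]
    lines.append(f"- package version: {meta['package_version']}")
    lines.append(f"- n cases: {meta['n_cases']}")
    lines.append(f"- source: {meta['source']}")
    lines.append("")
    if report.get("summary"):
        s = report["summary"]
        lines += [
            "## Overall outcomes",
            "",
            "| endpoint | successes | % |",
            "|---|---|---|",
            f"| technical | {s['technical_successes']}/{s['n']} | {s['technical_success_pct']} |",
            f"| procedural | {s['procedural_successes']}/{s['n']} | {s['procedural_success_pct']} |",
            "",
        ]
    if report.get("tier_table"):
        lines += [
            "## Success by operator-CTO difficulty tier",
            "",
            "| tier | n | technical success | % |",
            "|---|---|---|---|",
        ]
        for row in report["tier_table"]:
            pct = "—" if row["technical_pct"] is None else row["technical_pct"]
            lines.append(
                f"| {row['tier']} | {row['n']} | {row['technical_successes']} | {pct} |"
            )
        lines.append("")
    if report.get("scores"):
        lines += [
            "## Calibration and discrimination (positive class: technical failure)",
            "",
            "| score | AUC | CI | HL statistic | HL p |",
            "|---|---|---|---|---|",
        ]
        for name, res in report["scores"].items():
            hl = res["hosmer_lemeshow"]
            if "skipped" in hl:
                stat, p = "skipped", "—"
            else:
                stat, p = hl["statistic"], hl["p_value"]
            lines.append(
                f"| {name} | {res['auc']} | {res['auc_ci']} | {stat} | {p} |"
            )
        lines.append("")
    if report["skip_reasons"]:
        lines += ["## Skipped stages", ""]
        lines += [f"- {r}" for r in report["skip_reasons"]]
        lines.append("")
    return "\n".join(lines)


def emit_report(report: dict, path: str | Path, format: str = "json") -> Path:
    """Write the report as deterministic JSON or as Markdown tables."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    elif format == "markdown":
        path.write_text(_markdown_report(report))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
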