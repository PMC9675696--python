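"""Cohort-level comparison of staining strategies against the gold standard.

For every tumour the full nine-stain profile defines the gold-standard
diagnosis.  Each tiered algorithm is replayed against the same tumour
(via its stain oracle) and judged on:

* concordance — fraction of tumours whose tier-limited diagnosis equals
  the gold-standard diagnosis, at type level by default (a lineage-level
  mode compares only the defining transcription factor, keeping the
  distinction between the no-distinct-lineage diagnoses);
* workload — total and average number of immunostains;
* cost — average cost per tumour, derived as the 1-decimal rounded
  average stain count times the unit cost, reported to the nearest whole
  currency unit.

Averages are rounded half-up to 1 decimal and percentages to 1 decimal;
costs are unit-cost multiples with no intermediate rounding beyond the
average stain count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from ._util import round_half_up
from .ihc_core import IHCValidationError, TumourRecord
from .staining_strategies import (
    DEFAULT_UNIT_COST,
    GOLD_STANDARD,
    AlgorithmRules,
    StainOracle,
    diagnose_with_strategy,
)
from .who2022_rules import Classification, PIT1SubTable, TumourType, classify

__all__ = [
    "StrategySummary",
    "EvaluationReport",
    "evaluate",
    "render_report",
    "oracle_equivalence_audit",
]


@dataclass(frozen=True)
class StrategySummary:
    """One strategy's row of the evaluation report."""

    strategy: str
    n_concordant: int
    concordance_pct: float
    total_stains: int
    avg_stains: float  # half-up, 1 decimal
    avg_cost: float  # avg_stains x unit cost, nearest whole unit


@dataclass(frozen=True)
class EvaluationReport:
    """Concordance and cost of each strategy on one cohort."""

    n_tumours: int
    unit_cost: float
    concordance_level: str
    per_strategy: dict[str, StrategySummary]
    discordant_ids: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strategy": s.strategy,
                "n_concordant": s.n_concordant,
                "concordance_pct": s.concordance_pct,
                "total_stains": s.total_stains,
                "avg_stains": s.avg_stains,
                "avg_cost": s.avg_cost,
            }
            for s in self.per_strategy.values()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "strategy",
                "n_concordant",
                "concordance_pct",
                "total_stains",
                "avg_stains",
                "avg_cost",
            ],
        )


def _same_diagnosis(
    a: Classification, b: Classification, level: Literal["type", "lineage"]
) -> bool:
    if level == "type":
        return a.type is b.type
    # lineage level: same defining transcription factor; diagnoses without
    # a lineage are still compared by type (null cell vs plurihormonal stay
    # distinct)
    if a.type.lineage is None or b.type.lineage is None:
        return a.type is b.type
    return a.type.lineage is b.type.lineage


def evaluate(
    records: Sequence[TumourRecord],
    algorithms: Sequence[int] = (1, 2, 3),
    unit_cost: float = DEFAULT_UNIT_COST,
    level: Literal["type", "lineage"] = "type",
    rules: AlgorithmRules | None = None,
    classifier_rules: PIT1SubTable | None = None,
) -> EvaluationReport:
    """Evaluate tiered algorithms against the gold standard on a cohort.

    Every record must carry a fully performed profile (the oracle needs
    all nine true results).  The gold standard itself is always reported;
    its concordance is 100% by construction.
    """
    if not records:
        raise IHCValidationError("cannot evaluate an empty cohort")
    n = len(records)

    gold: list[Classification] = [
        classify(r.profile, r.morphology, classifier_rules) for r in records
    ]
    oracles = [StainOracle.from_record(r) for r in records]

    per_strategy: dict[str, StrategySummary] = {}
    discordant_ids: dict[str, list[str]] = {}
    strategies: list[int | str] = [GOLD_STANDARD, *algorithms]
    for strategy in strategies:
        total = 0
        concordant = 0
        discordant: list[str] = []
        for record, oracle, gold_cls in zip(records, oracles, gold):
            plan, cls = diagnose_with_strategy(
                oracle,
                strategy,
                record.morphology,
                unit_cost,
                rules,
                classifier_rules,
            )
            total += plan.n_stains
            if _same_diagnosis(cls, gold_cls, level):
                concordant += 1
            else:
                discordant.append(record.id)
        name = GOLD_STANDARD if strategy == GOLD_STANDARD else f"algorithm_{strategy}"
        avg = round_half_up(total / n, 1)
        per_strategy[name] = StrategySummary(
            strategy=name,
            n_concordant=concordant,
            concordance_pct=round_half_up(100.0 * concordant / n, 1),
            total_stains=total,
            avg_stains=avg,
            avg_cost=round_half_up(avg * unit_cost, 0),
        )
        discordant_ids[name] = discordant
    return EvaluationReport(
        n_tumours=n,
        unit_cost=unit_cost,
        concordance_level=level,
        per_strategy=per_strategy,
        discordant_ids=discordant_ids,
    )


def oracle_equivalence_audit(
    algorithms: Sequence[int] = (1, 2, 3),
    level: Literal["type", "lineage"] = "type",
    rules: AlgorithmRules | None = None,
    classifier_rules: PIT1SubTable | None = None,
) -> dict[int, list["IHCProfile"]]:
    """Exhaustively compare each tiered algorithm with the gold standard
    over all 2^9 fully performed positive/negative profiles (no morphology
    flags).

    Returns, per algorithm, the profiles on which the tier-limited
    diagnosis differs from the full-panel diagnosis.  The only information
    a tiered algorithm discards is hormone results outside the confirmed
    lineage of a single-transcription-factor tumour, so any discordant
    profile must have exactly one positive transcription factor and a
    positive out-of-lineage hormone; because such hormones raise warnings
    but never change the type, the discordant set is empty under the
    packaged decision table.
    """
    from itertools import product

    from .ihc_core import CANONICAL_STAIN_ORDER, IHCProfile

    discordant: dict[int, list[IHCProfile]] = {a: [] for a in algorithms}
    for bits in product((False, True), repeat=9):
        profile = IHCProfile.from_calls(
            positive={m for m, b in zip(CANONICAL_STAIN_ORDER, bits) if b}
        )
        gold = classify(profile, rules=classifier_rules)
        oracle = StainOracle.from_profile(profile)
        for a in algorithms:
            _, cls = diagnose_with_strategy(
                oracle, a, rules=rules, classifier_rules=classifier_rules
            )
            if not _same_diagnosis(cls, gold, level):
                discordant[a].append(profile)
    return discordant


def render_report(report: EvaluationReport, csv_path: str | None = None) -> str:
    """Render the report as a text table, optionally writing a CSV twin.

    A footer records the cohort size, the unit cost, and the derivation of
    the average cost from the rounded average stain count.
    """
    frame = report.to_frame()
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    lines = [frame.to_string(index=False)]
    lines.append("")
    lines.append(
        f"n_tumours={report.n_tumours}; unit_cost={report.unit_cost:g} AUD/stain; "
        f"concordance level: {report.concordance_level}"
    )
    lines.append(
        "avg_cost = avg_stains (half-up, 1 decimal) x unit_cost, "
        "rounded to the nearest whole unit"
    )
    gold = report.per_strategy.get(GOLD_STANDARD)
    if gold is not None:
        for name, s in report.per_strategy.items():
            if name != GOLD_STANDARD and gold.avg_cost > 0:
                reduction = 100.0 * (1.0 - s.avg_cost / gold.avg_cost)
                lines.append(
                    f"{name}: cost reduction vs gold standard "
                    f"{round_half_up(reduction, 1):g}%"
                )
    return "\n".join(lines)
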