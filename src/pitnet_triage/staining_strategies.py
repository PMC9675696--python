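"""Sequential stain-ordering strategies (gold standard and Algorithms 1-3).

The gold standard orders all nine immunostains up front.  The tiered
algorithms stain the three transcription factors first and choose the
second round from the tier-1 result:

* zero or two-plus positive transcription factors: complete hormone panel
  (all algorithms — these tumours have no distinct lineage and need the
  full work-up);
* exactly one positive transcription factor: Algorithm 1 orders the
  lineage-confirmatory hormones (LH/FSH after SF1, ACTH after TPIT, all
  six after PIT1); Algorithm 2 orders nothing after SF1 or TPIT and the
  full panel after PIT1; Algorithm 3 orders nothing after SF1 or TPIT and
  only the PIT1-lineage hormones (GH, PRL, TSH) after PIT1.

Strategies run against a :class:`StainOracle` — a stand-in for the
physical tumour block that answers what any stain *would* show — and
produce a :class:`StainPlan`: the ordered stains, the tier-limited
observed profile (everything else not performed) and the cost at a fixed
price per immunostain.  The two tiers are modelled as laboratory batches:
all tier-1 results are available before tier 2 is chosen, with no
stain-by-stain adaptivity inside a tier.

The single-positive branch rules are data (``data/algorithms.yaml``) so
that variant reflex policies can be evaluated without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from typing import Callable, Literal, Mapping

import yaml

from .ihc_core import (
    CANONICAL_STAIN_ORDER,
    HORMONES,
    TRANSCRIPTION_FACTORS,
    IHCProfile,
    IHCValidationError,
    Marker,
    MorphologyFlags,
    StainResult,
    StainStatus,
    TumourRecord,
)
from .who2022_rules import Classification, PIT1SubTable, classify

__all__ = [
    "DEFAULT_UNIT_COST",
    "GOLD_STANDARD",
    "StainOracle",
    "StainPlan",
    "AlgorithmRules",
    "load_algorithm_rules",
    "run_gold_standard",
    "run_tiered",
    "diagnose_with_strategy",
]

#: Price per immunostain per slide, in AUD.
DEFAULT_UNIT_COST: float = 50.0

GOLD_STANDARD: str = "gold_standard"

#: Tier-2 orders keyed by algorithm id, then by the single positive
#: transcription factor.
AlgorithmRules = dict[int, dict[Marker, tuple[Marker, ...]]]


@dataclass(frozen=True)
class StainOracle:
    """Total positive/negative answer for every marker of one tumour.

    Stands for the physical tumour block: a strategy may query any stain
    and always gets the same answer.  Built from a fully performed profile.
    """

    truth: Mapping[Marker, StainStatus]

    def __post_init__(self) -> None:
        missing = [m.value for m in Marker if m not in self.truth]
        if missing:
            raise IHCValidationError(
                "oracle must cover all nine markers; missing " + ", ".join(missing)
            )
        for m, s in self.truth.items():
            if s is StainStatus.NOT_PERFORMED:
                raise IHCValidationError(
                    f"oracle answers must be positive or negative ({m.value})"
                )

    @classmethod
    def from_profile(cls, profile: IHCProfile) -> "StainOracle":
        unperformed = [r.marker.value for r in profile.results if not r.performed]
        if unperformed:
            raise IHCValidationError(
                "cannot build an oracle from a partial profile; not performed: "
                + ", ".join(unperformed)
            )
        return cls({r.marker: r.status for r in profile.results})

    @classmethod
    def from_record(cls, record: TumourRecord) -> "StainOracle":
        return cls.from_profile(record.profile)

    def query(self, marker: Marker) -> StainStatus:
        return self.truth[marker]

    @property
    def lookup(self) -> Callable[[Marker], StainStatus]:
        return self.query


@dataclass(frozen=True)
class StainPlan:
    """The stains a strategy ordered for one tumour, with the observed
    (tier-limited) profile and the total cost."""

    strategy_name: str
    ordered_stains: tuple[Marker, ...]
    observed: IHCProfile
    unit_cost: float = DEFAULT_UNIT_COST

    def __post_init__(self) -> None:
        if len(set(self.ordered_stains)) != len(self.ordered_stains):
            raise IHCValidationError("a marker appears twice in ordered_stains")
        ordered = set(self.ordered_stains)
        for r in self.observed.results:
            if r.performed != (r.marker in ordered):
                raise IHCValidationError(
                    f"observed profile inconsistent with ordered stains at {r.marker.value}"
                )

    @property
    def n_stains(self) -> int:
        return len(self.ordered_stains)

    @property
    def cost(self) -> float:
        return self.n_stains * self.unit_cost


def _canonical(markers: set[Marker]) -> tuple[Marker, ...]:
    return tuple(m for m in CANONICAL_STAIN_ORDER if m in markers)


def _observe(oracle: StainOracle, stains: tuple[Marker, ...]) -> IHCProfile:
    return IHCProfile.from_results(
        StainResult(m, oracle.query(m)) for m in stains
    )


def run_gold_standard(
    oracle: StainOracle, unit_cost: float = DEFAULT_UNIT_COST
) -> StainPlan:
    """Order the full nine-stain panel (current routine practice)."""
    stains = CANONICAL_STAIN_ORDER
    return StainPlan(GOLD_STANDARD, stains, _observe(oracle, stains), unit_cost)


def load_algorithm_rules(path: str | None = None) -> AlgorithmRules:
    """Load the tier-2 branch rules, packaged or from a replacement file."""
    if path is None:
        text = files("pitnet_triage.data").joinpath("algorithms.yaml").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    rules: AlgorithmRules = {}
    for key, branches in raw.items():
        algo = int(str(key).removeprefix("algorithm_"))
        rules[algo] = {}
        for tf_name, hormones in branches.items():
            tf = Marker(tf_name)
            if tf not in TRANSCRIPTION_FACTORS:
                raise IHCValidationError(f"branch key {tf_name!r} is not a transcription factor")
            ordered = _canonical({Marker(h) for h in hormones})
            for h in ordered:
                if h in TRANSCRIPTION_FACTORS:
                    raise IHCValidationError(f"tier-2 stain {h.value} is not a hormone")
            rules[algo][tf] = ordered
        missing = [tf.value for tf in TRANSCRIPTION_FACTORS if tf not in rules[algo]]
        if missing:
            raise IHCValidationError(
                f"algorithm {algo} rules missing branch(es): {', '.join(missing)}"
            )
    return rules


_default_rules: AlgorithmRules | None = None


def _algorithm_rules(rules: AlgorithmRules | None) -> AlgorithmRules:
    global _default_rules
    if rules is not None:
        return rules
    if _default_rules is None:
        _default_rules = load_algorithm_rules()
    return _default_rules


def run_tiered(
    oracle: StainOracle,
    algorithm: int,
    unit_cost: float = DEFAULT_UNIT_COST,
    rules: AlgorithmRules | None = None,
) -> StainPlan:
    """Run one tiered algorithm against a tumour block.

    Tier 1 stains SF1, TPIT, PIT1.  With zero or multiple positives the
    complete hormone panel follows; with exactly one positive the
    algorithm's branch rule decides the second round.
    """
    table = _algorithm_rules(rules)
    if algorithm not in table:
        raise IHCValidationError(
            f"unknown algorithm {algorithm!r}; expected one of {sorted(table)}"
        )
    tier1 = TRANSCRIPTION_FACTORS
    positive = [tf for tf in tier1 if oracle.query(tf) is StainStatus.POSITIVE]
    if len(positive) == 1:
        tier2 = table[algorithm][positive[0]]
    else:
        tier2 = HORMONES  # no distinct lineage: full hormonal work-up
    stains = tier1 + tier2
    return StainPlan(f"algorithm_{algorithm}", stains, _observe(oracle, stains), unit_cost)


def diagnose_with_strategy(
    oracle: StainOracle,
    strategy: int | Literal["gold_standard"],
    morphology: MorphologyFlags = MorphologyFlags(),
    unit_cost: float = DEFAULT_UNIT_COST,
    rules: AlgorithmRules | None = None,
    classifier_rules: PIT1SubTable | None = None,
) -> tuple[StainPlan, Classification]:
    """Execute a strategy and type the tumour from what it observed.

    The classification sees only the tier-limited profile: stains the
    strategy never ordered stay not-performed, exactly as the reporting
    pathologist would experience them.
    """
    if strategy == GOLD_STANDARD:
        plan = run_gold_standard(oracle, unit_cost)
    else:
        plan = run_tiered(oracle, int(strategy), unit_cost, rules)
    return plan, classify(plan.observed, morphology, classifier_rules)
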