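"""Seeded generator of synthetic cohorts with the study's statistical structure.

Each record is drawn independently: a tumour type from the observed type
frequencies (45/113 gonadotroph, 21/113 lactotroph, ...), a functioning
status from that type's observed functioning fraction, then two optional
noise mechanisms:

* ``hormone_silent_rate`` — the lineage-defining hormone(s) of a
  distinct-lineage tumour are switched to immunonegative while the
  reference type is kept, emulating hormonally silent ("whispering")
  tumours such as TPIT+/ACTH- corticotrophs.  It never creates
  out-of-lineage positives, so tiered/gold concordance is unaffected.
* ``aberrant_tf_rate`` — one extra transcription factor is switched to
  positive on a distinct-lineage tumour, which by definition makes the
  reference type plurihormonal (no distinct lineage).  These cases route
  to the multi-TF full-panel branch of every tiered algorithm.

Draw order per record is fixed (type, functioning, silencing, aberrance,
aberrant-TF choice) and every record consumes the same number of draws
from a single stream, so growing ``n`` extends a cohort without
reshuffling earlier records, and a fixed seed reproduces a cohort exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .cohort_fixtures import (
    CANONICAL_FLAGS,
    CANONICAL_POSITIVE_MARKERS,
    FUNCTIONING_LABELS,
    REFERENCE_COHORT_SPEC,
)
from .ihc_core import (
    TRANSCRIPTION_FACTORS,
    ClinicalPresentation,
    IHCProfile,
    IHCValidationError,
    Marker,
    MorphologyFlags,
    TumourRecord,
)
from .who2022_rules import TYPE_REPORT_ORDER, TumourType

__all__ = ["GeneratorConfig", "default_type_probs", "default_functioning_probs", "generate"]


def default_type_probs() -> dict[TumourType, float]:
    """Observed cohort type frequencies (counts over 113)."""
    spec = REFERENCE_COHORT_SPEC
    return {t: spec.type_counts[t] / spec.n for t in TYPE_REPORT_ORDER}


def default_functioning_probs() -> dict[TumourType, float]:
    """Observed per-type clinically-functioning fractions (e.g. 10/11 for
    somatotroph, 0/45 for gonadotroph)."""
    spec = REFERENCE_COHORT_SPEC
    return {
        t: (spec.functioning_counts[t] / spec.type_counts[t])
        if spec.type_counts[t]
        else 0.0
        for t in TYPE_REPORT_ORDER
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: type and functioning
    probabilities from the observed cohort composition, and both noise
    rates at zero.
    """

    n: int
    seed: int
    type_probs: dict[TumourType, float] = field(default_factory=default_type_probs)
    functioning_probs: dict[TumourType, float] = field(
        default_factory=default_functioning_probs
    )
    aberrant_tf_rate: float = 0.0
    hormone_silent_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise IHCValidationError(f"n must be non-negative, got {self.n}")
        total = math.fsum(self.type_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise IHCValidationError(
                f"type_probs must sum to 1 (got {total!r})"
            )
        if any(p < 0 for p in self.type_probs.values()):
            raise IHCValidationError("type probabilities must be non-negative")
        for name in ("aberrant_tf_rate", "hormone_silent_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise IHCValidationError(f"{name} must lie in [0, 1], got {rate!r}")
        for t, p in self.functioning_probs.items():
            if not 0.0 <= p <= 1.0:
                raise IHCValidationError(
                    f"functioning probability for {t.value} must lie in [0, 1]"
                )


def _type_order(config: GeneratorConfig) -> list[TumourType]:
    # fixed sampling order: report order first, then any extra keys by name
    ordered = [t for t in TYPE_REPORT_ORDER if t in config.type_probs]
    extras = sorted(
        (t for t in config.type_probs if t not in set(ordered)), key=lambda t: t.value
    )
    return ordered + extras


def generate(config: GeneratorConfig) -> list[TumourRecord]:
    """Generate a synthetic cohort; identical config and seed give an
    identical cohort."""
    rng = np.random.default_rng(config.seed)
    order = _type_order(config)
    cumulative = np.cumsum([config.type_probs[t] for t in order])
    records: list[TumourRecord] = []
    for i in range(config.n):
        u_type, u_func, u_silent, u_aberrant, u_choice = rng.random(5)
        idx = int(np.searchsorted(cumulative, u_type, side="right"))
        idx = min(idx, len(order) - 1)  # guard the u_type == 1.0 edge
        tumour_type = order[idx]

        positives = set(CANONICAL_POSITIVE_MARKERS[tumour_type])
        morphology = CANONICAL_FLAGS.get(tumour_type, MorphologyFlags())
        reference = tumour_type

        lineage = tumour_type.lineage
        if lineage is not None and u_silent < config.hormone_silent_rate:
            positives = {m for m in positives if m in TRANSCRIPTION_FACTORS}
        if lineage is not None and u_aberrant < config.aberrant_tf_rate:
            others = [tf for tf in TRANSCRIPTION_FACTORS if tf is not lineage]
            positives.add(others[int(u_choice * len(others)) % len(others)])
            reference = TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE
            morphology = MorphologyFlags()

        functioning = u_func < config.functioning_probs.get(tumour_type, 0.0)
        clinical = (
            FUNCTIONING_LABELS[tumour_type]
            if functioning
            else ClinicalPresentation.NON_FUNCTIONING
        )
        records.append(
            TumourRecord(
                id=f"SYN-{i + 1:05d}",
                profile=IHCProfile.from_calls(positive=positives),
                clinical=clinical,
                morphology=morphology,
                reference_type=reference,
            )
        )
    return records
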