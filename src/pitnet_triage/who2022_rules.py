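"""WHO 2022 typing of pituitary neuroendocrine tumours from IHC.

The classifier is a deterministic decision table.  The top tier branches on
the number of positive transcription factors:

* none positive, all hormones performed and negative -> null cell tumour
  (a diagnosis of exclusion: it is never called with unperformed hormones);
* none positive but some hormone positive, or two or more transcription
  factors positive -> plurihormonal tumour with no distinct cell lineage;
* exactly one positive -> the tumour belongs to that lineage: SF1 gives
  gonadotroph and TPIT gives corticotroph regardless of hormone results
  (out-of-lineage hormone positivity is surfaced as a warning, not a type
  change), while PIT1 dispatches to a hormone sub-table on GH/PRL/TSH,
  refined by optional morphology flags.

The PIT1 sub-table is not prescribed operationally by the classification
itself; it is this package's documented convention and therefore ships as
an editable, versioned data file (``data/pit1_subtable.tsv``) rather than
as code.  Every classification carries the ordered list of rule
identifiers that fired, so a diagnosis can be audited row by row.

Clinical presentation is never an input to :func:`classify`: the typing
branches on IHC alone.  :func:`classify_cohort` uses the clinical label
only for the functioning column of the frequency table and for
plausibility warnings (e.g. acromegaly with a GH-negative tumour).
"""

from __future__ import annotations

import csv
import dataclasses
import enum
from dataclasses import dataclass
from importlib.resources import files
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up
from .ihc_core import (
    HORMONES,
    TRANSCRIPTION_FACTORS,
    ClinicalPresentation,
    IHCProfile,
    IHCValidationError,
    Marker,
    MorphologyFlags,
    StainStatus,
    TumourRecord,
)

__all__ = [
    "TumourType",
    "Classification",
    "MissingStainError",
    "PIT1SubTable",
    "classify",
    "classify_cohort",
]


class MissingStainError(IHCValidationError):
    """A stain required by the decision table was not performed."""


class TumourType(str, enum.Enum):
    """The twelve WHO 2022 tumour types plus an ``unclassifiable`` sentinel."""

    SOMATOTROPH = "somatotroph"
    LACTOTROPH = "lactotroph"
    MAMMOSOMATOTROPH = "mammosomatotroph"
    THYROTROPH = "thyrotroph"
    MATURE_PLURIHORMONAL_PIT1 = "mature_plurihormonal_PIT1"
    IMMATURE_PIT1 = "immature_PIT1"
    ACIDOPHIL_STEM_CELL = "acidophil_stem_cell"
    MIXED_SOMATOTROPH_LACTOTROPH = "mixed_somatotroph_lactotroph"
    CORTICOTROPH = "corticotroph"
    GONADOTROPH = "gonadotroph"
    PLURIHORMONAL_NO_DISTINCT_LINEAGE = "plurihormonal_no_distinct_lineage"
    NULL_CELL = "null_cell"
    UNCLASSIFIABLE = "unclassifiable"

    @property
    def lineage(self) -> Marker | None:
        """The defining transcription factor, or None for the no-distinct-
        lineage category and the sentinel."""
        return _TYPE_LINEAGE[self]


_PIT1_TYPES = (
    TumourType.SOMATOTROPH,
    TumourType.LACTOTROPH,
    TumourType.MAMMOSOMATOTROPH,
    TumourType.THYROTROPH,
    TumourType.MATURE_PLURIHORMONAL_PIT1,
    TumourType.IMMATURE_PIT1,
    TumourType.ACIDOPHIL_STEM_CELL,
    TumourType.MIXED_SOMATOTROPH_LACTOTROPH,
)

_TYPE_LINEAGE: dict[TumourType, Marker | None] = {
    **{t: Marker.PIT1 for t in _PIT1_TYPES},
    TumourType.CORTICOTROPH: Marker.TPIT,
    TumourType.GONADOTROPH: Marker.SF1,
    TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE: None,
    TumourType.NULL_CELL: None,
    TumourType.UNCLASSIFIABLE: None,
}

#: Reporting order for frequency tables: PIT1 lineage, TPIT, SF1, then the
#: no-distinct-lineage category.
TYPE_REPORT_ORDER: tuple[TumourType, ...] = _PIT1_TYPES + (
    TumourType.CORTICOTROPH,
    TumourType.GONADOTROPH,
    TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE,
    TumourType.NULL_CELL,
)


@dataclass(frozen=True)
class Classification:
    """Outcome of the decision table for one tumour."""

    type: TumourType
    tf_pattern: frozenset[Marker]
    rationale: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    def with_warnings(self, extra: Iterable[str]) -> "Classification":
        extra = tuple(extra)
        if not extra:
            return self
        return dataclasses.replace(self, warnings=self.warnings + extra)


class PIT1SubTable:
    """The PIT1-lineage hormone/morphology decision sub-table.

    Rows are matched in file order, first match wins.  Hormone cells are
    ``+``, ``-`` or ``*``; flag cells are ``true``, ``false``, ``absent``
    (the flag was not assessed) or ``*``.
    """

    _FLAG_COLS = ("acidophil", "immature", "monomorphous")
    _HORMONE_COLS = ("GH", "PRL", "TSH")

    def __init__(self, rows: Sequence[dict[str, str]]):
        if not rows:
            raise IHCValidationError("empty PIT1 sub-table")
        self.rows = list(rows)
        for row in self.rows:
            for col in ("rule_id", "type", *self._FLAG_COLS, *self._HORMONE_COLS):
                if col not in row:
                    raise IHCValidationError(
                        f"PIT1 sub-table row missing column {col!r}: {row}"
                    )
            TumourType(row["type"])  # validate

    @classmethod
    def load(cls, path: str | None = None) -> "PIT1SubTable":
        """Load the packaged sub-table, or a replacement from ``path``."""
        if path is None:
            text = files("pitnet_triage.data").joinpath("pit1_subtable.tsv").read_text("utf-8")
        else:
            with open(path, encoding="utf-8") as fh:
                text = fh.read()
        reader = csv.DictReader(text.splitlines(), delimiter="\t")
        rows = []
        for raw in reader:
            row = {k: (v or "").strip() for k, v in raw.items() if k is not None}
            row.setdefault("warning", "")
            rows.append(row)
        return cls(rows)

    @staticmethod
    def _flag_matches(cell: str, value: bool | None) -> bool:
        if cell == "*":
            return True
        if cell == "absent":
            return value is None
        return value is (cell == "true")

    @staticmethod
    def _hormone_matches(cell: str, status: StainStatus) -> bool:
        if cell == "*":
            return True
        return status is (StainStatus.POSITIVE if cell == "+" else StainStatus.NEGATIVE)

    def match(
        self, profile: IHCProfile, morphology: MorphologyFlags
    ) -> tuple[str, TumourType, str | None]:
        flags = {
            "acidophil": morphology.acidophil_stem_cell_features,
            "immature": morphology.immature,
            "monomorphous": morphology.monomorphous,
        }
        for row in self.rows:
            if all(self._flag_matches(row[c], flags[c]) for c in self._FLAG_COLS):
                if all(
                    self._hormone_matches(row[c], profile.status(Marker(c)))
                    for c in self._HORMONE_COLS
                ):
                    warning = row.get("warning") or None
                    return row["rule_id"], TumourType(row["type"]), warning
        raise IHCValidationError(
            "PIT1 sub-table is not exhaustive for profile "
            f"{[profile.status(Marker(c)).value for c in self._HORMONE_COLS]}"
        )


_default_subtable: PIT1SubTable | None = None


def _subtable(rules: PIT1SubTable | None) -> PIT1SubTable:
    global _default_subtable
    if rules is not None:
        return rules
    if _default_subtable is None:
        _default_subtable = PIT1SubTable.load()
    return _default_subtable


def _out_of_lineage_warnings(profile: IHCProfile, tf: Marker) -> list[str]:
    out = []
    for h in HORMONES:
        if h.lineage is not tf and profile.status(h) is StainStatus.POSITIVE:
            out.append(
                f"out-of-lineage hormone {h.value} positive in a {tf.value}-only tumour"
            )
    return out


def classify(
    profile: IHCProfile,
    morphology: MorphologyFlags = MorphologyFlags(),
    rules: PIT1SubTable | None = None,
) -> Classification:
    """Type a tumour from its IHC profile and optional morphology flags.

    All three transcription factors must have been performed; hormone
    stains may be unperformed wherever the fired rule does not need them.
    Returns ``unclassifiable`` (never raises) when a *hormone* stain that
    the decision table requires is missing.

    Raises
    ------
    MissingStainError
        If any transcription-factor stain was not performed.
    """
    missing_tfs = [
        tf.value for tf in TRANSCRIPTION_FACTORS
        if profile.status(tf) is StainStatus.NOT_PERFORMED
    ]
    if missing_tfs:
        raise MissingStainError(
            "transcription factor stain(s) not performed: " + ", ".join(missing_tfs)
        )

    pos_tfs = frozenset(profile.positive_transcription_factors())
    t = len(pos_tfs)
    rationale = [f"R1-TF-COUNT[{t}]"]

    if t == 0:
        hormone_status = {h: profile.status(h) for h in HORMONES}
        positives = [h for h, s in hormone_status.items() if s is StainStatus.POSITIVE]
        if positives:
            rationale.append("R3-TFNEG-HORMPOS")
            return Classification(
                TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE, pos_tfs, tuple(rationale)
            )
        unperformed = [h for h, s in hormone_status.items() if s is StainStatus.NOT_PERFORMED]
        if unperformed:
            rationale.append("R-UNCLASSIFIABLE")
            return Classification(
                TumourType.UNCLASSIFIABLE,
                pos_tfs,
                tuple(rationale),
                (
                    "null cell is a diagnosis of exclusion: hormone stain(s) "
                    + ", ".join(h.value for h in unperformed)
                    + " not performed",
                ),
            )
        rationale.append("R2-NULL-CELL")
        return Classification(TumourType.NULL_CELL, pos_tfs, tuple(rationale))

    if t >= 2:
        rationale.append("R4-MULTI-TF")
        return Classification(
            TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE, pos_tfs, tuple(rationale)
        )

    (tf,) = pos_tfs
    if tf is Marker.SF1:
        rationale.append("R5-SF1-GONADOTROPH")
        return Classification(
            TumourType.GONADOTROPH,
            pos_tfs,
            tuple(rationale),
            tuple(_out_of_lineage_warnings(profile, tf)),
        )
    if tf is Marker.TPIT:
        rationale.append("R6-TPIT-CORTICOTROPH")
        warnings = _out_of_lineage_warnings(profile, tf)
        if profile.status(Marker.ACTH) is StainStatus.NEGATIVE:
            warnings.append(
                "hormonally silent ('whispering') corticotroph: TPIT+/ACTH-"
            )
        return Classification(
            TumourType.CORTICOTROPH, pos_tfs, tuple(rationale), tuple(warnings)
        )

    # PIT1 lineage: dispatch on the GH/PRL/TSH sub-table
    rationale.append("R7-PIT1-SUBTABLE")
    required = (Marker.GH, Marker.PRL, Marker.TSH)
    missing = [h for h in required if profile.status(h) is StainStatus.NOT_PERFORMED]
    if missing:
        rationale.append("R-UNCLASSIFIABLE")
        return Classification(
            TumourType.UNCLASSIFIABLE,
            pos_tfs,
            tuple(rationale),
            (
                "PIT1-lineage hormone stain(s) "
                + ", ".join(h.value for h in missing)
                + " not performed",
            ),
        )
    rule_id, tumour_type, row_warning = _subtable(rules).match(profile, morphology)
    rationale.append(rule_id)
    warnings = _out_of_lineage_warnings(profile, tf)
    if row_warning:
        warnings.append(row_warning)
    return Classification(tumour_type, pos_tfs, tuple(rationale), tuple(warnings))


_EXPECTED_HORMONE = {
    ClinicalPresentation.ACROMEGALY: Marker.GH,
    ClinicalPresentation.PROLACTINOMA: Marker.PRL,
    ClinicalPresentation.CUSHING: Marker.ACTH,
    ClinicalPresentation.THYROTOXICOSIS: Marker.TSH,
}


def classify_cohort(
    records: Sequence[TumourRecord],
    rules: PIT1SubTable | None = None,
) -> tuple[list[Classification], pd.DataFrame]:
    """Classify every record and tabulate type frequencies.

    Returns the per-record classifications (in input order, each augmented
    with clinical-plausibility warnings) and a frequency table with one row
    per WHO 2022 type: count, percent of cohort (half-up, 1 decimal) and
    number clinically functioning.  Per-record errors are re-raised tagged
    with the record id.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise IHCValidationError("duplicate record ids in cohort")

    classifications: list[Classification] = []
    for record in records:
        try:
            c = classify(record.profile, record.morphology, rules)
        except IHCValidationError as exc:
            raise type(exc)(f"record {record.id!r}: {exc}") from exc
        expected = _EXPECTED_HORMONE.get(record.clinical)
        if (
            expected is not None
            and record.profile.status(expected) is StainStatus.NEGATIVE
        ):
            c = c.with_warnings(
                [
                    f"clinical presentation {record.clinical.value} but "
                    f"{expected.value} immunonegative"
                ]
            )
        classifications.append(c)

    if not records:
        return [], pd.DataFrame(
            columns=["type", "n", "percent", "n_functioning"]
        ).set_index("type")

    n = len(records)
    order = list(TYPE_REPORT_ORDER)
    if any(c.type is TumourType.UNCLASSIFIABLE for c in classifications):
        order.append(TumourType.UNCLASSIFIABLE)
    rows = []
    for t in order:
        members = [
            rec for rec, c in zip(records, classifications) if c.type is t
        ]
        rows.append(
            {
                "type": t.value,
                "n": len(members),
                "percent": round_half_up(100.0 * len(members) / n, 1),
                "n_functioning": sum(1 for rec in members if rec.clinical.functioning),
            }
        )
    table = pd.DataFrame(rows).set_index("type")
    return classifications, table
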