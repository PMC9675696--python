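"""Packaged reconstruction of the 113-tumour study cohort, plus cohort I/O.

The study cohort is reconstructed from its published summary: the per-type
counts and clinically-functioning fractions, and the twelve verbatim IHC
profiles of the tumours with no distinct cell lineage (eleven
plurihormonal, one null cell).  The 101 distinct-lineage tumours, whose
individual profiles were not published, are given the simplest canonical
profile consistent with each type's definition (e.g. a gonadotroph is
SF1+/LH+/FSH+, everything else negative).  Tiered stain counts depend only
on the transcription-factor pattern, which the published lineage
assignment fixes, so this choice does not affect the concordance/cost
evaluation.

Cohort CSV layout (UTF-8, one row per tumour)::

    id, clinical, PIT1, SF1, TPIT, PRL, TSH, GH, ACTH, LH, FSH,
    monomorphous, immature, acidophil_stem_cell_features, reference_type

Marker cells take ``+``, ``-`` (hyphen or typographic minus), a number
0-100 (percent positive cells) or empty (not performed); flag cells take
``true``/``false``/empty; ``reference_type`` is a WHO 2022 type name or
empty.  Round-tripping through :func:`write_cohort`/:func:`read_cohort`
is lossless, including not-performed stains and unassessed flags.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib.resources import files

from .ihc_core import (
    ClinicalPresentation,
    IHCProfile,
    IHCValidationError,
    Marker,
    MorphologyFlags,
    TumourRecord,
    parse_profile,
    serialize_profile,
)
from .who2022_rules import TumourType

__all__ = [
    "CohortSpec",
    "REFERENCE_COHORT_SPEC",
    "CANONICAL_POSITIVE_MARKERS",
    "CANONICAL_FLAGS",
    "FUNCTIONING_LABELS",
    "canonical_record",
    "load_table3_profiles",
    "load_reference_cohort",
    "build_reference_cohort",
    "read_cohort",
    "write_cohort",
]

_MARKER_COLUMNS = ("PIT1", "SF1", "TPIT", "PRL", "TSH", "GH", "ACTH", "LH", "FSH")
_FLAG_COLUMNS = ("monomorphous", "immature", "acidophil_stem_cell_features")
_COLUMNS = ("id", "clinical") + _MARKER_COLUMNS + _FLAG_COLUMNS + ("reference_type",)


#: Simplest fully-performed profile consistent with each type's definition:
#: the defining transcription factor plus the defining hormone(s) positive,
#: everything else negative.
CANONICAL_POSITIVE_MARKERS: dict[TumourType, tuple[Marker, ...]] = {
    TumourType.SOMATOTROPH: (Marker.PIT1, Marker.GH),
    TumourType.LACTOTROPH: (Marker.PIT1, Marker.PRL),
    TumourType.MAMMOSOMATOTROPH: (Marker.PIT1, Marker.GH, Marker.PRL),
    TumourType.THYROTROPH: (Marker.PIT1, Marker.TSH),
    TumourType.MATURE_PLURIHORMONAL_PIT1: (Marker.PIT1, Marker.GH, Marker.PRL, Marker.TSH),
    TumourType.IMMATURE_PIT1: (Marker.PIT1,),
    TumourType.ACIDOPHIL_STEM_CELL: (Marker.PIT1, Marker.PRL),
    TumourType.MIXED_SOMATOTROPH_LACTOTROPH: (Marker.PIT1, Marker.GH, Marker.PRL),
    TumourType.CORTICOTROPH: (Marker.TPIT, Marker.ACTH),
    TumourType.GONADOTROPH: (Marker.SF1, Marker.LH, Marker.FSH),
    TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE: (Marker.PIT1, Marker.SF1, Marker.PRL),
    TumourType.NULL_CELL: (),
}

#: Morphology flags required to pin down the PIT1 types the hormone pattern
#: alone cannot separate.
CANONICAL_FLAGS: dict[TumourType, MorphologyFlags] = {
    TumourType.MAMMOSOMATOTROPH: MorphologyFlags(monomorphous=True),
    TumourType.MIXED_SOMATOTROPH_LACTOTROPH: MorphologyFlags(monomorphous=False),
    TumourType.IMMATURE_PIT1: MorphologyFlags(immature=True),
    TumourType.ACIDOPHIL_STEM_CELL: MorphologyFlags(acidophil_stem_cell_features=True),
}

#: Presentation assigned to a clinically functioning tumour of each type.
FUNCTIONING_LABELS: dict[TumourType, ClinicalPresentation] = {
    TumourType.SOMATOTROPH: ClinicalPresentation.ACROMEGALY,
    TumourType.LACTOTROPH: ClinicalPresentation.PROLACTINOMA,
    TumourType.MAMMOSOMATOTROPH: ClinicalPresentation.ACROMEGALY,
    TumourType.THYROTROPH: ClinicalPresentation.OTHER,
    TumourType.MATURE_PLURIHORMONAL_PIT1: ClinicalPresentation.ACROMEGALY,
    TumourType.IMMATURE_PIT1: ClinicalPresentation.OTHER,
    TumourType.ACIDOPHIL_STEM_CELL: ClinicalPresentation.PROLACTINOMA,
    TumourType.MIXED_SOMATOTROPH_LACTOTROPH: ClinicalPresentation.ACROMEGALY,
    TumourType.CORTICOTROPH: ClinicalPresentation.CUSHING,
    TumourType.GONADOTROPH: ClinicalPresentation.OTHER,
    TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE: ClinicalPresentation.ACROMEGALY,
    TumourType.NULL_CELL: ClinicalPresentation.OTHER,
}


def canonical_record(
    tumour_type: TumourType,
    record_id: str,
    functioning: bool,
) -> TumourRecord:
    """Build one canonical-profile record of the given type."""
    if tumour_type not in CANONICAL_POSITIVE_MARKERS:
        raise IHCValidationError(f"no canonical profile for {tumour_type.value}")
    profile = IHCProfile.from_calls(positive=CANONICAL_POSITIVE_MARKERS[tumour_type])
    clinical = (
        FUNCTIONING_LABELS[tumour_type]
        if functioning
        else ClinicalPresentation.NON_FUNCTIONING
    )
    return TumourRecord(
        id=record_id,
        profile=profile,
        clinical=clinical,
        morphology=CANONICAL_FLAGS.get(tumour_type, MorphologyFlags()),
        reference_type=tumour_type,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Summary-level description of a cohort: per-type totals, per-type
    functioning counts, and the explicitly published records."""

    type_counts: dict[TumourType, int]
    functioning_counts: dict[TumourType, int]
    explicit_records: tuple[TumourRecord, ...] = ()

    def __post_init__(self) -> None:
        for t, k in self.functioning_counts.items():
            if k > self.type_counts.get(t, 0):
                raise IHCValidationError(
                    f"functioning count exceeds total for {t.value}"
                )
        if any(k < 0 for k in self.type_counts.values()):
            raise IHCValidationError("negative type count")

    @property
    def n(self) -> int:
        return sum(self.type_counts.values())


def _table2_spec() -> CohortSpec:
    counts = {
        TumourType.SOMATOTROPH: 11,
        TumourType.LACTOTROPH: 21,
        TumourType.MAMMOSOMATOTROPH: 3,
        TumourType.THYROTROPH: 2,
        TumourType.MATURE_PLURIHORMONAL_PIT1: 1,
        TumourType.IMMATURE_PIT1: 2,
        TumourType.ACIDOPHIL_STEM_CELL: 0,
        TumourType.MIXED_SOMATOTROPH_LACTOTROPH: 2,
        TumourType.CORTICOTROPH: 14,
        TumourType.GONADOTROPH: 45,
        TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE: 11,
        TumourType.NULL_CELL: 1,
    }
    functioning = {
        TumourType.SOMATOTROPH: 10,
        TumourType.LACTOTROPH: 20,
        TumourType.MAMMOSOMATOTROPH: 3,
        TumourType.THYROTROPH: 1,
        TumourType.MATURE_PLURIHORMONAL_PIT1: 1,
        TumourType.IMMATURE_PIT1: 1,
        TumourType.ACIDOPHIL_STEM_CELL: 0,
        TumourType.MIXED_SOMATOTROPH_LACTOTROPH: 1,
        TumourType.CORTICOTROPH: 10,
        TumourType.GONADOTROPH: 0,
        TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE: 6,
        TumourType.NULL_CELL: 0,
    }
    return CohortSpec(counts, functioning, tuple(load_table3_profiles()))


def load_table3_profiles() -> list[TumourRecord]:
    """The twelve published no-distinct-lineage profiles, transcribed
    marker for marker (eleven plurihormonal, one null cell)."""
    text = files("pitnet_triage.data").joinpath("table3_profiles.csv").read_text("utf-8")
    return _records_from_csv_text(text, source="packaged table3_profiles.csv")


def load_reference_cohort() -> list[TumourRecord]:
    """The packaged 113-record reconstructed cohort CSV.

    Identical to :func:`build_reference_cohort`; shipped as a file so it
    can be inspected and fed to external tools directly.
    """
    text = files("pitnet_triage.data").joinpath("reference_cohort.csv").read_text("utf-8")
    return _records_from_csv_text(text, source="packaged reference_cohort.csv")


#: Per-type record-id prefixes for the reconstructed canonical records.
_ID_PREFIX = {
    TumourType.SOMATOTROPH: "SOM",
    TumourType.LACTOTROPH: "LAC",
    TumourType.MAMMOSOMATOTROPH: "MSM",
    TumourType.THYROTROPH: "THY",
    TumourType.MATURE_PLURIHORMONAL_PIT1: "MPH",
    TumourType.IMMATURE_PIT1: "IMM",
    TumourType.ACIDOPHIL_STEM_CELL: "ASC",
    TumourType.MIXED_SOMATOTROPH_LACTOTROPH: "MIX",
    TumourType.CORTICOTROPH: "COR",
    TumourType.GONADOTROPH: "GON",
}


def build_reference_cohort() -> list[TumourRecord]:
    """Reconstruct the 113-record study cohort.

    The twelve published no-distinct-lineage profiles are included
    verbatim; the 101 distinct-lineage tumours get canonical profiles,
    with clinical labels distributed to match the published functioning
    fractions (functioning cases first within each type).
    """
    spec = REFERENCE_COHORT_SPEC
    records: list[TumourRecord] = list(spec.explicit_records)
    explicit_by_type: dict[TumourType, int] = {}
    for r in records:
        explicit_by_type[r.reference_type] = explicit_by_type.get(r.reference_type, 0) + 1
    for t, prefix in _ID_PREFIX.items():
        remaining = spec.type_counts[t] - explicit_by_type.get(t, 0)
        n_functioning = spec.functioning_counts[t]
        for i in range(remaining):
            records.append(
                canonical_record(t, f"{prefix}-{i + 1:02d}", functioning=i < n_functioning)
            )
    assert len(records) == spec.n
    return records


def _parse_flag(raw: str, column: str, where: str) -> bool | None:
    text = raw.strip().lower()
    if text == "":
        return None
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise IHCValidationError(f"{where}: cannot interpret {raw!r} in column {column!r}")


def _records_from_csv_text(text: str, source: str) -> list[TumourRecord]:
    reader = csv.DictReader(io.StringIO(text))
    header = reader.fieldnames or []
    unknown = [c for c in header if c not in _COLUMNS]
    if unknown:
        raise IHCValidationError(f"{source}: unknown column(s) {', '.join(map(repr, unknown))}")
    missing = [c for c in ("id", "clinical") if c not in header]
    if missing:
        raise IHCValidationError(f"{source}: missing column(s) {', '.join(missing)}")
    records: list[TumourRecord] = []
    for lineno, row in enumerate(reader, start=2):
        where = f"{source}, row {lineno}"
        try:
            profile = parse_profile(
                {m: row[m] for m in _MARKER_COLUMNS if m in row and row[m] is not None}
            )
            clinical = ClinicalPresentation(row["clinical"].strip())
            flags = MorphologyFlags(
                monomorphous=_parse_flag(row.get("monomorphous", ""), "monomorphous", where),
                immature=_parse_flag(row.get("immature", ""), "immature", where),
                acidophil_stem_cell_features=_parse_flag(
                    row.get("acidophil_stem_cell_features", ""),
                    "acidophil_stem_cell_features",
                    where,
                ),
            )
            ref_raw = (row.get("reference_type") or "").strip()
            reference = TumourType(ref_raw) if ref_raw else None
        except IHCValidationError as exc:
            raise IHCValidationError(f"{where}: {exc}") from exc
        except ValueError as exc:
            raise IHCValidationError(f"{where}: {exc}") from exc
        records.append(
            TumourRecord(
                id=row["id"].strip(),
                profile=profile,
                clinical=clinical,
                morphology=flags,
                reference_type=reference,
            )
        )
    return records


def read_cohort(path: str) -> list[TumourRecord]:
    """Read a cohort CSV, validating columns and every cell."""
    with open(path, encoding="utf-8") as fh:
        return _records_from_csv_text(fh.read(), source=str(path))


def _flag_to_cell(value: bool | None) -> str:
    return "" if value is None else ("true" if value else "false")


def write_cohort(records: list[TumourRecord], path: str) -> None:
    """Write a cohort CSV; ``read_cohort`` of the output reproduces the
    records exactly."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_COLUMNS)
        writer.writeheader()
        for r in records:
            row: dict[str, str] = {"id": r.id, "clinical": r.clinical.value}
            row.update(serialize_profile(r.profile))
            row["monomorphous"] = _flag_to_cell(r.morphology.monomorphous)
            row["immature"] = _flag_to_cell(r.morphology.immature)
            row["acidophil_stem_cell_features"] = _flag_to_cell(
                r.morphology.acidophil_stem_cell_features
            )
            row["reference_type"] = r.reference_type.value if r.reference_type else ""
            writer.writerow(row)


#: Summary of the reconstructed study cohort (per-type totals, functioning
#: counts, and the twelve explicitly published profiles).
REFERENCE_COHORT_SPEC: CohortSpec = _table2_spec()
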