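"""Domain types for pituitary tumour immunohistochemistry (IHC).

The WHO 2022 classification types pituitary neuroendocrine tumours by cell
lineage, established with three transcription factors (SF1 — gonadotroph
lineage; TPIT — corticotroph lineage; PIT1 — somatotroph / lactotroph /
thyrotroph lineage) and six anterior pituitary hormones (PRL, TSH, GH,
ACTH, LH, FSH).  This module defines the markers, the tri-state stain
result (positive / negative / not performed), the nine-slot IHC profile,
and the percent-positivity binarization rule.

A stain that was never ordered is *not performed*, which is distinct from
negative: the tiered staining strategies deliberately leave stains
unperformed, and the classifier must never conflate the two states.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .who2022_rules import TumourType

__all__ = [
    "IHCValidationError",
    "Marker",
    "MarkerCategory",
    "StainStatus",
    "StainResult",
    "IHCProfile",
    "MorphologyFlags",
    "ClinicalPresentation",
    "TumourRecord",
    "TRANSCRIPTION_FACTORS",
    "HORMONES",
    "CANONICAL_STAIN_ORDER",
    "HORMONES_BY_LINEAGE",
    "DEFAULT_POSITIVITY_THRESHOLD",
    "binarize",
    "parse_profile",
    "serialize_profile",
]


class IHCValidationError(ValueError):
    """Raised when an IHC value, profile or cohort row is invalid."""


class MarkerCategory(str, enum.Enum):
    TRANSCRIPTION_FACTOR = "transcription_factor"
    HORMONE = "hormone"


class Marker(str, enum.Enum):
    """The nine immunostains of the full diagnostic panel."""

    SF1 = "SF1"
    TPIT = "TPIT"
    PIT1 = "PIT1"
    PRL = "PRL"
    TSH = "TSH"
    GH = "GH"
    ACTH = "ACTH"
    LH = "LH"
    FSH = "FSH"

    @property
    def category(self) -> MarkerCategory:
        if self in (Marker.SF1, Marker.TPIT, Marker.PIT1):
            return MarkerCategory.TRANSCRIPTION_FACTOR
        return MarkerCategory.HORMONE

    @property
    def lineage(self) -> "Marker":
        """The transcription factor whose lineage produces this marker.

        For a transcription factor this is the marker itself; each hormone
        maps to exactly one lineage (GH/PRL/TSH -> PIT1, ACTH -> TPIT,
        LH/FSH -> SF1).
        """
        return _HORMONE_LINEAGE.get(self, self)


_HORMONE_LINEAGE: dict[Marker, Marker] = {
    Marker.GH: Marker.PIT1,
    Marker.PRL: Marker.PIT1,
    Marker.TSH: Marker.PIT1,
    Marker.ACTH: Marker.TPIT,
    Marker.LH: Marker.SF1,
    Marker.FSH: Marker.SF1,
}

TRANSCRIPTION_FACTORS: tuple[Marker, ...] = (Marker.SF1, Marker.TPIT, Marker.PIT1)
HORMONES: tuple[Marker, ...] = (
    Marker.PRL,
    Marker.TSH,
    Marker.GH,
    Marker.ACTH,
    Marker.LH,
    Marker.FSH,
)
#: Canonical stain sequence: transcription factors first, then hormones.
CANONICAL_STAIN_ORDER: tuple[Marker, ...] = TRANSCRIPTION_FACTORS + HORMONES

HORMONES_BY_LINEAGE: dict[Marker, tuple[Marker, ...]] = {
    tf: tuple(h for h in HORMONES if h.lineage is tf) for tf in TRANSCRIPTION_FACTORS
}

#: Clinical positivity cut-off: a stain is positive if at least this percent
#: of tumour cells stain.
DEFAULT_POSITIVITY_THRESHOLD: float = 10.0


class StainStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_PERFORMED = "not_performed"


def binarize(
    percent_positive_cells: float,
    threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
) -> StainStatus:
    """Convert a percent-positive-cells reading into a positive/negative call.

    The call is positive when at least ``threshold`` percent of cells stain;
    the boundary is inclusive (10% of cells at the default threshold is
    positive).

    Parameters
    ----------
    percent_positive_cells
        Fraction of stained tumour cells, in [0, 100].
    threshold
        Positivity cut-off in percent, in (0, 100]; default 10.
    """
    if not _is_finite_number(percent_positive_cells):
        raise IHCValidationError(
            f"percent_positive_cells must be a number, got {percent_positive_cells!r}"
        )
    if not 0.0 <= float(percent_positive_cells) <= 100.0:
        raise IHCValidationError(
            f"percent_positive_cells must lie in [0, 100], got {percent_positive_cells!r}"
        )
    if not _is_finite_number(threshold) or not 0.0 < float(threshold) <= 100.0:
        raise IHCValidationError(f"threshold must lie in (0, 100], got {threshold!r}")
    if float(percent_positive_cells) >= float(threshold):
        return StainStatus.POSITIVE
    return StainStatus.NEGATIVE


def _is_finite_number(x: object) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool) and math.isfinite(x)


@dataclass(frozen=True)
class StainResult:
    """One marker's result: tri-state status plus the optional raw percentage.

    If a percentage is recorded on a performed stain, the status must agree
    with its binarization at the profile's threshold; the constructor
    enforces this at the default threshold unless another is supplied.
    """

    marker: Marker
    status: StainStatus
    percent_positive_cells: float | None = None
    threshold: float = DEFAULT_POSITIVITY_THRESHOLD

    def __post_init__(self) -> None:
        if self.percent_positive_cells is not None:
            expected = binarize(self.percent_positive_cells, self.threshold)
            if self.status is not StainStatus.NOT_PERFORMED and self.status is not expected:
                raise IHCValidationError(
                    f"{self.marker.value}: status {self.status.value} contradicts "
                    f"{self.percent_positive_cells}% at threshold {self.threshold}%"
                )

    @property
    def performed(self) -> bool:
        return self.status is not StainStatus.NOT_PERFORMED


@dataclass(frozen=True)
class IHCProfile:
    """A complete nine-slot IHC profile (one result per marker).

    All nine slots are always present; unordered stains carry status
    ``not_performed``.  The container is immutable and hashable so profiles
    can be used as dictionary keys in exhaustive truth-table audits.
    """

    results: tuple[StainResult, ...]

    def __post_init__(self) -> None:
        markers = [r.marker for r in self.results]
        if sorted(m.value for m in markers) != sorted(m.value for m in Marker):
            raise IHCValidationError(
                "profile must contain exactly one result per marker; got "
                + ", ".join(m.value for m in markers)
            )
        # normalise slot order so equality/hashing ignore input order
        by_marker = {r.marker: r for r in self.results}
        object.__setattr__(
            self, "results", tuple(by_marker[m] for m in CANONICAL_STAIN_ORDER)
        )

    @classmethod
    def from_results(cls, results: Iterable[StainResult]) -> "IHCProfile":
        given = {r.marker: r for r in results}
        full = [
            given.get(m, StainResult(m, StainStatus.NOT_PERFORMED))
            for m in CANONICAL_STAIN_ORDER
        ]
        if len(given) != sum(1 for r in full if r.marker in given):
            raise IHCValidationError("duplicate marker in results")
        return cls(tuple(full))

    @classmethod
    def from_calls(cls, positive: Iterable[Marker] = (), negative: Iterable[Marker] | None = None) -> "IHCProfile":
        """Build a profile from sets of positive (and optionally negative) markers.

        With ``negative=None`` every marker not listed positive is negative,
        i.e. a fully performed profile.
        """
        pos = set(positive)
        if negative is None:
            neg = set(Marker) - pos
        else:
            neg = set(negative)
            if pos & neg:
                raise IHCValidationError("marker listed both positive and negative")
        results = []
        for m in CANONICAL_STAIN_ORDER:
            if m in pos:
                results.append(StainResult(m, StainStatus.POSITIVE))
            elif m in neg:
                results.append(StainResult(m, StainStatus.NEGATIVE))
            else:
                results.append(StainResult(m, StainStatus.NOT_PERFORMED))
        return cls(tuple(results))

    def result(self, marker: Marker) -> StainResult:
        return self.results[CANONICAL_STAIN_ORDER.index(marker)]

    def status(self, marker: Marker) -> StainStatus:
        return self.result(marker).status

    def positive_markers(self) -> tuple[Marker, ...]:
        return tuple(r.marker for r in self.results if r.status is StainStatus.POSITIVE)

    def positive_transcription_factors(self) -> tuple[Marker, ...]:
        return tuple(m for m in self.positive_markers() if m in TRANSCRIPTION_FACTORS)

    def performed_markers(self) -> tuple[Marker, ...]:
        return tuple(r.marker for r in self.results if r.performed)

    def restrict(self, markers: Iterable[Marker]) -> "IHCProfile":
        """A copy in which every marker outside ``markers`` is not performed."""
        keep = set(markers)
        return IHCProfile(
            tuple(
                r if r.marker in keep else StainResult(r.marker, StainStatus.NOT_PERFORMED)
                for r in self.results
            )
        )


# raw-value vocabulary accepted in cohort files; the typographic minus
# (U+2212) appears in published tables and is accepted alongside the hyphen
_POSITIVE_TOKENS = {"+", "pos", "positive"}
_NEGATIVE_TOKENS = {"-", "−", "neg", "negative"}


def parse_profile(
    row: Mapping[str, object],
    threshold: float = DEFAULT_POSITIVITY_THRESHOLD,
) -> IHCProfile:
    """Parse a marker-name -> raw-value mapping into a nine-slot profile.

    Accepted raw values per marker: ``"+"`` (positive), ``"-"`` or the
    typographic minus ``"−"`` (negative), a number in [0, 100] (percent
    positive cells, binarized at ``threshold``), or empty/``None``/NaN
    (not performed).  Markers absent from the mapping are not performed.

    Raises
    ------
    IHCValidationError
        On an unknown marker name, or a value that is neither a recognised
        token nor a percentage in range (the message names the cell).
    """
    valid_names = {m.value: m for m in Marker}
    results: list[StainResult] = []
    seen: set[Marker] = set()
    for key, raw in row.items():
        name = str(key).strip()
        if name not in valid_names:
            raise IHCValidationError(f"unknown marker name {name!r}")
        marker = valid_names[name]
        if marker in seen:
            raise IHCValidationError(f"duplicate marker {name!r}")
        seen.add(marker)
        results.append(_parse_cell(marker, raw, threshold))
    for m in Marker:
        if m not in seen:
            results.append(StainResult(m, StainStatus.NOT_PERFORMED))
    return IHCProfile.from_results(results)


def _parse_cell(marker: Marker, raw: object, threshold: float) -> StainResult:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return StainResult(marker, StainStatus.NOT_PERFORMED)
    if _is_finite_number(raw):
        pct = float(raw)
        return StainResult(marker, binarize(pct, threshold), pct, threshold)
    text = str(raw).strip()
    if text == "":
        return StainResult(marker, StainStatus.NOT_PERFORMED)
    low = text.lower()
    if low in _POSITIVE_TOKENS:
        return StainResult(marker, StainStatus.POSITIVE)
    if low in _NEGATIVE_TOKENS:
        return StainResult(marker, StainStatus.NEGATIVE)
    try:
        pct = float(text)
    except ValueError:
        raise IHCValidationError(
            f"cannot interpret value {text!r} for marker {marker.value}"
        ) from None
    return StainResult(marker, binarize(pct, threshold), pct, threshold)


def serialize_profile(profile: IHCProfile) -> dict[str, str]:
    """Render a profile back to the raw CSV vocabulary.

    Percentages are preserved when recorded; otherwise positive is ``"+"``,
    negative ``"-"`` and not-performed the empty string.  ``parse_profile``
    of the output reproduces the profile (round-trip identity).
    """
    out: dict[str, str] = {}
    for r in profile.results:
        if r.status is StainStatus.NOT_PERFORMED:
            out[r.marker.value] = ""
        elif r.percent_positive_cells is not None:
            # str() of a float is its shortest exact representation
            out[r.marker.value] = str(r.percent_positive_cells)
        else:
            out[r.marker.value] = "+" if r.status is StainStatus.POSITIVE else "-"
    return out


class ClinicalPresentation(str, enum.Enum):
    """Presenting clinical syndrome; carried for reporting, never used to type."""

    NON_FUNCTIONING = "non_functioning"
    ACROMEGALY = "acromegaly"
    PROLACTINOMA = "prolactinoma"
    CUSHING = "cushing"
    THYROTOXICOSIS = "thyrotoxicosis"
    OTHER = "other"

    @property
    def functioning(self) -> bool:
        return self is not ClinicalPresentation.NON_FUNCTIONING


@dataclass(frozen=True)
class MorphologyFlags:
    """Optional histology flags that disambiguate PIT1-lineage types.

    ``None`` means the feature was not assessed.  The underlying histology
    (cell populations on H&E, Cam5.2 patterns) is outside this package's
    scope; these booleans are its interface to it.
    """

    monomorphous: bool | None = None
    immature: bool | None = None
    acidophil_stem_cell_features: bool | None = None


@dataclass(frozen=True)
class TumourRecord:
    """One tumour: IHC profile, clinical presentation, optional morphology
    flags and optional gold-standard reference type."""

    id: str
    profile: IHCProfile
    clinical: ClinicalPresentation = ClinicalPresentation.NON_FUNCTIONING
    morphology: MorphologyFlags = field(default_factory=MorphologyFlags)
    reference_type: "TumourType | None" = None
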