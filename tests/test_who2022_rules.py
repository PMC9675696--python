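"""The WHO 2022 decision table: published profiles, branch rules,
exhaustiveness and error handling."""

from itertools import product

import pytest

from pitnet_triage import (
    ClinicalPresentation,
    IHCProfile,
    IHCValidationError,
    Marker,
    MissingStainError,
    MorphologyFlags,
    TumourRecord,
    TumourType,
    classify,
    classify_cohort,
)
from pitnet_triage.ihc_core import CANONICAL_STAIN_ORDER, TRANSCRIPTION_FACTORS


def full_profile(*positive: Marker) -> IHCProfile:
    return IHCProfile.from_calls(positive=set(positive))


class TestPublishedProfiles:
    def test_twelve_no_distinct_lineage_profiles(self, table3_records):
        """The 12 published no-distinct-lineage profiles classify exactly as
        printed: 11 plurihormonal, 1 null cell."""
        types = [classify(r.profile, r.morphology).type for r in table3_records]
        assert types.count(TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE) == 11
        assert types.count(TumourType.NULL_CELL) == 1
        # the all-negative profile is the null cell one
        null_record = table3_records[types.index(TumourType.NULL_CELL)]
        assert null_record.profile.positive_markers() == ()


class TestDecisionTable:
    def test_all_negative_is_null_cell(self):
        c = classify(full_profile())
        assert c.type is TumourType.NULL_CELL
        assert c.rationale  # auditable

    def test_null_cell_requires_all_hormones_performed(self):
        # diagnosis of exclusion: unperformed hormones block the call
        profile = full_profile().restrict(
            TRANSCRIPTION_FACTORS + (Marker.PRL, Marker.GH, Marker.TSH)
        )
        c = classify(profile)
        assert c.type is TumourType.UNCLASSIFIABLE
        assert any("ACTH" in w for w in c.warnings)

    def test_zero_tf_with_any_hormone_positive_is_plurihormonal(self):
        c = classify(full_profile(Marker.PRL, Marker.TSH, Marker.GH))
        assert c.type is TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE

    def test_multiple_tf_is_plurihormonal(self):
        c = classify(full_profile(Marker.PIT1, Marker.SF1, Marker.PRL))
        assert c.type is TumourType.PLURIHORMONAL_NO_DISTINCT_LINEAGE

    def test_sf1_only_is_gonadotroph(self):
        c = classify(full_profile(Marker.SF1, Marker.FSH, Marker.LH))
        assert c.type is TumourType.GONADOTROPH
        assert not c.warnings

    def test_sf1_with_out_of_lineage_hormone_warns_but_keeps_type(self):
        c = classify(full_profile(Marker.SF1, Marker.GH))
        assert c.type is TumourType.GONADOTROPH
        assert any("GH" in w for w in c.warnings)

    def test_silent_corticotroph_warns(self):
        c = classify(full_profile(Marker.TPIT))
        assert c.type is TumourType.CORTICOTROPH
        assert any("silent" in w for w in c.warnings)

    def test_acth_positive_corticotroph_has_no_silent_warning(self):
        c = classify(full_profile(Marker.TPIT, Marker.ACTH))
        assert c.type is TumourType.CORTICOTROPH
        assert not c.warnings


class TestPIT1SubTable:
    @pytest.mark.parametrize(
        "hormones,expected",
        [
            ((Marker.GH,), TumourType.SOMATOTROPH),
            ((Marker.PRL,), TumourType.LACTOTROPH),
            ((Marker.TSH,), TumourType.THYROTROPH),
            ((Marker.GH, Marker.PRL, Marker.TSH), TumourType.MATURE_PLURIHORMONAL_PIT1),
            ((Marker.GH, Marker.TSH), TumourType.MATURE_PLURIHORMONAL_PIT1),
            ((Marker.PRL, Marker.TSH), TumourType.MATURE_PLURIHORMONAL_PIT1),
        ],
    )
    def test_hormone_patterns_without_flags(self, hormones, expected):
        c = classify(full_profile(Marker.PIT1, *hormones))
        assert c.type is expected

    def test_gh_prl_split_on_monomorphous_flag(self):
        profile = full_profile(Marker.PIT1, Marker.GH, Marker.PRL)
        assert (
            classify(profile, MorphologyFlags(monomorphous=True)).type
            is TumourType.MAMMOSOMATOTROPH
        )
        assert (
            classify(profile, MorphologyFlags(monomorphous=False)).type
            is TumourType.MIXED_SOMATOTROPH_LACTOTROPH
        )
        c = classify(profile)  # flag not assessed: default with a warning
        assert c.type is TumourType.MAMMOSOMATOTROPH
        assert any("monomorphous" in w for w in c.warnings)

    def test_immature_flag_overrides_any_hormone_pattern(self):
        for hormones in [(), (Marker.GH,), (Marker.GH, Marker.PRL, Marker.TSH)]:
            c = classify(
                full_profile(Marker.PIT1, *hormones), MorphologyFlags(immature=True)
            )
            assert c.type is TumourType.IMMATURE_PIT1

    def test_acidophil_flag_takes_precedence_over_prl_row(self):
        c = classify(
            full_profile(Marker.PIT1, Marker.PRL),
            MorphologyFlags(acidophil_stem_cell_features=True),
        )
        assert c.type is TumourType.ACIDOPHIL_STEM_CELL

    def test_hormone_silent_pit1_defaults_to_immature_with_warning(self):
        c = classify(full_profile(Marker.PIT1))
        assert c.type is TumourType.IMMATURE_PIT1
        assert any("silent" in w for w in c.warnings)

    def test_missing_pit1_lineage_hormone_is_unclassifiable(self):
        profile = full_profile(Marker.PIT1).restrict(
            TRANSCRIPTION_FACTORS + (Marker.PRL, Marker.TSH)
        )
        c = classify(profile)
        assert c.type is TumourType.UNCLASSIFIABLE
        assert any("GH" in w for w in c.warnings)


class TestPreconditionsAndInvariants:
    def test_missing_transcription_factor_raises_naming_the_stain(self):
        profile = full_profile(Marker.SF1).restrict((Marker.SF1, Marker.TPIT))
        with pytest.raises(MissingStainError, match="PIT1"):
            classify(profile)

    def test_exhaustive_over_all_fully_performed_profiles(self):
        """Over all 2^9 +/- profiles classify is total, deterministic,
        never unclassifiable, and lineage-consistent."""
        for bits in product((False, True), repeat=9):
            positive = {m for m, b in zip(CANONICAL_STAIN_ORDER, bits) if b}
            profile = full_profile(*positive)
            first = classify(profile)
            second = classify(profile)
            assert first == second
            assert first.type is not TumourType.UNCLASSIFIABLE
            assert first.rationale
            n_tf = len(positive & set(TRANSCRIPTION_FACTORS))
            if n_tf == 1:
                (tf,) = positive & set(TRANSCRIPTION_FACTORS)
                assert first.type.lineage is tf
            else:
                assert first.type.lineage is None


class TestClassifyCohort:
    def test_empty_cohort_gives_empty_table(self):
        classifications, table = classify_cohort([])
        assert classifications == []
        assert table.empty

    def test_frequency_table_percentages_and_functioning(self, reference_cohort):
        _, table = classify_cohort(reference_cohort)
        assert table.loc["gonadotroph", "n"] == 45
        assert table.loc["gonadotroph", "percent"] == 39.8
        assert table.loc["corticotroph", "percent"] == 12.4
        assert table.loc["somatotroph", "n_functioning"] == 10
        assert table["n"].sum() == 113

    def test_errors_are_tagged_with_record_id(self):
        bad = TumourRecord(
            id="X-1",
            profile=full_profile(Marker.SF1).restrict((Marker.SF1,)),
        )
        with pytest.raises(MissingStainError, match="X-1"):
            classify_cohort([bad])

    def test_duplicate_ids_rejected(self):
        r = TumourRecord(id="dup", profile=full_profile(Marker.SF1))
        with pytest.raises(IHCValidationError, match="duplicate"):
            classify_cohort([r, r])

    def test_clinical_hormone_mismatch_warns(self):
        record = TumourRecord(
            id="ACRO-1",
            profile=full_profile(Marker.SF1),
            clinical=ClinicalPresentation.ACROMEGALY,
        )
        classifications, _ = classify_cohort([record])
        assert any("acromegaly" in w for w in classifications[0].warnings)
        # but presentation never changes the type
        assert classifications[0].type is TumourType.GONADOTROPH
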