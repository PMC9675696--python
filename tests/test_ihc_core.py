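"""Marker taxonomy, binarization and profile parsing/serialization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitnet_triage import (
    HORMONES,
    TRANSCRIPTION_FACTORS,
    IHCProfile,
    IHCValidationError,
    Marker,
    StainResult,
    StainStatus,
    binarize,
    parse_profile,
    serialize_profile,
)
from pitnet_triage.ihc_core import CANONICAL_STAIN_ORDER, MarkerCategory


class TestMarkerTaxonomy:
    def test_three_transcription_factors_and_six_hormones(self):
        tfs = [m for m in Marker if m.category is MarkerCategory.TRANSCRIPTION_FACTOR]
        hormones = [m for m in Marker if m.category is MarkerCategory.HORMONE]
        assert set(tfs) == set(TRANSCRIPTION_FACTORS) and len(tfs) == 3
        assert set(hormones) == set(HORMONES) and len(hormones) == 6

    def test_each_hormone_maps_to_exactly_one_lineage(self):
        expected = {
            Marker.GH: Marker.PIT1,
            Marker.PRL: Marker.PIT1,
            Marker.TSH: Marker.PIT1,
            Marker.ACTH: Marker.TPIT,
            Marker.LH: Marker.SF1,
            Marker.FSH: Marker.SF1,
        }
        assert {h: h.lineage for h in HORMONES} == expected
        for tf in TRANSCRIPTION_FACTORS:
            assert tf.lineage is tf


class TestBinarize:
    @pytest.mark.parametrize(
        "percent,expected",
        [
            (10, StainStatus.POSITIVE),  # boundary is inclusive
            (0, StainStatus.NEGATIVE),
            (9.99, StainStatus.NEGATIVE),
            (100, StainStatus.POSITIVE),
            (10.01, StainStatus.POSITIVE),
        ],
    )
    def test_default_threshold(self, percent, expected):
        assert binarize(percent) is expected

    def test_custom_threshold(self):
        assert binarize(5, threshold=5) is StainStatus.POSITIVE
        assert binarize(5, threshold=5.1) is StainStatus.NEGATIVE

    @pytest.mark.parametrize("percent", [-0.1, 100.1, float("nan"), "ten"])
    def test_out_of_range_percent_rejected(self, percent):
        with pytest.raises(IHCValidationError):
            binarize(percent)

    @pytest.mark.parametrize("threshold", [0, -1, 101])
    def test_invalid_threshold_rejected(self, threshold):
        with pytest.raises(IHCValidationError):
            binarize(50, threshold=threshold)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(min_value=0, max_value=100),
        b=st.floats(min_value=0, max_value=100),
        threshold=st.floats(min_value=0.1, max_value=100),
    )
    def test_monotone_in_percent(self, a, b, threshold):
        lo, hi = sorted((a, b))
        if binarize(lo, threshold) is StainStatus.POSITIVE:
            assert binarize(hi, threshold) is StainStatus.POSITIVE


class TestStainResult:
    def test_status_must_match_percentage(self):
        with pytest.raises(IHCValidationError):
            StainResult(Marker.SF1, StainStatus.NEGATIVE, percent_positive_cells=50.0)

    def test_percentage_on_unperformed_slot_allowed_only_as_not_performed(self):
        r = StainResult(Marker.SF1, StainStatus.NOT_PERFORMED, percent_positive_cells=50.0)
        assert not r.performed


class TestParseProfile:
    def test_partial_row_fills_not_performed(self):
        profile = parse_profile({"PIT1": "+", "SF1": "+", "PRL": "+"})
        assert profile.status(Marker.PIT1) is StainStatus.POSITIVE
        assert profile.status(Marker.SF1) is StainStatus.POSITIVE
        assert profile.status(Marker.PRL) is StainStatus.POSITIVE
        not_performed = [r.marker for r in profile.results if not r.performed]
        assert len(not_performed) == 6

    def test_empty_row_is_all_not_performed(self):
        profile = parse_profile({})
        assert all(not r.performed for r in profile.results)

    def test_percentage_is_binarized(self):
        profile = parse_profile({"SF1": "15"})
        assert profile.status(Marker.SF1) is StainStatus.POSITIVE
        assert profile.result(Marker.SF1).percent_positive_cells == 15

    def test_typographic_minus_accepted(self):
        profile = parse_profile({"TPIT": "−", "SF1": "-"})
        assert profile.status(Marker.TPIT) is StainStatus.NEGATIVE
        assert profile.status(Marker.SF1) is StainStatus.NEGATIVE

    def test_unknown_marker_rejected(self):
        with pytest.raises(IHCValidationError, match="KI67"):
            parse_profile({"KI67": "+"})

    def test_unparseable_value_names_the_cell(self):
        with pytest.raises(IHCValidationError, match="GH"):
            parse_profile({"GH": "maybe"})

    def test_percent_out_of_range_rejected(self):
        with pytest.raises(IHCValidationError):
            parse_profile({"GH": "120"})


class TestProfileContainer:
    def test_profile_requires_all_nine_markers(self):
        with pytest.raises(IHCValidationError):
            IHCProfile(tuple(StainResult(m, StainStatus.NEGATIVE) for m in HORMONES))

    def test_from_calls_default_negates_the_rest(self):
        p = IHCProfile.from_calls(positive={Marker.SF1})
        assert p.positive_markers() == (Marker.SF1,)
        assert all(r.performed for r in p.results)

    def test_restrict_leaves_other_markers_not_performed(self):
        p = IHCProfile.from_calls(positive={Marker.SF1, Marker.GH})
        q = p.restrict(TRANSCRIPTION_FACTORS)
        assert q.performed_markers() == TRANSCRIPTION_FACTORS
        assert q.status(Marker.GH) is StainStatus.NOT_PERFORMED


_status = st.sampled_from(list(StainStatus))


@st.composite
def profiles(draw):
    results = []
    for m in CANONICAL_STAIN_ORDER:
        status = draw(_status)
        pct = None
        if status is StainStatus.POSITIVE and draw(st.booleans()):
            pct = draw(st.floats(min_value=10, max_value=100))
        elif status is StainStatus.NEGATIVE and draw(st.booleans()):
            pct = draw(st.floats(min_value=0, max_value=9.9))
        results.append(StainResult(m, status, pct))
    return IHCProfile(tuple(results))


@settings(derandomize=True, max_examples=200)
@given(profile=profiles())
def test_serialize_parse_round_trip(profile):
    """parse_profile of serialize_profile is the identity on any valid profile."""
    again = parse_profile(serialize_profile(profile))
    for m in Marker:
        assert again.status(m) is profile.status(m)
        original_pct = profile.result(m).percent_positive_cells
        if original_pct is not None and profile.result(m).performed:
            assert again.result(m).percent_positive_cells == pytest.approx(original_pct)
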