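"""Zone annotation, bounded midpoint imputation and cross-section alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corticomap.align import (
    AlignmentConfig,
    Zone,
    ZoneAnnotation,
    align_sections,
    impute_zone,
    reference_lengths,
    zone_means,
)
from corticomap.profile import ColumnProfile


def _annotation(lengths, section_id=""):
    zones, start = [], 0
    for label, n in lengths:
        zones.append(Zone(label, start, start + n))
        start += n
    return ZoneAnnotation(tuple(zones), section_id=section_id)


def _profile(values):
    values = np.asarray(values, float)
    counts = np.where(np.isnan(values), 0, 4)
    return ColumnProfile(values, counts)


class TestAnnotation:
    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError):
            ZoneAnnotation((Zone("IM", 0, 3), Zone("OM", 4, 6)))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            ZoneAnnotation((Zone("IM", 0, 3), Zone("IM", 3, 6)))


class TestReferenceLengths:
    def test_maximum_across_sections(self):
        anns = [_annotation([("OM", n)]) for n in (8, 10, 9)]
        assert reference_lengths(anns) == {"OM": 10}

    def test_single_section_identity(self):
        ann = _annotation([("IM", 4), ("OM", 7)])
        assert reference_lengths([ann]) == {"IM": 4, "OM": 7}

    def test_inconsistent_sequences_rejected(self):
        with pytest.raises(ValueError):
            reference_lengths([_annotation([("IM", 3)]), _annotation([("OM", 3)])])


class TestImputeZone:
    def test_worked_example(self):
        values, flags, frac = impute_zone(np.array([1.0, 3.0, 5.0, 7.0]), 5)
        np.testing.assert_allclose(values, [1, 3, 4, 5, 7])
        np.testing.assert_array_equal(flags, [False, False, True, False, False])
        assert frac == pytest.approx(0.2)

    def test_midpoint(self):
        values, _, _ = impute_zone(np.array([2.0, 4.0]), 3)
        np.testing.assert_allclose(values, [2, 3, 4])

    def test_identity_when_lengths_match(self, rng):
        x = rng.uniform(0, 1, 9)
        values, flags, frac = impute_zone(x, 9)
        np.testing.assert_array_equal(values, x)
        assert not flags.any() and frac == 0.0

    def test_singleton_replicated(self):
        values, flags, _ = impute_zone(np.array([4.2]), 4)
        np.testing.assert_allclose(values, 4.2)
        assert list(flags) == [False, True, True, True]

    def test_rejects_shrinking_and_empty(self):
        with pytest.raises(ValueError):
            impute_zone(np.arange(5.0), 3)
        with pytest.raises(ValueError):
            impute_zone(np.array([]), 3)

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=20),
        st.integers(min_value=0, max_value=15),
    )
    @settings(derandomize=True, max_examples=80)
    def test_originals_preserved_in_order(self, xs, extra):
        x = np.asarray(xs)
        values, flags, frac = impute_zone(x, len(x) + extra)
        np.testing.assert_array_equal(values[~flags], x)
        assert frac == pytest.approx(extra / (len(x) + extra))

    @given(st.integers(2, 15), st.integers(0, 10))
    @settings(derandomize=True, max_examples=60)
    def test_monotone_and_extremes_preserved(self, n, extra):
        x = np.cumsum(np.abs(np.sin(np.arange(n))) + 0.1)
        values, _, _ = impute_zone(x, n + extra)
        assert np.all(np.diff(values) >= 0)
        assert values.min() == x.min() and values.max() == x.max()

    def test_constant_segment_stays_constant(self):
        values, _, _ = impute_zone(np.full(5, 2.5), 6)
        np.testing.assert_array_equal(values, np.full(6, 2.5))


class TestAlignSections:
    def test_already_at_reference_is_identity(self):
        profiles = [_profile([1, 2, 3, 4.0]), _profile([2, 3, 4, 5.0])]
        anns = [_annotation([("IM", 2), ("OM", 2)], f"s{i}") for i in range(2)]
        aligned, report = align_sections(profiles, anns)
        for ap, prof in zip(aligned, profiles):
            np.testing.assert_array_equal(
                np.concatenate([ap.zones["IM"], ap.zones["OM"]]), prof.values
            )
            assert not any(f.any() for f in ap.imputed_flags.values())
        assert (report["imputed_fraction"] == 0).all()

    def test_single_missing_point_imputed(self):
        wide = _profile(np.arange(10.0))
        narrow = _profile(np.arange(9.0))
        anns = [_annotation([("OM", 10)], "wide"), _annotation([("OM", 9)], "narrow")]
        aligned, report = align_sections([wide, narrow], anns)
        ap = aligned[1]
        assert ap.imputed_flags["OM"].sum() == 1
        np.testing.assert_array_equal(
            ap.zones["OM"][~ap.imputed_flags["OM"]], narrow.values
        )
        assert report.set_index("section").loc["narrow", "compliant"]

    def test_excessive_imputation_flagged_non_compliant(self):
        wide = _profile(np.arange(10.0))
        short = _profile(np.arange(6.0))  # needs 4/10 = 40 % > 20 %
        anns = [_annotation([("OM", 10)], "wide"), _annotation([("OM", 6)], "short")]
        with pytest.warns(UserWarning, match="non-compliant"):
            aligned, report = align_sections([wide, short], anns)
        comp = report.set_index("section")
        assert not comp.loc["short", "compliant"]
        assert not comp.loc["short", "meets_min_fraction"]  # 6 < 0.7 * 10
        # excluded from zone statistics by default
        assert np.isnan(zone_means(aligned[1])["OM"])
        assert zone_means(aligned[1], compliant_only=False)["OM"] == pytest.approx(2.7)

    def test_seventy_percent_is_a_qc_note_not_a_gate(self):
        # 8 of 10 columns: above the 70 % note, 20 % imputation — compliant
        wide = _profile(np.arange(10.0))
        ok = _profile(np.arange(8.0))
        anns = [_annotation([("OM", 10)], "wide"), _annotation([("OM", 8)], "ok")]
        _, report = align_sections([wide, ok], anns)
        row = report.set_index("section").loc["ok"]
        assert row["meets_min_fraction"] and row["compliant"]

    def test_deterministic(self):
        profiles = [_profile(np.arange(10.0)), _profile(np.arange(9.0))]
        anns = [_annotation([("OM", 10)], "a"), _annotation([("OM", 9)], "b")]
        a1, _ = align_sections(profiles, anns)
        a2, _ = align_sections(profiles, anns)
        np.testing.assert_array_equal(a1[1].zones["OM"], a2[1].zones["OM"])


class TestZoneMeans:
    def test_simple_mean(self):
        profiles = [_profile([2.0, 4.0])]
        anns = [_annotation([("OM", 2)])]
        aligned, _ = align_sections(profiles, anns)
        assert zone_means(aligned[0])["OM"] == pytest.approx(3.0)

    def test_all_undefined_zone(self):
        profiles = [_profile([np.nan, np.nan, 1.0])]
        anns = [_annotation([("OM", 2), ("IC", 1)])]
        aligned, _ = align_sections(profiles, anns)
        means = zone_means(aligned[0])
        assert np.isnan(means["OM"]) and means["IC"] == 1.0

    def test_exclude_imputed_option(self):
        profiles = [_profile([0.0, 10.0, 0.0, 10.0]), _profile([0.0, 4.0, 6.0, 8.0, 10.0])]
        anns = [_annotation([("OM", 4)], "a"), _annotation([("OM", 5)], "b")]
        aligned, _ = align_sections(profiles, anns)
        # one midpoint inserted into [0,10,0,10]: value 5 between columns 1 and 2
        with_imp = zone_means(aligned[0])["OM"]
        without = zone_means(aligned[0], include_imputed=False)["OM"]
        assert with_imp == pytest.approx(5.0) and without == pytest.approx(5.0)


def test_cohort_alignment_matches_generated_widths(default_cohort):
    """Reference lengths equal the widest generated section, zone by zone."""
    anns = [sec.annotation for sec in default_cohort]
    refs = reference_lengths(anns)
    for i, label in enumerate(anns[0].labels):
        assert refs[label] == max(a.zones[i].length for a in anns)
    widest = anns[0]  # cohort generator keeps section 1 at scale 1.0
    for i, label in enumerate(widest.labels):
        assert refs[label] == widest.zones[i].length
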