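import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhinopath import (
    CATEGORIES,
    PathologyCategory,
    ValidationError,
    category_ipa,
    ipa_profile,
    load_frequency_fixture,
    overall_ipa,
    percent_pathologic,
    round_for_report,
    tabulate_frequencies,
)
from rhinopath.ipa import CategoryFrequencyTable, frequency_report

from conftest import make_record, uniform_record


class TestTabulateFrequencies:
    def test_simple_tally(self):
        recs = [make_record(exostoses=r) for r in (1, 2, 2)]
        freq = tabulate_frequencies(recs, "T")
        assert freq.counts[PathologyCategory.exostoses] == (1, 2, 0, 0)

    def test_count_weighting(self):
        recs = [make_record(count=5, exostoses=3)]
        freq = tabulate_frequencies(recs, "T")
        assert freq.counts[PathologyCategory.exostoses] == (0, 0, 5, 0)

    def test_missing_ranks_contribute_nothing(self):
        recs = [make_record(exostoses=2), make_record(lipping=1)]
        freq = tabulate_frequencies(recs, "T")
        assert freq.total(PathologyCategory.exostoses) == 1
        assert freq.total(PathologyCategory.texture) == 0

    def test_unknown_taxon_lists_known(self):
        with pytest.raises(ValidationError, match="known taxa.*T"):
            tabulate_frequencies([make_record(exostoses=1)], "nope")


class TestCategoryIpa:
    def test_study_texture_row(self):
        # 17/81/15/1 scored elements at ranks 1-4
        assert category_ipa((17, 81, 15, 1)) == pytest.approx(2.0)

    def test_study_foramen_size_row(self):
        assert category_ipa((52, 42, 20, 0)) == pytest.approx(1.7193, abs=1e-4)

    @pytest.mark.parametrize("n", [1, 7, 100])
    def test_floor_and_ceiling(self, n):
        assert category_ipa((n, 0, 0, 0)) == 1.0
        assert category_ipa((0, 0, 0, n)) == 4.0

    def test_unscored_category_is_an_error(self):
        with pytest.raises(ValidationError, match="unscored"):
            category_ipa((0, 0, 0, 0))


class TestOverallIpa:
    def test_bounds_hit_exactly(self):
        assert overall_ipa([1.0] * 7) == 7.0
        assert overall_ipa([4.0] * 7) == 28.0

    def test_partial_profile_is_an_error(self):
        with pytest.raises(ValidationError, match="partial"):
            overall_ipa([1.0] * 6)

    def test_profile_flags_partial_instead_of_summing(self):
        freq = tabulate_frequencies([make_record(exostoses=2)], "T")
        prof = ipa_profile(freq)
        assert prof.partial and prof.overall is None

    @given(
        st.lists(
            st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0),
            min_size=7, max_size=7,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounds_property(self, rows):
        means = [category_ipa(r) for r in rows]
        assert all(1.0 <= m <= 4.0 for m in means)
        assert 7.0 <= overall_ipa(means) <= 28.0

    def test_monotone_in_any_single_rank(self, rng):
        # raising one element's rank never lowers the category mean,
        # the overall index, or a percent-pathologic figure containing it
        base = [uniform_record(rank=2) for _ in range(5)]
        raised = [uniform_record(rank=2) for _ in range(4)] + [uniform_record(rank=3)]
        for group in ("taxon",):
            p0 = percent_pathologic(base, group)["percent_pathologic"].iloc[0]
            p1 = percent_pathologic(raised, group)["percent_pathologic"].iloc[0]
            assert p1 >= p0
        m0 = ipa_profile(tabulate_frequencies(base, "T"))
        m1 = ipa_profile(tabulate_frequencies(raised, "T"))
        assert m1.overall >= m0.overall
        for c in CATEGORIES:
            assert m1.category_means[c] >= m0.category_means[c]

    def test_consistency_with_pooled_scores(self, rng):
        # with equal per-category n, the overall index equals the pooled
        # count-weighted total score divided by n (brute-force oracle)
        for _ in range(20):
            ranks = rng.integers(1, 5, size=(12, 7))
            recs = [
                make_record(**{c.value: int(ranks[i, j]) for j, c in enumerate(CATEGORIES)})
                for i in range(12)
            ]
            prof = ipa_profile(tabulate_frequencies(recs, "T"))
            assert prof.overall == pytest.approx(ranks.sum() / 12)


class TestPercentPathologic:
    def test_all_normal_is_zero_percent(self):
        recs = [uniform_record(rank=1) for _ in range(6)]
        df = percent_pathologic(recs, "taxon")
        assert df["percent_pathologic"].tolist() == [0.0]

    def test_single_affected_element(self):
        recs = [uniform_record(rank=1) for _ in range(3)] + [make_record(exostoses=2, lipping=1)]
        df = percent_pathologic(recs, "taxon")
        assert df["percent_pathologic"].iloc[0] == pytest.approx(25.0)

    def test_brute_force_count(self, rng):
        recs = []
        expected_pathologic = 0
        for i in range(10):
            ranks = {c: int(r) for c, r in zip(CATEGORIES, rng.integers(1, 5, 7))}
            if i < 3:  # force three all-normal elements
                ranks = {c: 1 for c in CATEGORIES}
            recs.append(
                make_record(**{c.value: v for c, v in ranks.items()})
            )
            expected_pathologic += int(any(v >= 2 for v in ranks.values()))
        df = percent_pathologic(recs, "taxon")
        assert df["percent_pathologic"].iloc[0] == pytest.approx(
            100.0 * expected_pathologic / 10
        )

    def test_anatomical_grouping_and_absent_groups(self):
        recs = [
            make_record(element="humerus", exostoses=2),
            make_record(element="femur", exostoses=1, lipping=1),
        ]
        df = percent_pathologic(recs, "functional").set_index("group")
        assert df.loc["forelimb", "percent_pathologic"] == 100.0
        assert df.loc["hindlimb", "percent_pathologic"] == 0.0
        assert "axial" not in df.index  # absent, not 0%

    def test_unscored_elements_excluded(self):
        recs = [uniform_record(rank=2), make_record()]  # second has no scores
        df = percent_pathologic(recs, "taxon")
        assert df["n_elements"].iloc[0] == 1


class TestRounding:
    @pytest.mark.parametrize(
        "value, places, expected",
        [(1.7193, 2, 1.72), (2.005, 2, 2.00), (11.0614, 2, 11.06),
         (1.895, 2, 1.90), (2.675, 2, 2.68), (1.25, 1, 1.2)],
    )
    def test_half_even(self, value, places, expected):
        assert round_for_report(value, places) == expected

    def test_negative_places_rejected(self):
        with pytest.raises(ValidationError):
            round_for_report(1.0, -1)


class TestFixtureAndReport:
    def test_fixture_has_seven_taxa_and_golden_counts(self):
        tables, df = load_frequency_fixture()
        assert len(tables) == 7
        to = tables["Trigonias osborni"]
        assert to.counts[PathologyCategory.exostoses] == (19, 88, 7, 0)
        assert to.counts[PathologyCategory.lipping] == (78, 34, 2, 0)
        assert to.counts[PathologyCategory.texture] == (17, 81, 15, 1)

    def test_report_mirrors_table_layout(self, tmp_path):
        tables, _ = load_frequency_fixture()
        out = tmp_path / "report.csv"
        df = frequency_report(tables.values(), out)
        assert out.exists()
        assert set(df.columns) >= {"taxon", "category", "n", "counts_1", "mean", "overall"}
        assert len(df) == 49  # 7 taxa x 7 categories
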