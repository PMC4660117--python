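"""Frequencies, odds ratios, enrichment, dominance."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igtkb.prioritizer import (
    UndefinedFrequencyError,
    flag_enriched,
    frequency,
    odds_ratio,
    select_dominant,
    woolf_ci,
)


class TestFrequency:
    @pytest.mark.parametrize(
        "n_with, n_total, expected_5dp",
        [
            (2, 18, "0.11111"),
            (0, 50, "0.00000"),
            (1036, 138229, "0.00749"),
            (33, 187, "0.17647"),
        ],
    )
    def test_reported_precision(self, n_with, n_total, expected_5dp):
        assert f"{frequency(n_with, n_total):.5f}" == expected_5dp

    def test_empty_group_is_an_error(self):
        with pytest.raises(UndefinedFrequencyError):
            frequency(0, 0)

    def test_count_exceeding_group_rejected(self):
        with pytest.raises(ValueError):
            frequency(5, 4)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "a, s1, b, s2, expected_5dp",
        [
            (2, 18, 1, 202, "25.12500"),
            (4, 187, 2, 240, "2.60109"),
            (1, 10, 1, 10, "1.00000"),
            (160, 514, 415, 138229, "150.09353"),
            (1, 18, 1, 202, "11.82353"),
            (1, 9, 46, 159, "0.30707"),
        ],
    )
    def test_known_values(self, a, s1, b, s2, expected_5dp):
        assert f"{odds_ratio(a, s1, b, s2):.5f}" == expected_5dp

    def test_degenerate_sentinels(self):
        assert odds_ratio(0, 10, 3, 10) == 0.0
        assert math.isinf(odds_ratio(3, 10, 0, 10))
        assert math.isinf(odds_ratio(10, 10, 3, 10))
        # 0/0 and inf/inf odds are undefined
        assert math.isnan(odds_ratio(0, 10, 0, 10))
        assert math.isnan(odds_ratio(10, 10, 10, 10))
        assert odds_ratio(0, 10, 10, 10) == 0.0

    def test_counts_exceeding_sizes_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(11, 10, 1, 10)

    def test_haldane_correction_handles_zero_cells(self):
        value = odds_ratio(3, 10, 0, 10, correction=True)
        assert value == (3.5 / 7.5) / (0.5 / 10.5)

    @settings(derandomize=True, max_examples=300)
    @given(
        s1=st.integers(1, 60), s2=st.integers(1, 60),
        data=st.data(),
    )
    def test_matches_brute_force_cross_product(self, s1, s2, data):
        """Independent oracle: the 2x2 cross-product ratio (a*d)/(b*c)."""
        a = data.draw(st.integers(1, s1 - 1)) if s1 > 1 else None
        b = data.draw(st.integers(1, s2 - 1)) if s2 > 1 else None
        if a is None or b is None:
            return
        cross = (a * (s2 - b)) / (b * (s1 - a))
        assert odds_ratio(a, s1, b, s2) == pytest.approx(cross, rel=1e-12)

    @settings(derandomize=True, max_examples=300)
    @given(
        s1=st.integers(2, 60), s2=st.integers(2, 60), data=st.data(),
    )
    def test_reciprocal_symmetry(self, s1, s2, data):
        a = data.draw(st.integers(1, s1 - 1))
        b = data.draw(st.integers(1, s2 - 1))
        product = odds_ratio(a, s1, b, s2) * odds_ratio(b, s2, a, s1)
        assert product == pytest.approx(1.0, rel=1e-12)

    def test_woolf_interval_contains_point_estimate(self):
        low, high = woolf_ci(4, 187, 2, 240)
        assert low < odds_ratio(4, 187, 2, 240) < high


class TestEnrichment:
    def test_positive_excess_examples(self):
        # Depression-like profile: positive frequency above negative
        assert flag_enriched(0.30653, 0.20833, 0.20755, 0.22222)
        # Asthma-like profile: positive below negative
        assert not flag_enriched(0.21469, 0.22727, 0.23267, 0.16667)

    def test_flat_profile_not_enriched(self):
        assert not flag_enriched(0.1, 0.1, 0.1, 0.1)
        assert not flag_enriched(0.1, 0.1, 0.1, 0.1,
                                 criterion="strict_monotone")

    def test_strict_monotone_criterion(self):
        assert flag_enriched(0.01, 0.02, 0.03, 0.04,
                             criterion="strict_monotone")
        assert not flag_enriched(0.05, 0.02, 0.03, 0.04,
                                 criterion="strict_monotone")

    @settings(derandomize=True, max_examples=300)
    @given(
        s1=st.integers(2, 50), s2=st.integers(2, 50), data=st.data(),
    )
    def test_equivalent_to_odds_ratio_above_one(self, s1, s2, data):
        """freq_P > freq_N if and only if OR_PN > 1, for finite ratios."""
        a = data.draw(st.integers(1, s1 - 1))
        b = data.draw(st.integers(1, s2 - 1))
        enriched = flag_enriched(0.0, 0.0, b / s2, a / s1)
        assert enriched == (odds_ratio(a, s1, b, s2) > 1.0)


class TestSelectDominant:
    def test_empty_input(self):
        import pandas as pd

        empty = pd.DataFrame(columns=["or_pn"])
        assert select_dominant(empty).empty

    def test_strictly_greater_than_threshold(self):
        import pandas as pd

        stats = pd.DataFrame({"or_pn": [0.5, 1.0, 1.0001, math.inf]})
        assert list(select_dominant(stats)["or_pn"]) == [1.0001, math.inf]


class TestPaperStatistics:
    """Full-table reproduction on the study-table cohort."""

    def test_every_published_cell_reproduced_at_5dp(self, paper_result,
                                                    printed_stats):
        from igtkb.pipeline import compare_to_printed

        assert compare_to_printed(paper_result.stats, printed_stats) == []

    @pytest.mark.parametrize(
        "test_id, term, expected",
        [
            ("9497", "Malabsorption", "25.12500"),
            ("9497", "Emphysema", "11.82353"),
            ("9569", "Seizure", "0.30707"),
            ("81508", "Telangiectasia", "7.92265"),
            ("82993", "Emphysema", "2.28283"),
        ],
    )
    def test_selected_odds_ratios(self, paper_result, test_id, term, expected):
        stats = paper_result.stats
        row = stats[(stats.test_id == test_id) & (stats.term == term)].iloc[0]
        assert f"{row.or_pn:.5f}" == expected

    def test_prevalence_weight_worked_example(self, paper_result):
        """Cirrhosis under the alpha-1 antitrypsin test: low P-vs-N ratio
        but the highest tested-vs-background prevalence weight."""
        stats = paper_result.stats
        row = stats[(stats.test_id == "82993")
                    & (stats.term == "Cirrhosis")].iloc[0]
        assert f"{row.or_pn:.5f}" == "0.78494"
        assert f"{row.or_ta:.5f}" == "150.09353"

    def test_enrichment_flag_matches_dominance(self, paper_result):
        stats = paper_result.stats
        assert (stats["enriched"] == stats["dominant"]).all()

    def test_dominant_features_for_alpha1_antitrypsin(self, paper_result):
        stats = paper_result.stats
        dominant = set(
            stats[(stats.test_id == "82993") & stats.dominant]["term"]
        )
        assert dominant == {"Emphysema", "Hepatic failure"}
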