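import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gcvolatiles import (
    abundance_class,
    classification_summary,
    classify_peaks,
    contingency_test,
    enrichment_test,
    inclusion_filter,
    range_share_summary,
    rt_range,
    sex_bias_class,
)

from conftest import make_table


class TestRtRange:
    @pytest.mark.parametrize(
        "label, expected",
        [
            (4.61, "short"),
            (10.39, "short"),
            (10.40, "mid"),
            (13.59, "mid"),
            (13.60, "long"),
            (21.0, "long"),
            (840, "short"),
            (1151, "mid"),  # a mid-range imputed KI
            (2175, "long"),
        ],
    )
    def test_boundaries(self, label, expected):
        assert rt_range(label) == expected

    @pytest.mark.parametrize("label", [4.0, 22.0, 830, 2200])
    def test_out_of_range_rejected(self, label):
        with pytest.raises(ValueError, match=str(label)):
            rt_range(label)


class TestInclusionFilter:
    def test_half_detection_in_one_cell_retains(self):
        # peak 1 detected in 2/4 virgin males of one line, nowhere else
        areas = [[5, 0], [7, 0], [0, 0], [0, 0], [0, 0], [0, 0]]
        tab = make_table(areas, lines=["L1"] * 4 + ["L2"] * 2)
        kept = inclusion_filter(tab, threshold=0.5)
        assert kept == [tab.areas.columns[0]]

    def test_all_detected_everywhere_identity(self):
        tab = make_table(np.ones((4, 3)), lines=["L1", "L1", "L2", "L2"])
        assert inclusion_filter(tab) == list(tab.areas.columns)

    @given(st.floats(min_value=0.05, max_value=1.0), st.floats(min_value=0.0, max_value=0.95))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_threshold(self, hi, lo_offset):
        lo = hi - lo_offset * hi
        rng = np.random.default_rng(11)
        areas = rng.integers(0, 2, size=(12, 6)) * rng.uniform(1, 10, size=(12, 6))
        tab = make_table(areas, lines=list("AABBCCDDEEFF"))
        kept_hi = set(map(float, inclusion_filter(tab, threshold=hi)))
        kept_lo = set(map(float, inclusion_filter(tab, threshold=lo)))
        assert kept_hi <= kept_lo


class TestAbundance:
    def _tables(self, shares):
        # one table per category, peak 0 takes `share` of a 10000 total
        tabs = {}
        for i, share in enumerate(shares):
            area0 = 10000 * share
            tabs[f"cat{i}"] = make_table([[area0, 10000 - area0]])
        return tabs

    @pytest.mark.parametrize(
        "shares, expected",
        [
            ((0.012, 0.001, 0.0, 0.0), "major"),
            ((0.01, 0.0005, 0.0, 0.0), "major"),  # boundary 1% is major
            ((0.001, 0.0002, 0.0, 0.0), "intermediate"),  # boundary 0.1%
            ((0.0002, 0.0005, 0.0009, 0.0), "minor"),
        ],
    )
    def test_max_share_rule(self, shares, expected):
        tabs = self._tables(shares)
        label = tabs["cat0"].areas.columns[0]
        assert abundance_class(tabs, label) == expected

    def test_absent_peak_is_error(self):
        tabs = self._tables((0.01,))
        with pytest.raises(KeyError):
            abundance_class(tabs, 19.99)


class TestSexBias:
    def _pair(self, male_vals, female_vals):
        return (
            make_table([[v] for v in male_vals], sexes=["male"] * len(male_vals)),
            make_table([[v] for v in female_vals], sexes=["female"] * len(female_vals)),
        )

    @pytest.mark.parametrize(
        "male_vals, female_vals, expected",
        [
            ([500, 500], [0, 0], "male_specific"),
            ([0, 0], [10, 0], "female_specific"),
            ([1000, 1000], [50, 50], "male_selective"),  # log10 ratio 1.30
            ([100], [100], "none"),
            ([1000], [100], "none"),  # exactly 10-fold is not selective
            ([0, 0], [0, 0], "not_detected"),
        ],
    )
    def test_rules(self, male_vals, female_vals, expected):
        m, f = self._pair(male_vals, female_vals)
        label = m.areas.columns[0]
        assert sex_bias_class(m, f, label) == expected

    def test_not_assayed(self):
        m, _ = self._pair([10], [10])
        assert sex_bias_class(m, None, m.areas.columns[0]) == "not_assayed"

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=5),
           st.lists(st.floats(0, 1e6), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_sex_swap(self, mv, fv):
        m, f = self._pair(mv, fv)
        label = m.areas.columns[0]
        swap = {
            "male_specific": "female_specific",
            "female_specific": "male_specific",
            "male_selective": "female_selective",
            "female_selective": "male_selective",
            "none": "none",
            "not_detected": "not_detected",
        }
        assert sex_bias_class(f, m, label) == swap[sex_bias_class(m, f, label)]


class TestEnrichment:
    def test_rt_range_ratio_statistic(self):
        chi2, df, p = enrichment_test((11, 3, 12), (31, 23, 147))
        assert round(chi2, 2) == 14.77
        assert df == 2
        assert p < 0.001

    def test_proportional_counts_give_zero(self):
        chi2, _, p = enrichment_test((10, 20, 30), (1, 2, 3))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_abundance_ratio_statistic(self):
        # goodness-of-fit formulation of the abundance-class comparison
        chi2, df, _ = enrichment_test((3, 13, 10), (21, 75, 105))
        assert chi2 == pytest.approx(2.10, abs=0.005)
        # the disjoint-contingency formulation of the same comparison
        chi2c, dfc, _ = contingency_test((3, 13, 10), (18, 62, 95))
        assert chi2c == pytest.approx(2.41, abs=0.005)
        assert df == dfc == 2

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=6).filter(lambda o: sum(o) > 0),
           st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_scipy_oracle(self, observed, data):
        reference = data.draw(
            st.lists(st.integers(1, 100), min_size=len(observed), max_size=len(observed))
        )
        chi2, df, p = enrichment_test(observed, reference)
        obs = np.asarray(observed, float)
        ref = np.asarray(reference, float)
        expected = obs.sum() * ref / ref.sum()
        oracle = stats.chisquare(obs, expected)
        assert chi2 == pytest.approx(float(oracle.statistic), abs=1e-9)
        assert p == pytest.approx(float(oracle.pvalue), abs=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            enrichment_test((1, 2), (0, 5))


class TestSummaries:
    def test_empty_classification_summary(self):
        empty = pd.DataFrame(columns=["virgin_bias", "mixed_bias", "rt_range", "abundance"])
        assert classification_summary(empty).empty

    def test_counts_match_construction(self):
        rows = (
            [("male_specific", "male_specific", "short", "minor")] * 3
            + [("none", "none", "long", "major")] * 2
        )
        df = pd.DataFrame(rows, columns=["virgin_bias", "mixed_bias", "rt_range", "abundance"])
        out = classification_summary(df).set_index(["virgin_bias", "rt_range"])["count"]
        assert out[("male_specific", "short")] == 3
        assert out[("none", "long")] == 2

    def test_range_share_summary_percentages(self):
        shares = range_share_summary(
            {"short": 14, "mid": 4, "long": 12}, {"short": 31, "mid": 23, "long": 147}
        )
        assert shares.loc["short", "case_share_pct"] == pytest.approx(100 * 14 / 30)
        assert shares.loc["short", "pct_of_range_significant"] == pytest.approx(100 * 14 / 31)


def test_classify_peaks_end_to_end(sim_study):
    tables, truth = sim_study
    labels = truth.peaks["rt"].tolist()[:40]
    out = classify_peaks(tables, labels)
    assert len(out) == 40
    assert set(out["rt_range"]) <= {"short", "mid", "long"}
    # truth sex patterns must show through for well-detected peaks
    merged = out.merge(truth.peaks, left_on="peak_label", right_on="rt")
    spec = merged[merged["sex_pattern"] == "male_specific"]
    detected = spec[spec["virgin_bias"] != "not_detected"]
    assert (detected["virgin_bias"] == "male_specific").all()
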