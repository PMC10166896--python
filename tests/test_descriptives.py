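"""Time-to-onset, summary table, fatality proportion and their tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from faerspv.cases import classify_exposure
from faerspv.descriptives import (
    _holm,
    age_bin,
    chisq_fatality,
    compute_tto,
    fatality_proportion,
    kruskal_wallis_tto,
    percent,
    summarize,
    tto_bin,
)
from faerspv.io import DrugMention

from conftest import make_report


def _tto_report(start, event, role="PS", drug="OPDIVO"):
    rep = make_report(
        event_date=event,
        drugs=[DrugMention(drug, role=role, therapy_start=start)],
    )
    return rep, classify_exposure(rep)


class TestComputeTto:
    def test_simple_interval(self):
        rep, label = _tto_report("20200101", "20200208")
        assert compute_tto(rep, label).days == 38

    def test_same_day_onset_is_day_one(self):
        rep, label = _tto_report("20200301", "20200301")
        assert compute_tto(rep, label).days == 1

    def test_partial_start_date_is_missing(self):
        rep, label = _tto_report("202003", "20200315")
        assert compute_tto(rep, label) is None

    def test_partial_event_date_is_missing(self):
        rep, label = _tto_report("20200301", "202003")
        assert compute_tto(rep, label) is None

    def test_negative_interval_is_missing(self):
        rep, label = _tto_report("20200301", "20200201")
        assert compute_tto(rep, label) is None

    def test_earliest_suspect_ici_start_is_used(self):
        rep = make_report(
            event_date="20200301",
            drugs=[
                DrugMention("OPDIVO", role="PS", therapy_start="20200210"),
                DrugMention("YERVOY", role="SS", therapy_start="20200110"),
                DrugMention("ACETAMINOPHEN", role="C", therapy_start="20190101"),
            ],
        )
        label = classify_exposure(rep)
        assert compute_tto(rep, label).days == 51  # from the ipilimumab start

    def test_no_dated_suspect_ici_is_missing(self):
        rep = make_report(
            event_date="20200301",
            drugs=[DrugMention("OPDIVO", role="PS", therapy_start=None)],
        )
        assert compute_tto(rep, classify_exposure(rep)) is None


class TestBinsAndRounding:
    @pytest.mark.parametrize(
        "days,expected",
        [(1, "<=28"), (28, "<=28"), (29, "29-56"), (56, "29-56"), (57, "57-84"),
         (84, "57-84"), (85, ">84"), (914, ">84"), (None, "missing")],
    )
    def test_tto_bins(self, days, expected):
        assert tto_bin(days) == expected

    @pytest.mark.parametrize(
        "age,expected",
        [(17.9, "<18"), (18, "18-44"), (44.9, "18-44"), (45, "45-64"),
         (64.9, "45-64"), (65, "65-74"), (75, ">=75"), (None, "unknown")],
    )
    def test_age_bins(self, age, expected):
        assert age_bin(age) == expected

    @pytest.mark.parametrize(
        "num,den,expected",
        [(382, 654, 58.41), (218, 654, 33.33), (37, 296, 12.50),
         (449, 654, 68.65), (126, 132, 95.45), (1, 3, 33.33), (0, 10, 0.00)],
    )
    def test_percent_half_up_two_decimals(self, num, den, expected):
        assert percent(num, den) == expected

    def test_percent_zero_denominator_is_nan(self):
        assert math.isnan(percent(1, 0))


class TestSummarize:
    def test_single_case_percentages_are_100(self, table1_cases):
        s = summarize(table1_cases.iloc[:1])
        for section in ("gender", "region", "outcome"):
            df = s.section(section)
            nonzero = df[df["count"] > 0]
            assert (nonzero["pct"] == 100.00).all()

    def test_empty_input_gives_empty_summary(self, table1_cases):
        s = summarize(table1_cases.iloc[:0])
        assert s.total == 0 and not s.sections

    def test_category_counts_sum_to_total(self, table1_cases):
        s = summarize(table1_cases)
        for section in ("gender", "age", "region", "year", "reporter", "outcome",
                        "n_concomitant"):
            assert s.section(section)["count"].sum() == s.total, section

    def test_tto_percentages_use_nonmissing_denominator(self, table1_cases):
        s = summarize(table1_cases)
        df = s.section("tto").set_index("level")
        known = df.drop(index="missing")["count"].sum()
        assert known == 296
        assert df.loc["<=28", "pct"] == percent(df.loc["<=28", "count"], known)

    def test_median_and_range_match_sort_oracle(self, table1_cases):
        s = summarize(table1_cases)
        tto = sorted(table1_cases["tto_days"].dropna())
        n = len(tto)
        oracle_median = (tto[n // 2 - 1] + tto[n // 2]) / 2 if n % 2 == 0 else tto[n // 2]
        assert s.medians["tto"] == (oracle_median, tto[0], tto[-1])


class TestFatality:
    def test_zero_deaths(self, table1_cases):
        alive = table1_cases[~table1_cases["died"]].iloc[:10]
        assert fatality_proportion(alive).proportion == 0.00

    def test_empty_not_computable(self, table1_cases):
        with pytest.raises(ValueError):
            fatality_proportion(table1_cases.iloc[:0])

    def test_equals_brute_force_and_order_invariant(self, table1_cases):
        res = fatality_proportion(table1_cases)
        brute = sum("DE" in o for o in table1_cases["outcomes"])
        assert res.deaths == brute
        shuffled = table1_cases.sample(frac=1.0, random_state=5)
        res2 = fatality_proportion(shuffled)
        assert (res2.deaths, res2.total, res2.proportion) == (
            res.deaths, res.total, res.proportion,
        )


def _kw_h_oracle(groups):
    """Brute-force Kruskal-Wallis H with tie correction via mid-ranks."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie


class TestKruskalWallis:
    def test_matches_rank_oracle(self):
        g1, g2 = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = kruskal_wallis_tto({"a": g1, "b": g2}, min_group_size=2)
        assert res.statistic == pytest.approx(_kw_h_oracle([g1, g2]), abs=1e-10)

    def test_matches_oracle_with_ties_three_groups(self):
        rng = np.random.default_rng(3)
        groups = [rng.integers(1, 20, size=30).astype(float) for _ in range(3)]
        res = kruskal_wallis_tto(dict(zip("abc", groups)))
        assert res.statistic == pytest.approx(_kw_h_oracle(groups), abs=1e-9)
        assert res.pvalue == pytest.approx(
            stats.chi2.sf(res.statistic, df=2), abs=1e-12
        )
        assert len(res.pairwise) == 3
        assert set(res.pairwise.columns) == {"group1", "group2", "H", "p", "p_holm"}

    def test_small_groups_excluded(self):
        res = kruskal_wallis_tto({"a": range(50), "b": range(50), "tiny": [1, 2]})
        assert res.groups == ["a", "b"]

    def test_fewer_than_two_groups_not_computable(self):
        assert kruskal_wallis_tto({"a": range(50)}) is None
        assert kruskal_wallis_tto({"a": [1], "b": [2]}) is None

    def test_all_identical_observations_degenerate(self):
        res = kruskal_wallis_tto({"a": [5.0] * 30, "b": [5.0] * 30})
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_type_one_error_calibrated(self):
        """Two groups from one distribution: ~5% rejections at alpha=0.05."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            g1 = rng.lognormal(3.6, 1.0, size=50)
            g2 = rng.lognormal(3.6, 1.0, size=50)
            res = kruskal_wallis_tto({"a": g1, "b": g2})
            rejections += res.pvalue < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_holm_matches_independent_implementation(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        pvals = [0.01, 0.04, 0.03, 0.2, 0.9]
        expected = sm.multipletests(pvals, method="holm")[1]
        assert _holm(pvals) == pytest.approx(expected)


class TestChisqFatality:
    def test_homogeneous_table_is_null(self):
        res = chisq_fatality({"a": (10, 21), "b": (10, 21)})
        # identical proportions: statistic ~ 0
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_pearson_oracle(self):
        data = {"a": (30, 100), "b": (45, 90), "c": (10, 60)}
        res = chisq_fatality(data)
        table = np.array([[k, n - k] for k, n in data.values()], dtype=float)
        expected = table.sum(1)[:, None] * table.sum(0)[None, :] / table.sum()
        x2 = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(x2, abs=1e-10)
        assert res.df == 2

    def test_extreme_difference_is_significant(self):
        res = chisq_fatality({"a": (50, 50), "b": (0, 50)})
        assert res.pvalue < 0.001

    def test_small_drugs_excluded_and_low_expected_flagged(self):
        res = chisq_fatality({"a": (0, 25), "b": (1, 25), "tiny": (9, 10)})
        assert res.drugs == ("a", "b")
        assert res.low_expected  # expected deaths 1 per arm, survivors fine
        assert chisq_fatality({"a": (5, 25)}) is None
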