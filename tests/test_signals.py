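"""ROR/IC statistics, 2x2 construction for the four designs, signal rule."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.signals import (
    ContingencyTable,
    DisproportionalityModel,
    build_table,
    compute_ic,
    compute_ror,
    drug_vs_drug_ror,
    evaluate_signal,
    reconstruct_two_by_two,
    signal_from_table,
    subgroup_ror,
)

cells = st.integers(min_value=1, max_value=5000)


def _case_frame(rows):
    """Minimal analysis frame: (is_event, regimen, regimen_key, substances,
    classes, concomitants, sex, age)."""
    recs = []
    for i, (event, regimen, key, subs, conc, sex, age) in enumerate(rows):
        classes = frozenset()
        recs.append(
            {
                "case_id": str(i),
                "is_event": event,
                "regimen": regimen,
                "regimen_key": key,
                "substances": frozenset(subs),
                "classes": classes,
                "concomitants": frozenset(conc),
                "n_concomitant": len(conc),
                "sex": sex,
                "age_years": age,
            }
        )
    return pd.DataFrame(recs)


def _bulk(n, **kw):
    defaults = dict(
        event=False, regimen="none", key="none", subs=(), conc=(), sex="male", age=50.0
    )
    defaults.update(kw)
    return [
        (
            defaults["event"],
            defaults["regimen"],
            defaults["key"],
            defaults["subs"],
            defaults["conc"],
            defaults["sex"],
            defaults["age"],
        )
    ] * n


class TestComputeRor:
    def test_independence_gives_one(self):
        t = ContingencyTable(5, 50, 10, 100)
        assert compute_ror(t).ror == pytest.approx(1.0)

    def test_worked_example_with_wald_interval(self):
        t = ContingencyTable(5, 95, 10, 890)
        est = compute_ror(t)
        assert est.ror == pytest.approx(4.684, abs=0.001)
        assert est.low == pytest.approx(1.57, abs=0.005)
        assert est.high == pytest.approx(13.99, abs=0.005)

    def test_zero_cell_triggers_haldane_anscombe(self):
        t = ContingencyTable(0, 100, 10, 890)
        est = compute_ror(t)
        assert est.corrected
        assert math.isfinite(est.ror) and est.ror > 0

    def test_empty_margin_not_computable(self):
        est = compute_ror(ContingencyTable(0, 0, 10, 890))
        assert not est.computable
        assert math.isnan(est.ror)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_interval_contains_point(self, a, b, c, d):
        est = compute_ror(ContingencyTable(a, b, c, d))
        assert est.low <= est.ror <= est.high

    def test_matches_cross_product_oracle_on_1000_random_tables(self):
        rng = np.random.default_rng(42)
        tables = rng.integers(1, 10_000, size=(1000, 4))
        for a, b, c, d in tables:
            est = compute_ror(ContingencyTable(int(a), int(b), int(c), int(d)))
            oracle = (a * d) / (b * c)
            assert abs(est.ror - oracle) <= 1e-10 * oracle

    def test_matches_independent_epidemiology_oracle(self):
        # statsmodels' Table2x2 is an independent OR/CI implementation
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        for a, b, c, d in rng.integers(2, 2000, size=(25, 4)):
            est = compute_ror(ContingencyTable(int(a), int(b), int(c), int(d)))
            t22 = sm.stats.Table2x2(np.array([[a, b], [c, d]]))
            low, high = t22.oddsratio_confint(0.05)
            assert est.ror == pytest.approx(t22.oddsratio, rel=1e-10)
            assert est.low == pytest.approx(low, rel=1e-9)
            assert est.high == pytest.approx(high, rel=1e-9)


class TestComputeIc:
    def test_zero_when_observed_equals_expected(self):
        # a = (a+b)(a+c)/N exactly
        est = compute_ic(ContingencyTable(10, 90, 90, 810))
        assert est.ic == 0.0
        assert est.expected == pytest.approx(10.0)

    def test_worked_example_gamma_bounds(self):
        est = compute_ic(ContingencyTable(5, 95, 10, 890))
        assert est.expected == pytest.approx(1.5)
        assert est.ic == pytest.approx(math.log2(5.5 / 2.0), abs=1e-12)
        assert est.ic == pytest.approx(1.459, abs=0.001)
        # frozen from an independent Gamma-quantile computation
        assert est.low == pytest.approx(-0.068, abs=0.001)

    def test_zero_count_is_finite_negative(self):
        est = compute_ic(ContingencyTable(0, 100, 10, 890))
        assert est.ic < 0
        assert math.isfinite(est.ic) and math.isfinite(est.low)

    def test_approx_variant_brackets_point(self):
        t = ContingencyTable(50, 950, 100, 8900)
        gamma = compute_ic(t, method="gamma")
        approx = compute_ic(t, method="approx")
        assert gamma.ic == approx.ic
        for est in (gamma, approx):
            assert est.low < est.ic < est.high

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            compute_ic(ContingencyTable(1, 1, 1, 1), method="bogus")

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_interval_contains_point(self, a, b, c, d):
        est = compute_ic(ContingencyTable(a, b, c, d))
        assert est.low <= est.ic <= est.high


class TestInvariants:
    @given(a=cells, b=cells, c=cells, d=cells, k=st.integers(2, 9))
    @settings(max_examples=100, deadline=None)
    def test_scaling_non_event_margins(self, a, b, c, d, k):
        """Multiplying b and d by k leaves the ROR unchanged; the IC moves
        only through the expected count."""
        base = ContingencyTable(a, b, c, d)
        scaled = ContingencyTable(a, b * k, c, d * k)
        assert compute_ror(scaled).ror == pytest.approx(compute_ror(base).ror, rel=1e-12)
        ic0, ic1 = compute_ic(base), compute_ic(scaled)
        # same a, so the IC difference is exactly the shift in log2(E + 0.5)
        assert ic1.ic - ic0.ic == pytest.approx(
            math.log2((ic0.expected + 0.5) / (ic1.expected + 0.5)), abs=1e-9
        )

    @given(
        a=st.integers(2, 80),
        n_drug=st.integers(100, 1000),
        n_event=st.integers(100, 1000),
        extra=st.integers(2000, 100_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_observed_count_at_fixed_margins(
        self, a, n_drug, n_event, extra
    ):
        """With the drug, event and grand totals held fixed, a larger
        observed count a strictly increases both ROR and IC."""
        n_total = n_drug + n_event + extra

        def table(a_):
            return ContingencyTable(
                a_, n_drug - a_, n_event - a_, n_total - n_drug - n_event + a_
            )

        lo, hi = table(a - 1), table(a)
        assert compute_ror(hi).ror > compute_ror(lo).ror
        assert compute_ic(hi).ic > compute_ic(lo).ic

    @given(
        a=st.integers(1, 30),
        b=st.integers(1000, 50_000),
        c=st.integers(1, 300),
        d=st.integers(100_000, 500_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_ic_sign_tracks_log_ror_for_rare_events(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ror = compute_ror(t).ror
        ic = compute_ic(t).ic
        if abs(math.log(ror)) > 0.2:  # away from the boundary
            assert (ic > 0) == (math.log(ror) > 0)


class TestEvaluateSignal:
    def test_truth_table_exhaustive(self):
        for n, ror_low, ic_low in itertools.product(
            [0, 1, 2, 3, 10], [0.5, 1.0, 1.001, 5.0], [-0.5, 0.0, 0.001, 2.0]
        ):
            expected = (ror_low > 1 and n >= 3) or (ic_low > 0)
            assert evaluate_signal(n, ror_low, ic_low) == expected

    def test_published_headline_flags(self):
        assert evaluate_signal(654, 2.70, 1.39)
        assert not evaluate_signal(2, 5.0, -0.1)
        assert evaluate_signal(3, 1.001, -0.5)

    def test_nan_bounds_never_signal(self):
        assert not evaluate_signal(100, float("nan"), float("nan"))


class TestBuildTable:
    def test_combo_vs_mono_partition(self):
        rows = (
            _bulk(3, event=True, regimen="combination", key="ipilimumab+nivolumab",
                  subs=("nivolumab", "ipilimumab"))
            + _bulk(7, event=False, regimen="combination", key="ipilimumab+nivolumab",
                    subs=("nivolumab", "ipilimumab"))
            + _bulk(4, event=True, regimen="monotherapy", key="nivolumab",
                    subs=("nivolumab",))
            + _bulk(36, event=False, regimen="monotherapy", key="nivolumab",
                    subs=("nivolumab",))
        )
        t = build_table(
            _case_frame(rows), "combo_vs_mono", ("ipilimumab+nivolumab", "nivolumab")
        )
        assert (t.a, t.b, t.c, t.d) == (3, 7, 4, 36)

    def test_empty_target_flagged_not_raised(self):
        rows = _bulk(5, event=True) + _bulk(5)
        t = build_table(_case_frame(rows), "mono_vs_all", "nivolumab")
        assert t.a == 0 and t.b == 0
        assert "empty_target" in t.flags

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError):
            build_table(_case_frame(_bulk(2, event=True)), "bogus", "x")

    def test_cells_equal_brute_force_intersections(self):
        rng = np.random.default_rng(11)
        rows = []
        for _ in range(500):
            exposed = rng.random() < 0.3
            combo = exposed and rng.random() < 0.3
            subs = ("nivolumab", "ipilimumab") if combo else (("nivolumab",) if exposed else ())
            regimen = "combination" if combo else ("monotherapy" if exposed else "none")
            key = "ipilimumab+nivolumab" if combo else ("nivolumab" if exposed else "none")
            conc = ("ACETAMINOPHEN",) if (exposed and rng.random() < 0.4) else ()
            rows.append(
                (bool(rng.random() < 0.2), regimen, key, subs, conc, "male", 50.0)
            )
        frame = _case_frame(rows)
        event = {i for i, r in enumerate(rows) if r[0]}
        exposed = {i for i, r in enumerate(rows) if r[3]}
        mono = {i for i, r in enumerate(rows) if r[1] == "monotherapy"}
        with_agent = {i for i, r in enumerate(rows) if "ACETAMINOPHEN" in r[4]}

        t = build_table(frame, "class_vs_all", "any")
        assert t.a == len(exposed & event)
        assert t.b == len(exposed - event)
        assert t.c == len(event - exposed)
        assert t.d == 500 - len(exposed | event)

        t4 = build_table(frame, "ici_plus_agent_vs_mono", "ACETAMINOPHEN")
        assert t4.a == len(exposed & with_agent & event)
        assert t4.b == len((exposed & with_agent) - event)
        assert t4.c == len((mono - with_agent) & event)
        assert t4.d == len((mono - with_agent) - event)


class TestSubgroupAndHeadToHead:
    def test_age_subgroup_worked_example(self):
        rows = (
            _bulk(30, event=True, regimen="monotherapy", key="n", subs=("nivolumab",), age=50.0)
            + _bulk(970, regimen="monotherapy", key="n", subs=("nivolumab",), age=50.0)
            + _bulk(25, event=True, regimen="monotherapy", key="n", subs=("nivolumab",), age=70.0)
            + _bulk(1085, regimen="monotherapy", key="n", subs=("nivolumab",), age=70.0)
        )
        res = subgroup_ror(_case_frame(rows), "age")
        assert res.ror == pytest.approx(1.342, abs=0.001)
        assert math.isnan(res.ic)

    def test_identical_rates_give_unit_ror(self):
        rows = (
            _bulk(10, event=True, regimen="monotherapy", key="n", subs=("n",), sex="female")
            + _bulk(90, regimen="monotherapy", key="n", subs=("n",), sex="female")
            + _bulk(20, event=True, regimen="monotherapy", key="n", subs=("n",), sex="male")
            + _bulk(180, regimen="monotherapy", key="n", subs=("n",), sex="male")
        )
        assert subgroup_ror(_case_frame(rows), "sex").ror == pytest.approx(1.0)

    def test_empty_stratum_flagged(self):
        rows = _bulk(10, event=True, regimen="monotherapy", key="n", subs=("n",), sex="male")
        res = subgroup_ror(_case_frame(rows), "sex")
        assert not res.computable

    def test_drug_vs_drug_worked_example(self):
        rows = (
            _bulk(12, event=True, regimen="combination", key="combo", subs=("a", "b"))
            + _bulk(188, regimen="combination", key="combo", subs=("a", "b"))
            + _bulk(30, event=True, regimen="monotherapy", key="mono", subs=("a",))
            + _bulk(970, regimen="monotherapy", key="mono", subs=("a",))
        )
        res = drug_vs_drug_ror(_case_frame(rows), "combo", "mono")
        assert res.ror == pytest.approx(2.064, abs=0.001)

    def test_identical_regimens_rejected(self):
        frame = _case_frame(_bulk(5, event=True, regimen="monotherapy", key="n", subs=("n",)))
        with pytest.raises(ValueError, match="overlap"):
            drug_vs_drug_ror(frame, "n", "n")

    def test_zero_event_comparator_corrected(self):
        rows = (
            _bulk(3, event=True, regimen="combination", key="c", subs=("a", "b"))
            + _bulk(7, regimen="combination", key="c", subs=("a", "b"))
            + _bulk(50, regimen="monotherapy", key="m", subs=("a",))
        )
        res = drug_vs_drug_ror(_case_frame(rows), "c", "m")
        assert res.corrected
        assert math.isfinite(res.ror)


class TestReconstruction:
    def test_published_margins_recover_full_table(self):
        t = reconstruct_two_by_two(654, 18_454, 9_647_655, 2.92)
        assert (t.a, t.c) == (654, 17_800)
        assert t.b == 119_656
        assert t.n_total == 9_647_655

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_two_by_two(20, 10, 1000, 2.0)


class TestModelResults:
    def test_fit_enumerates_designs_and_produces_frame(self, table1_cases):
        res = DisproportionalityModel(table1_cases, top_k=3).fit()
        df = res.frame
        assert set(df["design"]) == {
            "class_vs_all",
            "mono_vs_all",
            "combo_vs_mono",
            "ici_plus_agent_vs_mono",
        }
        # every enumerated contrast carries the full output schema
        for col in ("a", "ROR", "ROR025", "IC025", "signal"):
            assert col in df.columns
        assert len(res.subgroups) == 2
        assert "Disproportionality screen" in res.summary()

    def test_results_csv_roundtrip(self, table1_cases, tmp_path):
        res = DisproportionalityModel(table1_cases, top_k=2).fit()
        paths = res.to_csv(tmp_path)
        for p in paths.values():
            assert p.exists()
        df = pd.read_csv(paths["mono_vs_all"])
        assert (df["design"] == "mono_vs_all").all()

    def test_invalid_parameters_rejected(self, table1_cases):
        with pytest.raises(ValueError):
            DisproportionalityModel(table1_cases, designs=["bogus"])
        with pytest.raises(ValueError):
            DisproportionalityModel(table1_cases, alpha=1.5)
        with pytest.raises(ValueError):
            DisproportionalityModel(table1_cases, top_k=0)
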