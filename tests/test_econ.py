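"""Drug costing, accumulation, incremental analysis, dominance, frontier."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hccea import (AdverseEvent, CEResult, CohortTrace, DoseRule,
                   DrugComponent, ModelSettings, Schedule, SecondLineSpec,
                   StrategySpec, UtilitySet, accumulate, cycle_drug_cost,
                   frontier, incremental_vs_reference, net_monetary_benefit)

DEFAULTS = ModelSettings()
EMPTY_SECOND_LINE = SecondLineSpec(components=())


def _strategy(name="s", components=(), **kw):
    return StrategySpec(name=name, regimen=tuple(components), **kw)


def _component(mg, price, kind="per_day", times=1, weeks=3.0,
               basis="per_mg"):
    return DrugComponent("d", DoseRule("fixed", mg=mg),
                         Schedule(kind, times_per_day=times, weeks=weeks),
                         price, basis)


class TestCycleDrugCost:
    def test_fixed_twice_daily(self):
        s = _strategy(components=[_component(100, 1.0, times=2)])
        assert cycle_drug_cost(s, DEFAULTS) == pytest.approx(4200.0)

    def test_per_kg_every_three_weeks(self):
        c = DrugComponent("d", DoseRule("per_kg", mg_per_kg=15),
                          Schedule("every_k_weeks", weeks=3), 1.0)
        s = _strategy(components=[c])
        assert cycle_drug_cost(s, DEFAULTS, body_weight_kg=60) == \
            pytest.approx(900.0)

    def test_every_two_weeks_is_1_5_admins(self):
        c = DrugComponent("d", DoseRule("fixed", mg=200),
                          Schedule("every_k_weeks", weeks=2), 1.0,
                          "per_admin")
        s = _strategy(components=[c])
        assert cycle_drug_cost(s, DEFAULTS) == pytest.approx(1.5)

    def test_zero_price_regimen(self):
        s = _strategy(components=[_component(500, 0.0)])
        assert cycle_drug_cost(s, DEFAULTS) == 0.0

    def test_weight_threshold_rule(self):
        dose = DoseRule("weight_threshold", threshold_kg=60,
                        mg_below=8, mg_at_or_above=12)
        c = DrugComponent("d", dose, Schedule("per_day"), 1.0)
        s = _strategy(components=[c])
        assert cycle_drug_cost(s, DEFAULTS, body_weight_kg=59) == \
            pytest.approx(8 * 21)
        assert cycle_drug_cost(s, DEFAULTS, body_weight_kg=60) == \
            pytest.approx(12 * 21)

    def test_unknown_schedule_rejected(self):
        c = DrugComponent("d", DoseRule("fixed", mg=1),
                          Schedule("weekly-ish"), 1.0)
        with pytest.raises(ValueError, match="schedule"):
            cycle_drug_cost(_strategy(components=[c]), DEFAULTS)


def _manual_trace(pfs, pd_, strategy="x"):
    pfs = np.asarray(pfs, dtype=float)
    pd_ = np.asarray(pd_, dtype=float)
    return CohortTrace(t_months=np.arange(pfs.size) * DEFAULTS.cycle_months,
                       occ_pfs=pfs, occ_pd=pd_,
                       occ_dead=1.0 - pfs - pd_, strategy=strategy)


class TestAccumulate:
    def test_single_cycle_qaly_hand_computed(self):
        settings = ModelSettings(horizon_years=21.0 / 365.25)
        tr = _manual_trace([1.0], [0.0])
        s = _strategy()
        res = accumulate(tr, s, EMPTY_SECOND_LINE, UtilitySet(0.76, 0.68),
                         settings)
        assert res.qaly == pytest.approx(0.76 * 21.0 / 365.25, rel=1e-9)

    def test_everyone_dead_after_cycle_zero_costs_one_cycle(self):
        tr = _manual_trace([1.0] + [0.0] * 9, [0.0] * 10)
        s = _strategy(components=[_component(100, 1.0)],
                      testing_cost_per_cycle=50.0)
        res = accumulate(tr, s, EMPTY_SECOND_LINE, UtilitySet(), DEFAULTS)
        assert res.total_cost == pytest.approx(100 * 21 + 50)

    def test_unit_utilities_no_discount_make_qaly_equal_ly(self):
        settings = ModelSettings(discount_rate_annual=0.0)
        tr = _manual_trace([1.0, 0.8, 0.5], [0.0, 0.1, 0.2])
        res = accumulate(tr, _strategy(), EMPTY_SECOND_LINE,
                         UtilitySet(1.0, 1.0), settings)
        assert res.qaly == pytest.approx(res.ly)

    def test_ae_burden_applied_once(self):
        tr = _manual_trace([1.0, 1.0], [0.0, 0.0])
        ae = AdverseEvent("g3", incidence=0.5, cost=1000.0, disutility=0.1)
        with_ae = accumulate(tr, _strategy(ae_events=(ae,)),
                             EMPTY_SECOND_LINE, UtilitySet(), DEFAULTS)
        without = accumulate(tr, _strategy(), EMPTY_SECOND_LINE,
                             UtilitySet(), DEFAULTS)
        assert with_ae.total_cost - without.total_cost == pytest.approx(500.0)
        assert without.qaly - with_ae.qaly == pytest.approx(0.05)

    def test_second_line_accrues_on_pd_occupancy(self):
        tr = _manual_trace([1.0, 0.0], [0.0, 0.5])
        second = SecondLineSpec(components=(_component(250, 0.06),))
        res = accumulate(tr, _strategy(), second, UtilitySet(), DEFAULTS)
        expected = 0.5 * 250 * 0.06 * 21 * (1.05 ** (-21 / 365.25))
        assert res.total_cost == pytest.approx(expected)

    def test_qaly_never_exceeds_ly(self):
        tr = _manual_trace([1.0, 0.7, 0.4, 0.2], [0.0, 0.2, 0.3, 0.3])
        res = accumulate(tr, _strategy(), EMPTY_SECOND_LINE,
                         UtilitySet(0.76, 0.68), DEFAULTS)
        assert res.qaly <= res.ly


# printed base-case table: total cost and QALYs per strategy vs sorafenib
TABLE2 = {
    "sorafenib": (9070, 0.25),
    "sunitinib": (9362, 0.78),
    "donafenib": (33814, 0.45),
    "lenvatinib": (49120, 0.83),
    "sorafenib_plus_erlotinib": (63064, 0.81),
    "linifanib": (74814, 0.82),
    "brivanib": (81995, 0.82),
    "sintilimab_plus_ibi305": (74083, 0.85),
    "atezolizumab_plus_bevacizumab": (104188, 0.84),
}


def table2_results():
    return [CEResult(strategy=k, total_cost=c, ly=q + 0.1, qaly=q)
            for k, (c, q) in TABLE2.items()]


class TestIncrementalVsReference:
    def test_published_sunitinib_row(self):
        df = incremental_vs_reference(table2_results(), "sorafenib")
        row = df.set_index("strategy").loc["sunitinib"]
        assert row["incrC"] == 292
        assert row["incrE"] == pytest.approx(0.53)
        assert row["ICER"] == 551

    def test_all_incremental_costs_match_published(self):
        df = incremental_vs_reference(table2_results(), "sorafenib")
        expected = {"sunitinib": 292, "donafenib": 24744, "lenvatinib": 40050,
                    "sorafenib_plus_erlotinib": 53994, "linifanib": 65744,
                    "brivanib": 72925, "sintilimab_plus_ibi305": 65013,
                    "atezolizumab_plus_bevacizumab": 95118}
        got = df.set_index("strategy")["incrC"].dropna().astype(int).to_dict()
        assert got == expected

    def test_identical_strategies_have_undefined_icer(self):
        res = [CEResult("a", 100.0, 1.0, 0.5), CEResult("b", 100.0, 1.0, 0.5)]
        df = incremental_vs_reference(res, "a")
        row = df.set_index("strategy").loc["b"]
        assert row["incrC"] == 0 and np.isnan(row["ICER"])

    def test_cheaper_and_better_flagged_dominant(self):
        res = [CEResult("ref", 100.0, 1.0, 0.5), CEResult("b", 80.0, 2.0, 0.9)]
        df = incremental_vs_reference(res, "ref")
        assert df.set_index("strategy").loc["b", "note"] == "dominant"

    def test_worse_and_costlier_flagged_dominated(self):
        res = [CEResult("ref", 100.0, 1.0, 0.5), CEResult("b", 120.0, 0.9, 0.4)]
        df = incremental_vs_reference(res, "ref")
        assert "dominated" in df.set_index("strategy").loc["b", "note"]

    def test_duplicate_names_rejected(self):
        res = [CEResult("a", 1.0, 1.0, 0.5), CEResult("a", 2.0, 1.0, 0.6)]
        with pytest.raises(ValueError, match="duplicate"):
            incremental_vs_reference(res, "a")


class TestFrontier:
    def test_published_oral_tki_dominance(self):
        tki = ["sorafenib", "sunitinib", "donafenib", "lenvatinib",
               "sorafenib_plus_erlotinib", "linifanib", "brivanib"]
        res = [CEResult(k, *map(float, (TABLE2[k][0],)), ly=1.0,
                        qaly=TABLE2[k][1]) for k in tki]
        df = frontier(res).set_index("strategy")
        assert df.loc["donafenib", "dominance"] == "dominated"

    def test_published_ici_dominance(self):
        res = [CEResult("sintilimab_plus_ibi305", 74083.0, 1.0, 0.85),
               CEResult("atezolizumab_plus_bevacizumab", 104188.0, 1.0, 0.84)]
        df = frontier(res).set_index("strategy")
        assert df.loc["atezolizumab_plus_bevacizumab",
                      "dominance"] == "dominated"
        assert df.loc["sintilimab_plus_ibi305", "dominance"] == "none"

    def test_collinear_middle_strategy_retained(self):
        # equal sequential ICERs: no strict extended dominance
        res = [CEResult("a", 0.0, 1.0, 0.0), CEResult("b", 100.0, 1.0, 0.1),
               CEResult("c", 200.0, 1.0, 0.2)]
        df = frontier(res)
        assert list(df["dominance"]) == ["none"] * 3

    def test_extended_dominance_removed(self):
        # b's ICER vs a (1000) exceeds c's ICER vs b (200): b is
        # extendedly dominated
        res = [CEResult("a", 0.0, 1.0, 0.0), CEResult("b", 100.0, 1.0, 0.1),
               CEResult("c", 120.0, 1.0, 0.2)]
        df = frontier(res).set_index("strategy")
        assert df.loc["b", "dominance"] == "extended-dominated"
        assert df.loc["c", "ICER"] == round(120 / 0.2)

    @given(st.lists(st.tuples(st.floats(0, 1e5), st.floats(0, 3)),
                    min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_frontier_is_monotone_and_stable(self, pts):
        res = [CEResult(f"s{i}", c, 3.0, q) for i, (c, q) in enumerate(pts)]
        df = frontier(res)
        on = df[df["dominance"] == "none"]
        assert np.all(np.diff(on["cost"]) >= 0)
        assert np.all(np.diff(on["QALY"]) >= -1e-12)
        icers = on["ICER"].dropna().to_numpy()
        assert np.all(np.diff(icers) >= -1e-6)
        # removing a dominated strategy never changes the frontier set
        dom = df[df["dominance"] != "none"]["strategy"]
        if len(dom) and len(res) - 1 >= 2:
            res2 = [r for r in res if r.strategy != dom.iloc[0]]
            df2 = frontier(res2)
            assert set(df2[df2["dominance"] == "none"]["strategy"]) == \
                set(on["strategy"])


class TestNMB:
    def test_zero_wtp_is_negative_cost(self):
        r = CEResult("a", 123.0, 1.0, 0.5)
        assert net_monetary_benefit(r, 0.0) == -123.0

    def test_threshold_value(self):
        r = CEResult("a", 0.0, 1.5, 1.0)
        assert net_monetary_benefit(r, 37654.50) == pytest.approx(37654.50)

    @given(st.floats(10, 1e5), st.floats(10, 1e5),
           st.floats(0.1, 3), st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_nmb_ordering_flips_at_icer(self, c1, dc, q1, dq):
        a = CEResult("a", c1, 5.0, q1)
        b = CEResult("b", c1 + dc, 5.0, q1 + dq)
        icer = dc / dq
        for wtp, better in [(icer * 0.5, "a"), (icer * 2.0, "b")]:
            nmb_a = net_monetary_benefit(a, wtp)
            nmb_b = net_monetary_benefit(b, wtp)
            assert (nmb_b > nmb_a) == (better == "b")
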