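"""RAM construction and application: annualization, shared-resource
apportionment, normalization, scale invariance, conservation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rems.config import RunConfig
from rems.org_model import Quarter, ValidationError
from rems.ram import (
    AssessmentLineItem,
    BudgetLine,
    OperationalBudget,
    RAM,
    ServiceSchedule,
    allocate_all,
    allocate_ram,
    apportion_shared,
    build_budget,
    compute_ram,
    cost_line,
)
from rems.step_down import FacilityInflow

Q1 = Quarter(2016, 1)


def item(category, qty, unit_cost, service="HTC", life=None, fac="F1"):
    return AssessmentLineItem(fac, f"i-{category}-{service}", "", category, qty, unit_cost,
                              service, life)


class TestCostLine:
    def test_recurrent_is_quantity_times_unit_cost(self):
        assert cost_line(item("supplies", 1200, 2.5)) == 3000.0

    def test_equipment_annualized_straight_line(self):
        assert cost_line(item("equipment", 1, 5000, life=5)) == 1000.0

    def test_zero_quantity_is_free(self):
        assert cost_line(item("drugs", 0, 99.0)) == 0.0

    def test_capital_default_life_from_config(self):
        # equipment defaults to 5 years, vehicles to 8
        assert cost_line(item("equipment", 1, 1000)) == 200.0
        assert cost_line(item("vehicles", 1, 800)) == 100.0


class TestApportionShared:
    def test_proportional_to_session_weighted_volume(self):
        rows = [
            ServiceSchedule("F1", "A", sessions_per_week=1, relative_annual_volume=300),
            ServiceSchedule("F1", "B", sessions_per_week=1, relative_annual_volume=100),
        ]
        assert apportion_shared(400.0, rows) == pytest.approx({"A": 300.0, "B": 100.0})

    def test_sessions_weight_the_split(self):
        rows = [
            ServiceSchedule("F1", "A", sessions_per_week=3, relative_annual_volume=100),
            ServiceSchedule("F1", "B", sessions_per_week=1, relative_annual_volume=100),
        ]
        assert apportion_shared(400.0, rows) == pytest.approx({"A": 300.0, "B": 100.0})

    def test_single_service_degenerate_split(self):
        rows = [ServiceSchedule("F1", "A", 5, relative_annual_volume=10)]
        assert apportion_shared(999.0, rows) == {"A": 999.0}

    def test_no_eligible_service_is_error(self):
        rows = [ServiceSchedule("F1", "A", 0, relative_annual_volume=0)]
        with pytest.raises(ValidationError):
            apportion_shared(1.0, rows)

    def test_shares_sum_to_line_cost(self):
        rows = [
            ServiceSchedule("F1", s, sessions_per_week=w, relative_annual_volume=v)
            for s, w, v in [("A", 2, 7), ("B", 3, 11), ("C", 5, 13)]
        ]
        split = apportion_shared(123.45, rows)
        assert sum(split.values()) == pytest.approx(123.45, rel=1e-12)


class TestComputeRam:
    def test_two_line_normalization(self):
        budget = OperationalBudget("F1", (
            BudgetLine("a", "personnel", "HTC", 5000.0),
            BudgetLine("b", "drugs", "ART", 15000.0),
        ))
        ram = compute_ram(budget)
        assert ram.weight("HTC", "personnel") == pytest.approx(0.25)
        assert ram.weight("ART", "drugs") == pytest.approx(0.75)

    def test_single_line_weight_is_one(self):
        ram = compute_ram(OperationalBudget("F1", (BudgetLine("a", "other", "HTC", 7.0),)))
        assert ram.weights == ((("HTC", "other"), 1.0),)

    def test_five_percent_personnel_htc_share(self):
        """A budget where personnel supporting HTC are 5% of the total gives
        that cell a weight of exactly 0.05."""
        budget = OperationalBudget("F1", (
            BudgetLine("a", "personnel", "HTC", 500.0),
            BudgetLine("b", "drugs", "ART", 9500.0),
        ))
        assert compute_ram(budget).weight("HTC", "personnel") == pytest.approx(0.05)

    def test_zero_total_budget_is_error(self):
        with pytest.raises(ValidationError, match="zero-total"):
            compute_ram(OperationalBudget("F1", ()))

    @given(st.lists(st.floats(0.01, 1e6), min_size=1, max_size=12),
           st.floats(0.001, 1e4))
    @settings(max_examples=200)
    def test_scale_invariance_and_normalization(self, costs, scale):
        services = ["HTC", "EMTCT", "ART"]
        cats = ["personnel", "drugs", "other"]
        lines = tuple(
            BudgetLine(f"i{k}", cats[k % 3], services[k % 3], c) for k, c in enumerate(costs)
        )
        scaled = tuple(
            BudgetLine(l.item_id, l.resource_category, l.service, l.annual_cost * scale)
            for l in lines
        )
        r1 = compute_ram(OperationalBudget("F1", lines))
        r2 = compute_ram(OperationalBudget("F1", scaled))
        assert sum(w for _, w in r1.weights) == pytest.approx(1.0, abs=1e-12)
        for (cell, w1), (cell2, w2) in zip(r1.weights, r2.weights):
            assert cell == cell2
            assert w1 == pytest.approx(w2, rel=1e-9)


class TestBuildBudget:
    def test_brute_force_per_line_equivalence(self):
        """Budget totals per (service, category) equal a per-line brute-force
        recomputation on a mixed dedicated/shared assessment."""
        rng = np.random.default_rng(5)
        cats = ["personnel", "drugs", "supplies"]
        services = ["HTC", "ART"]
        items = []
        for k in range(20):
            dedicated = services[k % 2] if k % 3 else "SHARED"
            items.append(
                AssessmentLineItem("F1", f"i{k}", "", cats[k % 3],
                                   float(rng.integers(1, 50)), float(rng.uniform(1, 40)),
                                   dedicated)
            )
        sched = [
            ServiceSchedule("F1", "HTC", 5, relative_annual_volume=120),
            ServiceSchedule("F1", "ART", 2, relative_annual_volume=300),
        ]
        budget = build_budget("F1", items, sched)
        # brute force over (line, service, category) triples
        w_htc = 5 * 120
        w_art = 2 * 300
        expect = {}
        for it in items:
            cost = it.annual_quantity * it.standard_unit_cost
            if it.dedicated_service != "SHARED":
                expect[(it.dedicated_service, it.resource_category)] = (
                    expect.get((it.dedicated_service, it.resource_category), 0.0) + cost)
            else:
                for svc, w in (("HTC", w_htc), ("ART", w_art)):
                    expect[(svc, it.resource_category)] = (
                        expect.get((svc, it.resource_category), 0.0)
                        + cost * w / (w_htc + w_art))
        got = {}
        for line in budget.lines:
            got[(line.service, line.resource_category)] = (
                got.get((line.service, line.resource_category), 0.0) + line.annual_cost)
        assert got.keys() == expect.keys()
        for cell, v in expect.items():
            assert got[cell] == pytest.approx(v, rel=1e-12)

    def test_shared_item_without_schedules_is_error(self):
        items = [item("personnel", 1, 100, service="SHARED")]
        with pytest.raises(ValidationError, match="no service schedules"):
            build_budget("F1", items, [])


class TestAllocateRam:
    def test_five_percent_of_each_kwacha(self):
        """A RAM whose personnel-for-HTC weight is 5% assigns 5% of any
        facility inflow to that cell."""
        ram = RAM("F1", ((("ART", "drugs"), 0.95), (("HTC", "personnel"), 0.05)))
        inflow = FacilityInflow("F1", Q1, 1000.0, "GRZ")
        cells = {(a.service, a.resource_category): a.amount for a in allocate_ram(inflow, ram)}
        assert cells[("HTC", "personnel")] == pytest.approx(50.0)

    def test_single_cell_identity(self):
        ram = RAM("F1", ((("HTC", "other"), 1.0),))
        (cell,) = allocate_ram(FacilityInflow("F1", Q1, 777.0), ram)
        assert cell.amount == 777.0

    def test_zero_inflow_zero_cells(self):
        ram = RAM("F1", ((("ART", "drugs"), 0.4), (("HTC", "personnel"), 0.6)))
        assert all(c.amount == 0.0 for c in allocate_ram(FacilityInflow("F1", Q1, 0.0), ram))

    def test_conservation_and_linearity(self):
        rng = np.random.default_rng(2)
        raw = rng.dirichlet(np.ones(6))
        cells = [("HTC", "personnel"), ("HTC", "drugs"), ("ART", "drugs"),
                 ("ART", "personnel"), ("EMTCT", "supplies"), ("EMTCT", "other")]
        ram = RAM("F1", tuple(zip(cells, (raw / raw.sum()).tolist())))
        for amount in (1.0, 12345.67):
            out = allocate_ram(FacilityInflow("F1", Q1, amount), ram)
            assert sum(c.amount for c in out) == pytest.approx(amount, abs=1e-6)
        a1 = allocate_ram(FacilityInflow("F1", Q1, 100.0), ram)
        a2 = allocate_ram(FacilityInflow("F1", Q1, 300.0), ram)
        for c1, c2 in zip(a1, a2):
            assert c2.amount == pytest.approx(3 * c1.amount, rel=1e-12)

    def test_missing_ram_lists_facilities(self):
        inflows = [FacilityInflow("F1", Q1, 10.0), FacilityInflow("F2", Q1, 10.0)]
        with pytest.raises(ValidationError) as err:
            allocate_all(inflows, {})
        assert "F1" in str(err.value) and "F2" in str(err.value)

    def test_facility_mismatch_rejected(self):
        ram = RAM("F1", ((("HTC", "other"), 1.0),))
        with pytest.raises(ValidationError, match="does not match"):
            allocate_ram(FacilityInflow("F2", Q1, 1.0), ram)


class TestRamInvariants:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            RAM("F1", ((("HTC", "personnel"), 0.5),))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            RAM("F1", ((("HTC", "personnel"), -0.5), (("ART", "drugs"), 1.5)))
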