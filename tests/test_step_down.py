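"""Step-down cascade: matching, HIV isolation, conservation, and equivalence
with a brute-force path-enumeration oracle."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rems.ledger_io import ExpenditureRecord
from rems.org_model import Quarter, ValidationError, parse_account, validate_hierarchy
from rems.step_down import (
    FlowDownRule,
    HivShareWeight,
    apply_hiv_share,
    cascade,
    isolate_hiv,
    match_weight,
)
from conftest import make_units

Q1 = Quarter(2016, 1)


def rec(account, unit, amount, quarter=Q1, source="GRZ"):
    return ExpenditureRecord(parse_account(account), unit, quarter, amount, source)


def pattern(text):
    return parse_account(text, full=False)


class TestMatchWeight:
    def test_most_specific_prefix_wins(self):
        weights = [
            HivShareWeight(pattern("01"), 0.1),
            HivShareWeight(pattern("01/02/03"), 0.5),
        ]
        assert match_weight(parse_account("01/02/03/04"), weights) == 0.5

    def test_no_match_falls_back_to_default(self):
        weights = [HivShareWeight(pattern("01"), 0.1)]
        assert match_weight(parse_account("02/01/01/01"), weights) == 0.0
        assert match_weight(parse_account("02/01/01/01"), weights, default=0.25) == 0.25

    def test_equally_specific_duplicate_patterns_rejected(self):
        weights = [
            HivShareWeight(pattern("01/02"), 0.3),
            HivShareWeight(pattern("01/02"), 0.4),
        ]
        with pytest.raises(ValidationError, match="ambiguous"):
            match_weight(parse_account("01/02/03/04"), weights)

    @pytest.mark.parametrize("amount,share,expected", [(1000, 0.25, 250), (1000, 0, 0), (1000, 1, 1000)])
    def test_apply_hiv_share_proportional(self, amount, share, expected):
        assert apply_hiv_share(rec("01/01/01/01", "NAT", amount), share) == expected

    def test_share_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            apply_hiv_share(rec("01/01/01/01", "NAT", 10), 1.5)


class TestFlowDownRule:
    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="expected 1"):
            FlowDownRule(pattern("01"), "NAT", 0.5, (("P1", 0.3),))

    def test_retention_only_rule_allowed(self):
        FlowDownRule(pattern("01"), "NAT", 1.0)  # no children needed


class TestCascade:
    def test_worked_two_province_example(self, hierarchy):
        """National 10,000: 20% retained, provinces 60/40, districts pass all
        through, facilities split equally -> frozen from the path oracle."""
        units = make_units(2, 1, 2)  # 2 provinces, 1 district each, 2 facilities
        h = validate_hierarchy(units)
        rules = [
            FlowDownRule(pattern("01"), "NAT", 0.2, (("P1", 0.48), ("P2", 0.32))),
            FlowDownRule(pattern("01"), "P1", 0.0, (("P1D1", 1.0),)),
            FlowDownRule(pattern("01"), "P2", 0.0, (("P2D1", 1.0),)),
            FlowDownRule(pattern("01"), "P1D1", 0.0, (("P1D1F1", 0.5), ("P1D1F2", 0.5))),
            FlowDownRule(pattern("01"), "P2D1", 0.0, (("P2D1F1", 0.5), ("P2D1F2", 0.5))),
        ]
        inflows, above = cascade([rec("01/01/01/01", "NAT", 10_000)], rules, h)
        assert {(a.org_unit, a.amount) for a in above} == {("NAT", 2000.0)}
        got = {i.facility: pytest.approx(i.amount) for i in inflows}
        assert got == {"P1D1F1": 2400.0, "P1D1F2": 2400.0, "P2D1F1": 1600.0, "P2D1F2": 1600.0}
        # provenance records the source account
        assert all(i.provenance == (("01/01/01/01", pytest.approx(i.amount)),) for i in inflows)

    def test_full_retention_absorbs_everything(self, hierarchy):
        rules = [FlowDownRule(pattern("01"), "NAT", 1.0)]
        inflows, above = cascade([rec("01/01/01/01", "NAT", 750)], rules, hierarchy)
        assert inflows == []
        assert [(a.org_unit, a.amount) for a in above] == [("NAT", 750.0)]

    def test_facility_account_passes_through(self, hierarchy):
        inflows, above = cascade([rec("01/01/01/01", "P1D1F1", 500)], [], hierarchy)
        assert above == []
        (i,) = inflows
        assert (i.facility, i.amount) == ("P1D1F1", 500.0)

    def test_missing_rules_reported_before_any_allocation(self, hierarchy):
        records = [
            rec("01/01/01/01", "NAT", 100),
            rec("02/01/01/01", "P1", 100),
        ]
        with pytest.raises(ValidationError) as err:
            cascade(records, [], hierarchy)
        text = "\n".join(err.value.violations)
        assert "01/01/01/01" in text and "02/01/01/01" in text

    def test_default_split_proportional_to_facility_count(self):
        # P1 has 1 district with 3 facilities; P2 has 1 district with 1 facility
        units = make_units(2, 1, 3)
        units = [u for u in units if not u.id.startswith("P2D1F") or u.id == "P2D1F1"]
        h = validate_hierarchy(units)
        rules = [FlowDownRule(pattern("01"), uid, 0.0) for uid in ("NAT", "P1", "P2", "P1D1", "P2D1")]
        inflows, above = cascade([rec("01/01/01/01", "NAT", 400)], rules, h)
        got = {i.facility: i.amount for i in inflows}
        assert got == pytest.approx(
            {"P1D1F1": 100.0, "P1D1F2": 100.0, "P1D1F3": 100.0, "P2D1F1": 100.0}
        )


# ---------------------------------------------------------------------------
# randomized conservation / linearity / oracle equivalence


def random_instance(rng, n_accounts=8, n_provinces=2, districts=2, facilities=3):
    units = make_units(n_provinces, districts, facilities)
    h = validate_hierarchy(units)
    non_facility = [u for u in units if u.level != "facility"]
    rules = []
    for u in non_facility:
        children = [c.id for c in h.children(u.id)]
        retained = float(rng.uniform(0, 0.5))
        raw = rng.dirichlet(np.ones(len(children)))
        shares = tuple((c, float((1 - retained) * s)) for c, s in zip(children, raw))
        rules.append(FlowDownRule(pattern("01"), u.id, retained, shares))
    records = []
    all_units = [u.id for u in units]
    for i in range(n_accounts):
        segs = f"01/{rng.integers(1, 4):02d}/{rng.integers(1, 4):02d}/{i:02d}"
        unit = all_units[int(rng.integers(0, len(all_units)))]
        records.append(rec(segs, unit, float(rng.uniform(10, 10_000))))
    # aggregate duplicate keys the way ingest would
    agg = {}
    for r in records:
        agg[r.key] = agg.get(r.key, 0.0) + r.amount
    records = [
        ExpenditureRecord(parse_account(k[0]), k[1], k[2], v, k[3]) for k, v in agg.items()
    ]
    return h, rules, records


def oracle_cascade(records, rules, h):
    """Independent re-implementation: enumerate every account->facility path
    and multiply fractions along it."""
    inflows, above = {}, {}

    def rules_for(account, unit):
        best, best_len = None, -1
        for r in rules:
            if r.source_unit == unit and r.account_pattern.is_prefix_of(account):
                if r.account_pattern.specificity > best_len:
                    best, best_len = r, r.account_pattern.specificity
        return best

    def walk(account, unit, fraction, record):
        if h.level(unit) == "facility":
            key = (unit, record.quarter, record.funding_source)
            inflows[key] = inflows.get(key, 0.0) + record.amount * fraction
            return
        rule = rules_for(account, unit)
        if rule.retained_share:
            key = (unit, record.quarter, record.funding_source)
            above[key] = above.get(key, 0.0) + record.amount * fraction * rule.retained_share
        for child, share in rule.child_shares:
            if share > 0:
                walk(account, child, fraction * share, record)

    for record in records:
        walk(record.account, record.org_unit, 1.0, record)
    return inflows, above


class TestCascadeProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_equals_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h, rules, records = random_instance(
            rng, n_accounts=50, n_provinces=2, districts=2, facilities=5
        )  # 20 facilities
        inflows, above = cascade(records, rules, h)
        o_inflows, o_above = oracle_cascade(records, rules, h)
        got_in = {(i.facility, i.quarter, i.funding_source): i.amount for i in inflows}
        got_ab = {(a.org_unit, a.quarter, a.funding_source): a.amount for a in above}
        assert set(got_in) == set(o_inflows) and set(got_ab) == set(o_above)
        for k, v in o_inflows.items():
            assert got_in[k] == pytest.approx(v, rel=1e-9)
        for k, v in o_above.items():
            assert got_ab[k] == pytest.approx(v, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_money_conserved_per_quarter_and_source(self, seed):
        rng = np.random.default_rng(100 + seed)
        h, rules, records = random_instance(rng)
        inflows, above = cascade(records, rules, h)
        total_in = sum(r.amount for r in records)
        total_out = sum(i.amount for i in inflows) + sum(a.amount for a in above)
        assert abs(total_in - total_out) <= 1e-6

    def test_linearity_in_the_ledger(self):
        rng = np.random.default_rng(7)
        h, rules, records = random_instance(rng)
        inflows, _ = cascade(records, rules, h)
        scaled = [
            ExpenditureRecord(r.account, r.org_unit, r.quarter, 2.5 * r.amount, r.funding_source)
            for r in records
        ]
        inflows2, _ = cascade(scaled, rules, h)
        base = {i.facility: i.amount for i in inflows}
        doubled = {i.facility: i.amount for i in inflows2}
        for fac, amount in base.items():
            assert doubled[fac] == pytest.approx(2.5 * amount, rel=1e-12)

    def test_additivity_in_the_ledger(self):
        rng = np.random.default_rng(11)
        h, rules, records = random_instance(rng, n_accounts=6)
        half1, half2 = records[:3], records[3:]
        combined, _ = cascade(records, rules, h)
        a, _ = cascade(half1, rules, h)
        b, _ = cascade(half2, rules, h)
        partial = {}
        for i in list(a) + list(b):
            partial[i.facility] = partial.get(i.facility, 0.0) + i.amount
        for i in combined:
            assert partial[i.facility] == pytest.approx(i.amount, rel=1e-12)


class TestIsolateHiv:
    def test_scales_and_drops_non_hiv(self):
        weights = [HivShareWeight(pattern("01"), 0.5)]
        records = [rec("01/01/01/01", "NAT", 1000), rec("02/01/01/01", "NAT", 999)]
        (only,) = isolate_hiv(records, weights)
        assert only.amount == 500.0
        assert only.account.format() == "01/01/01/01"
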