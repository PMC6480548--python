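"""Step one of the expenditure-output linkage: isolate the HIV-related part
of every ledger account and cascade it down the administrative hierarchy to
facilities, retaining "above-facility" expenses at each level.

Two elicited weight tables drive the stage:

* **HIV-share weights** — per account prefix, the fraction of spending that
  supports HIV services ("what portion of the expenditures in that account
  support HIV/AIDS services").
* **Flow-down rules** — per (account prefix, controlling org unit), the
  fraction retained at that level versus passed to each child unit.

Matching is by most-specific account prefix in both tables; rules are
time-invariant within a run (one elicitation applied to every quarter).
Money is conserved at every node: for each quarter and funding source,
facility inflows plus above-facility retentions equal the HIV-share total.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .config import RunConfig
from .ledger_io import ExpenditureRecord, IngestError, _read_rows
from .org_model import (
    AccountCode,
    AccountParseError,
    Hierarchy,
    Quarter,
    ValidationError,
    parse_account,
)

__all__ = [
    "HivShareWeight",
    "FlowDownRule",
    "AboveFacilityExpense",
    "FacilityInflow",
    "load_hiv_share_weights",
    "load_flow_down_rules",
    "match_weight",
    "apply_hiv_share",
    "isolate_hiv",
    "cascade",
]

SHARE_TOL = 1e-9


@dataclass(frozen=True)
class HivShareWeight:
    """Fraction of an account's spending that supports HIV services."""

    account_pattern: AccountCode
    hiv_share: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.hiv_share <= 1.0:
            raise ValidationError(
                [f"hiv_share for {self.account_pattern.format()} outside [0, 1]"]
            )


@dataclass(frozen=True)
class FlowDownRule:
    """How one org unit splits an account: retained vs passed to children.

    ``child_shares`` empty with ``retained_share < 1`` means "flows down,
    apportionment unspecified": the unretained part is split across the
    unit's children in proportion to the number of facilities beneath each.
    """

    account_pattern: AccountCode
    source_unit: str
    retained_share: float
    child_shares: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        problems = []
        if not 0.0 <= self.retained_share <= 1.0 + SHARE_TOL:
            problems.append(f"retained_share {self.retained_share} outside [0, 1]")
        for child, share in self.child_shares:
            if share < 0:
                problems.append(f"negative child share for {child}")
        if self.child_shares:
            total = self.retained_share + sum(s for _, s in self.child_shares)
            if abs(total - 1.0) > SHARE_TOL:
                problems.append(
                    f"rule ({self.account_pattern.format()}, {self.source_unit}): "
                    f"retained + child shares = {total!r}, expected 1"
                )
        if problems:
            raise ValidationError(problems)


@dataclass(frozen=True)
class AboveFacilityExpense:
    """HIV-related money retained above the facility level."""

    org_unit: str
    level: str
    quarter: Quarter
    amount: float
    funding_source: str = ""


@dataclass(frozen=True)
class FacilityInflow:
    """HIV-related money reaching one facility in one quarter, with the
    contributing source accounts recorded for traceability."""

    facility: str
    quarter: Quarter
    amount: float
    funding_source: str = ""
    provenance: tuple[tuple[str, float], ...] = ()


# ---------------------------------------------------------------------------
# weight / rule tables


def load_hiv_share_weights(path: str | Path) -> list[HivShareWeight]:
    """Load ``account_pattern,hiv_share`` CSV; duplicate patterns are a
    configuration error (they would make matching ambiguous)."""
    errors: list[str] = []
    seen: dict[str, float] = {}
    out: list[HivShareWeight] = []
    for lineno, row in _read_rows(path, ["account_pattern", "hiv_share"]):
        where = f"{path}:{lineno}"
        try:
            pattern = parse_account(row["account_pattern"], full=False)
        except AccountParseError as exc:
            errors.append(f"{where}: {exc}")
            continue
        try:
            share = float(row["hiv_share"])
        except ValueError:
            errors.append(f"{where}: non-numeric hiv_share {row['hiv_share']!r}")
            continue
        if pattern.format() in seen:
            errors.append(f"{where}: duplicate pattern {pattern.format()!r}")
            continue
        seen[pattern.format()] = share
        try:
            out.append(HivShareWeight(pattern, share))
        except ValidationError as exc:
            errors.append(f"{where}: {exc}")
    if errors:
        raise IngestError(errors)
    return out


def load_flow_down_rules(path: str | Path, hierarchy: Hierarchy) -> list[FlowDownRule]:
    """Load flow-down rules (one CSV row per child; retained repeated).

    A row with an empty ``child_unit_id`` declares a rule with no explicit
    children (pure retention, or default facility-count apportionment).
    """
    errors: list[str] = []
    acc: dict[tuple[str, str], dict] = {}
    for lineno, row in _read_rows(
        path,
        ["account_pattern", "source_unit_id", "retained_share", "child_unit_id", "child_share"],
    ):
        where = f"{path}:{lineno}"
        try:
            pattern = parse_account(row["account_pattern"], full=False)
        except AccountParseError as exc:
            errors.append(f"{where}: {exc}")
            continue
        unit_id = row["source_unit_id"]
        if unit_id not in hierarchy:
            errors.append(f"{where}: unknown org unit {unit_id!r}")
            continue
        try:
            retained = float(row["retained_share"])
        except ValueError:
            errors.append(f"{where}: non-numeric retained_share")
            continue
        key = (pattern.format(), unit_id)
        entry = acc.setdefault(
            key, {"pattern": pattern, "unit": unit_id, "retained": retained, "children": {}}
        )
        if abs(entry["retained"] - retained) > SHARE_TOL:
            errors.append(f"{where}: inconsistent retained_share for rule {key}")
            continue
        child = row["child_unit_id"]
        if child:
            if child not in hierarchy:
                errors.append(f"{where}: unknown child unit {child!r}")
                continue
            if hierarchy.unit(child).parent_id != unit_id:
                errors.append(f"{where}: {child!r} is not a child of {unit_id!r}")
                continue
            if child in entry["children"]:
                errors.append(f"{where}: duplicate child {child!r} in rule {key}")
                continue
            try:
                entry["children"][child] = float(row["child_share"])
            except ValueError:
                errors.append(f"{where}: non-numeric child_share")
    if errors:
        raise IngestError(errors)
    out = []
    for entry in acc.values():
        try:
            out.append(
                FlowDownRule(
                    entry["pattern"],
                    entry["unit"],
                    entry["retained"],
                    tuple(sorted(entry["children"].items())),
                )
            )
        except ValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise IngestError(errors)
    return out


# ---------------------------------------------------------------------------
# matching


def _most_specific(matches: list, account: AccountCode, what: str):
    best = max(m.account_pattern.specificity for m in matches)
    top = [m for m in matches if m.account_pattern.specificity == best]
    if len(top) > 1:
        raise ValidationError(
            [
                f"ambiguous {what} for account {account.format()}: "
                + ", ".join(m.account_pattern.format() for m in top)
            ]
        )
    return top[0]


def match_weight(
    account: AccountCode,
    weights: Sequence[HivShareWeight],
    default: float = 0.0,
) -> float:
    """HIV share of the most specific weight pattern matching ``account``;
    accounts matching nothing get ``default`` (0 = not HIV-related)."""
    matches = [w for w in weights if w.account_pattern.is_prefix_of(account)]
    if not matches:
        return default
    return _most_specific(matches, account, "HIV-share weight").hiv_share


def apply_hiv_share(record: ExpenditureRecord, share: float) -> float:
    """HIV-attributable amount of one ledger record."""
    if not 0.0 <= share <= 1.0:
        raise ValidationError([f"hiv share {share} outside [0, 1]"])
    return record.amount * share


def isolate_hiv(
    records: Iterable[ExpenditureRecord],
    weights: Sequence[HivShareWeight],
    config: RunConfig | None = None,
) -> list[ExpenditureRecord]:
    """Scale every ledger record by its matched HIV share, dropping records
    whose share is zero."""
    config = config or RunConfig()
    out = []
    for rec in records:
        share = match_weight(rec.account, weights, default=config.default_hiv_share)
        hiv = apply_hiv_share(rec, share)
        if hiv > 0:
            out.append(
                ExpenditureRecord(rec.account, rec.org_unit, rec.quarter, hiv, rec.funding_source)
            )
    return out


def _match_rule(
    account: AccountCode, unit_id: str, rules_by_unit: Mapping[str, list[FlowDownRule]]
) -> Optional[FlowDownRule]:
    matches = [
        r for r in rules_by_unit.get(unit_id, []) if r.account_pattern.is_prefix_of(account)
    ]
    if not matches:
        return None
    return _most_specific(matches, account, "flow-down rule")


def _effective_children(
    rule: FlowDownRule, hierarchy: Hierarchy
) -> list[tuple[str, float]]:
    """Explicit child shares, or the facility-count default split of the
    unretained part; empty when retained_share == 1."""
    if rule.child_shares:
        return [(c, s) for c, s in rule.child_shares if s > 0]
    passed = 1.0 - rule.retained_share
    if passed <= SHARE_TOL:
        return []
    children = hierarchy.children(rule.source_unit)
    counts = {c.id: len(hierarchy.facilities_below(c.id)) for c in children}
    total = sum(counts.values())
    if total == 0:
        return []
    return [(cid, passed * n / total) for cid, n in sorted(counts.items()) if n > 0]


# ---------------------------------------------------------------------------
# cascade


def cascade(
    hiv_expenditures: Iterable[ExpenditureRecord],
    rules: Sequence[FlowDownRule],
    hierarchy: Hierarchy,
) -> tuple[list[FacilityInflow], list[AboveFacilityExpense]]:
    """Step HIV-isolated expenditures down to facilities.

    Facility-controlled records flow whole to their facility. Records
    controlled higher are split by the matched flow-down rule at each node:
    the retained share becomes an above-facility expense at that node, the
    rest recurses into the children. Before any allocation, every needed
    (account, unit) rule is checked and ALL gaps are reported at once.

    Returns inflows aggregated per (facility, quarter, funding source) with
    per-account provenance, and above-facility expenses per
    (unit, quarter, funding source).
    """
    records = list(hiv_expenditures)
    rules_by_unit: dict[str, list[FlowDownRule]] = {}
    for r in rules:
        rules_by_unit.setdefault(r.source_unit, []).append(r)

    # pre-validation: walk the allocation tree, collecting every rule gap
    gaps: list[str] = []
    seen_nodes: set[tuple[str, str]] = set()

    def check(account: AccountCode, unit_id: str) -> None:
        if hierarchy.level(unit_id) == "facility":
            return
        node = (account.format(), unit_id)
        if node in seen_nodes:
            return
        seen_nodes.add(node)
        rule = _match_rule(account, unit_id, rules_by_unit)
        if rule is None:
            gaps.append(f"no flow-down rule for account {account.format()} at unit {unit_id}")
            return
        children = _effective_children(rule, hierarchy)
        if not children and rule.retained_share < 1.0 - SHARE_TOL:
            gaps.append(
                f"rule ({account.format()}, {unit_id}) passes down "
                f"{1.0 - rule.retained_share:g} but has no usable children"
            )
        for child, _ in children:
            check(account, child)

    for rec in records:
        check(rec.account, rec.org_unit)
    if gaps:
        raise ValidationError(sorted(set(gaps)))

    inflow_amt: dict[tuple, float] = {}
    inflow_prov: dict[tuple, dict[str, float]] = {}
    above: dict[tuple, float] = {}

    def allocate(account: AccountCode, unit_id: str, amount: float, rec: ExpenditureRecord) -> None:
        if amount == 0.0:
            return
        if hierarchy.level(unit_id) == "facility":
            key = (unit_id, rec.quarter, rec.funding_source)
            inflow_amt[key] = inflow_amt.get(key, 0.0) + amount
            prov = inflow_prov.setdefault(key, {})
            prov[account.format()] = prov.get(account.format(), 0.0) + amount
            return
        rule = _match_rule(account, unit_id, rules_by_unit)
        assert rule is not None  # pre-validated
        retained = amount * rule.retained_share
        if retained > 0:
            akey = (unit_id, rec.quarter, rec.funding_source)
            above[akey] = above.get(akey, 0.0) + retained
        for child, share in _effective_children(rule, hierarchy):
            allocate(account, child, amount * share, rec)

    for rec in records:
        allocate(rec.account, rec.org_unit, rec.amount, rec)

    inflows = [
        FacilityInflow(
            facility=fac,
            quarter=quarter,
            amount=amt,
            funding_source=src,
            provenance=tuple(sorted(inflow_prov[(fac, quarter, src)].items())),
        )
        for (fac, quarter, src), amt in sorted(inflow_amt.items())
    ]
    aboves = [
        AboveFacilityExpense(
            org_unit=uid,
            level=hierarchy.level(uid),
            quarter=quarter,
            amount=amt,
            funding_source=src,
        )
        for (uid, quarter, src), amt in sorted(above.items())
    ]
    return inflows, aboves
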