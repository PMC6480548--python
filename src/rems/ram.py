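"""Resource Allocation Matrices: build from ingredients-based facility
assessments, apply to distribute facility inflows over service ×
resource-category cells.

An assessment lists the inputs a facility uses (quantities × standard unit
costs, ingredients approach); capital items are annualized straight-line.
Line costs are apportioned to services — wholly for dedicated items,
proportionally to session-weighted relative service volume for shared ones
— yielding an annual prototypical operational budget. Cell weights are each
(service, category) cost share of the budget total; e.g. if personnel
supporting HTC are 5% of total annual HIV-related resources, 5% of each
HIV-related Kwacha reaching the facility is assigned to personnel for HTC.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .config import RunConfig
from .ledger_io import IngestError, _read_rows
from .org_model import SHARED, Hierarchy, Quarter, ValidationError
from .step_down import FacilityInflow

__all__ = [
    "AssessmentLineItem",
    "ServiceSchedule",
    "BudgetLine",
    "OperationalBudget",
    "RAM",
    "AllocatedExpenditure",
    "load_assessment",
    "load_schedules",
    "cost_line",
    "apportion_shared",
    "build_budget",
    "compute_ram",
    "allocate_ram",
]

WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class AssessmentLineItem:
    """One inventoried input at a facility (ingredients approach)."""

    facility: str
    item_id: str
    description: str
    resource_category: str
    annual_quantity: float
    standard_unit_cost: float
    dedicated_service: str = SHARED  # service code, or SHARED
    useful_life_years: Optional[float] = None  # capital items only

    def __post_init__(self) -> None:
        problems = []
        if self.annual_quantity < 0:
            problems.append(f"item {self.item_id}: negative quantity")
        if self.standard_unit_cost < 0:
            problems.append(f"item {self.item_id}: negative unit cost")
        if self.useful_life_years is not None and self.useful_life_years <= 0:
            problems.append(f"item {self.item_id}: useful life must be positive")
        if problems:
            raise ValidationError(problems)


@dataclass(frozen=True)
class ServiceSchedule:
    """When/where a service runs at a facility, and its relative volume."""

    facility: str
    service: str
    sessions_per_week: float
    location: str = "facility"
    relative_annual_volume: float = 0.0

    def __post_init__(self) -> None:
        if self.sessions_per_week < 0 or self.relative_annual_volume < 0:
            raise ValidationError(
                [f"schedule ({self.facility}, {self.service}): negative value"]
            )


@dataclass(frozen=True)
class BudgetLine:
    item_id: str
    resource_category: str
    service: str
    annual_cost: float


@dataclass(frozen=True)
class OperationalBudget:
    """Annual prototypical operational budget for one facility, with every
    line already apportioned to a single service."""

    facility: str
    lines: tuple[BudgetLine, ...]

    @property
    def total(self) -> float:
        return sum(line.annual_cost for line in self.lines)


@dataclass(frozen=True)
class RAM:
    """Per-facility weights over (service, resource category); nonnegative,
    summing to 1."""

    facility: str
    weights: tuple[tuple[tuple[str, str], float], ...]  # ((service, category), weight)

    def __post_init__(self) -> None:
        problems = []
        total = 0.0
        for (svc, cat), w in self.weights:
            if w < 0:
                problems.append(f"negative weight for ({svc}, {cat})")
            total += w
        if abs(total - 1.0) > WEIGHT_TOL:
            problems.append(f"RAM for {self.facility}: weights sum to {total!r}, expected 1")
        if problems:
            raise ValidationError(problems)

    def as_dict(self) -> dict[tuple[str, str], float]:
        return dict(self.weights)

    def weight(self, service: str, category: str) -> float:
        return self.as_dict().get((service, category), 0.0)


@dataclass(frozen=True)
class AllocatedExpenditure:
    """Money assigned to one (facility, quarter, service, category) cell."""

    facility: str
    quarter: Quarter
    service: str
    resource_category: str
    amount: float
    funding_source: str = ""


# ---------------------------------------------------------------------------
# loaders


def load_assessment(
    path: str | Path, hierarchy: Hierarchy, config: RunConfig | None = None
) -> list[AssessmentLineItem]:
    config = config or RunConfig()
    known_services = set(config.service_codes) | {SHARED}
    known_categories = set(config.category_codes)
    errors: list[str] = []
    out: list[AssessmentLineItem] = []
    for lineno, row in _read_rows(
        path,
        [
            "facility_id",
            "item_id",
            "description",
            "resource_category",
            "annual_quantity",
            "standard_unit_cost",
            "dedicated_service",
            "useful_life_years",
        ],
    ):
        where = f"{path}:{lineno}"
        fid = row["facility_id"]
        if fid not in hierarchy or hierarchy.level(fid) != "facility":
            errors.append(f"{where}: {fid!r} is not a known facility")
            continue
        if row["resource_category"] not in known_categories:
            errors.append(f"{where}: unknown resource category {row['resource_category']!r}")
            continue
        svc = row["dedicated_service"] or SHARED
        if svc not in known_services:
            errors.append(f"{where}: unknown service {svc!r}")
            continue
        try:
            qty = float(row["annual_quantity"])
            cost = float(row["standard_unit_cost"])
            life = float(row["useful_life_years"]) if row["useful_life_years"] else None
        except ValueError:
            errors.append(f"{where}: non-numeric quantity/cost/life")
            continue
        try:
            out.append(
                AssessmentLineItem(
                    fid, row["item_id"], row["description"], row["resource_category"],
                    qty, cost, svc, life,
                )
            )
        except ValidationError as exc:
            errors.append(f"{where}: {exc}")
    if errors:
        raise IngestError(errors)
    return out


def load_schedules(
    path: str | Path, hierarchy: Hierarchy, config: RunConfig | None = None
) -> list[ServiceSchedule]:
    config = config or RunConfig()
    known_services = set(config.service_codes)
    errors: list[str] = []
    out: list[ServiceSchedule] = []
    for lineno, row in _read_rows(
        path, ["facility_id", "service", "sessions_per_week", "location", "relative_annual_volume"]
    ):
        where = f"{path}:{lineno}"
        fid = row["facility_id"]
        if fid not in hierarchy or hierarchy.level(fid) != "facility":
            errors.append(f"{where}: {fid!r} is not a known facility")
            continue
        if row["service"] not in known_services:
            errors.append(f"{where}: unknown service {row['service']!r}")
            continue
        try:
            out.append(
                ServiceSchedule(
                    fid,
                    row["service"],
                    float(row["sessions_per_week"]),
                    row["location"] or "facility",
                    float(row["relative_annual_volume"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            errors.append(f"{where}: {exc}")
    if errors:
        raise IngestError(errors)
    return out


# ---------------------------------------------------------------------------
# budget construction


def cost_line(item: AssessmentLineItem, config: RunConfig | None = None) -> float:
    """Annual cost of one line: quantity × standard unit cost, with capital
    categories annualized straight-line over the useful life (the item's own
    life, else the configured default for its category)."""
    config = config or RunConfig()
    base = item.annual_quantity * item.standard_unit_cost
    default_life = config.useful_life_years.get(item.resource_category)
    life = item.useful_life_years if item.useful_life_years is not None else default_life
    if default_life is None and item.useful_life_years is None:
        return base  # recurrent category
    if life is None or life <= 0:
        raise ValidationError(
            [f"item {item.item_id}: capital category {item.resource_category!r} "
             "needs a useful life (item or config default)"]
        )
    return base / life


def apportion_shared(
    line_cost: float, service_rows: Sequence[ServiceSchedule]
) -> dict[str, float]:
    """Split a shared line cost across services proportionally to
    session-weighted relative volume (sessions_per_week ×
    relative_annual_volume, renormalized); shares sum to ``line_cost``."""
    weights = {
        s.service: s.sessions_per_week * s.relative_annual_volume for s in service_rows
    }
    total = sum(weights.values())
    if total <= 0:
        raise ValidationError(
            ["cannot apportion a shared line: no service with positive "
             "session-weighted relative volume"]
        )
    return {svc: line_cost * w / total for svc, w in weights.items() if w > 0}


def build_budget(
    facility: str,
    items: Sequence[AssessmentLineItem],
    schedules: Sequence[ServiceSchedule],
    config: RunConfig | None = None,
) -> OperationalBudget:
    """Assemble the facility's annual operational budget: cost each line,
    then apportion shared lines over the facility's scheduled services."""
    config = config or RunConfig()
    my_items = [i for i in items if i.facility == facility]
    my_sched = [s for s in schedules if s.facility == facility]
    lines: list[BudgetLine] = []
    for item in my_items:
        annual = cost_line(item, config)
        if annual == 0:
            continue
        if item.dedicated_service != SHARED:
            lines.append(
                BudgetLine(item.item_id, item.resource_category, item.dedicated_service, annual)
            )
        else:
            if not my_sched:
                raise ValidationError(
                    [f"facility {facility}: shared item {item.item_id} but no service schedules"]
                )
            for svc, cost in sorted(apportion_shared(annual, my_sched).items()):
                lines.append(BudgetLine(item.item_id, item.resource_category, svc, cost))
    return OperationalBudget(facility, tuple(lines))


def compute_ram(budget: OperationalBudget) -> RAM:
    """Weights = each (service, category) share of the budget total.

    Scale-invariant: multiplying every line cost by a constant leaves the
    RAM unchanged. A zero-total budget is an error — the facility cannot be
    allocated.
    """
    total = budget.total
    if total <= 0:
        raise ValidationError(
            [f"facility {budget.facility}: zero-total operational budget, cannot build RAM"]
        )
    cells: dict[tuple[str, str], float] = {}
    for line in budget.lines:
        key = (line.service, line.resource_category)
        cells[key] = cells.get(key, 0.0) + line.annual_cost
    weights = tuple(sorted((k, v / total) for k, v in cells.items() if v > 0))
    # renormalize away float summation error so the invariant is exact
    s = sum(w for _, w in weights)
    weights = tuple((k, w / s) for k, w in weights)
    return RAM(budget.facility, weights)


def allocate_ram(
    inflow: FacilityInflow, ram: RAM
) -> list[AllocatedExpenditure]:
    """Distribute one facility inflow across RAM cells: cell amount =
    inflow × weight; cell amounts sum to the inflow (linear, conservative)."""
    if ram.facility != inflow.facility:
        raise ValidationError(
            [f"RAM facility {ram.facility!r} does not match inflow facility "
             f"{inflow.facility!r}"]
        )
    return [
        AllocatedExpenditure(
            facility=inflow.facility,
            quarter=inflow.quarter,
            service=svc,
            resource_category=cat,
            amount=inflow.amount * w,
            funding_source=inflow.funding_source,
        )
        for (svc, cat), w in ram.weights
    ]


def allocate_all(
    inflows: Sequence[FacilityInflow], rams: Mapping[str, RAM]
) -> list[AllocatedExpenditure]:
    """Apply each facility's RAM to its inflows; facilities with inflow but
    no RAM are reported together as one error."""
    missing = sorted({i.facility for i in inflows if i.facility not in rams})
    if missing:
        raise ValidationError([f"no RAM for facility {f}" for f in missing])
    out: list[AllocatedExpenditure] = []
    for inflow in inflows:
        out.extend(allocate_ram(inflow, rams[inflow.facility]))
    return out
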