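"""Step two of the linkage: divide allocated service expenditures by
same-quarter output volumes to get unit expenditures, decomposed by
resource category, plus roll-ups by geography/service/period.

Division is only ever performed for records with a positive same-quarter
volume; zero and missing volumes are distinct statuses (an omission in the
output system must stay visible, not silently become zero), and services
with output but no allocated money are flagged ``zero_expenditure`` rather
than given a unit cost of 0. Group-level unit expenditure is the
volume-weighted ratio of sums (Σ amount ÷ Σ volume), which preserves money
conservation under aggregation — never the mean of facility unit costs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .org_model import Hierarchy, Quarter, ValidationError
from .ledger_io import OutputVolume
from .ram import AllocatedExpenditure
from .step_down import AboveFacilityExpense, FacilityInflow

__all__ = [
    "UnitExpenditure",
    "compute_unit_expenditure",
    "units_frame",
    "rollup",
    "above_facility_share",
]

GROUP_KEYS = ("district", "province", "service", "quarter", "resource_category", "funding_source")


@dataclass(frozen=True)
class UnitExpenditure:
    """Unit expenditure for one (facility, service, quarter).

    ``status`` is ``ok`` only when a positive volume and positive
    expenditure coexist; then ``unit_total = total_amount / volume`` and the
    category decomposition sums to it.
    """

    facility: str
    quarter: Quarter
    service: str
    volume: Optional[int]  # None = missing in the output system
    total_amount: float
    unit_total: Optional[float]
    unit_by_category: tuple[tuple[str, float], ...]
    status: str  # ok | zero_volume | missing_volume | zero_expenditure
    amount_by_category: tuple[tuple[str, float], ...] = ()
    amount_by_source: tuple[tuple[str, float], ...] = ()


def compute_unit_expenditure(
    allocated: Iterable[AllocatedExpenditure],
    volumes: Iterable[OutputVolume],
) -> list[UnitExpenditure]:
    """Join allocated expenditures with same-quarter volumes.

    One record per (facility, service, quarter) present in either input;
    categories are summed into the total before division; statuses follow
    the zero/missing distinction documented on the module.
    """
    amounts: dict[tuple, dict[str, float]] = {}
    sources: dict[tuple, dict[str, float]] = {}
    for a in allocated:
        key = (a.facility, a.service, a.quarter)
        cat = amounts.setdefault(key, {})
        cat[a.resource_category] = cat.get(a.resource_category, 0.0) + a.amount
        src = sources.setdefault(key, {})
        src[a.funding_source] = src.get(a.funding_source, 0.0) + a.amount
    vols: dict[tuple, int] = {}
    for v in volumes:
        vols[(v.facility, v.service, v.quarter)] = v.count

    out: list[UnitExpenditure] = []
    for key in sorted(set(amounts) | set(vols)):
        facility, service, quarter = key
        by_cat = amounts.get(key, {})
        total = sum(by_cat.values())
        volume = vols.get(key)  # None = missing
        if total > 0 and volume is not None and volume > 0:
            status = "ok"
            unit_total = total / volume
            unit_by_cat = tuple(sorted((c, amt / volume) for c, amt in by_cat.items()))
        elif total > 0 and volume is None:
            status, unit_total, unit_by_cat = "missing_volume", None, ()
        elif total > 0:  # volume == 0
            status, unit_total, unit_by_cat = "zero_volume", None, ()
        elif volume is not None and volume > 0:
            status, unit_total, unit_by_cat = "zero_expenditure", None, ()
        else:  # volume == 0 (or absent) and no money: degenerate row
            status, unit_total, unit_by_cat = "zero_volume", None, ()
        out.append(
            UnitExpenditure(
                facility=facility,
                quarter=quarter,
                service=service,
                volume=volume,
                total_amount=total,
                unit_total=unit_total,
                unit_by_category=unit_by_cat,
                status=status,
                amount_by_category=tuple(sorted(by_cat.items())),
                amount_by_source=tuple(sorted(sources.get(key, {}).items())),
            )
        )
    return out


def units_frame(
    records: Sequence[UnitExpenditure], categories: Sequence[str] = ()
) -> pd.DataFrame:
    """Tidy table of unit-expenditure records (one row per record, unit_<cat>
    columns for the category decomposition)."""
    from .ledger_io import round_currency

    cats = list(categories) or sorted(
        {c for r in records for c, _ in r.unit_by_category}
    )

    def money(v: Optional[float]) -> str:
        return "" if v is None else f"{round_currency(v):.2f}"

    rows = []
    for r in records:
        unit_cats = dict(r.unit_by_category)
        rows.append(
            {
                "facility_id": r.facility,
                "service": r.service,
                "year": r.quarter.year,
                "quarter": r.quarter.q,
                "volume": "" if r.volume is None else r.volume,
                "total_amount": money(r.total_amount),
                "unit_total": money(r.unit_total),
                **{
                    f"unit_{c}": money(unit_cats.get(c, 0.0)) if r.status == "ok" else ""
                    for c in cats
                },
                "status": r.status,
            }
        )
    return pd.DataFrame(rows)


def _geo(hierarchy: Hierarchy, facility: str, key: str) -> str:
    return (
        hierarchy.district_of(facility).id
        if key == "district"
        else hierarchy.province_of(facility).id
    )


def rollup(
    records: Sequence[UnitExpenditure],
    group_by: Sequence[str],
    hierarchy: Optional[Hierarchy] = None,
) -> pd.DataFrame:
    """Aggregate unit-expenditure records over ``group_by`` keys.

    Keys may be any subset of district, province, service, quarter,
    resource_category, funding_source (geographic keys need ``hierarchy``).
    total_amount and volume are summed within groups; the group unit
    expenditure is recomputed as Σ amount ÷ Σ volume over status=ok records
    (volume-weighted). Records excluded from the unit computation are
    counted in ``n_flagged``; ``mean_facility_unit`` is offered as a
    diagnostic only.
    """
    bad = [k for k in group_by if k not in GROUP_KEYS]
    if bad:
        raise ValidationError([f"unknown roll-up key {k!r}" for k in bad])
    if any(k in ("district", "province") for k in group_by) and hierarchy is None:
        raise ValidationError(["geographic roll-up needs the org hierarchy"])

    rows = []
    for r in records:
        base = {}
        for k in group_by:
            if k in ("district", "province"):
                base[k] = _geo(hierarchy, r.facility, k)
            elif k == "quarter":
                base[k] = r.quarter.format()
            elif k == "service":
                base[k] = r.service
        ok = r.status == "ok"
        if "resource_category" in group_by or "funding_source" in group_by:
            split = (
                r.amount_by_category
                if "resource_category" in group_by
                else r.amount_by_source
            )
            col = "resource_category" if "resource_category" in group_by else "funding_source"
            for label, amt in split or (("", 0.0),):
                rows.append(
                    {
                        **base,
                        col: label,
                        "total_amount": amt,
                        "volume": r.volume if ok else 0,
                        "ok_amount": amt if ok else 0.0,
                        "ok_volume": r.volume if ok else 0,
                        "facility_unit": (amt / r.volume) if ok else None,
                        "flagged": 0 if ok else 1,
                    }
                )
        else:
            rows.append(
                {
                    **base,
                    "total_amount": r.total_amount,
                    "volume": r.volume if r.volume is not None else 0,
                    "ok_amount": r.total_amount if ok else 0.0,
                    "ok_volume": r.volume if ok else 0,
                    "facility_unit": r.unit_total if ok else None,
                    "flagged": 0 if ok else 1,
                }
            )
    df = pd.DataFrame(rows)
    keys = [k for k in group_by]
    if not keys:
        df["_all"] = "all"
        keys = ["_all"]
    g = df.groupby(keys, dropna=False)
    out = g.agg(
        total_amount=("total_amount", "sum"),
        volume=("volume", "sum"),
        ok_amount=("ok_amount", "sum"),
        ok_volume=("ok_volume", "sum"),
        n_flagged=("flagged", "sum"),
        mean_facility_unit=("facility_unit", "mean"),
    ).reset_index()
    out["unit_expenditure"] = out.apply(
        lambda r: r["ok_amount"] / r["ok_volume"] if r["ok_volume"] > 0 else float("nan"),
        axis=1,
    )
    if "_all" in out.columns:
        return out.drop(columns="_all")
    return out.sort_values(keys, kind="mergesort").reset_index(drop=True)


def above_facility_share(
    above: Sequence[AboveFacilityExpense],
    inflows: Sequence[FacilityInflow],
    group_by: Sequence[str] = ("quarter",),
) -> pd.DataFrame:
    """Share of HIV expenditure retained above the facility level:
    above ÷ (above + inflows), per group (keys ⊆ {quarter, level,
    funding_source}); by construction in [0, 1]."""
    bad = [k for k in group_by if k not in ("quarter", "level", "funding_source")]
    if bad:
        raise ValidationError([f"unknown share key {k!r}" for k in bad])

    def akey(a: AboveFacilityExpense) -> tuple:
        return tuple(
            a.quarter.format() if k == "quarter" else (a.level if k == "level" else a.funding_source)
            for k in group_by
        )

    def ikey(i: FacilityInflow) -> tuple | None:
        out = []
        for k in group_by:
            if k == "quarter":
                out.append(i.quarter.format())
            elif k == "funding_source":
                out.append(i.funding_source)
            else:
                out.append(None)  # inflows have no level; fill per level group
        return tuple(out)

    above_tot: dict[tuple, float] = {}
    for a in above:
        above_tot[akey(a)] = above_tot.get(akey(a), 0.0) + a.amount
    inflow_tot: dict[tuple, float] = {}
    for i in inflows:
        inflow_tot[ikey(i)] = inflow_tot.get(ikey(i), 0.0) + i.amount

    rows = []
    all_groups = set(above_tot)
    if "level" not in group_by:
        all_groups |= set(inflow_tot)
    for grp in sorted(all_groups, key=lambda t: tuple(str(x) for x in t)):
        up = above_tot.get(grp, 0.0)
        ikey_grp = tuple(
            None if k == "level" else v for k, v in zip(group_by, grp)
        )
        down = inflow_tot.get(ikey_grp, 0.0)
        denom = up + down
        rows.append(
            {
                **{k: v for k, v in zip(group_by, grp)},
                "above_facility": up,
                "facility_inflows": down,
                "share": up / denom if denom > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
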