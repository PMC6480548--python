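"""Comparative efficiency analytics: outlier flags, trends, unit-cost vs
volume views, and data-quality reports, exported as tidy tables.

Outliers — facilities with high or low expenditure per unit of output
relative to their comparison group — are flagged with a robust z-score,
(x − median) / (1.4826 · MAD), the MAD-consistency constant making the
score comparable to a normal z. Comparison groups default to same district
× service × quarter (the district-management use case). All functions are
pure: re-running on the same inputs yields identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .ledger_io import OutputVolume
from .org_model import Hierarchy, Quarter, ValidationError
from .ram import RAM
from .step_down import FacilityInflow
from .unit_expenditure import UnitExpenditure

__all__ = [
    "OutlierFlag",
    "flag_outliers",
    "trend",
    "cost_volume_view",
    "data_quality_report",
    "dashboard_export",
    "MAD_CONSISTENCY",
]

#: Scales the median absolute deviation to estimate a normal sigma.
MAD_CONSISTENCY = 1.4826


@dataclass(frozen=True)
class OutlierFlag:
    facility: str
    service: str
    quarter: Quarter
    unit_total: float
    center: float  # group median
    spread: float  # MAD-based robust sigma
    score: float  # robust z
    direction: str  # high | low
    note: str = ""


def _robust_z(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    center = float(np.median(values))
    mad = float(np.median(np.abs(values - center)))
    spread = MAD_CONSISTENCY * mad
    if spread == 0.0:
        return np.zeros_like(values), center, 0.0
    return (values - center) / spread, center, spread


def flag_outliers(
    units: Sequence[UnitExpenditure],
    hierarchy: Hierarchy,
    config: RunConfig | None = None,
) -> tuple[list[OutlierFlag], list[str]]:
    """Flag unit-expenditure outliers within comparison groups.

    Groups are (geo unit at ``config.outlier_group_level``) × service ×
    quarter over status=ok records; a record is flagged iff |robust z| >
    ``config.outlier_threshold`` and the group has at least
    ``config.outlier_min_group`` members. Returns the flags plus notes for
    groups that were too small or had degenerate (zero) spread.
    Flags are invariant to rescaling all unit costs by a positive constant.
    """
    config = config or RunConfig()
    level = config.outlier_group_level
    ok = [u for u in units if u.status == "ok"]
    groups: dict[tuple, list[UnitExpenditure]] = {}
    for u in ok:
        geo = hierarchy.ancestor_at(u.facility, level)
        key = (geo.id if geo else "", u.service, u.quarter)
        groups.setdefault(key, []).append(u)

    flags: list[OutlierFlag] = []
    notes: list[str] = []
    for key in sorted(groups, key=lambda k: (k[0], k[1], k[2])):
        members = groups[key]
        if len(members) < config.outlier_min_group:
            notes.append(
                f"group {key[0]}/{key[1]}/{key[2].format()}: too small "
                f"({len(members)} < {config.outlier_min_group})"
            )
            continue
        values = np.array([u.unit_total for u in members], dtype=float)
        scores, center, spread = _robust_z(values)
        if spread == 0.0:
            notes.append(
                f"group {key[0]}/{key[1]}/{key[2].format()}: degenerate spread (MAD = 0)"
            )
            continue
        for u, z in zip(members, scores):
            if abs(z) > config.outlier_threshold:
                flags.append(
                    OutlierFlag(
                        facility=u.facility,
                        service=u.service,
                        quarter=u.quarter,
                        unit_total=float(u.unit_total),
                        center=center,
                        spread=spread,
                        score=float(z),
                        direction="high" if z > 0 else "low",
                    )
                )
    flags.sort(key=lambda f: (f.facility, f.service, f.quarter))
    return flags, notes


def trend(
    units: Sequence[UnitExpenditure],
    facility: str,
    service: str,
    window: Optional[Sequence[Quarter]] = None,
) -> pd.DataFrame:
    """Per-quarter unit-expenditure series with quarter-over-quarter change.

    ``change = (current − previous) / previous``; undefined (NaN, flagged)
    for the first quarter and whenever the previous value is 0 or the
    previous quarter is not status=ok.
    """
    rows = [
        u
        for u in units
        if u.facility == facility
        and u.service == service
        and (window is None or u.quarter in set(window))
    ]
    rows.sort(key=lambda u: u.quarter)
    out = []
    prev: Optional[UnitExpenditure] = None
    for u in rows:
        change: float = float("nan")
        note = ""
        if u.status != "ok":
            note = u.status
        elif prev is None:
            note = "first_quarter"
        elif prev.status != "ok" or prev.unit_total in (None, 0):
            note = "undefined_change"
        elif prev.quarter.next() != u.quarter:
            note = "gap_in_series"
        else:
            change = (u.unit_total - prev.unit_total) / prev.unit_total
        out.append(
            {
                "quarter": u.quarter.format(),
                "unit_total": u.unit_total if u.status == "ok" else float("nan"),
                "change": change,
                "note": note,
            }
        )
        prev = u
    return pd.DataFrame(out, columns=["quarter", "unit_total", "change", "note"])


def cost_volume_view(
    units: Sequence[UnitExpenditure],
    service: str,
    quarter: Quarter,
    scope: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Unit cost vs volume per facility, with quadrant tags.

    Quadrants split at the group medians of unit_total and volume
    (high_volume_high_cost, low_volume_low_cost, …); facilities sitting on
    a median are tagged ``boundary``. Rows are ordered by unit_total
    descending (the comparison-chart ordering).
    """
    rows = [
        u
        for u in units
        if u.service == service
        and u.quarter == quarter
        and u.status == "ok"
        and (scope is None or u.facility in set(scope))
    ]
    if not rows:
        return pd.DataFrame(columns=["facility_id", "unit_total", "volume", "quadrant"])
    costs = np.array([u.unit_total for u in rows], dtype=float)
    vols = np.array([u.volume for u in rows], dtype=float)
    med_cost, med_vol = float(np.median(costs)), float(np.median(vols))
    tags = []
    for c, v in zip(costs, vols):
        if c == med_cost or v == med_vol:
            tags.append("boundary")
        else:
            tags.append(
                ("high" if v > med_vol else "low")
                + "_volume_"
                + ("high" if c > med_cost else "low")
                + "_cost"
            )
    df = pd.DataFrame(
        {
            "facility_id": [u.facility for u in rows],
            "unit_total": costs,
            "volume": vols.astype(int),
            "quadrant": tags,
        }
    )
    return df.sort_values(
        ["unit_total", "facility_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def data_quality_report(
    units: Sequence[UnitExpenditure],
    inflows: Sequence[FacilityInflow],
    rams: Mapping[str, RAM],
    hierarchy: Hierarchy,
) -> pd.DataFrame:
    """Tidy issue table: every anomalous unit-expenditure status plus
    facilities that have inflow but no RAM, each attributed to its district."""
    rows = []
    for u in units:
        if u.status == "ok":
            continue
        rows.append(
            {
                "district": hierarchy.district_of(u.facility).id,
                "facility_id": u.facility,
                "service": u.service,
                "quarter": u.quarter.format(),
                "issue": u.status,
            }
        )
    for fac in sorted({i.facility for i in inflows} - set(rams)):
        rows.append(
            {
                "district": hierarchy.district_of(fac).id,
                "facility_id": fac,
                "service": "",
                "quarter": "",
                "issue": "ram_missing",
            }
        )
    df = pd.DataFrame(rows, columns=["district", "facility_id", "service", "quarter", "issue"])
    return df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)


def dashboard_export(
    path: str | Path,
    selection: Mapping[str, object],
    views: Mapping[str, pd.DataFrame],
) -> None:
    """Bundle analytic views into one JSON export, echoing the selection
    parameters (period, geographic level, service, resource type, total vs
    unit) alongside each table."""
    payload = {
        "selection": dict(selection),
        "views": {
            name: json.loads(df.to_json(orient="records")) for name, df in views.items()
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
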