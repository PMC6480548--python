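"""End-to-end driver: ingest → HIV isolation → step-down cascade → RAM
build/apply → unit expenditure → analytics, with a run manifest.

The driver is pure composition over the stage functions; its outputs equal
running the stages individually. Everything is plain files in, plain files
out — deterministic given identical inputs and config — and the manifest
records input checksums, row counts and the global money-conservation
residual so a rerun can be verified byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import analytics as an
from . import ram as ram_mod
from . import step_down as sd
from . import unit_expenditure as ue
from .config import RunConfig, load_config
from .ledger_io import (
    ExpenditureRecord,
    OutputVolume,
    read_ledger,
    read_org_units,
    read_volumes,
    write_table,
)
from .org_model import Hierarchy, ValidationError

log = logging.getLogger("rems")

__all__ = ["PipelineResult", "run_pipeline", "InputPaths"]


@dataclass(frozen=True)
class InputPaths:
    org_units: Path
    ledger: Path
    volumes: Path
    hiv_share_weights: Path
    flow_down_rules: Path
    assessment: Path
    schedule: Path
    config: Optional[Path] = None

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "InputPaths":
        d = Path(in_dir)
        cfg = d / "config.yaml"
        return cls(
            org_units=d / "org_units.csv",
            ledger=d / "expenditures.csv",
            volumes=d / "output_volumes.csv",
            hiv_share_weights=d / "hiv_share_weights.csv",
            flow_down_rules=d / "flow_down_rules.csv",
            assessment=d / "facility_assessment.csv",
            schedule=d / "service_schedule.csv",
            config=cfg if cfg.exists() else None,
        )


@dataclass
class PipelineResult:
    """Every intermediate and final product of one run, in memory."""

    hierarchy: Hierarchy
    config: RunConfig
    records: list  # aggregated ledger records
    hiv_records: list
    volumes: list
    inflows: list
    above: list
    budgets: dict  # facility -> OperationalBudget
    rams: dict  # facility -> RAM
    allocated: list
    units: list
    outlier_flags: list
    outlier_notes: list
    data_quality: pd.DataFrame
    conservation_residual: float
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _conservation_residual(
    hiv_records: Sequence[ExpenditureRecord],
    inflows,
    above,
) -> float:
    """Max |HIV-share total − (inflows + above)| over quarter × source."""
    def agg(items, amount, quarter, source):
        out: dict[tuple, float] = {}
        for it in items:
            key = (quarter(it), source(it))
            out[key] = out.get(key, 0.0) + amount(it)
        return out

    left = agg(hiv_records, lambda r: r.amount, lambda r: r.quarter, lambda r: r.funding_source)
    right = agg(inflows, lambda i: i.amount, lambda i: i.quarter, lambda i: i.funding_source)
    for key, amt in agg(
        above, lambda a: a.amount, lambda a: a.quarter, lambda a: a.funding_source
    ).items():
        right[key] = right.get(key, 0.0) + amt
    residual = 0.0
    for key in set(left) | set(right):
        residual = max(residual, abs(left.get(key, 0.0) - right.get(key, 0.0)))
    return residual


def run_pipeline(paths: InputPaths, out_dir: str | Path) -> PipelineResult:
    """Run the whole computation chain and write every result table.

    Raises :class:`~rems.org_model.ValidationError` (with row-level detail)
    on any stage failure; the CLI maps that to a non-zero exit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = load_config(paths.config) if paths.config else RunConfig()
    hierarchy = read_org_units(paths.org_units)
    log.info("hierarchy: %d units, %d facilities", len(hierarchy), len(hierarchy.facilities()))

    records = read_ledger(paths.ledger, hierarchy, config)
    volumes = read_volumes(paths.volumes, hierarchy, config)
    weights = sd.load_hiv_share_weights(paths.hiv_share_weights)
    rules = sd.load_flow_down_rules(paths.flow_down_rules, hierarchy)
    log.info("ingest: %d ledger records, %d volume rows", len(records), len(volumes))

    hiv_records = sd.isolate_hiv(records, weights, config)
    inflows, above = sd.cascade(hiv_records, rules, hierarchy)
    residual = _conservation_residual(hiv_records, inflows, above)
    log.info(
        "step-down: %d inflows, %d above-facility rows, conservation residual %.3g",
        len(inflows), len(above), residual,
    )
    if residual > config.conservation_tol:
        raise ValidationError(
            [f"money conservation violated: residual {residual!r} > {config.conservation_tol}"]
        )

    items = ram_mod.load_assessment(paths.assessment, hierarchy, config)
    schedules = ram_mod.load_schedules(paths.schedule, hierarchy, config)
    budgets, rams = {}, {}
    for fid in sorted({i.facility for i in items}):
        budget = ram_mod.build_budget(fid, items, schedules, config)
        budgets[fid] = budget
        rams[fid] = ram_mod.compute_ram(budget)
    allocated = ram_mod.allocate_all(inflows, rams)
    units = ue.compute_unit_expenditure(allocated, volumes)
    flags, notes = an.flag_outliers(units, hierarchy, config)
    dq = an.data_quality_report(units, inflows, rams, hierarchy)
    log.info(
        "results: %d allocated cells, %d unit-expenditure rows, "
        "%d outlier flags, %d data-quality issues",
        len(allocated), len(units), len(flags), len(dq),
    )

    _write_outputs(out, config, hierarchy, inflows, above, budgets, rams,
                   allocated, units, flags, notes, dq)

    manifest = {
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in vars(paths).items()
            if p is not None
        },
        "config": {
            "services": list(config.service_codes),
            "resource_categories": list(config.category_codes),
            "negative_amount_policy": config.negative_amount_policy,
            "outlier_threshold": config.outlier_threshold,
            "outlier_min_group": config.outlier_min_group,
            "outlier_group_level": config.outlier_group_level,
        },
        "rows": {
            "ledger_records": len(records),
            "hiv_records": len(hiv_records),
            "volumes": len(volumes),
            "facility_inflows": len(inflows),
            "above_facility": len(above),
            "allocated_cells": len(allocated),
            "unit_expenditures": len(units),
            "outlier_flags": len(flags),
            "data_quality_issues": int(len(dq)),
        },
        "conservation": {
            "residual": residual,
            "tolerance": config.conservation_tol,
            "status": "pass" if residual <= config.conservation_tol else "fail",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        hierarchy=hierarchy, config=config, records=records, hiv_records=hiv_records,
        volumes=volumes, inflows=inflows, above=above, budgets=budgets, rams=rams,
        allocated=allocated, units=units, outlier_flags=flags, outlier_notes=notes,
        data_quality=dq, conservation_residual=residual, manifest=manifest,
    )


def _write_outputs(out, config, hierarchy, inflows, above, budgets, rams,
                   allocated, units, flags, notes, dq) -> None:
    write_table(
        pd.DataFrame(
            [{"facility_id": i.facility, "year": i.quarter.year, "quarter": i.quarter.q,
              "funding_source": i.funding_source, "amount": i.amount} for i in inflows]
            or [], columns=["facility_id", "year", "quarter", "funding_source", "amount"]),
        out / "facility_inflows.csv", amount_cols=("amount",))
    write_table(
        pd.DataFrame(
            [{"org_unit_id": a.org_unit, "level": a.level, "year": a.quarter.year,
              "quarter": a.quarter.q, "funding_source": a.funding_source,
              "amount": a.amount} for a in above]
            or [], columns=["org_unit_id", "level", "year", "quarter",
                            "funding_source", "amount"]),
        out / "above_facility.csv", amount_cols=("amount",))
    write_table(
        pd.DataFrame(
            [{"facility_id": b.facility, "item_id": line.item_id,
              "resource_category": line.resource_category, "service": line.service,
              "annual_cost": line.annual_cost}
             for b in budgets.values() for line in b.lines]
            or [], columns=["facility_id", "item_id", "resource_category",
                            "service", "annual_cost"]),
        out / "operational_budget.csv", amount_cols=("annual_cost",))
    write_table(
        pd.DataFrame(
            [{"facility_id": r.facility, "service": svc, "resource_category": cat,
              "weight": f"{w:.12g}"}
             for r in rams.values() for (svc, cat), w in r.weights]
            or [], columns=["facility_id", "service", "resource_category", "weight"]),
        out / "ram_weights.csv")
    write_table(
        pd.DataFrame(
            [{"facility_id": a.facility, "year": a.quarter.year, "quarter": a.quarter.q,
              "service": a.service, "resource_category": a.resource_category,
              "funding_source": a.funding_source, "amount": a.amount} for a in allocated]
            or [], columns=["facility_id", "year", "quarter", "service",
                            "resource_category", "funding_source", "amount"]),
        out / "allocated_expenditure.csv", amount_cols=("amount",),
        sum_groups=("facility_id", "year", "quarter", "funding_source"))
    unit_df = ue.units_frame(units, config.category_codes)
    write_table(unit_df, out / "unit_expenditure.csv")
    share = ue.above_facility_share(above, inflows, group_by=("quarter",))
    write_table(share, out / "above_facility_share.csv",
                amount_cols=("above_facility", "facility_inflows"))
    write_table(
        pd.DataFrame(
            [{"facility_id": f.facility, "service": f.service, "year": f.quarter.year,
              "quarter": f.quarter.q, "unit_total": f.unit_total, "center": f.center,
              "spread": f.spread, "score": f.score, "direction": f.direction,
              "note": f.note} for f in flags]
            or [], columns=["facility_id", "service", "year", "quarter", "unit_total",
                            "center", "spread", "score", "direction", "note"]),
        out / "outliers.csv", amount_cols=("unit_total",))
    write_table(dq, out / "data_quality.csv")
    if units:
        roll = ue.rollup(units, ("district", "service", "quarter"), hierarchy)
        write_table(roll, out / "rollup_district.csv",
                    amount_cols=("total_amount", "ok_amount"))
        trend_parts = []
        for fac, svc in sorted({(u.facility, u.service) for u in units}):
            t = an.trend(units, fac, svc)
            t.insert(0, "service", svc)
            t.insert(0, "facility_id", fac)
            trend_parts.append(t)
        write_table(pd.concat(trend_parts, ignore_index=True), out / "trends.csv")
    an.dashboard_export(
        out / "dashboard_export.json",
        selection={
            "geographic_level": config.outlier_group_level,
            "services": list(config.service_codes),
            "resource_categories": list(config.category_codes),
            "measure": "unit",
        },
        views={
            "unit_expenditure": unit_df,
            "above_facility_share": share,
            "data_quality": dq,
        },
    )
    (out / "outlier_notes.txt").write_text("".join(n + "\n" for n in notes))


# ---------------------------------------------------------------------------
# readers for staged (file-by-file) pipeline runs


def read_inflows_table(path: str | Path) -> list:
    from .ledger_io import read_table
    from .org_model import Quarter
    from .step_down import FacilityInflow

    df = read_table(path, amount_cols=("amount",))
    return [
        sd.FacilityInflow(
            facility=r["facility_id"],
            quarter=Quarter(int(r["year"]), int(r["quarter"])),
            amount=float(r["amount"]),
            funding_source=r["funding_source"],
        )
        for r in df.to_dict("records")
    ]


def read_ram_table(path: str | Path) -> dict:
    """Read ``ram_weights.csv`` back into per-facility RAMs (weights are
    renormalized to absorb serialization round-off)."""
    from .ledger_io import read_table

    df = read_table(path)
    rams = {}
    for fid, grp in df.groupby("facility_id"):
        weights = [
            ((r["service"], r["resource_category"]), float(r["weight"]))
            for r in grp.to_dict("records")
        ]
        total = sum(w for _, w in weights)
        rams[fid] = ram_mod.RAM(fid, tuple(sorted((k, w / total) for k, w in weights)))
    return rams


def read_allocated_table(path: str | Path) -> list:
    from .ledger_io import read_table
    from .org_model import Quarter

    df = read_table(path, amount_cols=("amount",))
    return [
        ram_mod.AllocatedExpenditure(
            facility=r["facility_id"],
            quarter=Quarter(int(r["year"]), int(r["quarter"])),
            service=r["service"],
            resource_category=r["resource_category"],
            amount=float(r["amount"]),
            funding_source=r["funding_source"],
        )
        for r in df.to_dict("records")
    ]


def read_units_table(path: str | Path) -> list:
    from .ledger_io import read_table
    from .org_model import Quarter

    df = read_table(path)
    cats = [c[len("unit_"):] for c in df.columns if c.startswith("unit_") and c != "unit_total"]
    out = []
    for r in df.to_dict("records"):
        volume = None if r["volume"] == "" else int(r["volume"])
        unit_total = None if r["unit_total"] == "" else float(r["unit_total"])
        by_cat = tuple(
            (c, float(r[f"unit_{c}"])) for c in cats if r.get(f"unit_{c}", "") != ""
        )
        total = float(r["total_amount"])
        out.append(
            ue.UnitExpenditure(
                facility=r["facility_id"],
                quarter=Quarter(int(r["year"]), int(r["quarter"])),
                service=r["service"],
                volume=volume,
                total_amount=total,
                unit_total=unit_total,
                unit_by_category=by_cat,
                status=r["status"],
                amount_by_category=tuple(
                    (c, u * volume) for c, u in by_cat
                ) if volume else (),
            )
        )
    return out
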