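"""Synthetic scenario generator: internally consistent ledger, weights,
assessments, schedules and volumes with known ground truth.

Generation is truth-first. Service volumes and true unit costs are fixed
first; each facility's true service expenditure follows as
``true_unit_cost × volume × (1 + noise)``; the ledger, HIV-share weights
and flow-down rules are then synthesized so that the cascade delivers
exactly those facility totals plus the configured above-facility
retentions. Running the full pipeline on a noiseless bundle therefore
recovers ``true_unit_cost`` for every (facility, service, quarter) — the
generator makes the whole computation chain falsifiable.

Constructions that make exact recovery possible under a time-invariant RAM:

* volumes are drawn once per (facility, service) and held constant across
  quarters (a stable caseload), so each facility's service mix matches its
  annual operational budget in every quarter;
* ledger noise is one multiplicative factor per facility-quarter, applied
  to the facility's whole inflow, leaving the within-facility mix intact.

Draw order from the single seeded stream is fixed (volumes, then noise
factors, then decoy amounts) so adding downstream options never perturbs
earlier draws.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import DEFAULT_SERVICES, RunConfig
from .ledger_io import write_table
from .org_model import OrgUnit, Quarter, ValidationError, quarter_range

__all__ = ["Scenario", "Bundle", "generate", "corrupt", "load_scenario"]

DEFAULT_TRUE_UNIT_COST: dict[tuple[str, str], float] = {
    ("hospital", "HTC"): 150.0, ("hospital", "EMTCT"): 900.0, ("hospital", "ART"): 700.0,
    ("urban_health_centre", "HTC"): 90.0, ("urban_health_centre", "EMTCT"): 400.0,
    ("urban_health_centre", "ART"): 450.0,
    ("rural_health_centre", "HTC"): 60.0, ("rural_health_centre", "EMTCT"): 250.0,
    ("rural_health_centre", "ART"): 300.0,
}

DEFAULT_VOLUME_MEAN: dict[tuple[str, str], float] = {
    ("hospital", "HTC"): 800.0, ("hospital", "EMTCT"): 120.0, ("hospital", "ART"): 1500.0,
    ("urban_health_centre", "HTC"): 400.0, ("urban_health_centre", "EMTCT"): 60.0,
    ("urban_health_centre", "ART"): 600.0,
    ("rural_health_centre", "HTC"): 150.0, ("rural_health_centre", "EMTCT"): 25.0,
    ("rural_health_centre", "ART"): 200.0,
}

DEFAULT_CATEGORY_MIX: dict[str, dict[str, float]] = {
    "HTC": {"personnel": 0.45, "drugs": 0.05, "supplies": 0.30, "equipment": 0.10,
            "vehicles": 0.02, "other": 0.08},
    "EMTCT": {"personnel": 0.40, "drugs": 0.25, "supplies": 0.15, "equipment": 0.10,
              "vehicles": 0.03, "other": 0.07},
    "ART": {"personnel": 0.30, "drugs": 0.45, "supplies": 0.10, "equipment": 0.08,
            "vehicles": 0.02, "other": 0.05},
}

FACILITY_TYPES = ("hospital", "urban_health_centre", "rural_health_centre")

#: Account heads: facility-controlled, national step-down chain, non-HIV decoy.
HEAD_FACILITY, HEAD_CHAIN, HEAD_DECOY = "01", "90", "80"


@dataclass(frozen=True)
class Scenario:
    """Ground-truth study conditions for one synthetic bundle.

    ``above_facility_fraction`` gives, per non-facility level, the share of
    money arriving at that level on the step-down chain that is retained
    there. ``routed_fraction`` is the portion of each facility's baseline
    requirement delivered via the national→province→district chain; the
    remainder arrives on the facility's own ledger account. HIV-share
    weights gross the HIV amounts up into larger ledger totals so the
    isolation step is exercised.
    """

    seed: int = 1
    n_provinces: int = 2
    districts_per_province: int = 2
    facilities_per_district: int = 3
    start: Quarter = Quarter(2016, 1)
    n_quarters: int = 4
    services: tuple[str, ...] = tuple(s.code for s in DEFAULT_SERVICES)
    true_unit_cost: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_UNIT_COST))
    volume_mean: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_MEAN))
    volume_dispersion: float = 8.0  # negative-binomial shape; larger = tighter
    category_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_CATEGORY_MIX))
    above_facility_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"national": 0.10, "provincial": 0.06, "district": 0.04})
    routed_fraction: float = 0.5
    hiv_share_facility: float = 0.6
    hiv_share_chain: float = 0.8
    noise_sd: float = 0.1
    funding_source: str = "GRZ"

    def validate(self) -> None:
        problems = []
        for lvl in ("national", "provincial", "district"):
            frac = self.above_facility_fraction.get(lvl, 0.0)
            if not 0.0 <= frac <= 1.0:
                problems.append(f"above_facility_fraction[{lvl}] outside [0, 1]")
            if frac >= 1.0 and self.routed_fraction > 0:
                problems.append(
                    f"above_facility_fraction[{lvl}] = 1 absorbs the whole chain; "
                    "no money can reach facilities")
        if not 0.0 <= self.routed_fraction < 1.0:
            problems.append("routed_fraction must be in [0, 1)")
        for svc in self.services:
            mix = self.category_mix.get(svc)
            if mix is None:
                problems.append(f"no category mix for service {svc}")
                continue
            if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
                problems.append(f"category mix for {svc} must be nonnegative and sum to 1")
        if not 0.0 < self.hiv_share_facility <= 1.0 or not 0.0 < self.hiv_share_chain <= 1.0:
            problems.append("HIV shares must be in (0, 1]")
        if self.noise_sd < 0:
            problems.append("noise_sd must be nonnegative")
        if self.n_provinces < 1 or self.districts_per_province < 1 \
                or self.facilities_per_district < 1 or self.n_quarters < 1:
            problems.append("counts must be positive")
        if problems:
            raise ValidationError(problems)


@dataclass
class Bundle:
    """Generated input tables (CSV-schema DataFrames) plus ground truth."""

    scenario: Scenario
    org_units: pd.DataFrame
    expenditures: pd.DataFrame
    hiv_share_weights: pd.DataFrame
    flow_down_rules: pd.DataFrame
    facility_assessment: pd.DataFrame
    service_schedule: pd.DataFrame
    output_volumes: pd.DataFrame
    ground_truth: pd.DataFrame          # facility × service × quarter truth
    ground_truth_above: pd.DataFrame    # per-level above-facility truth
    manifest: list = field(default_factory=list)  # injected faults

    def write(self, out_dir: str | Path) -> None:
        """Write every input table (and the ground truth) as CSV, plus the
        services/categories config the loaders need."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(self.org_units, out / "org_units.csv")
        # full-precision amounts: the ledger is an input stream, and exact
        # noiseless parameter recovery requires it to round-trip bit-exact
        write_table(self.expenditures, out / "expenditures.csv")
        write_table(self.hiv_share_weights, out / "hiv_share_weights.csv")
        write_table(self.flow_down_rules, out / "flow_down_rules.csv")
        write_table(self.facility_assessment, out / "facility_assessment.csv")
        write_table(self.service_schedule, out / "service_schedule.csv")
        write_table(self.output_volumes, out / "output_volumes.csv")
        write_table(self.ground_truth, out / "ground_truth.csv")
        write_table(self.ground_truth_above, out / "ground_truth_above.csv")
        cats = sorted({c for mix in self.scenario.category_mix.values() for c in mix})
        config = {
            "services": [{"code": s, "label": s, "output_indicator": f"{s} visits"}
                         for s in self.scenario.services],
            "resource_categories": cats,
        }
        (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
        if self.manifest:
            (out / "fault_manifest.yaml").write_text(
                yaml.safe_dump(self.manifest, sort_keys=True))


def _hierarchy_rows(scenario: Scenario) -> tuple[pd.DataFrame, list[dict]]:
    rows = [{"id": "NAT", "name": "National", "level": "national",
             "parent_id": "", "facility_type": ""}]
    facilities = []
    for p in range(1, scenario.n_provinces + 1):
        pid = f"P{p:02d}"
        rows.append({"id": pid, "name": f"Province {p}", "level": "provincial",
                     "parent_id": "NAT", "facility_type": ""})
        for d in range(1, scenario.districts_per_province + 1):
            did = f"{pid}-D{d:02d}"
            rows.append({"id": did, "name": f"District {p}.{d}", "level": "district",
                         "parent_id": pid, "facility_type": ""})
            for f in range(1, scenario.facilities_per_district + 1):
                fid = f"{did}-F{f:02d}"
                ftype = FACILITY_TYPES[(f - 1) % len(FACILITY_TYPES)]
                rows.append({"id": fid, "name": f"Facility {p}.{d}.{f}",
                             "level": "facility", "parent_id": did,
                             "facility_type": ftype})
                facilities.append({"id": fid, "province": pid, "district": did,
                                   "type": ftype, "p": p, "d": d, "f": f})
    return pd.DataFrame(rows), facilities


def generate(scenario: Scenario) -> Bundle:
    """Build a complete input bundle from a scenario; deterministic per seed."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    quarters = quarter_range(scenario.start, _end_quarter(scenario))
    org_df, facilities = _hierarchy_rows(scenario)
    services = list(scenario.services)
    cats = sorted({c for mix in scenario.category_mix.values() for c in mix})
    cfg = RunConfig()
    capital_life = cfg.useful_life_years  # equipment/vehicles annualization

    # -- draw 1: volumes, constant across quarters (stable caseload)
    vol: dict[tuple[str, str], int] = {}
    for fac in facilities:
        for svc in services:
            mean = scenario.volume_mean[(fac["type"], svc)]
            k = scenario.volume_dispersion
            draw = rng.negative_binomial(k, k / (k + mean))
            vol[(fac["id"], svc)] = max(1, int(draw))

    # baseline quarterly requirement per facility/service (noise-free)
    base_fs = {
        (fac["id"], svc): scenario.true_unit_cost[(fac["type"], svc)] * vol[(fac["id"], svc)]
        for fac in facilities for svc in services
    }
    base_f = {fac["id"]: sum(base_fs[(fac["id"], s)] for s in services) for fac in facilities}
    base_tot = sum(base_f.values())

    # -- draw 2: one multiplicative noise factor per facility-quarter
    alpha = scenario.routed_fraction
    eps: dict[tuple[str, str], float] = {}
    for fac in facilities:
        for q in quarters:
            e = rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd > 0 else 0.0
            eps[(fac["id"], q.format())] = max(e, -(1.0 - alpha) * 0.95)

    # -- draw 3: decoy (non-HIV) ledger amounts per quarter
    decoy = {q.format(): float(rng.uniform(5e4, 2e5)) for q in quarters}

    rho = {lvl: scenario.above_facility_fraction.get(lvl, 0.0)
           for lvl in ("national", "provincial", "district")}
    pass_through = (1 - rho["national"]) * (1 - rho["provincial"]) * (1 - rho["district"])
    if alpha > 0 and pass_through <= 0:
        raise ValidationError(["chain retains everything; routed_fraction must be 0"])

    # ledger rows -----------------------------------------------------------
    led_rows, truth_above = [], []
    chain_account = f"{HEAD_CHAIN}/00/00/01"
    routed_deliver = alpha * base_tot  # per quarter, delivered to facilities
    chain_amount = routed_deliver / pass_through if alpha > 0 else 0.0
    for q in quarters:
        if alpha > 0:
            led_rows.append({
                "account_code": chain_account, "org_unit_id": "NAT",
                "year": q.year, "quarter": q.q,
                "amount": chain_amount / scenario.hiv_share_chain,
                "funding_source": scenario.funding_source})
            # above-facility truth along the chain
            truth_above.append({"level": "national", "org_unit_id": "NAT",
                                "year": q.year, "quarter": q.q,
                                "amount": chain_amount * rho["national"]})
            after_nat = chain_amount * (1 - rho["national"])
            for p in range(1, scenario.n_provinces + 1):
                pid = f"P{p:02d}"
                share_p = sum(base_f[f["id"]] for f in facilities if f["province"] == pid) / base_tot
                arriving = after_nat * share_p
                truth_above.append({"level": "provincial", "org_unit_id": pid,
                                    "year": q.year, "quarter": q.q,
                                    "amount": arriving * rho["provincial"]})
                after_prov = arriving * (1 - rho["provincial"])
                prov_base = sum(base_f[f["id"]] for f in facilities if f["province"] == pid)
                for d in range(1, scenario.districts_per_province + 1):
                    did = f"{pid}-D{d:02d}"
                    dist_base = sum(base_f[f["id"]] for f in facilities if f["district"] == did)
                    arriving_d = after_prov * dist_base / prov_base
                    truth_above.append({"level": "district", "org_unit_id": did,
                                        "year": q.year, "quarter": q.q,
                                        "amount": arriving_d * rho["district"]})
        # facility direct accounts balance each facility to its noisy truth
        for fac in facilities:
            fid = fac["id"]
            account = f"{HEAD_FACILITY}/{fac['p']:02d}/{fac['d']:02d}/{fac['f']:02d}"
            direct = base_f[fid] * (1 - alpha + eps[(fid, q.format())])
            led_rows.append({
                "account_code": account, "org_unit_id": fid,
                "year": q.year, "quarter": q.q,
                "amount": direct / scenario.hiv_share_facility,
                "funding_source": scenario.funding_source})
        # decoy non-HIV spending (no weight pattern -> default share 0)
        led_rows.append({
            "account_code": f"{HEAD_DECOY}/01/01/01", "org_unit_id": "NAT",
            "year": q.year, "quarter": q.q, "amount": decoy[q.format()],
            "funding_source": scenario.funding_source})

    weights_df = pd.DataFrame([
        {"account_pattern": HEAD_FACILITY, "hiv_share": scenario.hiv_share_facility},
        {"account_pattern": HEAD_CHAIN, "hiv_share": scenario.hiv_share_chain},
    ])

    # flow-down rules for the chain account (explicit shares, base-proportional)
    rule_rows = []
    if alpha > 0:
        for p in range(1, scenario.n_provinces + 1):
            pid = f"P{p:02d}"
            share = (1 - rho["national"]) * sum(
                base_f[f["id"]] for f in facilities if f["province"] == pid) / base_tot
            rule_rows.append({"account_pattern": HEAD_CHAIN, "source_unit_id": "NAT",
                              "retained_share": rho["national"],
                              "child_unit_id": pid, "child_share": share})
            prov_base = sum(base_f[f["id"]] for f in facilities if f["province"] == pid)
            for d in range(1, scenario.districts_per_province + 1):
                did = f"{pid}-D{d:02d}"
                dist_base = sum(base_f[f["id"]] for f in facilities if f["district"] == did)
                rule_rows.append({"account_pattern": HEAD_CHAIN, "source_unit_id": pid,
                                  "retained_share": rho["provincial"],
                                  "child_unit_id": did,
                                  "child_share": (1 - rho["provincial"]) * dist_base / prov_base})
                for f in facilities:
                    if f["district"] != did:
                        continue
                    rule_rows.append({
                        "account_pattern": HEAD_CHAIN, "source_unit_id": did,
                        "retained_share": rho["district"], "child_unit_id": f["id"],
                        "child_share": (1 - rho["district"]) * base_f[f["id"]] / dist_base})
    rules_df = pd.DataFrame(
        rule_rows,
        columns=["account_pattern", "source_unit_id", "retained_share",
                 "child_unit_id", "child_share"])

    # assessments & schedules (annual; budgets reproduce the category mix)
    assess_rows, sched_rows = [], []
    for fac in facilities:
        fid = fac["id"]
        for svc in services:
            annual = base_fs[(fid, svc)] * len(quarters)
            for cat in cats:
                target = annual * scenario.category_mix[svc].get(cat, 0.0)
                if target <= 0:
                    continue
                life = capital_life.get(cat)
                assess_rows.append({
                    "facility_id": fid, "item_id": f"{fid}-{svc}-{cat}",
                    "description": f"{cat} supporting {svc}",
                    "resource_category": cat,
                    "annual_quantity": 1.0,
                    "standard_unit_cost": target * life if life else target,
                    "dedicated_service": svc,
                    "useful_life_years": life if life else ""})
            sched_rows.append({
                "facility_id": fid, "service": svc, "sessions_per_week": 5.0,
                "location": "facility",
                "relative_annual_volume": vol[(fid, svc)] * len(quarters)})

    # volumes and per-cell ground truth
    vol_rows, truth_rows = [], []
    for fac in facilities:
        fid = fac["id"]
        for svc in services:
            for q in quarters:
                v = vol[(fid, svc)]
                noise_factor = 1.0 + eps[(fid, q.format())]
                vol_rows.append({"facility_id": fid, "service": svc,
                                 "year": q.year, "quarter": q.q, "count": v})
                truth_rows.append({
                    "facility_id": fid, "service": svc,
                    "year": q.year, "quarter": q.q, "volume": v,
                    "true_unit_cost": scenario.true_unit_cost[(fac["type"], svc)],
                    "noise_factor": noise_factor,
                    "true_expenditure": base_fs[(fid, svc)] * noise_factor})

    return Bundle(
        scenario=scenario,
        org_units=org_df,
        expenditures=pd.DataFrame(led_rows),
        hiv_share_weights=weights_df,
        flow_down_rules=rules_df,
        facility_assessment=pd.DataFrame(assess_rows),
        service_schedule=pd.DataFrame(sched_rows),
        output_volumes=pd.DataFrame(vol_rows),
        ground_truth=pd.DataFrame(truth_rows),
        ground_truth_above=pd.DataFrame(
            truth_above, columns=["level", "org_unit_id", "year", "quarter", "amount"]),
    )


def _end_quarter(scenario: Scenario) -> Quarter:
    q = scenario.start
    for _ in range(scenario.n_quarters - 1):
        q = q.next()
    return q


# ---------------------------------------------------------------------------
# fault injection


def corrupt(bundle: Bundle, faults: Sequence[Mapping[str, object]]) -> Bundle:
    """Return a copy of the bundle with data-quality faults injected.

    Supported fault kinds (each recorded in the returned bundle's manifest):

    * ``{"kind": "drop_volume", "facility": ..., "service": ..., "quarter": "2016Q1"}``
      — remove the volume row (missing, not zero);
    * ``{"kind": "zero_volume", ...same keys...}`` — set the count to 0;
    * ``{"kind": "delete_ram", "facility": ...}`` — remove the facility's
      assessment lines so no RAM can be built;
    * ``{"kind": "inflate_ledger", "facility": ..., "factor": 10}`` —
      multiply the facility's own ledger rows.

    An empty fault list returns an identical copy.
    """
    out = Bundle(
        scenario=bundle.scenario,
        org_units=bundle.org_units.copy(),
        expenditures=bundle.expenditures.copy(),
        hiv_share_weights=bundle.hiv_share_weights.copy(),
        flow_down_rules=bundle.flow_down_rules.copy(),
        facility_assessment=bundle.facility_assessment.copy(),
        service_schedule=bundle.service_schedule.copy(),
        output_volumes=bundle.output_volumes.copy(),
        ground_truth=bundle.ground_truth.copy(),
        ground_truth_above=bundle.ground_truth_above.copy(),
        manifest=list(bundle.manifest),
    )
    for fault in faults:
        kind = fault["kind"]
        if kind in ("drop_volume", "zero_volume"):
            q = Quarter.parse(str(fault["quarter"]))
            mask = (
                (out.output_volumes["facility_id"] == fault["facility"])
                & (out.output_volumes["service"] == fault["service"])
                & (out.output_volumes["year"] == q.year)
                & (out.output_volumes["quarter"] == q.q)
            )
            if not mask.any():
                raise ValidationError([f"fault targets absent volume row: {fault}"])
            if kind == "drop_volume":
                out.output_volumes = out.output_volumes[~mask].reset_index(drop=True)
            else:
                out.output_volumes.loc[mask, "count"] = 0
        elif kind == "delete_ram":
            mask = out.facility_assessment["facility_id"] == fault["facility"]
            if not mask.any():
                raise ValidationError([f"fault targets unknown facility: {fault}"])
            out.facility_assessment = out.facility_assessment[~mask].reset_index(drop=True)
        elif kind == "inflate_ledger":
            factor = float(fault.get("factor", 10.0))
            mask = out.expenditures["org_unit_id"] == fault["facility"]
            if not mask.any():
                raise ValidationError([f"fault targets unknown facility: {fault}"])
            out.expenditures.loc[mask, "amount"] = (
                out.expenditures.loc[mask, "amount"].astype(float) * factor)
        else:
            raise ValidationError([f"unknown fault kind {kind!r}"])
        out.manifest.append(dict(fault))
    return out


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario YAML; tuple-keyed maps use "type|service" keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for simple in ("seed", "n_provinces", "districts_per_province",
                   "facilities_per_district", "n_quarters", "volume_dispersion",
                   "routed_fraction", "hiv_share_facility", "hiv_share_chain",
                   "noise_sd", "funding_source"):
        if simple in raw:
            kwargs[simple] = raw[simple]
    if "start" in raw:
        kwargs["start"] = Quarter.parse(str(raw["start"]))
    if "services" in raw:
        kwargs["services"] = tuple(raw["services"])
    for mapkey in ("true_unit_cost", "volume_mean"):
        if mapkey in raw:
            kwargs[mapkey] = {tuple(k.split("|")): float(v) for k, v in raw[mapkey].items()}
    if "category_mix" in raw:
        kwargs["category_mix"] = {s: dict(m) for s, m in raw["category_mix"].items()}
    if "above_facility_fraction" in raw:
        kwargs["above_facility_fraction"] = dict(raw["above_facility_fraction"])
    return Scenario(**kwargs)
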