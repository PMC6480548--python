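"""Readers, validators and writers for ledger, weights, volumes and results.

All readers validate against the org hierarchy and service/category
registries and report *every* bad row (with its line number) in one error.
All writers emit a fixed CSV dialect — UTF-8, comma-separated, quoted text
fields, LF line endings, deterministic column order and row sort, currency
serialized at 2 decimals with round-half-even — so re-running a pipeline
yields byte-identical tables.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import RunConfig
from .org_model import (
    AccountCode,
    AccountParseError,
    Hierarchy,
    Quarter,
    ValidationError,
    parse_account,
)

__all__ = [
    "ExpenditureRecord",
    "OutputVolume",
    "IngestError",
    "read_org_units",
    "read_ledger",
    "read_volumes",
    "write_table",
    "read_table",
    "round_currency",
    "round_preserving_sum",
]

TWO_DP = Decimal("0.01")


class IngestError(ValidationError):
    """Ingest failure; ``violations`` lists every offending row."""


@dataclass(frozen=True)
class ExpenditureRecord:
    """Money spent against one account by one org unit in one quarter."""

    account: AccountCode
    org_unit: str
    quarter: Quarter
    amount: float
    funding_source: str = ""

    @property
    def key(self) -> tuple:
        return (self.account.format(), self.org_unit, self.quarter, self.funding_source)


@dataclass(frozen=True)
class OutputVolume:
    """Service output count for one facility in one quarter (DHIS2-style)."""

    facility: str
    service: str
    quarter: Quarter
    count: int


def _read_rows(path: str | Path, expected_header: Sequence[str]) -> list[tuple[int, dict]]:
    """Read CSV rows as (line_number, dict); enforce the header contract."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise IngestError([f"{path}: empty file, expected header {','.join(expected_header)}"])
        missing = [c for c in expected_header if c not in reader.fieldnames]
        if missing:
            raise IngestError([f"{path}: missing columns {missing} (header {reader.fieldnames})"])
        return [(i, row) for i, row in enumerate(reader, start=2)]


def read_org_units(path: str | Path) -> Hierarchy:
    """Read ``org_units.csv`` (id,name,level,parent_id,facility_type) and
    validate it into a :class:`~rems.org_model.Hierarchy`."""
    from .org_model import OrgUnit, validate_hierarchy

    units = []
    for lineno, row in _read_rows(path, ["id", "name", "level", "parent_id", "facility_type"]):
        units.append(
            OrgUnit(
                id=row["id"],
                name=row["name"],
                level=row["level"],
                parent_id=row["parent_id"] or None,
                facility_type=row["facility_type"] or None,
            )
        )
    return validate_hierarchy(units)


def read_ledger(
    path: str | Path,
    hierarchy: Hierarchy,
    config: RunConfig | None = None,
) -> list[ExpenditureRecord]:
    """Ingest an expenditure ledger CSV into aggregated records.

    Duplicate (account, org_unit, quarter, funding_source) keys are summed
    exactly (decimal arithmetic). Negative rows follow
    ``config.negative_amount_policy``: with ``net`` they offset positive rows
    within their key and a key that nets negative is an error; with
    ``reject`` any negative row is an error. Ingest is order-independent.
    """
    config = config or RunConfig()
    errors: list[str] = []
    totals: dict[tuple, Decimal] = {}
    parsed: dict[tuple, tuple[AccountCode, str, Quarter, str]] = {}
    for lineno, row in _read_rows(
        path, ["account_code", "org_unit_id", "year", "quarter", "amount", "funding_source"]
    ):
        where = f"{path}:{lineno}"
        try:
            account = parse_account(row["account_code"])
        except AccountParseError as exc:
            errors.append(f"{where}: {exc}")
            continue
        unit_id = row["org_unit_id"]
        if unit_id not in hierarchy:
            errors.append(f"{where}: unknown org unit {unit_id!r}")
            continue
        try:
            quarter = Quarter(int(row["year"]), int(row["quarter"]))
        except (ValueError, ValidationError):
            errors.append(f"{where}: bad period {row['year']!r}Q{row['quarter']!r}")
            continue
        try:
            amount = Decimal(row["amount"])
        except ArithmeticError:
            errors.append(f"{where}: non-numeric amount {row['amount']!r}")
            continue
        if amount < 0 and config.negative_amount_policy == "reject":
            errors.append(f"{where}: negative amount {amount} (policy=reject)")
            continue
        source = row.get("funding_source") or ""
        key = (account.format(), unit_id, quarter, source)
        totals[key] = totals.get(key, Decimal(0)) + amount
        parsed[key] = (account, unit_id, quarter, source)
    for key, total in totals.items():
        if total < 0:
            acct, unit_id, quarter, source = parsed[key]
            errors.append(
                f"{path}: key ({acct.format()}, {unit_id}, {quarter}, {source!r}) "
                f"nets negative ({total})"
            )
    if errors:
        raise IngestError(errors)
    return sorted(
        (
            ExpenditureRecord(*parsed[key][:3], float(total), parsed[key][3])
            for key, total in totals.items()
        ),
        key=lambda r: r.key,
    )


def read_volumes(
    path: str | Path,
    hierarchy: Hierarchy,
    config: RunConfig | None = None,
) -> list[OutputVolume]:
    """Ingest facility output volumes.

    Missing (facility, service, quarter) combinations stay absent — absence
    is a data-quality signal downstream, never an implicit zero. Duplicate
    keys are an error: the output system reports one value per
    indicator-period, so a duplicate means a malformed export.
    """
    config = config or RunConfig()
    known_services = set(config.service_codes)
    errors: list[str] = []
    out: dict[tuple, OutputVolume] = {}
    for lineno, row in _read_rows(path, ["facility_id", "service", "year", "quarter", "count"]):
        where = f"{path}:{lineno}"
        fid = row["facility_id"]
        if fid not in hierarchy:
            errors.append(f"{where}: unknown facility {fid!r}")
            continue
        if hierarchy.level(fid) != "facility":
            errors.append(f"{where}: org unit {fid!r} is not a facility")
            continue
        if row["service"] not in known_services:
            errors.append(f"{where}: unregistered service {row['service']!r}")
            continue
        try:
            quarter = Quarter(int(row["year"]), int(row["quarter"]))
        except (ValueError, ValidationError):
            errors.append(f"{where}: bad period {row['year']!r}Q{row['quarter']!r}")
            continue
        try:
            count = int(row["count"])
        except ValueError:
            errors.append(f"{where}: non-integer count {row['count']!r}")
            continue
        if count < 0:
            errors.append(f"{where}: negative count {count}")
            continue
        key = (fid, row["service"], quarter)
        if key in out:
            errors.append(f"{where}: duplicate volume row for {key}")
            continue
        out[key] = OutputVolume(fid, row["service"], quarter, count)
    if errors:
        raise IngestError(errors)
    return sorted(out.values(), key=lambda v: (v.facility, v.service, v.quarter))


# ---------------------------------------------------------------------------
# currency rounding


def round_currency(x: float) -> float:
    """Round to 2 decimals, half-even (banker's rounding)."""
    return float(Decimal(repr(x)).quantize(TWO_DP, rounding=ROUND_HALF_EVEN))


def round_preserving_sum(values: Sequence[float]) -> list[float]:
    """Round each value to 2 dp such that the rounded values sum to the
    rounded total (largest-remainder adjustment on whole cents).

    Per-value rounding is half-even; any cent discrepancy against the
    rounded total is distributed to the values whose rounding moved them
    furthest in the compensating direction, so written rows always sum to
    the written total.
    """
    if not values:
        return []
    cents = [Decimal(repr(v)) * 100 for v in values]
    rounded = [c.quantize(Decimal(1), rounding=ROUND_HALF_EVEN) for c in cents]
    target = sum(cents).quantize(Decimal(1), rounding=ROUND_HALF_EVEN)
    diff = int(target - sum(rounded))  # cents still to hand out (can be negative)
    if diff:
        step = 1 if diff > 0 else -1
        # residual = what rounding took away (positive if rounded down)
        order = sorted(
            range(len(values)), key=lambda i: step * (cents[i] - rounded[i]), reverse=True
        )
        for k in range(abs(diff)):
            rounded[order[k % len(values)]] += step
    return [float(r) / 100.0 for r in rounded]


# ---------------------------------------------------------------------------
# generic result tables


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    amount_cols: Sequence[str] = (),
    sum_groups: Optional[Sequence[str]] = None,
) -> None:
    """Write a result table deterministically.

    Rows are sorted ascending on every non-amount column; amount columns are
    serialized at 2 dp (round-half-even). When ``sum_groups`` is given,
    largest-remainder adjustment is applied within each group so the written
    amounts sum exactly to the written group totals. Text fields are quoted;
    line endings are LF; re-reading reproduces values exactly.
    """
    df = df.copy()
    key_cols = [c for c in df.columns if c not in amount_cols]
    if key_cols and len(df):
        df = df.sort_values(key_cols, kind="mergesort").reset_index(drop=True)
    for col in amount_cols:
        if not len(df):
            continue
        vals = df[col].astype(float)
        if sum_groups:
            parts = []
            for _, idx in df.groupby(list(sum_groups), sort=False, dropna=False).groups.items():
                sub = vals.loc[idx]
                parts.append(pd.Series(round_preserving_sum(list(sub)), index=sub.index))
            vals = pd.concat(parts).sort_index()
        else:
            vals = vals.map(round_currency)
        df[col] = vals.map(lambda v: f"{v:.2f}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_NONNUMERIC, lineterminator="\n")
        writer.writerow(list(df.columns))
        for row in df.itertuples(index=False):
            out = []
            for x in row:
                if isinstance(x, str):
                    out.append(x)
                elif pd.isna(x):
                    out.append("")
                elif hasattr(x, "item"):  # numpy scalar -> python number
                    out.append(x.item())
                else:
                    out.append(x)
            writer.writerow(out)


def read_table(path: str | Path, amount_cols: Sequence[str] = ()) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`.

    Quoted (text) fields stay strings; unquoted integer columns come back as
    integers, so write -> read -> write reproduces the file byte-exact.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in df.columns:
        if col in amount_cols:
            df[col] = df[col].map(lambda s: float(s) if s != "" else float("nan"))
        elif len(df) and df[col].str.fullmatch(r"-?\d+").all():
            # column was written unquoted-numeric; restore the dtype
            df[col] = df[col].astype(int)
    return df
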