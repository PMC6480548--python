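"""Administrative hierarchy, chart of accounts, periods, services, categories.

The domain model mirrors how a ministry-of-health ledger and a facility
output system are organised: a strict four-level administrative tree
(national → provincial → district → facility), hierarchical account codes
of the head/department/unit/programme[/activity] form, calendar quarters,
and the registries of HIV service lines and expense (resource) categories
that the allocation engine distributes money over.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "LEVELS",
    "AccountCode",
    "Quarter",
    "OrgUnit",
    "ServiceLine",
    "ResourceCategory",
    "Hierarchy",
    "ValidationError",
    "AccountParseError",
    "parse_account",
    "validate_hierarchy",
    "quarter_range",
    "DEFAULT_RESOURCE_CATEGORIES",
    "SHARED",
]

#: Administrative levels from root to leaf; child level is exactly one rank
#: below its parent.
LEVELS: tuple[str, ...] = ("national", "provincial", "district", "facility")

#: Sentinel service code meaning "used by several services" on an
#: assessment line item.
SHARED = "SHARED"


class ValidationError(ValueError):
    """Raised when domain invariants are violated; carries every violation."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class AccountParseError(ValueError):
    """Raised for malformed account-code text."""


@dataclass(frozen=True, order=True)
class AccountCode:
    """Hierarchical ledger key: head/department/unit/programme[/activity].

    Segments are opaque text (zero-padded codes round-trip unchanged).
    A code with more segments is more specific; ``is_prefix_of`` gives the
    partial order used for weight- and rule-matching.
    """

    segments: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (1 <= len(self.segments) <= 5):
            raise AccountParseError(
                f"account code needs 1-5 segments, got {len(self.segments)}"
            )
        for seg in self.segments:
            if not seg:
                raise AccountParseError("empty segment in account code")
            if "/" in seg:
                raise AccountParseError(f"segment {seg!r} contains '/'")

    @property
    def head(self) -> str:
        return self.segments[0]

    @property
    def department(self) -> Optional[str]:
        return self.segments[1] if len(self.segments) > 1 else None

    @property
    def unit(self) -> Optional[str]:
        return self.segments[2] if len(self.segments) > 2 else None

    @property
    def programme(self) -> Optional[str]:
        return self.segments[3] if len(self.segments) > 3 else None

    @property
    def activity(self) -> Optional[str]:
        return self.segments[4] if len(self.segments) > 4 else None

    @property
    def specificity(self) -> int:
        return len(self.segments)

    def is_prefix_of(self, other: "AccountCode") -> bool:
        return (
            len(self.segments) <= len(other.segments)
            and other.segments[: len(self.segments)] == self.segments
        )

    def format(self) -> str:
        return "/".join(self.segments)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


def parse_account(code_text: str, *, full: bool = True) -> AccountCode:
    """Parse ``"01/02/03/04[/05]"`` into an :class:`AccountCode`.

    Full ledger codes carry 4 or 5 segments; with ``full=False`` any
    1-5 segment prefix is accepted (used for weight/rule patterns).
    ``parse_account(c).format() == c`` for every valid input.
    """
    if not isinstance(code_text, str) or not code_text:
        raise AccountParseError(f"not an account code: {code_text!r}")
    segments = code_text.split("/")
    if any(not s for s in segments):
        raise AccountParseError(f"empty segment in account code {code_text!r}")
    if full and len(segments) not in (4, 5):
        raise AccountParseError(
            f"account code {code_text!r} has {len(segments)} segments, expected 4 or 5"
        )
    return AccountCode(tuple(segments))


@dataclass(frozen=True, order=True)
class Quarter:
    """A calendar quarter; totally ordered, with succ/pred across years."""

    year: int
    q: int

    def __post_init__(self) -> None:
        if not 1 <= self.q <= 4:
            raise ValidationError([f"quarter must be in 1..4, got {self.q}"])

    @property
    def index(self) -> int:
        """Monotone integer index; consecutive quarters differ by 1."""
        return self.year * 4 + (self.q - 1)

    def next(self) -> "Quarter":
        return Quarter(self.year + (self.q == 4), 1 if self.q == 4 else self.q + 1)

    def prev(self) -> "Quarter":
        return Quarter(self.year - (self.q == 1), 4 if self.q == 1 else self.q - 1)

    def format(self) -> str:
        return f"{self.year}Q{self.q}"

    @classmethod
    def parse(cls, text: str) -> "Quarter":
        try:
            year, q = text.upper().split("Q")
            return cls(int(year), int(q))
        except (ValueError, TypeError) as exc:
            raise ValidationError([f"bad quarter {text!r}"]) from exc

    def __str__(self) -> str:  # pragma: no cover
        return self.format()


def quarter_range(start: Quarter, end: Quarter) -> list[Quarter]:
    """Inclusive ordered sequence of quarters from ``start`` to ``end``."""
    if start > end:
        raise ValidationError([f"quarter range start {start} after end {end}"])
    out, q = [], start
    while q <= end:
        out.append(q)
        q = q.next()
    return out


@dataclass(frozen=True)
class OrgUnit:
    """A node in the administrative tree."""

    id: str
    name: str
    level: str
    parent_id: Optional[str] = None
    facility_type: Optional[str] = None


@dataclass(frozen=True)
class ServiceLine:
    """A distinct HIV service (e.g. HTC, EMTCT, ART) and its output measure."""

    code: str
    label: str = ""
    output_indicator: str = ""


@dataclass(frozen=True)
class ResourceCategory:
    """An expense category a facility's resources are classified into."""

    code: str
    label: str = ""


DEFAULT_RESOURCE_CATEGORIES: tuple[ResourceCategory, ...] = tuple(
    ResourceCategory(c, c.capitalize())
    for c in ("personnel", "drugs", "supplies", "equipment", "vehicles", "other")
)


class Hierarchy:
    """Validated administrative tree with traversal helpers.

    Construct via :func:`validate_hierarchy`; all :class:`OrgUnit`
    invariants hold on an instance (unique ids, one national root, each
    child exactly one level below its parent, acyclic).
    """

    def __init__(self, units: Mapping[str, OrgUnit], children: Mapping[str, tuple[str, ...]]):
        self._units = dict(units)
        self._children = dict(children)

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self._units

    def __iter__(self) -> Iterator[OrgUnit]:
        return iter(self._units.values())

    def __len__(self) -> int:
        return len(self._units)

    def unit(self, unit_id: str) -> OrgUnit:
        try:
            return self._units[unit_id]
        except KeyError:
            raise ValidationError([f"unknown org unit {unit_id!r}"]) from None

    def level(self, unit_id: str) -> str:
        return self.unit(unit_id).level

    @property
    def root(self) -> OrgUnit:
        return next(u for u in self._units.values() if u.level == "national")

    def children(self, unit_id: str) -> list[OrgUnit]:
        return [self._units[c] for c in self._children.get(unit_id, ())]

    def parent(self, unit_id: str) -> Optional[OrgUnit]:
        pid = self.unit(unit_id).parent_id
        return self._units[pid] if pid is not None else None

    def facilities(self) -> list[OrgUnit]:
        return [u for u in self._units.values() if u.level == "facility"]

    def facilities_below(self, unit_id: str) -> list[OrgUnit]:
        """Every facility in the subtree rooted at ``unit_id`` (inclusive)."""
        u = self.unit(unit_id)
        if u.level == "facility":
            return [u]
        out: list[OrgUnit] = []
        for child in self.children(unit_id):
            out.extend(self.facilities_below(child.id))
        return out

    def ancestor_at(self, unit_id: str, level: str) -> Optional[OrgUnit]:
        """The (unique) ancestor of ``unit_id`` at ``level``, or the unit
        itself if already at that level; None if ``level`` is below it."""
        if level not in LEVELS:
            raise ValidationError([f"unknown level {level!r}"])
        u: Optional[OrgUnit] = self.unit(unit_id)
        while u is not None and u.level != level:
            u = self._units.get(u.parent_id) if u.parent_id else None
        return u

    def district_of(self, facility_id: str) -> OrgUnit:
        anc = self.ancestor_at(facility_id, "district")
        assert anc is not None
        return anc

    def province_of(self, facility_id: str) -> OrgUnit:
        anc = self.ancestor_at(facility_id, "provincial")
        assert anc is not None
        return anc


def validate_hierarchy(units: Iterable[OrgUnit]) -> Hierarchy:
    """Validate org units into a :class:`Hierarchy`, collecting ALL violations.

    Checks: unique ids; exactly one national root with no parent; every
    non-root has a known parent exactly one level above; no cycles.
    """
    units = list(units)
    violations: list[str] = []
    by_id: dict[str, OrgUnit] = {}
    for u in units:
        if u.id in by_id:
            violations.append(f"duplicate org unit id {u.id!r}")
        by_id[u.id] = u
        if u.level not in LEVELS:
            violations.append(f"unit {u.id!r}: unknown level {u.level!r}")

    roots = [u for u in units if u.level == "national"]
    if len(roots) != 1:
        violations.append(f"expected exactly one national root, found {len(roots)}")
    for u in roots:
        if u.parent_id is not None:
            violations.append(f"national root {u.id!r} must not have a parent")

    rank = {lvl: i for i, lvl in enumerate(LEVELS)}
    children: dict[str, list[str]] = {}
    for u in units:
        if u.level == "national" or u.level not in rank:
            continue
        if u.parent_id is None:
            violations.append(f"unit {u.id!r} ({u.level}) has no parent")
            continue
        parent = by_id.get(u.parent_id)
        if parent is None:
            violations.append(f"unit {u.id!r}: orphan parent id {u.parent_id!r}")
            continue
        if parent.level in rank and rank[u.level] != rank[parent.level] + 1:
            violations.append(
                f"unit {u.id!r} ({u.level}) under {parent.id!r} ({parent.level}): level skip"
            )
        children.setdefault(u.parent_id, []).append(u.id)

    # cycle check: walk parents from every node, bounded by tree depth
    for u in units:
        seen = {u.id}
        cur = u
        while cur.parent_id is not None:
            if cur.parent_id in seen:
                violations.append(f"cycle in parent chain at unit {u.id!r}")
                break
            seen.add(cur.parent_id)
            nxt = by_id.get(cur.parent_id)
            if nxt is None:
                break
            cur = nxt

    if violations:
        raise ValidationError(sorted(set(violations)))
    return Hierarchy(by_id, {k: tuple(sorted(v)) for k, v in children.items()})
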