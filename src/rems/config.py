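"""Run configuration: service/category registries and policy toggles."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from .org_model import (
    DEFAULT_RESOURCE_CATEGORIES,
    ResourceCategory,
    ServiceLine,
    ValidationError,
)

__all__ = ["RunConfig", "load_config", "DEFAULT_SERVICES"]

DEFAULT_SERVICES: tuple[ServiceLine, ...] = (
    ServiceLine("HTC", "HIV testing & counselling", "HTC client visits"),
    ServiceLine("EMTCT", "Elimination of mother-to-child transmission", "patient visits for EMTCT"),
    ServiceLine("ART", "Antiretroviral therapy", "ART patient visits"),
)


@dataclass(frozen=True)
class RunConfig:
    """Policies and registries shared across the pipeline stages.

    negative_amount_policy
        ``net``: negative ledger rows (journal corrections) are netted within
        their aggregation key, a key netting below zero is an error;
        ``reject``: any negative row is an error.
    default_hiv_share
        HIV share applied to accounts matching no weight pattern (0 = not
        HIV-related).
    useful_life_years
        Straight-line annualization horizon per capital resource category.
    outlier_threshold / outlier_min_group
        Robust-z cutoff and minimum comparison-group size for outlier flags.
    """

    services: tuple[ServiceLine, ...] = DEFAULT_SERVICES
    resource_categories: tuple[ResourceCategory, ...] = DEFAULT_RESOURCE_CATEGORIES
    negative_amount_policy: str = "net"
    default_hiv_share: float = 0.0
    useful_life_years: dict[str, float] = field(
        default_factory=lambda: {"equipment": 5.0, "vehicles": 8.0}
    )
    outlier_threshold: float = 3.0
    outlier_min_group: int = 5
    outlier_group_level: str = "district"
    conservation_tol: float = 1e-6

    def __post_init__(self) -> None:
        problems = []
        if self.negative_amount_policy not in ("net", "reject"):
            problems.append(f"negative_amount_policy {self.negative_amount_policy!r}")
        if not 0.0 <= self.default_hiv_share <= 1.0:
            problems.append("default_hiv_share outside [0, 1]")
        if self.outlier_threshold <= 0:
            problems.append("outlier_threshold must be positive")
        if self.outlier_min_group < 1:
            problems.append("outlier_min_group must be >= 1")
        if self.outlier_group_level not in ("district", "provincial", "national"):
            problems.append(f"outlier_group_level {self.outlier_group_level!r}")
        codes = [s.code for s in self.services]
        if len(codes) != len(set(codes)):
            problems.append("duplicate service codes")
        cats = [c.code for c in self.resource_categories]
        if len(cats) != len(set(cats)):
            problems.append("duplicate resource category codes")
        if problems:
            raise ValidationError(problems)

    @property
    def service_codes(self) -> tuple[str, ...]:
        return tuple(s.code for s in self.services)

    @property
    def category_codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.resource_categories)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; absent keys fall back to defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "services" in raw:
        kwargs["services"] = tuple(
            ServiceLine(
                code=s["code"],
                label=s.get("label", ""),
                output_indicator=s.get("output_indicator", ""),
            )
            for s in raw["services"]
        )
    if "resource_categories" in raw:
        kwargs["resource_categories"] = tuple(
            ResourceCategory(code=c["code"], label=c.get("label", ""))
            if isinstance(c, dict)
            else ResourceCategory(code=str(c))
            for c in raw["resource_categories"]
        )
    for key in (
        "negative_amount_policy",
        "default_hiv_share",
        "useful_life_years",
        "outlier_threshold",
        "outlier_min_group",
        "outlier_group_level",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)
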