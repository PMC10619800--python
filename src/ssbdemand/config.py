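"""Category and column configuration for a demand system.

A :class:`CategoryConfig` names the product categories that make up the
system (the last one conventionally being a residual "other foods" group),
the geography columns used for price imputation, and the household
covariates that drive both the purchase-decision probits and the
total-expenditure (Engel) regression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["CategoryConfig", "load_config"]


@dataclass(frozen=True)
class CategoryConfig:
    """Declarative description of the demand system's columns.

    Parameters
    ----------
    categories
        Ordered labels of the ``n >= 2`` product categories.
    state_column, region_column
        Geography columns used for the state → region → national price
        imputation fallback chain.
    income_column
        Monthly household income column (currency units).
    covariate_columns
        Household sociodemographic regressors used in the probit first
        stage and the expenditure regression.
    reference_category
        The residual category absorbing the remainder of the food budget.
        Defaults to the last category.
    """

    categories: tuple[str, ...]
    state_column: str = "state"
    region_column: str = "region"
    income_column: str = "income"
    covariate_columns: tuple[str, ...] = ()
    reference_category: str | None = None

    def __post_init__(self) -> None:
        cats = tuple(self.categories)
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "covariate_columns", tuple(self.covariate_columns))
        if len(cats) < 2:
            raise ValueError("a demand system needs at least 2 categories")
        if len(set(cats)) != len(cats):
            raise ValueError("category labels must be unique")
        if not self.covariate_columns:
            raise ValueError("covariate_columns must be non-empty")
        ref = self.reference_category
        if ref is None:
            object.__setattr__(self, "reference_category", cats[-1])
        elif ref not in cats:
            raise ValueError(f"reference_category {ref!r} not among categories")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def category_index(self, label: str) -> int:
        return self.categories.index(label)

    def to_dict(self) -> dict:
        return {
            "categories": list(self.categories),
            "state_column": self.state_column,
            "region_column": self.region_column,
            "income_column": self.income_column,
            "covariate_columns": list(self.covariate_columns),
            "reference_category": self.reference_category,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryConfig":
        return cls(
            categories=tuple(d["categories"]),
            state_column=d.get("state_column", "state"),
            region_column=d.get("region_column", "region"),
            income_column=d.get("income_column", "income"),
            covariate_columns=tuple(d.get("covariate_columns", ())),
            reference_category=d.get("reference_category"),
        )


def load_config(path: str | Path) -> CategoryConfig:
    """Load a :class:`CategoryConfig` from a YAML or JSON mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return CategoryConfig.from_dict(payload)
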