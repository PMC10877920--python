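"""Covariate encoding: household table -> design matrices z and X.

Dummy coding is fixed by the closed category sets below (not by the levels
observed in a particular sample), so subsamples always produce the same
column layout.  Reference categories default to the ones used in the source
survey analysis: female head, age 18-34, urban, single, college-educated,
housekeeper, rent-free housing, family of 1-2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DataError

logger = logging.getLogger(__name__)

#: Closed category sets of the household record, in display order.
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "head_gender": ("female", "male"),
    "head_age_group": ("18-34", "35-51", "52-68", "69-85", "86+"),
    "living_sector": ("urban", "rural"),
    "marital_status": ("single", "divorced", "widowed", "married"),
    "education": ("illiterate", "primary", "secondary", "college_plus"),
    "job_status": ("housekeeper", "unemployed", "employed"),
    "ownership": ("free", "tenant", "owner"),
    "family_size_group": ("1-2", "3-5", "6+"),
}

#: Continuous household covariates (passed through, optionally rescaled).
CONTINUOUS_FIELDS = ("income", "insurance_cost", "n_children_under5")

DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "head_gender": "female",
    "head_age_group": "18-34",
    "living_sector": "urban",
    "marital_status": "single",
    "education": "college_plus",
    "job_status": "housekeeper",
    "ownership": "free",
    "family_size_group": "1-2",
}

#: Covariate order of the survey analysis: money first, then demographics.
DEFAULT_TERMS = (
    "income",
    "insurance_cost",
    "head_gender",
    "head_age_group",
    "living_sector",
    "marital_status",
    "education",
    "job_status",
    "ownership",
    "n_children_under5",
    "family_size_group",
)

OUTCOME_FIELD = "oop_pharma"


@dataclass
class DesignSpec:
    """Which covariates enter each hurdle, and how categoricals are coded.

    Both hurdles default to the same covariate list (the published
    coefficient table reports the two blocks over identical variables);
    exclusion restrictions are expressed by passing different term lists.
    ``scales`` divides a continuous column by a constant (e.g. income per
    1000 USD) without touching the stored data.
    """

    participation_terms: Sequence[str] = DEFAULT_TERMS
    expenditure_terms: Sequence[str] = DEFAULT_TERMS
    reference_levels: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS))
    include_intercept: bool = True
    scales: Mapping[str, float] = field(default_factory=dict)
    log_continuous: bool = False

    def __post_init__(self) -> None:
        self.participation_terms = tuple(self.participation_terms)
        self.expenditure_terms = tuple(self.expenditure_terms)
        for term in (*self.participation_terms, *self.expenditure_terms):
            if term not in CATEGORY_LEVELS and term not in CONTINUOUS_FIELDS:
                raise ContractError(f"unknown covariate term {term!r}")
        for var, ref in self.reference_levels.items():
            if var not in CATEGORY_LEVELS:
                raise ContractError(f"reference level given for non-categorical {var!r}")
            if ref not in CATEGORY_LEVELS[var]:
                raise ContractError(f"{ref!r} is not a level of {var!r}")

    def with_terms(self, participation: Sequence[str], expenditure: Sequence[str]) -> "DesignSpec":
        return replace(self, participation_terms=tuple(participation), expenditure_terms=tuple(expenditure))

    def columns(self, hurdle: str) -> list[str]:
        """Column labels produced for one hurdle ('participation'|'expenditure')."""
        terms = self.participation_terms if hurdle == "participation" else self.expenditure_terms
        cols = ["const"] if self.include_intercept else []
        for term in terms:
            if term in CONTINUOUS_FIELDS:
                cols.append(term)
            else:
                ref = self.reference_levels.get(term, DEFAULT_REFERENCE_LEVELS[term])
                cols.extend(f"{term}[{lev}]" for lev in CATEGORY_LEVELS[term] if lev != ref)
        return cols


@dataclass
class DesignMatrices:
    """Aligned participation matrix z, expenditure matrix X and outcome y."""

    z: np.ndarray
    X: np.ndarray
    y: np.ndarray
    z_names: list[str]
    x_names: list[str]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.y.shape[0]
        if self.z.shape[0] != n or self.X.shape[0] != n:
            raise ContractError("z, X and y must have identical row counts")
        for name, arr in (("z", self.z), ("X", self.X), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise DataError(f"non-finite entries in {name}")
        if np.any(self.y < 0):
            raise DataError("outcome contains negative values; OOP expenditure must be >= 0")

    @property
    def n_obs(self) -> int:
        return int(self.y.shape[0])

    @property
    def d(self) -> np.ndarray:
        """Participation indicator d_i = 1{y_i > 0}."""
        return (self.y > 0).astype(float)


def complete_cases(table: pd.DataFrame, fields: Sequence[str] | None = None) -> pd.DataFrame:
    """Drop rows with any missing value in the named fields (all columns if None)."""
    fields = list(fields) if fields is not None else list(table.columns)
    mask = table[fields].notna().all(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("complete_cases: dropped %d of %d rows with missing values", n_drop, len(table))
    if n_drop == len(table):
        warnings.warn("all rows contain missing values; returning empty table", stacklevel=2)
    return table.loc[mask].reset_index(drop=True)


def _encode_block(table: pd.DataFrame, terms: Sequence[str], spec: DesignSpec) -> tuple[np.ndarray, list[str]]:
    n = len(table)
    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.include_intercept:
        cols.append(np.ones(n))
        names.append("const")
    for term in terms:
        if term not in table.columns:
            raise DataError(f"table lacks required column {term!r}")
        if term in CONTINUOUS_FIELDS:
            vals = pd.to_numeric(table[term], errors="coerce").to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                bad = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise DataError(f"non-numeric value in column {term!r} at row {bad}")
            if spec.log_continuous and term != "n_children_under5":
                vals = np.log1p(vals)
            scale = float(spec.scales.get(term, 1.0))
            cols.append(vals / scale)
            names.append(term)
        else:
            levels = CATEGORY_LEVELS[term]
            ref = spec.reference_levels.get(term, DEFAULT_REFERENCE_LEVELS[term])
            observed = table[term].astype(str)
            unknown = ~observed.isin(levels)
            if unknown.any():
                row = int(np.flatnonzero(unknown.to_numpy())[0])
                raise DataError(
                    f"unknown category {observed.iloc[row]!r} for field {term!r} at row {row}"
                )
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((observed == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
    return np.column_stack(cols) if cols else np.empty((n, 0)), names


def encode_design(table: pd.DataFrame, spec: DesignSpec | None = None) -> DesignMatrices:
    """Encode a household table into ``DesignMatrices`` under ``spec``.

    One 0/1 dummy per non-reference level of each categorical term (levels
    fixed by :data:`CATEGORY_LEVELS`), continuous terms passed through, and
    a leading intercept column when ``spec.include_intercept``.

    Raises
    ------
    DataError
        Empty table, unknown category value, or missing column.
    """
    spec = spec if spec is not None else DesignSpec()
    if len(table) == 0:
        raise DataError("cannot encode an empty table")
    if OUTCOME_FIELD not in table.columns:
        raise DataError(f"table lacks outcome column {OUTCOME_FIELD!r}")
    z, z_names = _encode_block(table, spec.participation_terms, spec)
    X, x_names = _encode_block(table, spec.expenditure_terms, spec)
    y = pd.to_numeric(table[OUTCOME_FIELD], errors="raise").to_numpy(dtype=float)
    return DesignMatrices(z=z, X=X, y=y, z_names=z_names, x_names=x_names)
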