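"""Domain types, fixed constants, CSV readers/writers and validation.

The model world is: 24 Latin American and Caribbean countries, 18 five-year
age bands (0-4 ... 85+), current health expenditure (CHE) tracked per ICD-10
chapter in million 2018 US$, four NCD risk factors (tobacco, alcohol, high
systolic blood pressure, high blood glucose) and five conditions (cancer,
type-2 diabetes, cardiovascular disease, COPD, chronic kidney disease), each
condition sitting inside one ICD-10 chapter with a fixed within-chapter cost
share estimated from Colombian administrative (RIPS) data.

All shares and attributable fractions are stored as fractions in [0, 1];
percentage formatting happens only in reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "ValidationError",
    "RISK_FACTORS",
    "CONDITION_NAMES",
    "ICD_CHAPTERS",
    "AGE_GROUPS",
    "CONDITION_CHAPTER",
    "LINKS",
    "Country",
    "Condition",
    "LinkMatrix",
    "Scenario",
    "CheSeries",
    "PafSeries",
    "DalySeries",
    "ImpactTable",
    "default_condition_table",
    "default_link_matrix",
    "validate_paf",
    "load_che",
    "load_paf",
    "load_daly",
    "load_countries",
    "write_countries",
]


class ValidationError(ValueError):
    """Raised when an input table violates a model invariant.

    The message always names the offending key (country, chapter, year, ...).
    """


# ---------------------------------------------------------------------------
# Fixed vocabularies
# ---------------------------------------------------------------------------

RISK_FACTORS: tuple[str, ...] = ("tobacco", "alcohol", "high_sbp", "high_glucose")

CONDITION_NAMES: tuple[str, ...] = ("cancer", "diabetes_t2", "cvd", "copd", "ckd")

#: The 22 top-level ICD-10 chapters as Roman-numeral strings.  Only the five
#: mapped chapters participate in the CRA, but expenditure series may carry
#: all of them so that percent-of-total-CHE denominators are computable.
ICD_CHAPTERS: tuple[str, ...] = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI",
    "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX",
    "XXI", "XXII",
)

#: Lower bounds of the 18 five-year age bands; the last band (85) is open-ended.
AGE_GROUPS: tuple[int, ...] = tuple(range(0, 90, 5))

#: Condition -> ICD-10 chapter.  Total and injective on the five conditions.
CONDITION_CHAPTER: dict[str, str] = {
    "cancer": "II",
    "diabetes_t2": "IV",
    "cvd": "IX",
    "copd": "X",
    "ckd": "XIV",
}

#: Within-chapter cost shares (fractions), 2015-2019 Colombian RIPS averages.
_DEFAULT_SHARES: dict[str, float] = {
    "cancer": 1.0,
    "diabetes_t2": 0.2485,
    "cvd": 0.9191,
    "copd": 0.3689,
    "ckd": 0.372,
}

#: The biologically linked (risk factor, condition) pairs.  Attributable
#: fractions must be zero everywhere else.  Exactly 12 true cells.
LINKS: frozenset[tuple[str, str]] = frozenset(
    [
        ("tobacco", "cvd"),
        ("tobacco", "cancer"),
        ("tobacco", "copd"),
        ("tobacco", "diabetes_t2"),
        ("high_sbp", "cvd"),
        ("high_sbp", "ckd"),
        ("high_glucose", "cvd"),
        ("high_glucose", "cancer"),
        ("high_glucose", "diabetes_t2"),
        ("high_glucose", "ckd"),
        ("alcohol", "cvd"),
        ("alcohol", "cancer"),
    ]
)

REGIONS: tuple[str, ...] = ("latin_america", "caribbean")


# ---------------------------------------------------------------------------
# Small record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Country:
    """One country: short code, display name, region and expenditure group.

    The expenditure group (1-4) reflects grouping by 2015-2019 average per
    capita health expenditure, used when extrapolating projections.
    """

    code: str
    name: str
    region: str
    expenditure_group: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"country {self.code!r}: region {self.region!r} not in {REGIONS}"
            )
        if self.expenditure_group not in (1, 2, 3, 4):
            raise ValidationError(
                f"country {self.code!r}: expenditure_group "
                f"{self.expenditure_group!r} not in 1..4"
            )


@dataclass(frozen=True)
class Condition:
    """A modelled condition, its ICD-10 chapter and within-chapter cost share."""

    name: str
    chapter: str
    share_within_chapter: float

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise ValidationError(f"unknown condition {self.name!r}")
        if CONDITION_CHAPTER[self.name] != self.chapter:
            raise ValidationError(
                f"condition {self.name!r}: chapter must be "
                f"{CONDITION_CHAPTER[self.name]!r}, got {self.chapter!r}"
            )
        if not 0.0 < self.share_within_chapter <= 1.0:
            raise ValidationError(
                f"condition {self.name!r}: share {self.share_within_chapter} "
                "outside (0, 1]"
            )


def default_condition_table() -> list[Condition]:
    """The five conditions with their default within-chapter cost shares."""
    return [
        Condition(name, CONDITION_CHAPTER[name], _DEFAULT_SHARES[name])
        for name in CONDITION_NAMES
    ]


@dataclass(frozen=True)
class LinkMatrix:
    """Boolean risk-factor x condition link structure."""

    pairs: frozenset[tuple[str, str]] = LINKS

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def linked(self, risk_factor: str, condition: str) -> bool:
        return (risk_factor, condition) in self.pairs

    def as_frame(self) -> pd.DataFrame:
        """Dense boolean frame, risk factors as rows, conditions as columns."""
        frame = pd.DataFrame(
            False, index=list(RISK_FACTORS), columns=list(CONDITION_NAMES)
        )
        for rf, cond in self.pairs:
            frame.loc[rf, cond] = True
        return frame


def default_link_matrix() -> LinkMatrix:
    return LinkMatrix()


class Scenario(BaseModel):
    """A deterministic prevalence-reduction scenario.

    Parameters
    ----------
    reductions
        Map risk factor -> fractional prevalence reduction in [0, 1]
        (0.10 means a 10% reduction).  Negative values (prevalence
        increases) are permitted and yield negative savings.
    start_year
        Year the policy takes effect; the ramp is 0 here.
    ramp_years
        Length of the linear phase-in; full effect at
        ``start_year + ramp_years``.
    horizon_end
        Last simulated year.
    discount_rate
        Annual discount rate applied from ``base_year``.
    base_year
        Present-value anchor (discount factor 1 at this year).
    """

    reductions: dict[str, float]
    start_year: int = 2020
    ramp_years: int = Field(default=10, ge=0)
    horizon_end: int = 2050
    discount_rate: float = Field(default=0.03, ge=0.0)
    base_year: int = 2020

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        for rf, frac in self.reductions.items():
            if rf not in RISK_FACTORS:
                raise ValueError(f"unknown risk factor {rf!r}")
            if frac > 1.0:
                raise ValueError(f"reduction for {rf!r} exceeds 1: {frac}")
        if self.horizon_end < self.start_year:
            raise ValueError("horizon_end before start_year")
        return self

    def single_factor(self, risk_factor: str) -> "Scenario":
        """Copy of this scenario keeping only one risk factor's reduction."""
        return self.model_copy(
            update={"reductions": {risk_factor: self.reductions[risk_factor]}}
        )

    def scaled(self, factor: float) -> "Scenario":
        """Copy with every reduction multiplied by ``factor``."""
        return self.model_copy(
            update={"reductions": {k: v * factor for k, v in self.reductions.items()}}
        )


# ---------------------------------------------------------------------------
# Keyed series wrappers
# ---------------------------------------------------------------------------


def _require_columns(frame: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def _check_unique(index: pd.MultiIndex, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValidationError(f"{what}: duplicate key {dup}")


@dataclass(frozen=True)
class CheSeries:
    """Projected current health expenditure in million 2018 US$.

    Keyed by (country, age_group, chapter, year).  Every (country,
    age_group, chapter) combination present in the series must cover the
    full year range with no gaps, and all values must be non-negative.
    """

    data: pd.Series

    INDEX = ("country", "age_group", "chapter", "year")
    VALUE = "value_musd2018"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "CheSeries")
        if (self.data < 0).any():
            key = self.data.index[self.data.values < 0][0]
            raise ValidationError(f"CheSeries: negative value at {key}")
        years = self.years
        full = set(range(years.min(), years.max() + 1))
        counts = self.data.groupby(level=["country", "age_group", "chapter"]).size()
        bad = counts[counts != len(full)]
        if len(bad):
            country, age, chapter = bad.index[0]
            present = set(
                self.data.xs(
                    (country, age, chapter), level=("country", "age_group", "chapter")
                ).index
            )
            missing_year = min(full - present)
            raise ValidationError(
                f"CheSeries: country {country!r} chapter {chapter!r} "
                f"age {age} missing year {missing_year}"
            )

    @property
    def years(self) -> np.ndarray:
        return self.data.index.get_level_values("year").unique().to_numpy()

    @property
    def countries(self) -> list[str]:
        return sorted(self.data.index.get_level_values("country").unique())

    def scale(self, factor: float) -> "CheSeries":
        return CheSeries(self.data * factor)

    def total_by_year(self) -> pd.Series:
        """Total CHE across all chapters and ages, per (country, year)."""
        return self.data.groupby(level=["country", "year"]).sum()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CheSeries":
        _require_columns(frame, (*cls.INDEX, cls.VALUE), "CheSeries")
        s = frame.set_index(list(cls.INDEX))[cls.VALUE].astype(float)
        s.name = cls.VALUE
        return cls(s.sort_index())

    def to_frame(self) -> pd.DataFrame:
        return self.data.rename(self.VALUE).reset_index()

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PafSeries:
    """Attributable-DALY fractions keyed by
    (country, age_group, condition, risk_factor, year).

    Values live in [0, 1] and must be zero (or absent) wherever the
    risk-factor/condition link matrix is false; absent keys mean zero.
    """

    data: pd.Series

    INDEX = ("country", "age_group", "condition", "risk_factor", "year")
    VALUE = "fraction"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "PafSeries")
        bad = self.data[(self.data < 0) | (self.data > 1)]
        if len(bad):
            raise ValidationError(
                f"PafSeries: value {bad.iloc[0]} at {bad.index[0]} outside [0, 1]"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PafSeries":
        _require_columns(frame, (*cls.INDEX, cls.VALUE), "PafSeries")
        s = frame.set_index(list(cls.INDEX))[cls.VALUE].astype(float)
        s.name = cls.VALUE
        return cls(s.sort_index())

    def to_frame(self) -> pd.DataFrame:
        return self.data.rename(self.VALUE).reset_index()

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def at_year(self, year: int) -> pd.Series:
        """Cross-section keyed by (country, age_group, condition, risk_factor)."""
        return self.data.xs(year, level="year")


@dataclass(frozen=True)
class DalySeries:
    """DALY totals (person-years) keyed by (country, age_group, condition, year)."""

    data: pd.Series

    INDEX = ("country", "age_group", "condition", "year")
    VALUE = "dalys"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "DalySeries")
        if (self.data < 0).any():
            key = self.data.index[self.data.values < 0][0]
            raise ValidationError(f"DalySeries: negative value at {key}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DalySeries":
        _require_columns(frame, (*cls.INDEX, cls.VALUE), "DalySeries")
        s = frame.set_index(list(cls.INDEX))[cls.VALUE].astype(float)
        s.name = cls.VALUE
        return cls(s.sort_index())

    def to_frame(self) -> pd.DataFrame:
        return self.data.rename(self.VALUE).reset_index()

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def at_year(self, year: int) -> pd.Series:
        return self.data.xs(year, level="year")


@dataclass(frozen=True)
class ImpactTable:
    """Per-cell expenditure savings of a scenario.

    A DataFrame indexed by (country, risk_factor, condition, year) with two
    columns: ``undiscounted`` and ``discounted`` (both million 2018 US$).
    """

    data: pd.DataFrame

    INDEX = ("country", "risk_factor", "condition", "year")
    COLUMNS = ("undiscounted", "discounted")

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "ImpactTable")
        for col in self.COLUMNS:
            if col not in self.data.columns:
                raise ValidationError(f"ImpactTable: missing column {col!r}")

    def __add__(self, other: "ImpactTable") -> "ImpactTable":
        return ImpactTable(self.data.add(other.data, fill_value=0.0).sort_index())

    def to_frame(self) -> pd.DataFrame:
        return self.data.reset_index()

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ImpactTable":
        _require_columns(frame, (*cls.INDEX, *cls.COLUMNS), "ImpactTable")
        return cls(frame.set_index(list(cls.INDEX)).sort_index())


# ---------------------------------------------------------------------------
# Validation and IO entry points
# ---------------------------------------------------------------------------


def validate_paf(paf: PafSeries, links: LinkMatrix | None = None) -> PafSeries:
    """Check link-structure zeros; return the input unchanged if valid.

    Range checks ([0, 1]) run at construction; this adds the structural
    check that no attributable fraction is positive for a (risk factor,
    condition) pair outside the link matrix — e.g. alcohol has no
    attributable COPD burden in this model.
    """
    links = links or default_link_matrix()
    rf = paf.data.index.get_level_values("risk_factor")
    cond = paf.data.index.get_level_values("condition")
    off_link = ~pd.Series(
        [(r, c) in links for r, c in zip(rf, cond)], index=paf.data.index
    )
    violating = paf.data[off_link & (paf.data != 0.0)]
    if len(violating):
        key = violating.index[0]
        raise ValidationError(
            f"PafSeries: nonzero fraction {violating.iloc[0]} for unlinked pair "
            f"(risk_factor={key[3]!r}, condition={key[2]!r}) at {key}"
        )
    return paf


def load_che(path: str | Path) -> CheSeries:
    """Read a CHE table (country,age_group,chapter,year,value_musd2018)."""
    return CheSeries.from_frame(pd.read_csv(path, float_precision="round_trip"))


def load_paf(
    path: str | Path, links: LinkMatrix | None = None
) -> PafSeries:
    """Read and structurally validate a PAF table."""
    return validate_paf(
        PafSeries.from_frame(pd.read_csv(path, float_precision="round_trip")), links
    )


def load_daly(path: str | Path) -> DalySeries:
    return DalySeries.from_frame(pd.read_csv(path, float_precision="round_trip"))


def load_countries(path: str | Path) -> list[Country]:
    frame = pd.read_csv(path)
    _require_columns(frame, ("code", "name", "region", "expenditure_group"), "countries")
    return [
        Country(row.code, row.name, row.region, int(row.expenditure_group))
        for row in frame.itertuples(index=False)
    ]


def write_countries(countries: Iterable[Country], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "code": c.code,
                "name": c.name,
                "region": c.region,
                "expenditure_group": c.expenditure_group,
            }
            for c in countries
        ]
    ).to_csv(path, index=False)
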