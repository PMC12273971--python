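"""Comparative risk assessment engine.

Computes the expected policy impact of prevalence reductions in NCD risk
factors on projected current health expenditure.  Per country *i*, age group
*j*, condition *k*, risk factor *p* and year *t* the annual impact is the
product

    impact = CHE(i, j, chapter(k), t)
             x share_within_chapter(k)
             x reduction(p)
             x PAF(i, j, k, p, t)
             x ramp(t)

where ``ramp`` phases the effect in linearly over a configurable number of
years (default 10): a change in risk-factor prevalence is assumed to be fully
translated into condition prevalence only after a decade.  Impacts are summed
over age groups, accumulated over the horizon, and reported both undiscounted
and discounted to a base year at an annual rate (default 3%).

The model is deterministic and has no interaction terms: impacts are linear
in the reduction fraction and additive across risk factors, so a joint
scenario equals the cellwise sum of its single-factor scenarios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CONDITION_CHAPTER,
    Condition,
    CheSeries,
    DalySeries,
    ImpactTable,
    PafSeries,
    Scenario,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RampFunction",
    "DiscountSpec",
    "ramp_factor",
    "discount_factor",
    "annual_policy_impact",
    "run_scenario",
    "cumulative_savings",
    "daly_reduction",
]


@dataclass(frozen=True)
class RampFunction:
    """Linear phase-in: 0 at ``start_year``, 1 at ``start_year + ramp_years``."""

    start_year: int
    ramp_years: int = 10

    def __post_init__(self) -> None:
        if self.ramp_years < 0:
            raise ValidationError("ramp_years must be >= 0")


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting to a base year, end-of-year convention."""

    rate: float = 0.03
    base_year: int = 2020

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError("discount rate must be >= 0")


def ramp_factor(year: int | np.ndarray, ramp: RampFunction) -> float | np.ndarray:
    """Fraction of the full policy effect realised in ``year``.

    Zero at the start year (the effect begins accruing the year after
    adoption), one from ``start_year + ramp_years`` onward, linear between.
    """
    if ramp.ramp_years == 0:
        out = np.where(np.asarray(year) >= ramp.start_year, 1.0, 0.0)
    else:
        out = np.clip(
            (np.asarray(year) - ramp.start_year) / ramp.ramp_years, 0.0, 1.0
        )
    return float(out) if np.isscalar(year) else out


def discount_factor(
    year: int | np.ndarray, spec: DiscountSpec
) -> float | np.ndarray:
    """Present-value factor (1 + rate)^-(year - base_year)."""
    years = np.asarray(year)
    if (years < spec.base_year).any():
        raise ValidationError(
            f"discount_factor: year {years.min()} before base_year {spec.base_year}"
        )
    out = (1.0 + spec.rate) ** -(years - spec.base_year)
    return float(out) if np.isscalar(year) else out


def _condition_shares(
    conditions: Iterable[Condition],
    age_shares: pd.Series | None = None,
) -> pd.Series:
    """Within-chapter cost share per condition (optionally per age group).

    ``age_shares``, if given, is keyed by (condition, age_group) and
    overrides the scalar per-condition shares — the national RIPS value is a
    single number, but the model allows age-specific shares.
    """
    if age_shares is not None:
        return age_shares
    return pd.Series(
        {c.name: c.share_within_chapter for c in conditions}, name="share"
    )


def annual_policy_impact(
    che: CheSeries,
    conditions: Sequence[Condition],
    paf: PafSeries,
    scenario: Scenario,
    year: int,
    age_shares: pd.Series | None = None,
) -> pd.Series:
    """Undiscounted impact for one year, keyed (country, risk_factor, condition).

    Impacts are computed per age group and summed over ages.  Risk factors
    absent from the scenario, and (risk factor, condition) pairs absent from
    the attributable-fraction table, contribute zero.
    """
    try:
        che_year = che.data.xs(year, level="year")
    except KeyError:
        raise ValidationError(f"annual_policy_impact: year {year} not in CheSeries")
    paf_year = paf.at_year(year).rename("paf").reset_index()
    paf_year = paf_year[paf_year["risk_factor"].isin(scenario.reductions)]

    shares = _condition_shares(conditions, age_shares)
    chapters = {c.name: c.chapter for c in conditions}
    missing = [
        ch
        for ch in chapters.values()
        if ch not in che_year.index.get_level_values("chapter")
    ]
    if missing:
        raise ValidationError(
            f"annual_policy_impact: chapter(s) {missing} absent from CheSeries"
        )

    paf_year["chapter"] = paf_year["condition"].map(chapters)
    paf_year = paf_year.dropna(subset=["chapter"])
    merged = paf_year.merge(
        che_year.rename("che").reset_index(),
        on=["country", "age_group", "chapter"],
        how="left",
    )
    if merged["che"].isna().any():
        bad = merged[merged["che"].isna()].iloc[0]
        raise ValidationError(
            f"annual_policy_impact: CHE missing for country {bad['country']!r} "
            f"age {bad['age_group']} chapter {bad['chapter']!r} year {year}"
        )
    if age_shares is not None:
        share_vals = merged.set_index(["condition", "age_group"]).index.map(age_shares)
        merged["share"] = np.asarray(share_vals, dtype=float)
    else:
        merged["share"] = merged["condition"].map(shares)
    merged["reduction"] = merged["risk_factor"].map(scenario.reductions)
    ramp = ramp_factor(year, RampFunction(scenario.start_year, scenario.ramp_years))
    merged["impact"] = (
        merged["che"]
        * merged["share"]
        * merged["reduction"]
        * merged["paf"]
        * ramp
    )
    return (
        merged.groupby(["country", "risk_factor", "condition"])["impact"]
        .sum()
        .sort_index()
    )


def run_scenario(
    che: CheSeries,
    conditions: Sequence[Condition],
    paf: PafSeries,
    scenario: Scenario,
    age_shares: pd.Series | None = None,
) -> ImpactTable:
    """Annual impacts for every year in [start_year, horizon_end].

    Each cell carries the undiscounted impact and its discounted twin
    (impact x discount factor at the scenario's rate and base year).
    """
    spec = DiscountSpec(scenario.discount_rate, scenario.base_year)
    pieces = []
    for year in range(scenario.start_year, scenario.horizon_end + 1):
        annual = annual_policy_impact(che, conditions, paf, scenario, year, age_shares)
        frame = annual.rename("undiscounted").to_frame()
        frame["discounted"] = frame["undiscounted"] * discount_factor(year, spec)
        frame["year"] = year
        pieces.append(frame.reset_index())
    table = pd.concat(pieces, ignore_index=True)
    return ImpactTable.from_frame(table)


def cumulative_savings(
    impact: ImpactTable,
    che: CheSeries,
    spec: DiscountSpec | None = None,
    discounted_denominator: bool = True,
) -> pd.DataFrame:
    """Cumulative savings per (country, risk_factor) over the impact horizon.

    Returns a frame with columns ``undiscounted``, ``discounted`` (summed
    over conditions and years) and ``percent``: discounted savings as a
    percentage of the base-case cumulative total CHE (all chapters, all
    ages) over the same years, discounted with the same specification.  The
    percent statistic is invariant to a common currency rescaling of CHE.
    """
    if impact.data.empty:
        raise ValidationError("cumulative_savings: empty impact table")
    spec = spec or DiscountSpec()
    years = impact.data.index.get_level_values("year").unique().to_numpy()
    totals = impact.data.groupby(level=["country", "risk_factor"]).sum()

    base = che.total_by_year()
    base = base[base.index.get_level_values("year").isin(years)]
    if discounted_denominator:
        dfac = discount_factor(
            base.index.get_level_values("year").to_numpy(), spec
        )
        base = base * dfac
    denom = base.groupby(level="country").sum()
    totals["base_discounted"] = totals.index.get_level_values("country").map(denom)
    totals["percent"] = totals["discounted"] / totals["base_discounted"] * 100.0
    return totals


def daly_reduction(
    paf: PafSeries,
    daly: DalySeries,
    reduction_levels: Sequence[float],
    year: int | None = None,
    across_country: str = "unweighted",
) -> pd.DataFrame:
    """Average percent DALY reduction per (condition, risk_factor, level).

    Within each country the attributable fraction is averaged over age
    groups with DALY weights (evaluated at a full-ramp year — by default the
    last year common to both tables); the percent reduction for level *s* is
    ``s x PAF x 100``; the table value is then the mean across countries
    (unweighted by default, or DALY-weighted with
    ``across_country='daly_weighted'``).  Countries with zero total DALYs
    for a condition are excluded from that condition's average with a
    logged warning.  Values are exact fractions; rounding is left to display.
    """
    if across_country not in ("unweighted", "daly_weighted"):
        raise ValidationError(
            f"across_country must be 'unweighted' or 'daly_weighted', "
            f"got {across_country!r}"
        )
    paf_years = set(paf.data.index.get_level_values("year"))
    daly_years = set(daly.data.index.get_level_values("year"))
    if year is None:
        common = paf_years & daly_years
        if not common:
            raise ValidationError("daly_reduction: no common year in PAF and DALY")
        year = max(common)

    p = paf.at_year(year).rename("paf").reset_index()
    d = daly.at_year(year).rename("dalys").reset_index()
    merged = p.merge(d, on=["country", "age_group", "condition"], how="inner")
    merged["weighted"] = merged["paf"] * merged["dalys"]
    grouped = merged.groupby(["country", "condition", "risk_factor"])
    num = grouped["weighted"].sum()
    den = grouped["dalys"].sum()

    zero = den[den == 0.0]
    for country, condition, _rf in zero.index:
        logger.warning(
            "daly_reduction: country %r has zero total DALYs for %r; "
            "excluded from the average",
            country,
            condition,
        )
    mean_paf = (num / den).dropna()

    if across_country == "unweighted":
        country_mean = mean_paf.groupby(level=["condition", "risk_factor"]).mean()
    else:
        w = den[den > 0.0]
        country_mean = (mean_paf * w).groupby(
            level=["condition", "risk_factor"]
        ).sum() / w.groupby(level=["condition", "risk_factor"]).sum()

    out = {
        level: country_mean * level * 100.0 for level in reduction_levels
    }
    result = pd.DataFrame(out)
    result.columns.name = "reduction_level"
    return result
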