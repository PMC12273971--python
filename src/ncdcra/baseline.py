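"""Baseline (counterfactual) health-expenditure projection.

When only a base-year CHE snapshot is available, the counterfactual series
is projected forward with a deterministic multiplicative recurrence:

    CHE(t) = CHE(t-1) x (1 + pop_change) x (1 + prev_change) x (1 + residual)

per (country, age group, ICD-10 chapter) cell, compounding annually at year
boundaries.  The three factors are population change (ageing), the relative
change in disease prevalence for the chapter, and a composite residual that
absorbs real growth from income, technology, wages and coverage policy.

Chapter XXI (factors influencing health status and contact with health
services — screening, immunisation, certificates) has no meaningful
prevalence trend, so its prevalence contribution is held flat at zero.

Users who already hold a full externally produced CHE projection bypass this
module entirely and feed that projection to the CRA engine directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import CheSeries, ValidationError

__all__ = ["GrowthComponents", "project_che", "load_growth"]

#: Chapter whose prevalence trend is held flat.
FLAT_PREVALENCE_CHAPTER = "XXI"


@dataclass(frozen=True)
class GrowthComponents:
    """Annual growth factors feeding the projection recurrence.

    ``pop_change``
        per-annum fraction keyed by (country, age_group, year);
    ``prev_change``
        per-annum fraction keyed by (country, chapter, age_group, year);
    ``residual_growth``
        per-annum fraction keyed by (country, year), the composite real
        growth term.

    A factor of 0.02 means 2% growth that year; all factors must exceed -1
    so the multipliers stay positive.
    """

    pop_change: pd.Series
    prev_change: pd.Series
    residual_growth: pd.Series

    def __post_init__(self) -> None:
        for name, series in (
            ("pop_change", self.pop_change),
            ("prev_change", self.prev_change),
            ("residual_growth", self.residual_growth),
        ):
            if (series <= -1.0).any():
                key = series.index[series.values <= -1.0][0]
                raise ValidationError(
                    f"GrowthComponents.{name}: factor <= -1 at {key}"
                )


def _lookup_all(series: pd.Series, index: pd.MultiIndex, what: str) -> np.ndarray:
    """Vectorised lookup; a missing key raises, naming the first missing cell."""
    values = series.reindex(index).to_numpy(dtype=float)
    missing = np.isnan(values)
    if missing.any():
        raise ValidationError(
            f"project_che: missing {what} for {tuple(index[int(missing.argmax())])}"
        )
    return values


def project_che(
    base: CheSeries,
    growth: GrowthComponents,
    horizon_end: int,
) -> CheSeries:
    """Project a base-year CHE snapshot through ``horizon_end``.

    ``base`` must contain exactly one year; every (country, age_group,
    chapter) cell present there is carried forward.  A growth component
    missing for any cell-year is an error naming the cell.
    """
    years = base.years
    if len(years) != 1:
        raise ValidationError(
            f"project_che: base snapshot must hold one year, found {sorted(years)}"
        )
    base_year = int(years[0])
    if horizon_end < base_year:
        raise ValidationError("project_che: horizon_end before base year")

    cells = base.data.xs(base_year, level="year")
    values = cells.to_numpy(dtype=float).copy()
    index = cells.index  # (country, age_group, chapter)

    frames = [
        pd.DataFrame(
            {
                "country": index.get_level_values("country"),
                "age_group": index.get_level_values("age_group"),
                "chapter": index.get_level_values("chapter"),
                "year": base_year,
                CheSeries.VALUE: values,
            }
        )
    ]
    countries = index.get_level_values("country")
    ages = index.get_level_values("age_group")
    chapters = index.get_level_values("chapter")

    n = len(index)
    flat = chapters == FLAT_PREVALENCE_CHAPTER
    for year in range(base_year + 1, horizon_end + 1):
        year_col = np.full(n, year)
        pop = _lookup_all(
            growth.pop_change,
            pd.MultiIndex.from_arrays([countries, ages, year_col]),
            "pop_change",
        )
        prev = np.zeros(n)
        if (~flat).any():
            prev_idx = pd.MultiIndex.from_arrays(
                [countries[~flat], chapters[~flat], ages[~flat], year_col[~flat]]
            )
            prev[~flat] = _lookup_all(growth.prev_change, prev_idx, "prev_change")
        res = _lookup_all(
            growth.residual_growth,
            pd.MultiIndex.from_arrays([countries, year_col]),
            "residual_growth",
        )
        values = values * (1.0 + pop) * (1.0 + prev) * (1.0 + res)
        frames.append(
            pd.DataFrame(
                {
                    "country": countries,
                    "age_group": ages,
                    "chapter": chapters,
                    "year": year,
                    CheSeries.VALUE: values,
                }
            )
        )
    return CheSeries.from_frame(pd.concat(frames, ignore_index=True))


def load_growth(
    pop_path: str | Path,
    prev_path: str | Path,
    residual_path: str | Path,
) -> GrowthComponents:
    """Read the three growth-component CSVs.

    Schemas: pop (country,age_group,year,pop_change);
    prev (country,chapter,age_group,year,prev_change);
    residual (country,year,residual_growth).
    """
    pop = pd.read_csv(pop_path).set_index(["country", "age_group", "year"])[
        "pop_change"
    ]
    prev = pd.read_csv(prev_path).set_index(
        ["country", "chapter", "age_group", "year"]
    )["prev_change"]
    residual = pd.read_csv(residual_path).set_index(["country", "year"])[
        "residual_growth"
    ]
    return GrowthComponents(pop, prev, residual)
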