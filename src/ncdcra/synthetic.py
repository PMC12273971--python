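"""Synthetic input generator.

Real runs of this model need three inputs that are not publicly deposited at
the granularity used here: projected current health expenditure by country,
age and ICD-10 chapter; attributable-DALY fractions (PAFs) by country, age,
condition and risk factor; and DALY totals.  This module fabricates datasets
with the same joint structure — 24 countries in two regions, 18 five-year age
bands, all 22 ICD-10 chapters, PAFs respecting the risk-factor/condition link
matrix — so the full pipeline runs and is tested without any download.

Default PAF ranges are centred on the fractions back-solved from the
published average DALY-reduction table (e.g. tobacco->COPD 0.458,
high SBP->CVD 0.5232), so DALY-weighted mean PAFs of a default run land near
those values.  Magnitudes are plausible for the region, nothing more: the
generator makes no attempt to match any real country's estimates.

Determinism: one named random stream per dataset per country, keyed by
(seed, dataset code, country index), in that order.  Adding a country never
perturbs the draws of earlier countries, and the same seed reproduces
byte-identical CSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import engine
from .data_model import (
    AGE_GROUPS,
    CONDITION_NAMES,
    ICD_CHAPTERS,
    LINKS,
    RISK_FACTORS,
    CheSeries,
    Condition,
    Country,
    DalySeries,
    PafSeries,
    Scenario,
    ValidationError,
    validate_paf,
    write_countries,
)

__all__ = [
    "GeneratorConfig",
    "DEFAULT_PAF_RANGES",
    "generate_inputs",
    "write_inputs",
    "CalibrationResult",
    "calibrate_to_totals",
]

# Stream codes (arbitrary fixed integers) for per-dataset generators.
_STREAM_CHE = 11
_STREAM_PAF = 22
_STREAM_DALY = 33

#: Mean attributable fractions back-solved from the published average DALY
#: reduction percentages (percent / (100 x reduction level)); the generator
#: draws uniformly in +/-10% relative bands around these.
_BACKSOLVED_MEAN_PAF: dict[tuple[str, str], float] = {
    ("tobacco", "cvd"): 0.147,
    ("tobacco", "cancer"): 0.157,
    ("tobacco", "copd"): 0.458,
    ("tobacco", "diabetes_t2"): 0.129,
    ("high_sbp", "cvd"): 0.5232,
    ("high_sbp", "ckd"): 0.564,
    ("high_glucose", "cvd"): 0.230,
    ("high_glucose", "cancer"): 0.039,
    ("high_glucose", "diabetes_t2"): 1.0,
    ("high_glucose", "ckd"): 0.310,
    ("alcohol", "cvd"): 0.017,
    ("alcohol", "cancer"): 0.041,
}

def _centered_band(v: float) -> tuple[float, float]:
    # symmetric so the band mean stays at v even when v is near 1
    half = min(0.1 * v, 1.0 - v)
    return (v - half, v + half)


DEFAULT_PAF_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    pair: _centered_band(v) for pair, v in _BACKSOLVED_MEAN_PAF.items()
}

#: 2020 total-country CHE group means, million 2018 US$/yr, groups 1-4
#: (high to low per-capita spenders).
_GROUP_CHE_LEVEL = {1: 40_000.0, 2: 16_000.0, 3: 6_000.0, 4: 2_400.0}

#: Relative DALY magnitude per condition (CVD dominates NCD burden).
_CONDITION_DALY_WEIGHT = {
    "cvd": 4.0,
    "cancer": 3.0,
    "diabetes_t2": 1.5,
    "copd": 1.0,
    "ckd": 0.8,
}


class GeneratorConfig(BaseModel):
    """Configuration of the synthetic world.

    Defaults state the modelled conditions: 16 Latin American + 8 Caribbean
    countries, years 2020-2050, ~4.5%/yr real CHE growth, PAF bands centred
    on the published back-solved means, time-constant PAFs.
    """

    seed: int = 0
    n_latin: int = Field(default=16, ge=0)
    n_carib: int = Field(default=8, ge=0)
    year_start: int = 2020
    year_end: int = 2050
    che_growth_mean: float = 0.045
    che_growth_sd: float = 0.01
    paf_ranges: dict[tuple[str, str], tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_PAF_RANGES)
    )
    paf_age_gradient: float = 0.0  # optional mild monotone-in-age tilt, off
    paf_drift: float = 0.0  # optional linear per-year drift, off
    daly_scale: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.n_latin + self.n_carib < 1:
            raise ValueError("need at least one country")
        if self.year_end < self.year_start:
            raise ValueError("year_end before year_start")
        for pair, (lo, hi) in self.paf_ranges.items():
            if pair not in LINKS:
                raise ValueError(f"paf_ranges: pair {pair} not in the link matrix")
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"paf_ranges: range {lo, hi} for {pair} outside [0, 1]")
        return self

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


def _make_countries(config: GeneratorConfig) -> list[Country]:
    countries = []
    for i in range(config.n_latin):
        countries.append(
            Country(f"L{i + 1:02d}", f"Latinia {i + 1:02d}", "latin_america", i % 4 + 1)
        )
    for i in range(config.n_carib):
        countries.append(
            Country(f"C{i + 1:02d}", f"Caribia {i + 1:02d}", "caribbean", i % 4 + 1)
        )
    return countries


def _rng(config: GeneratorConfig, stream: int, country_idx: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, country_idx])


def _generate_che_country(
    config: GeneratorConfig, country: Country, idx: int
) -> pd.DataFrame:
    rng = _rng(config, _STREAM_CHE, idx)
    years = config.years
    ages = np.array(AGE_GROUPS, dtype=float)

    level = _GROUP_CHE_LEVEL[country.expenditure_group] * rng.lognormal(0.0, 0.3)
    # expenditure rises with age; mild jitter keeps profiles country-specific
    age_w = (0.5 + 2.0 * (ages / 85.0) ** 1.5) * rng.lognormal(0.0, 0.1, len(ages))
    age_w /= age_w.sum()
    chap_base = np.ones(len(ICD_CHAPTERS))
    chap_base[ICD_CHAPTERS.index("IX")] = 3.0  # circulatory
    chap_base[ICD_CHAPTERS.index("II")] = 2.0  # neoplasms
    chap_w = chap_base * rng.lognormal(0.0, 0.2, len(ICD_CHAPTERS))
    chap_w /= chap_w.sum()

    growth = rng.normal(config.che_growth_mean, config.che_growth_sd, len(years) - 1)
    mult = np.concatenate([[1.0], np.cumprod(1.0 + growth)])

    base = level * np.einsum("a,c->ac", age_w, chap_w)  # (age, chapter)
    values = np.einsum("ac,y->acy", base, mult).ravel()
    age_col, chap_col, year_col = (
        arr.ravel()
        for arr in np.meshgrid(AGE_GROUPS, ICD_CHAPTERS, years, indexing="ij")
    )
    return pd.DataFrame(
        {
            "country": country.code,
            "age_group": age_col.astype(int),
            "chapter": chap_col,
            "year": year_col.astype(int),
            CheSeries.VALUE: values,
        }
    )


def _generate_paf_country(
    config: GeneratorConfig, country: Country, idx: int
) -> pd.DataFrame:
    rng = _rng(config, _STREAM_PAF, idx)
    years = config.years
    n_ages = len(AGE_GROUPS)
    frames = []
    # iterate pairs in fixed (risk factor, condition) vocabulary order so the
    # stream order is stable regardless of dict insertion order
    for rf in RISK_FACTORS:
        for cond in CONDITION_NAMES:
            if (rf, cond) not in config.paf_ranges:
                continue
            lo, hi = config.paf_ranges[(rf, cond)]
            base = rng.uniform(lo, hi, n_ages)
            if config.paf_age_gradient:
                tilt = 1.0 + config.paf_age_gradient * (
                    np.arange(n_ages) / (n_ages - 1) - 0.5
                )
                base = np.clip(base * tilt, 0.0, 1.0)
            drift = 1.0 + config.paf_drift * (years - years[0])
            vals = np.clip(np.einsum("a,y->ay", base, drift), 0.0, 1.0).ravel()
            age_col, year_col = (
                arr.ravel() for arr in np.meshgrid(AGE_GROUPS, years, indexing="ij")
            )
            frames.append(
                pd.DataFrame(
                    {
                        "country": country.code,
                        "age_group": age_col.astype(int),
                        "condition": cond,
                        "risk_factor": rf,
                        "year": year_col.astype(int),
                        PafSeries.VALUE: vals,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _generate_daly_country(
    config: GeneratorConfig, country: Country, idx: int
) -> pd.DataFrame:
    rng = _rng(config, _STREAM_DALY, idx)
    years = config.years
    ages = np.array(AGE_GROUPS, dtype=float)
    # burden scales with country size; proxy via expenditure group
    size = config.daly_scale * _GROUP_CHE_LEVEL[country.expenditure_group] * 10.0
    frames = []
    for cond in CONDITION_NAMES:
        level = size * _CONDITION_DALY_WEIGHT[cond] * rng.lognormal(0.0, 0.3)
        age_w = (0.2 + (ages / 85.0) ** 2) * rng.lognormal(0.0, 0.15, len(ages))
        age_w /= age_w.sum()
        growth = 1.0 + 0.01 * (years - years[0])  # slow secular increase
        vals = np.einsum("a,y->ay", level * age_w, growth).ravel()
        age_col, year_col = (
            arr.ravel() for arr in np.meshgrid(AGE_GROUPS, years, indexing="ij")
        )
        frames.append(
            pd.DataFrame(
                {
                    "country": country.code,
                    "age_group": age_col.astype(int),
                    "condition": cond,
                    "year": year_col.astype(int),
                    DalySeries.VALUE: vals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_inputs(
    config: GeneratorConfig,
) -> tuple[CheSeries, PafSeries, DalySeries, list[Country]]:
    """Generate the full synthetic input set for one configuration.

    Deterministic for a fixed seed.  Outputs always pass data-model
    validation: CHE strictly positive with smooth growth, PAFs inside the
    configured ranges and zero off the link matrix, DALYs positive.
    """
    countries = _make_countries(config)
    che = CheSeries.from_frame(
        pd.concat(
            [_generate_che_country(config, c, i) for i, c in enumerate(countries)],
            ignore_index=True,
        )
    )
    paf = validate_paf(
        PafSeries.from_frame(
            pd.concat(
                [_generate_paf_country(config, c, i) for i, c in enumerate(countries)],
                ignore_index=True,
            )
        )
    )
    daly = DalySeries.from_frame(
        pd.concat(
            [_generate_daly_country(config, c, i) for i, c in enumerate(countries)],
            ignore_index=True,
        )
    )
    return che, paf, daly, countries


def write_inputs(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write che.csv, paf.csv, daly.csv, countries.csv and a manifest.

    Same seed => byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    che, paf, daly, countries = generate_inputs(config)
    paths = {
        "che": out / "che.csv",
        "paf": out / "paf.csv",
        "daly": out / "daly.csv",
        "countries": out / "countries.csv",
        "manifest": out / "manifest.json",
    }
    che.to_csv(paths["che"])
    paf.to_csv(paths["paf"])
    daly.to_csv(paths["daly"])
    write_countries(countries, paths["countries"])
    cfg = config.model_dump()
    cfg["paf_ranges"] = {
        f"{rf}|{cond}": list(rng_) for (rf, cond), rng_ in config.paf_ranges.items()
    }
    manifest = {"seed": config.seed, "config": cfg}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# Calibration against published cumulative-savings totals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationResult:
    """Per-risk-factor CHE scale factors matching target cumulative savings.

    Savings are exactly linear in expenditure levels, so running a
    single-factor scenario on ``che.scale(factors[rf])`` reproduces the
    target for that factor; the joint calibrated total is the sum of the
    calibrated single-factor totals (the model is additive across factors).
    """

    factors: dict[str, float]
    current: dict[str, float]
    targets: dict[str, float]

    def scaled_che(self, che: CheSeries, risk_factor: str) -> CheSeries:
        return che.scale(self.factors[risk_factor])


def calibrate_to_totals(
    che: CheSeries,
    conditions: Sequence[Condition],
    paf: PafSeries,
    scenario: Scenario,
    targets: Mapping[str, float],
) -> CalibrationResult:
    """Solve for CHE scale factors reproducing target cumulative savings.

    ``targets`` maps risk factor -> desired cumulative discounted savings
    (million US$) under ``scenario``'s reduction level for that factor.
    Zero target gives factor 0 (that factor's CHE contribution vanishes);
    a target unreachable with non-negative scaling raises.
    """
    spec = engine.DiscountSpec(scenario.discount_rate, scenario.base_year)
    factors: dict[str, float] = {}
    current: dict[str, float] = {}
    for rf, target in targets.items():
        single = scenario.single_factor(rf)
        impact = engine.run_scenario(che, conditions, paf, single)
        total = float(
            engine.cumulative_savings(impact, che, spec)["discounted"].sum()
        )
        current[rf] = total
        if target == 0.0:
            factors[rf] = 0.0
            continue
        if total <= 0.0 or target < 0.0:
            raise ValidationError(
                f"calibrate_to_totals: target {target} for {rf!r} unreachable "
                f"with nonnegative scaling (current total {total})"
            )
        factors[rf] = target / total
    return CalibrationResult(factors=factors, current=current, targets=dict(targets))
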