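from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ncdcra import (
    CheSeries,
    DalySeries,
    GeneratorConfig,
    PafSeries,
    generate_inputs,
)


@pytest.fixture(scope="session")
def tiny_world():
    """Three-country synthetic world (2 Latin American, 1 Caribbean), full horizon."""
    config = GeneratorConfig(seed=11, n_latin=2, n_carib=1)
    che, paf, daly, countries = generate_inputs(config)
    return config, che, paf, daly, countries


def make_che(
    countries=("AA",),
    ages=(40,),
    chapters=("IX",),
    years=range(2020, 2023),
    value=1000.0,
) -> CheSeries:
    """Constant-valued CHE table over a full cartesian key grid."""
    idx = pd.MultiIndex.from_product(
        [countries, ages, chapters, list(years)],
        names=["country", "age_group", "chapter", "year"],
    )
    return CheSeries(pd.Series(value, index=idx, name=CheSeries.VALUE))


def make_paf(
    countries=("AA",),
    ages=(40,),
    pairs=((("cvd"), ("tobacco")),),
    years=range(2020, 2023),
    value=0.5,
) -> PafSeries:
    rows = []
    for c in countries:
        for a in ages:
            for cond, rf in pairs:
                for y in years:
                    rows.append((c, a, cond, rf, y, value))
    frame = pd.DataFrame(
        rows,
        columns=["country", "age_group", "condition", "risk_factor", "year", "fraction"],
    )
    return PafSeries.from_frame(frame)


def make_daly(
    countries=("AA",),
    ages=(40,),
    conditions=("cvd",),
    years=range(2020, 2023),
    value=1e5,
) -> DalySeries:
    idx = pd.MultiIndex.from_product(
        [countries, ages, conditions, list(years)],
        names=["country", "age_group", "condition", "year"],
    )
    return DalySeries(pd.Series(value, index=idx, name=DalySeries.VALUE))
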