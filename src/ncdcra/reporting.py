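"""Aggregation to country/region/grand totals and table rendering.

Produces the two headline table shapes: cumulative discounted savings by
country with region subtotals and a grand total (savings in million 2018
US$ plus percent of base-case cumulative expenditure), and average percent
DALY reductions by condition x risk factor x reduction level with blanks at
unlinked pairs.

Subtotals are always computed from unrounded values; rounding happens only
at render time, so a displayed subtotal may differ from the sum of displayed
member rows by up to one unit in the last place per member.  Rendering is a
pure function of the summary objects.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import engine, synthetic
from .data_model import (
    CONDITION_NAMES,
    RISK_FACTORS,
    Country,
    Scenario,
    ValidationError,
    default_condition_table,
    load_che,
    load_countries,
    load_daly,
    load_paf,
)

logger = logging.getLogger(__name__)

__all__ = ["ReportSpec", "savings_table", "daly_table", "run_pipeline"]

#: Printed column order of the savings table.
_RF_ORDER = ("tobacco", "high_sbp", "high_glucose", "alcohol")
_RF_LABEL = {
    "tobacco": "Tobacco",
    "high_sbp": "Hypertension",
    "high_glucose": "High blood glucose",
    "alcohol": "Alcohol",
}
#: Printed row order of the DALY table.
_CONDITION_ORDER = ("cvd", "cancer", "copd", "diabetes_t2", "ckd")
_CONDITION_LABEL = {
    "cvd": "Cardiovascular diseases",
    "cancer": "Cancer (neoplasms)",
    "copd": "Chronic obstructive pulmonary disease",
    "diabetes_t2": "Diabetes mellitus type 2",
    "ckd": "Chronic kidney disease",
}
_REGION_LABEL = {
    "latin_america": "All Latin American countries",
    "caribbean": "All Caribbean countries",
}


@dataclass(frozen=True)
class ReportSpec:
    """What to render and how."""

    grouping: str = "all"  # country | region | all
    formats: tuple[str, ...] = ("csv", "markdown")
    savings_decimals: int = 0
    percent_decimals: int = 2

    def __post_init__(self) -> None:
        if self.grouping not in ("country", "region", "all"):
            raise ValidationError(f"unknown grouping {self.grouping!r}")
        if not self.formats:
            raise ValidationError("at least one output format required")
        unknown = set(self.formats) - {"csv", "markdown"}
        if unknown:
            raise ValidationError(f"unknown format(s) {sorted(unknown)}")


def _gfm_table(frame: pd.DataFrame) -> str:
    """Minimal GitHub-flavored-markdown renderer (cells already strings)."""
    cols = list(frame.columns)
    widths = [
        max(len(str(c)), *(len(str(v)) for v in frame[c])) if len(frame) else len(str(c))
        for c in cols
    ]
    def row(cells: Sequence[str]) -> str:
        return "| " + " | ".join(str(v).ljust(w) for v, w in zip(cells, widths)) + " |"
    lines = [row(cols), "| " + " | ".join("-" * w for w in widths) + " |"]
    lines += [row(r) for r in frame.itertuples(index=False)]
    return "\n".join(lines) + "\n"


def _savings_frame(
    summary: pd.DataFrame, countries: Sequence[Country], spec: ReportSpec
) -> pd.DataFrame:
    """Unrounded savings table: one row per country/subtotal/grand total.

    ``summary`` is the cumulative-savings frame keyed (country, risk_factor)
    with columns discounted and base_discounted.
    """
    by_code = {c.code: c for c in countries}
    known = set(summary.index.get_level_values("country"))
    missing = known - set(by_code)
    if missing:
        raise ValidationError(f"savings_table: unknown country {sorted(missing)[0]!r}")

    rfs = [rf for rf in _RF_ORDER if rf in summary.index.get_level_values("risk_factor")]
    wide = summary["discounted"].unstack("risk_factor").reindex(columns=rfs).fillna(0.0)
    denom = summary["base_discounted"].groupby(level="country").first()

    def rows_for(codes: list[str], label: str | None = None) -> dict:
        sav = wide.loc[codes].sum(axis=0)
        d = denom.loc[codes].sum()
        rec: dict = {"row": label}
        for rf in rfs:
            rec[f"{rf}_savings"] = sav[rf]
            rec[f"{rf}_percent"] = sav[rf] / d * 100.0
        rec["combined_savings"] = sav.sum()
        rec["combined_percent"] = sav.sum() / d * 100.0
        return rec

    records = []
    for region in ("latin_america", "caribbean"):
        members = sorted(
            (c for c in countries if c.region == region and c.code in known),
            key=lambda c: c.name,
        )
        if not members:
            continue
        if spec.grouping in ("country", "all"):
            for c in members:
                records.append(rows_for([c.code], c.name))
        if spec.grouping in ("region", "all"):
            records.append(rows_for([c.code for c in members], _REGION_LABEL[region]))
    all_codes = [c.code for c in countries if c.code in known]
    records.append(rows_for(all_codes, "All countries"))
    return pd.DataFrame(records)


def savings_table(
    summary: pd.DataFrame,
    countries: Sequence[Country],
    spec: ReportSpec = ReportSpec(),
) -> dict[str, str]:
    """Render cumulative savings by country with subtotals and grand total.

    Returns one rendered string per requested format.  Markdown gets
    thousands separators; CSV stays machine-readable.
    """
    frame = _savings_frame(summary, countries, spec)
    out: dict[str, str] = {}
    if "csv" in spec.formats:
        csv_frame = frame.copy()
        for col in csv_frame.columns:
            if col.endswith("_savings"):
                csv_frame[col] = csv_frame[col].round(spec.savings_decimals)
            elif col.endswith("_percent"):
                csv_frame[col] = csv_frame[col].round(spec.percent_decimals)
        out["csv"] = csv_frame.to_csv(index=False)
    if "markdown" in spec.formats:
        md = pd.DataFrame()
        md["Country"] = frame["row"]
        for col in frame.columns:
            if col == "row":
                continue
            name = col.rsplit("_", 1)[0]
            label = _RF_LABEL.get(name, "All four risk factors")
            if col.endswith("_savings"):
                md[f"{label} (M US$)"] = [
                    f"{v:,.{spec.savings_decimals}f}" for v in frame[col]
                ]
            else:
                md[f"{label} (%)"] = [
                    f"{v:.{spec.percent_decimals}f}%" for v in frame[col]
                ]
        out["markdown"] = _gfm_table(md)
    return out


def daly_table(
    daly_summary: pd.DataFrame,
    spec: ReportSpec = ReportSpec(),
    links=None,
) -> dict[str, str]:
    """Render average percent DALY reductions, blanks at unlinked pairs.

    ``daly_summary`` is the frame from :func:`ncdcra.engine.daly_reduction`:
    indexed (condition, risk_factor), one column per reduction level.
    """
    from .data_model import default_link_matrix

    links = links or default_link_matrix()
    levels = list(daly_summary.columns)
    rows: list[dict[str, str]] = []
    for cond in _CONDITION_ORDER:
        rec = {"Condition": _CONDITION_LABEL[cond]}
        for rf in _RF_ORDER:
            for level in levels:
                col = f"{_RF_LABEL[rf]} {level * 100:g}%"
                if not links.linked(rf, cond):
                    rec[col] = ""
                elif (cond, rf) in daly_summary.index:
                    rec[col] = (
                        f"{daly_summary.loc[(cond, rf), level]:.{spec.percent_decimals}f}"
                    )
                else:
                    rec[col] = ""
        rows.append(rec)
    frame = pd.DataFrame(rows)
    out: dict[str, str] = {}
    if "csv" in spec.formats:
        out["csv"] = frame.to_csv(index=False)
    if "markdown" in spec.formats:
        out["markdown"] = _gfm_table(frame)
    return out


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

_DEFAULT_SCENARIO = {
    "reductions": {rf: 0.10 for rf in RISK_FACTORS},
    "start_year": 2020,
    "ramp_years": 10,
    "horizon_end": 2050,
    "discount_rate": 0.03,
    "base_year": 2020,
}
_DEFAULT_DALY_LEVELS = [0.05, 0.10, 0.25]


def _load_inputs(inputs_cfg: Mapping):
    if "synthetic" in inputs_cfg:
        syn = inputs_cfg["synthetic"] or {}
        config = synthetic.GeneratorConfig(**syn)
        return synthetic.generate_inputs(config), config
    if "files" in inputs_cfg:
        files = inputs_cfg["files"]
        che = load_che(files["che"])
        paf = load_paf(files["paf"])
        daly = load_daly(files["daly"])
        countries = load_countries(files["countries"])
        return (che, paf, daly, countries), None
    raise ValidationError("pipeline config: inputs must name 'synthetic' or 'files'")


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Run inputs -> scenario -> reports end to end; idempotent per config.

    ``config`` is a mapping or a YAML file path with keys ``inputs``
    (``synthetic: {seed: ...}`` or ``files: {...}``), optional ``scenario``,
    ``daly_levels``, ``report`` and ``out_dir``.  Writes a run manifest,
    the impact table, the savings table and the DALY table; on any failure
    the partially written outputs are removed and the error re-raised.
    """
    if isinstance(config, (str, Path)):
        raw = Path(config).read_text()
        config = yaml.safe_load(raw)
        if not isinstance(config, Mapping):
            raise ValidationError("pipeline config: top level must be a mapping")
    out = Path(out_dir or config.get("out_dir", "cra_output"))
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> Path:
        path = out / name
        path.write_text(text)
        written.append(path)
        return path

    try:
        (che, paf, daly, countries), gen_config = _load_inputs(config["inputs"])
        scenario = Scenario(**{**_DEFAULT_SCENARIO, **config.get("scenario", {})})
        levels = config.get("daly_levels", _DEFAULT_DALY_LEVELS)
        spec = ReportSpec(**config.get("report", {}))
        conditions = default_condition_table()

        impact = engine.run_scenario(che, conditions, paf, scenario)
        dspec = engine.DiscountSpec(scenario.discount_rate, scenario.base_year)
        summary = engine.cumulative_savings(impact, che, dspec)
        dsum = engine.daly_reduction(paf, daly, levels)

        path = out / "impact.csv"
        impact.to_csv(path)
        written.append(path)
        for fmt, text in savings_table(summary, countries, spec).items():
            emit(f"savings_table.{'md' if fmt == 'markdown' else 'csv'}", text)
        for fmt, text in daly_table(dsum, spec).items():
            emit(f"daly_table.{'md' if fmt == 'markdown' else 'csv'}", text)

        cfg_json = json.dumps(config, sort_keys=True, default=str)
        manifest = {
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": (gen_config.seed if gen_config is not None else None),
            "scenario": json.loads(scenario.model_dump_json()),
            "versions": {
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        emit("run_manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline wrote %d files to %s", len(written), out)
        return written
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
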