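"""Domain types and tabular I/O for farm survey datasets.

The analysis operates on two paired tables: a farm-by-variable design matrix
``X`` (explanatory variables describing each farm, its management and its study
field) and a farm-by-indicator response matrix ``Y`` (crop performance
indicators measured on the study field). Both are plain CSV on disk and
:class:`pandas.DataFrame` in memory; the classes here add schema metadata and
validation on top.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LEVELS",
    "KINDS",
    "RESPONSE_NAMES",
    "POSITIVE_RESPONSES",
    "VariableSpec",
    "FarmRecord",
    "DesignMatrix",
    "ResponseMatrix",
    "SchemaError",
    "ValidationError",
    "load_schema",
    "default_schema",
    "read_farm_table",
    "write_farm_table",
    "read_response_table",
    "write_response_table",
    "write_report_tables",
]

LEVELS = frozenset(
    {"farm_description", "farm_management", "field_history", "field_current", "soil", "landscape"}
)
KINDS = frozenset({"continuous", "dummy", "ordinal", "percentage", "index"})

#: Default barley performance indicators, in reporting order.
RESPONSE_NAMES = ("DM1", "N-Cut1", "DM2", "Grain-M", "Grain-N", "Straw-N", "Ears")
#: Yield / count indicators that must be strictly positive.
POSITIVE_RESPONSES = frozenset({"DM1", "DM2", "Grain-M", "Ears"})

#: Units per default indicator (dry matter t/ha, N concentrations %, ear count 1/m2).
RESPONSE_UNITS = {
    "DM1": "t/ha",
    "N-Cut1": "%",
    "DM2": "t/ha",
    "Grain-M": "t/ha",
    "Grain-N": "%",
    "Straw-N": "%",
    "Ears": "1/m2",
}

METADATA_COLUMNS = ("farm_id", "region", "farm_type", "years_since_transition")

#: Decimal places used when formatting report tables (round-trip contract).
REPORT_DECIMALS = 6


class SchemaError(ValueError):
    """A table does not conform to the declared variable schema."""


class ValidationError(ValueError):
    """A value violates a variable's declared kind or range."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one explanatory variable.

    Parameters
    ----------
    name : str
        Short unique identifier (column name).
    label : str
        Human-readable description.
    level : str
        Organisational level the variable describes (one of :data:`LEVELS`).
    kind : str
        Measurement kind (one of :data:`KINDS`).
    unit : str
        Physical unit; empty for dimensionless variables.
    region_standardized : bool
        Whether the variable is median-centred within region before analysis
        (e.g. sowing date, which differs systematically between climatic zones).
    valid_range : tuple of float, optional
        Closed interval of admissible raw values; ``None`` disables range checks.
    """

    name: str
    label: str = ""
    level: str = "farm_description"
    kind: str = "continuous"
    unit: str = ""
    region_standardized: bool = False
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise SchemaError(f"unknown level {self.level!r} for variable {self.name!r}")
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.kind == "dummy":
            if self.valid_range != (0.0, 1.0):
                raise SchemaError(f"dummy variable {self.name!r} must have valid_range (0, 1)")
        if self.kind == "ordinal":
            if self.valid_range is None:
                raise SchemaError(f"ordinal variable {self.name!r} needs an integer valid_range")
            lo, hi = self.valid_range
            if lo != int(lo) or hi != int(hi):
                raise SchemaError(f"ordinal variable {self.name!r} has non-integer bounds")
        if self.valid_range is not None and self.valid_range[0] > self.valid_range[1]:
            raise SchemaError(f"variable {self.name!r} has an empty valid_range")

    def check_values(self, values: np.ndarray, context: str = "") -> None:
        """Raise :class:`ValidationError` if any value violates this spec."""
        arr = np.asarray(values, dtype=float)
        where = f" in {context}" if context else ""
        if np.isnan(arr).any():
            raise ValidationError(f"missing value for variable {self.name!r}{where}")
        if self.kind == "dummy":
            if not np.isin(arr, (0.0, 1.0)).all():
                raise ValidationError(f"dummy variable {self.name!r} has non-binary value{where}")
            return
        if self.kind == "ordinal" and not (arr == np.round(arr)).all():
            raise ValidationError(f"ordinal variable {self.name!r} has non-integer value{where}")
        # Range checks apply to raw values; once a variable is median-centred
        # within region the raw bounds no longer hold.
        if self.valid_range is not None and not self.region_standardized:
            lo, hi = self.valid_range
            if (arr < lo).any() or (arr > hi).any():
                raise ValidationError(
                    f"variable {self.name!r} outside valid range [{lo}, {hi}]{where}"
                )


def _check_unique_names(schema: Sequence[VariableSpec]) -> None:
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate variable names in schema: {dupes}")


def load_schema(path: str | Path) -> list[VariableSpec]:
    """Load a variable schema from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for entry in raw["variables"]:
        entry = dict(entry)
        rng = entry.get("valid_range")
        if rng is not None:
            entry["valid_range"] = (float(rng[0]), float(rng[1]))
        specs.append(VariableSpec(**entry))
    _check_unique_names(specs)
    return specs


def default_schema() -> list[VariableSpec]:
    """The shipped 34-variable schema (farm description, landscape index,
    management practices at farm and field level, and soil parameters)."""
    ref = importlib.resources.files("agropls") / "data" / "default_schema.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_schema(path)


@dataclass
class FarmRecord:
    """One surveyed farm: identity, stratification labels and variable values."""

    farm_id: str
    region: str
    farm_type: str  # CF, YOF or OOF
    years_since_transition: int
    values: dict[str, float] = field(default_factory=dict)

    #: Default bounds on years-since-transition per organic farm type.
    YOF_MAX_YEARS = 6  # exclusive
    OOF_YEARS = (11, 26)  # inclusive

    def __post_init__(self) -> None:
        if self.farm_type not in ("CF", "YOF", "OOF"):
            raise ValidationError(f"farm {self.farm_id!r}: unknown farm type {self.farm_type!r}")
        if self.years_since_transition < 0:
            raise ValidationError(f"farm {self.farm_id!r}: negative years since transition")

    @property
    def is_organic(self) -> bool:
        return self.farm_type in ("YOF", "OOF")

    def check_type_consistency(
        self,
        yof_max: int = YOF_MAX_YEARS,
        oof_years: tuple[int, int] = OOF_YEARS,
    ) -> None:
        """Check farm type against years since transition (YOF < 6 years,
        OOF 11--26 years by default). The type label is authoritative; this is
        a consistency check, not a derivation."""
        t = self.years_since_transition
        if self.farm_type == "YOF" and not t < yof_max:
            raise ValidationError(
                f"farm {self.farm_id!r}: YOF with {t} years since transition (>= {yof_max})"
            )
        if self.farm_type == "OOF" and not oof_years[0] <= t <= oof_years[1]:
            raise ValidationError(
                f"farm {self.farm_id!r}: OOF with {t} years since transition "
                f"(outside {oof_years})"
            )


def _as_frame(values, rows, columns) -> pd.DataFrame:
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(rows), columns=list(columns))
    df.index.name = "farm_id"
    return df


@dataclass
class DesignMatrix:
    """The n x p explanatory matrix with its schema.

    ``values`` is a DataFrame indexed by farm_id with one column per
    :class:`VariableSpec`, in schema order.
    """

    values: pd.DataFrame
    schema: list[VariableSpec]

    def __post_init__(self) -> None:
        _check_unique_names(self.schema)
        names = [v.name for v in self.schema]
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise SchemaError(f"design matrix missing schema columns: {missing}")
        self.values = self.values.loc[:, names].astype(float)
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate farm_id in design matrix")
        for spec in self.schema:
            spec.check_values(self.values[spec.name].to_numpy(), context="design matrix")

    @property
    def farm_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.schema]

    def subset(self, farm_ids: Iterable[str]) -> "DesignMatrix":
        return DesignMatrix(self.values.loc[list(farm_ids)], self.schema)


@dataclass
class ResponseMatrix:
    """The n x m crop performance indicator matrix."""

    values: pd.DataFrame
    indicators: tuple[str, ...] = RESPONSE_NAMES

    def __post_init__(self) -> None:
        missing = [n for n in self.indicators if n not in self.values.columns]
        if missing:
            raise SchemaError(f"response matrix missing indicators: {missing}")
        self.values = self.values.loc[:, list(self.indicators)].astype(float)
        if self.values.isna().any().any():
            raise ValidationError("missing values in response matrix")
        for name in self.indicators:
            if name in POSITIVE_RESPONSES and (self.values[name] <= 0).any():
                raise ValidationError(f"indicator {name!r} must be strictly positive")

    @property
    def farm_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, farm_ids: Iterable[str]) -> "ResponseMatrix":
        return ResponseMatrix(self.values.loc[list(farm_ids)], self.indicators)


def read_farm_table(path: str | Path, schema: Sequence[VariableSpec]) -> list[FarmRecord]:
    """Read a farm table CSV into validated :class:`FarmRecord` objects.

    The CSV must contain the metadata columns ``farm_id, region, farm_type,
    years_since_transition`` plus one column per schema variable.
    """
    df = pd.read_csv(path)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"farm table missing required column {col!r}")
    for spec in schema:
        if spec.name not in df.columns:
            raise SchemaError(f"farm table missing schema column {spec.name!r}")
    if df["farm_id"].duplicated().any():
        dupes = sorted(df.loc[df["farm_id"].duplicated(), "farm_id"].astype(str))
        raise ValidationError(f"duplicate farm_id values: {dupes}")
    records = []
    for _, row in df.iterrows():
        farm_id = str(row["farm_id"])
        values = {}
        for spec in schema:
            val = float(row[spec.name])
            spec.check_values(np.array([val]), context=f"farm {farm_id!r}")
            values[spec.name] = val
        records.append(
            FarmRecord(
                farm_id=farm_id,
                region=str(row["region"]),
                farm_type=str(row["farm_type"]),
                years_since_transition=int(row["years_since_transition"]),
                values=values,
            )
        )
    return records


def write_farm_table(
    records: Sequence[FarmRecord], schema: Sequence[VariableSpec], path: str | Path
) -> Path:
    """Write farm records to CSV (inverse of :func:`read_farm_table`).

    Dummy and ordinal variables are written as integers; continuous values use
    full repr precision so a read round-trip is exact.
    """
    path = Path(path)
    rows = []
    int_kinds = {"dummy", "ordinal"}
    for rec in records:
        row: dict[str, object] = {
            "farm_id": rec.farm_id,
            "region": rec.region,
            "farm_type": rec.farm_type,
            "years_since_transition": rec.years_since_transition,
        }
        for spec in schema:
            v = rec.values[spec.name]
            row[spec.name] = int(round(v)) if spec.kind in int_kinds else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_response_table(
    path: str | Path, indicators: Sequence[str] = RESPONSE_NAMES
) -> ResponseMatrix:
    df = pd.read_csv(path).set_index("farm_id")
    df.index = df.index.astype(str)
    return ResponseMatrix(df, tuple(indicators))


def write_response_table(responses: ResponseMatrix, path: str | Path) -> Path:
    path = Path(path)
    responses.values.to_csv(path)
    return path


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(REPORT_DECIMALS)


def write_report_tables(report, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a fit report or suite result to tidy CSV files.

    Writes, depending on the report type:

    ``metrics.csv``
        one row per (model, response) plus an ``overall`` row per model, with
        R2Y(cum), Q2Y(cum) and RMSRE (%).
    ``retained.csv``
        one row per (model, variable) for the VIP-retained variables.
    ``vip.csv``
        one row per (model, variable) with the first-round VIP score.
    ``summary.csv`` (suites only)
        mean and SD of overall R2Y/Q2Y per resample group.

    Values are written with a fixed number of decimals
    (:data:`REPORT_DECIMALS`), so re-reading reproduces them bit-exactly at
    that precision.
    """
    from .model_selection import FitReport  # local import to avoid a cycle
    from .suite import SuiteResult

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(report, FitReport):
        reports = [report]
        summary = None
    elif isinstance(report, SuiteResult):
        reports = list(report.reports)
        summary = report.summary
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot serialize report of type {type(report).__name__}")

    metric_rows, retained_rows, vip_rows = [], [], []
    for rep in reports:
        for resp in list(rep.r2y.index):
            metric_rows.append(
                {
                    "model": rep.label,
                    "response": resp,
                    "r2y_cum": rep.r2y[resp],
                    "q2y_cum": rep.q2y[resp],
                    "rmsre_pct": rep.rmsre.get(resp, np.nan),
                }
            )
        metric_rows.append(
            {
                "model": rep.label,
                "response": "overall",
                "r2y_cum": rep.r2y_overall,
                "q2y_cum": rep.q2y_overall,
                "rmsre_pct": np.nan,
            }
        )
        for var in rep.retained:
            retained_rows.append({"model": rep.label, "variable": var})
        for var, score in rep.vip.items():
            vip_rows.append({"model": rep.label, "variable": var, "vip": score})

    paths = {}
    metrics = pd.DataFrame(metric_rows, columns=["model", "response", "r2y_cum", "q2y_cum", "rmsre_pct"])
    paths["metrics"] = out_dir / "metrics.csv"
    _fmt(metrics).to_csv(paths["metrics"], index=False)
    retained = pd.DataFrame(retained_rows, columns=["model", "variable"])
    paths["retained"] = out_dir / "retained.csv"
    retained.to_csv(paths["retained"], index=False)
    vip = pd.DataFrame(vip_rows, columns=["model", "variable", "vip"])
    paths["vip"] = out_dir / "vip.csv"
    _fmt(vip).to_csv(paths["vip"], index=False)
    if summary is not None:
        paths["summary"] = out_dir / "summary.csv"
        _fmt(summary).to_csv(paths["summary"], index=False)
    return paths


def export_model(model, out_dir: str | Path) -> dict[str, Path]:
    """Export a fitted PLS model as tidy CSVs (weights, loadings, scores) plus
    a JSON of scalar diagnostics."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def tidy(mat, rows, what):
        recs = []
        for i, r in enumerate(rows):
            for a in range(mat.shape[1]):
                recs.append({"name": r, "component": a + 1, "value": mat[i, a]})
        return pd.DataFrame(recs)

    xnames = list(model.feature_names_in_)
    ynames = list(model.response_names_in_)
    rows = list(model.row_index_)
    for what, mat, names in (
        ("x_weights", model.x_weights_, xnames),
        ("x_loadings", model.x_loadings_, xnames),
        ("y_loadings", model.y_loadings_, ynames),
        ("x_scores", model.x_scores_, rows),
    ):
        paths[what] = out_dir / f"{what}.csv"
        _fmt(tidy(mat, names, what)).to_csv(paths[what], index=False)
    scalars = {
        "n_components": int(model.n_components_),
        "r2x_cum": float(model.r2x_cum_[-1]),
        "r2y_cum": float(model.r2y_cum_[-1]),
        "r2y_per_response": {k: float(v) for k, v in model.r2y_per_response_.items()},
    }
    paths["scalars"] = out_dir / "model.json"
    with open(paths["scalars"], "w", encoding="utf-8") as fh:
        json.dump(scalars, fh, indent=2)
    return paths
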