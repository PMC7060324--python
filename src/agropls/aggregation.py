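"""Aggregation of raw survey answers into the explanatory-variable schema.

Farm questionnaires yield many heterogeneous answers per farm (areas, counts
per year, categorical practice descriptions); the analysis uses a much smaller
set of synthetic variables. Each schema variable of non-soil level is produced
by exactly one :class:`AggregationRule`; soil variables come from laboratory
measurements and bypass aggregation.

Two cross-farm computations live here as well: the landscape heterogeneity
index (LHI), a 45-degree rotation of the two standardized landscape
proportions, and region-median standardization used to remove systematic
between-region differences (e.g. sowing date shifts with latitude).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import DesignMatrix, FarmRecord, SchemaError, ValidationError, VariableSpec

__all__ = [
    "AggregationRule",
    "LandscapeInputs",
    "AggregationError",
    "load_rules",
    "default_rules",
    "aggregate_survey",
    "compute_lhi",
    "standardize_by_region_median",
    "build_design_matrix",
]

SIN_45 = math.sin(math.radians(45.0))  # sqrt(2)/2; a 45-degree axis rotation

METHODS = frozenset(
    {
        "identity",
        "proportion",
        "count_over_years",
        "ordinal_scale",
        "dummy",
        "index_formula",
        "mean_over_assessments",
    }
)


class AggregationError(ValueError):
    """A raw answer required by a rule is missing or unusable."""


@dataclass(frozen=True)
class AggregationRule:
    """How one schema variable is derived from raw survey answers.

    ``method`` semantics:

    identity
        the single input, optionally times ``parameters['scale']``.
    proportion
        ``inputs[0] / inputs[1]`` times ``parameters['scale']`` (default 100,
        i.e. a percentage).
    count_over_years
        sum of the inputs divided by ``parameters['years']`` (e.g. number of
        organic fertilizer applications over three seasons divided by 3).
    ordinal_scale
        categorical answer mapped through ``parameters['mapping']``.
    dummy
        1 if the answer is in ``parameters['true_values']`` else 0.
    index_formula
        cross-farm formula (currently only the LHI); handled by
        :func:`aggregate_survey` with pooled standardization statistics.
    mean_over_assessments
        arithmetic mean of the inputs (e.g. repeated weed-cover assessments).
    """

    target: str
    inputs: tuple[str, ...]
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise SchemaError(f"rule {self.target!r}: unknown method {self.method!r}")
        object.__setattr__(self, "inputs", tuple(self.inputs))

    def _get(self, raw: Mapping[str, Any], name: str, farm_id: str) -> Any:
        if name not in raw or raw[name] is None:
            raise AggregationError(
                f"farm {farm_id!r}: raw answer {name!r} required by rule "
                f"{self.target!r} is missing"
            )
        return raw[name]

    def apply(self, raw: Mapping[str, Any], farm_id: str = "?") -> float:
        vals = [self._get(raw, name, farm_id) for name in self.inputs]
        if self.method == "identity":
            return float(vals[0]) * float(self.parameters.get("scale", 1.0))
        if self.method == "proportion":
            denom = float(vals[1])
            if denom == 0:
                raise AggregationError(
                    f"farm {farm_id!r}: zero denominator in rule {self.target!r}"
                )
            return float(vals[0]) / denom * float(self.parameters.get("scale", 100.0))
        if self.method == "count_over_years":
            years = float(self.parameters["years"])
            return float(sum(float(v) for v in vals)) / years
        if self.method == "ordinal_scale":
            mapping = self.parameters["mapping"]
            answer = vals[0]
            if answer in mapping:
                return float(mapping[answer])
            if isinstance(answer, (int, float)) and float(answer) in {
                float(v) for v in mapping.values()
            }:
                return float(answer)  # already coded on the scale
            raise AggregationError(
                f"farm {farm_id!r}: answer {answer!r} not on the scale of rule "
                f"{self.target!r}"
            )
        if self.method == "dummy":
            true_values = set(self.parameters.get("true_values", [1, True, "yes"]))
            return 1.0 if vals[0] in true_values else 0.0
        if self.method == "mean_over_assessments":
            return float(np.mean([float(v) for v in vals]))
        raise AggregationError(f"rule {self.target!r}: method {self.method!r} "
                               "is cross-farm and cannot be applied per farm")


@dataclass
class LandscapeInputs:
    """One farm's landscape proportions plus the standardization statistics of
    the reference population (all analysed farms by default)."""

    prop_seminatural: float
    prop_field_border: float
    mean_seminatural: float
    sd_seminatural: float
    mean_field_border: float
    sd_field_border: float

    def z_scores(self) -> tuple[float, float]:
        if self.sd_seminatural <= 0 or self.sd_field_border <= 0:
            raise ValueError("degenerate standardization set: zero SD")
        return (
            (self.prop_seminatural - self.mean_seminatural) / self.sd_seminatural,
            (self.prop_field_border - self.mean_field_border) / self.sd_field_border,
        )


def compute_lhi(inputs: LandscapeInputs) -> float:
    """Landscape heterogeneity index: sin(45 deg) times the sum of the two
    standardized landscape proportions (semi-natural grassland and field
    border within 1 km of the field)."""
    z1, z2 = inputs.z_scores()
    return SIN_45 * (z1 + z2)


def standardize_by_region_median(values, regions) -> pd.Series:
    """Subtract the region median from each value, making every region's
    median exactly zero. No rescaling by spread is applied."""
    values = pd.Series(values, dtype=float).reset_index(drop=True)
    regions = pd.Series(list(regions)).reset_index(drop=True)
    if len(values) != len(regions):
        raise ValueError("values and region labels differ in length")
    out = values.copy()
    for region, idx in values.groupby(regions).groups.items():
        group = values.loc[idx]
        if group.empty:
            raise ValueError(f"empty region group {region!r}")
        out.loc[idx] = group - group.median()
    return out


def load_rules(path: str | Path) -> list[AggregationRule]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    rules = [
        AggregationRule(
            target=entry["target"],
            inputs=tuple(entry["inputs"]),
            method=entry["method"],
            parameters=dict(entry.get("parameters") or {}),
        )
        for entry in raw["rules"]
    ]
    targets = [r.target for r in rules]
    if len(set(targets)) != len(targets):
        raise SchemaError("duplicate rule targets")
    return rules


def default_rules() -> list[AggregationRule]:
    """The shipped rule set covering every non-soil variable of the default
    schema (29 rules)."""
    ref = importlib.resources.files("agropls") / "data" / "default_rules.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_rules(path)


def check_rule_coverage(rules: Sequence[AggregationRule], schema: Sequence[VariableSpec]) -> None:
    """Every non-soil schema variable must have exactly one rule."""
    targets = [r.target for r in rules]
    non_soil = [v.name for v in schema if v.level != "soil"]
    missing = [n for n in non_soil if targets.count(n) != 1]
    if missing:
        raise SchemaError(f"non-soil variables without exactly one rule: {missing}")


def aggregate_survey(
    raw: Mapping[str, Mapping[str, Any]],
    rules: Sequence[AggregationRule],
    lhi_pooled: bool = True,
) -> pd.DataFrame:
    """Apply the rule set to every farm's raw answers.

    ``raw`` maps farm_id to a mapping of raw answer name to value. Returns a
    DataFrame with one column per rule target (schema order of the rules).
    ``index_formula`` rules (the LHI) standardize their two proportion inputs
    over the pooled farm set (sample SD); per-region standardization can be
    selected with ``lhi_pooled=False``.
    """
    farm_ids = list(raw.keys())
    data: dict[str, list[float]] = {}
    index_rules = [r for r in rules if r.method == "index_formula"]
    for rule in rules:
        if rule.method == "index_formula":
            continue
        data[rule.target] = [rule.apply(raw[f], farm_id=f) for f in farm_ids]
    for rule in index_rules:
        p1_name, p2_name = rule.inputs
        p1 = np.array([rule._get(raw[f], p1_name, f) for f in farm_ids], dtype=float)
        p2 = np.array([rule._get(raw[f], p2_name, f) for f in farm_ids], dtype=float)
        if lhi_pooled:
            groups = [np.arange(len(farm_ids))]
        else:
            region_key = rule.parameters.get("region_key", "region")
            labels = np.array([str(raw[f].get(region_key, "")) for f in farm_ids])
            groups = [np.flatnonzero(labels == r) for r in np.unique(labels)]
        out = np.empty(len(farm_ids))
        for idx in groups:
            for arr in (p1, p2):
                if len(idx) > 1 and arr[idx].std(ddof=1) == 0:
                    raise ValueError(
                        f"rule {rule.target!r}: zero SD in standardization set"
                    )
            s1, s2 = p1[idx].std(ddof=1), p2[idx].std(ddof=1)
            out[idx] = [
                compute_lhi(
                    LandscapeInputs(
                        p1[i], p2[i], p1[idx].mean(), s1, p2[idx].mean(), s2
                    )
                )
                for i in idx
            ]
        data[rule.target] = list(out)
    df = pd.DataFrame(data, index=farm_ids)
    df.index.name = "farm_id"
    ordered = [r.target for r in rules]
    return df.loc[:, ordered]


def build_design_matrix(
    records: Sequence[FarmRecord], schema: Sequence[VariableSpec]
) -> DesignMatrix:
    """Assemble the analysis matrix from aggregated farm records, applying
    region-median standardization to the flagged variables (sowing date, soil
    clay content under the default schema)."""
    if not records:
        raise ValidationError("no farm records")
    farm_ids = [r.farm_id for r in records]
    regions = [r.region for r in records]
    cols = {}
    for spec in schema:
        try:
            vals = pd.Series([r.values[spec.name] for r in records],
                             index=farm_ids, dtype=float)
        except KeyError as exc:
            raise SchemaError(f"farm record missing variable {exc.args[0]!r}") from None
        if spec.region_standardized:
            vals = pd.Series(
                standardize_by_region_median(vals.to_numpy(), regions).to_numpy(),
                index=farm_ids,
            )
        cols[spec.name] = vals
    df = pd.DataFrame(cols, index=farm_ids)
    df.index.name = "farm_id"
    return DesignMatrix(df, list(schema))
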