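"""The nineteen-model analysis suite.

Besides the three primary farm groupings (Model 1: all farms; Model 2: organic
only; Model 3: conventional only), sixteen resampled subsets guard against the
organic/conventional imbalance: six balanced draws of 6 organic + 6
conventional farms per region (Models 4-9, n = 24) and ten draws of 6 organic
farms per region (Models 10-19, n = 12). Each subset runs the same
VIP-filter-and-refit workflow; replicate groups are summarised as mean +- SD of
the overall fit (R2Y cum) and prediction (Q2Y cum).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregation import build_design_matrix
from .datamodel import DesignMatrix, FarmRecord, ResponseMatrix, VariableSpec
from .model_selection import FitReport, VIPFilterPLS

__all__ = [
    "AnalysisConfig",
    "ModelSpec",
    "SuiteResult",
    "build_subsets",
    "run_suite",
    "predicted_vs_observed",
]

logger = logging.getLogger(__name__)

SUBSET_RULES = ("all", "organic_only", "conventional_only",
                "balanced_resample", "of_region_resample")

N_BALANCED = 6  # replicates of the balanced 6 OF + 6 CF per-region design
N_OF_REGION = 10  # replicates of the 6-OF-per-region design
PER_STRATUM = 6  # farms drawn per (region, type) stratum


@dataclass(frozen=True)
class AnalysisConfig:
    """Run configuration shared by all suite models."""

    k: int = 7
    q2_limit: float = 0.05
    vip_threshold: float = 1.0
    a_max: int | None = None
    scale_y: bool = True
    seed: int = 0


@dataclass(frozen=True)
class ModelSpec:
    """One suite member: its subset rule, replicate index, seed and the
    resolved farm identifiers."""

    label: str
    rule: str
    replicate: int
    seed: int
    farm_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.rule not in SUBSET_RULES:
            raise ValueError(f"unknown subset rule {self.rule!r}")


@dataclass
class SuiteResult:
    """All fitted reports plus the per-group resampling summaries."""

    reports: list[FitReport]
    summary: pd.DataFrame  # rows: resample groups; columns: mean/sd of R2Y, Q2Y

    def report(self, label: str) -> FitReport:
        for rep in self.reports:
            if rep.label == label:
                return rep
        raise KeyError(label)


def _model_seed(master: int, index: int) -> int:
    """Deterministic per-model seed below 2**31, derived so that adding models
    never perturbs earlier draws."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def build_subsets(farms: Sequence[FarmRecord], seed: int = 0) -> list[ModelSpec]:
    """Resolve the nineteen model subsets over the farm list.

    Resampling is stratified by (region, organic-vs-conventional), without
    replacement within stratum, seeded and reproducible. Raises when a
    required stratum has fewer than six farms.
    """
    regions = sorted({f.region for f in farms})
    if len(regions) != 2:
        raise ValueError(f"expected farms from exactly 2 regions, found {regions}")
    by_stratum: dict[tuple[str, str], list[str]] = {}
    for f in farms:
        group = "OF" if f.is_organic else "CF"
        by_stratum.setdefault((f.region, group), []).append(f.farm_id)
    for region in regions:
        for group in ("OF", "CF"):
            found = len(by_stratum.get((region, group), []))
            if found < PER_STRATUM:
                raise ValueError(
                    f"stratum ({region}, {group}) has {found} farms; "
                    f"need at least {PER_STRATUM}"
                )

    all_ids = tuple(f.farm_id for f in farms)
    of_ids = tuple(f.farm_id for f in farms if f.is_organic)
    cf_ids = tuple(f.farm_id for f in farms if not f.is_organic)

    specs = [
        ModelSpec("Model 1", "all", 0, _model_seed(seed, 1), all_ids),
        ModelSpec("Model 2", "organic_only", 0, _model_seed(seed, 2), of_ids),
        ModelSpec("Model 3", "conventional_only", 0, _model_seed(seed, 3), cf_ids),
    ]
    idx = 4
    for rep in range(N_BALANCED):
        s = _model_seed(seed, idx)
        rng = np.random.default_rng(s)
        ids: list[str] = []
        for region in regions:
            for group in ("OF", "CF"):
                pool = sorted(by_stratum[(region, group)])
                ids.extend(rng.choice(pool, size=PER_STRATUM, replace=False))
        specs.append(ModelSpec(f"Model {idx}", "balanced_resample", rep + 1, s, tuple(ids)))
        idx += 1
    for rep in range(N_OF_REGION):
        s = _model_seed(seed, idx)
        rng = np.random.default_rng(s)
        ids = []
        for region in regions:
            pool = sorted(by_stratum[(region, "OF")])
            ids.extend(rng.choice(pool, size=PER_STRATUM, replace=False))
        specs.append(ModelSpec(f"Model {idx}", "of_region_resample", rep + 1, s, tuple(ids)))
        idx += 1
    return specs


def _usable_columns(X: pd.DataFrame, k: int) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns that are constant on the subset or could become constant
    inside a cross-validation training fold (all non-modal rows fitting into
    one held-out fold). Typical casualties: dummies with a tiny minority class
    and structurally constant columns such as years-since-transition on the
    conventional-only subset."""
    n = len(X)
    max_fold = math.ceil(n / k)
    keep, dropped = [], []
    for col in X.columns:
        counts = X[col].value_counts()
        minority = n - int(counts.iloc[0])
        (keep if minority > max_fold else dropped).append(col)
    return X.loc[:, keep], dropped


def run_suite(
    farms: Sequence[FarmRecord],
    responses: ResponseMatrix,
    schema: Sequence[VariableSpec],
    config: AnalysisConfig = AnalysisConfig(),
) -> SuiteResult:
    """Fit the full nineteen-model suite.

    The design matrix is assembled (and region-standardized) once over all
    farms; each model subsets its rows. Fully reproducible under the master
    seed in ``config``.
    """
    dm = build_design_matrix(farms, schema)
    specs = build_subsets(farms, seed=config.seed)
    reports: list[FitReport] = []
    for spec in specs:
        X = dm.values.loc[list(spec.farm_ids)]
        Y = responses.values.loc[list(spec.farm_ids)]
        Xu, dropped = _usable_columns(X, config.k)
        try:
            est = VIPFilterPLS(
                vip_threshold=config.vip_threshold,
                k=config.k,
                q2_limit=config.q2_limit,
                a_max=config.a_max,
                scale_y=config.scale_y,
                random_state=spec.seed,
                label=spec.label,
            ).fit(Xu, Y)
        except Exception as exc:
            raise RuntimeError(f"{spec.label} ({spec.rule}) failed: {exc}") from exc
        rep = est.report_
        rep.dropped_constant = dropped
        logger.info(
            "%s (%s, n=%d): A=%d, retained %d variables, R2Y=%.3f, Q2Y=%.3f",
            spec.label, spec.rule, len(spec.farm_ids), rep.n_components,
            len(rep.retained), rep.r2y_overall, rep.q2y_overall,
        )
        logger.info("%s retained: %s", spec.label, ", ".join(rep.retained))
        reports.append(rep)

    rows = []
    groups = {
        "balanced_resample": [r for r, s in zip(reports, specs) if s.rule == "balanced_resample"],
        "of_region_resample": [r for r, s in zip(reports, specs) if s.rule == "of_region_resample"],
    }
    for name, reps in groups.items():
        r2 = np.array([r.r2y_overall for r in reps])
        q2 = np.array([r.q2y_overall for r in reps])
        rows.append(
            {
                "group": name,
                "n_models": len(reps),
                "r2y_mean": r2.mean(),
                "r2y_sd": r2.std(ddof=1),
                "q2y_mean": q2.mean(),
                "q2y_sd": q2.std(ddof=1),
            }
        )
    summary = pd.DataFrame(rows).set_index("group")
    return SuiteResult(reports=reports, summary=summary)


def predicted_vs_observed(reports: Sequence[FitReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (model, farm, response, observed, predicted) table plus the
    per-(model, response) squared correlation between observed and predicted
    values. Constant predictions score 0 by convention."""
    frames = []
    for rep in reports:
        if rep.predictions is None:
            continue
        df = rep.predictions.copy()
        df.insert(0, "model", rep.label)
        frames.append(df)
    if not frames:
        raise ValueError("no predictions available")
    table = pd.concat(frames, ignore_index=True)
    fit_rows = []
    for (model, resp), grp in table.groupby(["model", "response"], sort=False):
        obs, pred = grp["observed"].to_numpy(), grp["predicted"].to_numpy()
        if np.std(pred) == 0 or np.std(obs) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
        fit_rows.append({"model": model, "response": resp, "r2_linear": r2})
    return table, pd.DataFrame(fit_rows)
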