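"""Synthetic farm datasets with known latent ground truth.

The generator emulates the statistical structure the analysis assumes: a small
number of latent factors drive both a subset of the explanatory variables and
all crop performance indicators. Farms are stratified over two regions and
three types (conventional CF, young organic YOF, old organic OOF); organic
farms draw on a larger set of *active* explanatory variables than conventional
farms, reproducing the qualitative contrast that organic crop performance
depends on more factors.

For each farm i a latent score vector t_i is drawn i.i.d. standard normal with
a small additive region offset on the first factor. Active explanatory
variables carry the latent signal plus noise (signal-to-noise ratio
``snr_x``); inactive variables are pure unit-variance background noise. Each
latent propensity is then mapped into the variable's declared kind:
continuous/percentage/index values are affinely placed inside the schema range
and clipped, dummies threshold the propensity at a configurable quantile, and
ordinal scales bin it at equal-probability normal quantiles. Responses are
``y_m = loc_m + scale_m * (q_m . t + eps)`` with unit-norm response loadings
q_m and type-dependent noise, so the *designed* fraction of explainable
response variance is a closed form of the SNR (:func:`design_r2`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    RESPONSE_NAMES,
    FarmRecord,
    ResponseMatrix,
    VariableSpec,
    default_schema,
)

__all__ = ["SyntheticConfig", "GroundTruth", "generate_synthetic_farms", "design_r2"]


#: Plausible location/scale (in indicator units) used to map standardized
#: response signals into each barley performance indicator.
RESPONSE_UNITS_MAP = {
    "DM1": (2.0, 0.15),  # t/ha dry matter at stem elongation
    "N-Cut1": (3.0, 0.20),  # % N in early biomass
    "DM2": (8.0, 0.60),  # t/ha total dry matter at ripening
    "Grain-M": (4.5, 0.35),  # t/ha grain yield
    "Grain-N": (1.8, 0.12),  # % N in grain
    "Straw-N": (0.8, 0.05),  # % N in straw
    "Ears": (600.0, 40.0),  # ears per m2
}

#: Default response loadings (7 indicators x 2 latent factors), unit-norm rows.
_DEFAULT_Q0 = np.array(
    [
        [0.9, 0.1],
        [0.2, 0.8],
        [0.6, 0.3],
        [1.0, 0.2],
        [0.3, 0.9],
        [0.2, 0.7],
        [0.8, 0.1],
    ]
)
_DEFAULT_Q0 = _DEFAULT_Q0 / np.linalg.norm(_DEFAULT_Q0, axis=1, keepdims=True)

#: Default active explanatory variables: organic farm performance depends on
#: soil status, weed pressure, history and landscape; conventional farm
#: performance on current external inputs.
DEFAULT_ACTIVE_OF = (
    "SMN1", "Tot-C", "Tot-N", "Weed", "US-12", "TST", "LHI",
    "StdSd", "PC-leys", "SMR-L12", "OFe-AT12", "Freq-OFe",
)
DEFAULT_ACTIVE_CF = ("Min-N", "Min-N12", "PEST", "PEST-12")

#: Active set of the variable-recovery preset: five continuous variables
#: shared by both farm types.
RECOVERY_ACTIVE = ("SMN1", "Tot-C", "Weed", "Min-N12", "Size")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the generator.

    Defaults reproduce the default study layout: 34 farms, 17 per region,
    12 CF / 10 YOF / 12 OOF (22 organic), two latent factors, X signal-to-noise
    3, response SNR 3 on organic rows and 0.65 on conventional rows (so the
    designed explainable response variance is ~0.9 for organic and ~0.3 for
    conventional farms, mirroring the reported contrast in explained
    variation between the two systems).
    """

    n_cf_per_region: int = 6
    n_yof_per_region: int = 5
    n_oof_per_region: int = 6
    regions: tuple[str, str] = ("zone_A", "zone_B")
    n_latent: int = 2
    active_of: tuple[str, ...] = DEFAULT_ACTIVE_OF
    active_cf: tuple[str, ...] = DEFAULT_ACTIVE_CF
    snr_x: float = 3.0
    snr_y_of: float = 3.0
    snr_y_cf: float = 0.65
    region_effect: float = 0.5
    dummy_quantile: float = 0.5
    y_loadings: np.ndarray | None = None  # (m, A0); default pattern if None

    def active_for(self, farm_type: str) -> tuple[str, ...]:
        return self.active_cf if farm_type == "CF" else self.active_of

    def snr_y_for(self, farm_type: str) -> float:
        return self.snr_y_cf if farm_type == "CF" else self.snr_y_of

    @property
    def n_farms(self) -> int:
        return 2 * (self.n_cf_per_region + self.n_yof_per_region + self.n_oof_per_region)

    def noiseless(self) -> "SyntheticConfig":
        """Variant with no noise on the latent-to-response channel and none
        inside the active explanatory variables (inactive variables keep their
        background variation so no column is constant)."""
        return replace(self, snr_x=math.inf, snr_y_of=math.inf, snr_y_cf=math.inf)

    @staticmethod
    def recovery(snr: float = 3.0) -> "SyntheticConfig":
        """Preset for variable-recovery experiments: five designed active
        variables shared by both farm types, equal response SNR."""
        return SyntheticConfig(
            active_of=RECOVERY_ACTIVE,
            active_cf=RECOVERY_ACTIVE,
            snr_x=snr,
            snr_y_of=snr,
            snr_y_cf=snr,
        )


@dataclass
class GroundTruth:
    """What the generator knows and the analysis tries to recover."""

    scores: pd.DataFrame  # n x A0 latent scores
    x_loadings: pd.DataFrame  # p x A0 designed loadings (unit-norm rows)
    y_loadings: pd.DataFrame  # m x A0
    active_of: tuple[str, ...]
    active_cf: tuple[str, ...]
    design_r2_of: pd.Series
    design_r2_cf: pd.Series
    config: SyntheticConfig
    seed: int


def _latent_var(config: SyntheticConfig) -> np.ndarray:
    var = np.ones(config.n_latent)
    var[0] += config.region_effect**2 / 4.0
    return var


def _y_loadings(config: SyntheticConfig, m: int) -> np.ndarray:
    if config.y_loadings is not None:
        Q0 = np.asarray(config.y_loadings, dtype=float)
        if Q0.shape != (m, config.n_latent):
            raise ValueError(
                f"y_loadings shape {Q0.shape} inconsistent with ({m}, {config.n_latent})"
            )
        return Q0
    if config.n_latent == 2 and m == len(RESPONSE_NAMES):
        return _DEFAULT_Q0.copy()
    rng = np.random.default_rng(20120718)  # fixed: loadings are design, not noise
    Q0 = rng.normal(size=(m, config.n_latent))
    return Q0 / np.linalg.norm(Q0, axis=1, keepdims=True)


def _x_loadings(p: int, n_latent: int) -> np.ndarray:
    """Deterministic unit-norm loading directions for the explanatory
    variables: golden-angle spacing for two factors, a fixed draw otherwise.
    Independent of the simulation seed (the loadings are part of the design)."""
    if n_latent == 2:
        golden = (1 + math.sqrt(5)) / 2
        ang = 2 * math.pi * ((np.arange(p) * golden) % 1.0)
        return np.column_stack([np.cos(ang), np.sin(ang)])
    rng = np.random.default_rng(19870412)
    P0 = rng.normal(size=(p, n_latent))
    return P0 / np.linalg.norm(P0, axis=1, keepdims=True)


def design_r2(config: SyntheticConfig, farm_type: str = "OOF") -> pd.Series:
    """Designed per-response explainable variance fraction.

    For response m with unit-norm loadings q_m, latent variances v and noise
    SD 1/SNR: R2_m = (sum_a q_ma^2 v_a) / (sum_a q_ma^2 v_a + 1/SNR^2).
    """
    Q0 = _y_loadings(config, len(RESPONSE_NAMES))
    var = _latent_var(config)
    signal = (Q0**2) @ var
    snr = config.snr_y_for(farm_type)
    noise = 0.0 if math.isinf(snr) else 1.0 / snr**2
    return pd.Series(signal / (signal + noise), index=list(RESPONSE_NAMES))


def _map_to_kind(spec: VariableSpec, z: float, dummy_quantile: float) -> float:
    lo, hi = spec.valid_range if spec.valid_range is not None else (-4.0, 4.0)
    if spec.kind == "dummy":
        return 1.0 if z > stats.norm.ppf(dummy_quantile) else 0.0
    if spec.kind == "ordinal":
        levels = int(hi - lo) + 1
        edges = stats.norm.ppf(np.arange(1, levels) / levels)
        return float(lo + int(np.searchsorted(edges, z)))
    mid = (lo + hi) / 2.0
    sigma = (hi - lo) / 8.0  # clipping beyond +-4 sigma is negligible
    return float(np.clip(mid + sigma * z, lo, hi))


def _tst_value(farm_type: str, z: float) -> int:
    """Years since transition, consistent with the farm type: CF 0, YOF 1-5,
    OOF 11-26, monotone in the latent propensity for organic farms."""
    if farm_type == "CF":
        return 0
    if farm_type == "YOF":
        return int(np.clip(round(3 + 1.5 * z), 1, 5))
    return int(np.clip(round(18.5 + 4.0 * z), 11, 26))


def generate_synthetic_farms(
    config: SyntheticConfig = SyntheticConfig(),
    seed: int = 0,
    schema: list[VariableSpec] | None = None,
) -> tuple[list[FarmRecord], ResponseMatrix, GroundTruth]:
    """Generate a farm dataset with exported ground truth.

    Deterministic for a fixed ``(config, seed)``. Farm records carry raw
    (pre-standardization) variable values; assemble the analysis matrix with
    :func:`agropls.aggregation.build_design_matrix`.
    """
    if schema is None:
        schema = default_schema()
    names = [v.name for v in schema]
    unknown = [v for v in config.active_of + config.active_cf if v not in names]
    if unknown:
        raise ValueError(f"active variables not in schema: {sorted(set(unknown))}")
    if config.n_latent < 1:
        raise ValueError("need at least one latent factor")

    rng = np.random.default_rng(seed)
    p = len(schema)
    m = len(RESPONSE_NAMES)
    P0 = _x_loadings(p, config.n_latent)
    Q0 = _y_loadings(config, m)

    # farm roster: per region, CF / YOF / OOF blocks
    roster: list[tuple[str, str, str]] = []
    for ri, region in enumerate(config.regions):
        tag = chr(ord("A") + ri)
        counts = (
            ("CF", config.n_cf_per_region),
            ("YOF", config.n_yof_per_region),
            ("OOF", config.n_oof_per_region),
        )
        i = 1
        for ftype, cnt in counts:
            for _ in range(cnt):
                roster.append((f"{tag}{i:02d}", region, ftype))
                i += 1
    n = len(roster)

    # latent scores with a region offset on the first factor
    T0 = rng.normal(size=(n, config.n_latent))
    offs = np.array([+0.5 if r == config.regions[0] else -0.5 for _, r, _ in roster])
    T0[:, 0] += config.region_effect * offs

    x_noise_sd = 0.0 if math.isinf(config.snr_x) else 1.0 / config.snr_x

    records: list[FarmRecord] = []
    y_rows = np.zeros((n, m))
    for i, (farm_id, region, ftype) in enumerate(roster):
        active = set(config.active_for(ftype))
        values: dict[str, float] = {}
        tst: int | None = None
        for j, spec in enumerate(schema):
            if spec.name in active:
                z = float(P0[j] @ T0[i]) + rng.normal(scale=x_noise_sd)
            else:
                z = float(rng.normal())
            if spec.name == "TST":
                tst = _tst_value(ftype, z)
                values[spec.name] = float(tst)
            else:
                values[spec.name] = _map_to_kind(spec, z, config.dummy_quantile)
        if tst is None:
            # schema without an explicit transition-time variable: draw a
            # type-consistent value for the record metadata
            tst = _tst_value(ftype, float(rng.normal()))
        snr = config.snr_y_for(ftype)
        y_noise_sd = 0.0 if math.isinf(snr) else 1.0 / snr
        ys = Q0 @ T0[i] + rng.normal(scale=y_noise_sd, size=m) if y_noise_sd else Q0 @ T0[i]
        for k, resp in enumerate(RESPONSE_NAMES):
            loc, scale = RESPONSE_UNITS_MAP[resp]
            y_rows[i, k] = loc + scale * ys[k]
        records.append(
            FarmRecord(
                farm_id=farm_id,
                region=region,
                farm_type=ftype,
                years_since_transition=tst,
                values=values,
            )
        )
        records[-1].check_type_consistency()

    farm_ids = [r.farm_id for r in records]
    ydf = pd.DataFrame(y_rows, index=farm_ids, columns=list(RESPONSE_NAMES))
    ydf.index.name = "farm_id"
    responses = ResponseMatrix(ydf)
    truth = GroundTruth(
        scores=pd.DataFrame(T0, index=farm_ids,
                            columns=[f"t{a+1}" for a in range(config.n_latent)]),
        x_loadings=pd.DataFrame(P0, index=names,
                                columns=[f"t{a+1}" for a in range(config.n_latent)]),
        y_loadings=pd.DataFrame(Q0, index=list(RESPONSE_NAMES),
                                columns=[f"t{a+1}" for a in range(config.n_latent)]),
        active_of=tuple(config.active_of),
        active_cf=tuple(config.active_cf),
        design_r2_of=design_r2(config, "OOF"),
        design_r2_cf=design_r2(config, "CF"),
        config=config,
        seed=seed,
    )
    return records, responses, truth
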