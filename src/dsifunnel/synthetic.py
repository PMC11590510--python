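"""Synthetic multimodal memory-clinic cohorts.

Generates cohorts whose group-wise marginal distributions, group sizes,
sex ratios and missing-data rates emulate the published characteristics
of the published memory-clinic population (n = 883: 188 CN,
191 MCI, 302 AD, 107 FTD, 35 VaD, 60 DLB).  No joint covariance is
published, so dependence is induced by a Gaussian copula with a simple
block structure: one correlation within a modality, a weaker one across
modalities.

Two marginal families are supported:

* ``normal`` cells (printed as mean +/- SD) are drawn from a truncated
  normal whose *latent* location/scale are moment-matched so that the
  truncated distribution itself has the printed mean and SD — without
  this, bounded features with large SDs (e.g. WMH volume, trail-making
  times) would be visibly biased by the truncation.
* ``skewed`` cells (printed as median [IQR]) are drawn from a
  quantile-spliced two-piece normal that reproduces the printed median
  and both quartiles exactly.

cCOG has mixed provenance, as in the source population: a configurable
fraction of subjects (default 13%) get cCOG drawn directly from the
cCOG marginals ("measured"); everyone else gets cCOG simulated from the
neuropsychological equivalents by within-diagnosis percentile matching.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .cohort import (
    CcogSource,
    Cohort,
    DiagnosisLabel,
    FeatureDef,
    MISSING,
    Modality,
    PatientRecord,
    Sex,
    default_schema,
    is_missing,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MarginalSpec",
    "SyntheticSpec",
    "default_spec",
    "generate",
    "simulate_ccog_from_np",
    "summarize_by_group",
    "CCOG_NP_EQUIVALENTS",
]

_GROUPS = [
    DiagnosisLabel.CN,
    DiagnosisLabel.MCI,
    DiagnosisLabel.AD,
    DiagnosisLabel.FTD,
    DiagnosisLabel.VaD,
    DiagnosisLabel.DLB,
]

#: cCOG task -> neuropsychological equivalent used for simulation.
CCOG_NP_EQUIVALENTS = {
    "ccog_learning": "memory_learning",
    "ccog_recall": "memory_recall",
    "ccog_tmt_a": "tmt_a",
    "ccog_tmt_b": "tmt_b",
}


@dataclass(frozen=True)
class MarginalSpec:
    """One (feature, diagnosis group) marginal distribution.

    ``kind='normal'`` uses ``params=(mean, sd)``; ``kind='skewed'`` uses
    ``params=(median, q1, q3)``.  Truncation is the feature's valid
    range.
    """

    feature_id: str
    group: DiagnosisLabel
    kind: str  # "normal" | "skewed"
    params: tuple
    truncation: tuple = (None, None)

    def __post_init__(self):
        if self.kind == "normal":
            mean, sd = self.params
            if not sd > 0:
                raise ValueError(f"{self.feature_id}/{self.group}: sd must be > 0")
        elif self.kind == "skewed":
            median, q1, q3 = self.params
            if not (q1 <= median <= q3 and q1 < q3):
                raise ValueError(
                    f"{self.feature_id}/{self.group}: need q1 <= median <= q3, q1 < q3"
                )
        else:
            raise ValueError(f"unknown marginal kind {self.kind!r}")


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic cohort draw."""

    marginals: list[MarginalSpec]
    group_sizes: dict[DiagnosisLabel, int]
    sex_props: dict[DiagnosisLabel, float]  # fraction female per group
    age_params: dict[DiagnosisLabel, tuple]  # (mean, sd)
    missing_rates: dict[str, float]
    within_modality_rho: float = 0.3
    cross_modality_rho: float = 0.1
    ccog_measured_fraction: float = 0.13
    seed: int = 0
    schema: list[FeatureDef] = field(default_factory=default_schema)

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {g}")
        for fid, r in self.missing_rates.items():
            if not 0 <= r <= 1:
                raise ValueError(f"missing rate for {fid} outside [0,1]")
        for rho in (self.within_modality_rho, self.cross_modality_rho):
            if not 0 <= rho < 1:
                raise ValueError("correlations must lie in [0, 1)")

    def marginal(self, feature_id: str, group: DiagnosisLabel) -> Optional[MarginalSpec]:
        for m in self.marginals:
            if m.feature_id == feature_id and m.group == group:
                return m
        return None

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "seed": self.seed,
            "within_modality_rho": self.within_modality_rho,
            "cross_modality_rho": self.cross_modality_rho,
            "ccog_measured_fraction": self.ccog_measured_fraction,
            "group_sizes": {g.value: n for g, n in self.group_sizes.items()},
            "sex_props": {g.value: p for g, p in self.sex_props.items()},
            "age_params": {g.value: list(p) for g, p in self.age_params.items()},
            "missing_rates": dict(self.missing_rates),
            "marginals": [
                {
                    "feature_id": m.feature_id,
                    "group": m.group.value,
                    "kind": m.kind,
                    "params": list(m.params),
                }
                for m in self.marginals
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        schema = default_schema()
        ranges = {f.id: f.valid_range for f in schema}
        marginals = [
            MarginalSpec(
                m["feature_id"],
                DiagnosisLabel(m["group"]),
                m["kind"],
                tuple(m["params"]),
                truncation=(ranges[m["feature_id"]].lo, ranges[m["feature_id"]].hi),
            )
            for m in doc["marginals"]
        ]
        return cls(
            marginals=marginals,
            group_sizes={DiagnosisLabel(g): n for g, n in doc["group_sizes"].items()},
            sex_props={DiagnosisLabel(g): p for g, p in doc["sex_props"].items()},
            age_params={DiagnosisLabel(g): tuple(p) for g, p in doc["age_params"].items()},
            missing_rates=doc["missing_rates"],
            within_modality_rho=doc["within_modality_rho"],
            cross_modality_rho=doc["cross_modality_rho"],
            ccog_measured_fraction=doc["ccog_measured_fraction"],
            seed=doc["seed"],
            schema=schema,
        )

    def with_group_sizes(self, n_per_group: int) -> "SyntheticSpec":
        sizes = {g: n_per_group for g in self.group_sizes}
        return dataclasses.replace(self, group_sizes=sizes)


# ---------------------------------------------------------------------------
# Published group-wise characteristics (CN, MCI, AD, FTD, VaD, DLB order).
# mean/SD cells; None SD means the source printed "+/- NA" (tiny measured
# subgroup) and is filled with the across-group mean SD for that feature.
# ---------------------------------------------------------------------------

_NORMAL_CELLS: dict[str, list[tuple]] = {
    "ccog_learning": [(23, 8), (19, 4), (15, 5), (17, 6), (19, None), (15, 8)],
    "ccog_recall": [(9, 2), (6, 2), (4, 2), (7, 5), (8, None), (6, 3)],
    "ccog_tmt_a": [(48, 16), (65, 22), (77, 32), (163, 173), (63, None), (84, 35)],
    "ccog_tmt_b": [(171, 98), (231, 82), (322, 153), (153, None), (283, None), (246, 91)],
    "memory_learning": [(42, 9), (31, 8), (22, 8), (28, 8), (24, 8), (25, 9)],
    "memory_recall": [(9, 3), (4, 3), (2, 2), (4, 3), (3, 3), (4, 3)],
    "tmt_a": [(36, 14), (48, 19), (72, 39), (59, 30), (90, 37), (92, 38)],
    "tmt_b": [(85, 36), (133, 67), (191, 82), (161, 77), (224, 82), (218, 87)],
    "fluency": [(23, 6), (19, 5), (13, 6), (12, 7), (11, 5), (13, 6)],
    "gds": [(3, 3), (3, 3), (3, 2.3), (3, 3), (4, 3), (4, 3)],
    "npi": [(8, 10), (10, 11), (11, 10), (21, 17), (14, 9), (14, 12)],
    "cmta_left": [(0.35, 0.61), (0.94, 1.00), (1.53, 0.92), (2.07, 1.33), (1.79, 1.24), (1.08, 0.75)],
    "cmta_right": [(0.37, 0.58), (0.96, 0.99), (1.48, 0.93), (1.72, 1.27), (1.73, 1.10), (1.07, 0.85)],
    "cgca": [(0.51, 0.58), (0.80, 0.71), (1.30, 0.74), (1.37, 0.68), (1.70, 0.68), (1.19, 0.59)],
    "cfazekas": [(0.65, 0.66), (1.15, 0.93), (1.06, 0.80), (0.90, 0.81), (2.64, 0.53), (1.01, 0.75)],
    "wmh": [(3.71, 6.23), (10.58, 18.83), (8.29, 11.85), (6.36, 11.40), (50.54, 31.58), (6.08, 6.99)],
    "aps": [(0.35, 1.21), (0.01, 1.29), (0.30, 1.68), (-2.68, 2.39), (0.28, 1.52), (0.42, 1.37)],
    "ad_similarity": [(0.39, 0.10), (0.47, 0.12), (0.60, 0.11), (0.44, 0.12), (0.60, 0.10), (0.51, 0.10)],
    "abeta42": [(1034, 246), (830, 297), (617, 164), (1017, 266), (798, 215), (845, 249)],
    "ttau": [(284, 152), (446, 274), (717, 413), (383, 205), (302, 163), (311, 158)],
    "ptau": [(48, 18), (65, 32), (86, 38), (49, 22), (42, 20), (47, 21)],
}

_SKEWED_CELLS: dict[str, list[tuple]] = {
    "education": [(13, 10, 17), (12, 9, 14), (10, 9, 13), (10, 9, 13), (10, 9, 13), (10, 9, 13)],
    "mmse": [(29, 28, 30), (27, 25, 29), (23, 19, 25), (25, 23, 27), (26, 23, 27), (24, 22, 26)],
    "dad": [(100, 92, 100), (93, 86, 98), (88, 75, 96), (83, 63, 97), (70, 66, 83), (77, 60, 96)],
}

_GROUP_SIZES = {
    DiagnosisLabel.CN: 188,
    DiagnosisLabel.MCI: 191,
    DiagnosisLabel.AD: 302,
    DiagnosisLabel.FTD: 107,
    DiagnosisLabel.VaD: 35,
    DiagnosisLabel.DLB: 60,
}

_SEX_PROPS = {
    DiagnosisLabel.CN: 0.426,
    DiagnosisLabel.MCI: 0.366,
    DiagnosisLabel.AD: 0.540,
    DiagnosisLabel.FTD: 0.430,
    DiagnosisLabel.VaD: 0.314,
    DiagnosisLabel.DLB: 0.133,
}

_AGE_PARAMS = {
    DiagnosisLabel.CN: (61, 8),
    DiagnosisLabel.MCI: (66, 8),
    DiagnosisLabel.AD: (67, 7.8),
    DiagnosisLabel.FTD: (63, 7),
    DiagnosisLabel.VaD: (70, 8),
    DiagnosisLabel.DLB: (69, 8),
}

# non-missing N out of 883 per feature; cCOG is governed by the measured
# fraction mechanism instead and is omitted here.
_FEATURE_N = {
    "education": 836,
    "mmse": 879,
    "memory_learning": 839,
    "memory_recall": 839,
    "tmt_a": 861,
    "tmt_b": 710,
    "fluency": 855,
    "gds": 783,
    "npi": 706,
    "dad": 510,
    "cmta_left": 883,
    "cmta_right": 883,
    "cgca": 882,
    "cfazekas": 881,
    "wmh": 881,
    "aps": 883,
    "ad_similarity": 882,
    "abeta42": 883,
    "ttau": 883,
    "ptau": 883,
}


def default_spec(seed: int = 0) -> SyntheticSpec:
    """Spec embedding every published group-wise marginal cell."""
    schema = default_schema()
    ranges = {f.id: f.valid_range for f in schema}
    marginals: list[MarginalSpec] = []
    for fid, cells in _NORMAL_CELLS.items():
        known_sds = [sd for _, sd in cells if sd is not None]
        fallback_sd = float(np.mean(known_sds))
        for group, (mean, sd) in zip(_GROUPS, cells):
            marginals.append(
                MarginalSpec(
                    fid,
                    group,
                    "normal",
                    (float(mean), float(sd if sd is not None else fallback_sd)),
                    truncation=(ranges[fid].lo, ranges[fid].hi),
                )
            )
    for fid, cells in _SKEWED_CELLS.items():
        for group, (median, q1, q3) in zip(_GROUPS, cells):
            marginals.append(
                MarginalSpec(
                    fid,
                    group,
                    "skewed",
                    (float(median), float(q1), float(q3)),
                    truncation=(ranges[fid].lo, ranges[fid].hi),
                )
            )
    missing_rates = {fid: 1.0 - n / 883.0 for fid, n in _FEATURE_N.items()}
    return SyntheticSpec(
        marginals=marginals,
        group_sizes=dict(_GROUP_SIZES),
        sex_props=dict(_SEX_PROPS),
        age_params=dict(_AGE_PARAMS),
        missing_rates=missing_rates,
        seed=seed,
        schema=schema,
    )


# ---------------------------------------------------------------------------
# marginal transforms
# ---------------------------------------------------------------------------

_Z_QUARTILE = stats.norm.ppf(0.75)  # 0.6744897...
_moment_match_cache: dict[tuple, tuple] = {}


def _matched_truncnorm_params(mean: float, sd: float, lo, hi) -> tuple:
    """Latent (mu, sigma, a, b) so truncnorm has the requested mean/SD.

    Returns the identity parametrization when the bounds are effectively
    inactive (> 8 sigma away).  Some published cells are infeasible for
    a truncated normal (e.g. coefficient of variation > 1 with a lower
    bound at 0); there the mean alone is matched — always possible,
    since the truncated mean is strictly increasing in the latent mu —
    and the SD comes as close as the family permits.
    """
    lo_f = -math.inf if lo is None else float(lo)
    hi_f = math.inf if hi is None else float(hi)
    key = (round(mean, 10), round(sd, 10), lo_f, hi_f)
    if key in _moment_match_cache:
        return _moment_match_cache[key]
    if (mean - lo_f) > 8 * sd and (hi_f - mean) > 8 * sd:
        out = (mean, sd, (lo_f - mean) / sd, (hi_f - mean) / sd)
        _moment_match_cache[key] = out
        return out

    def residual(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a, b = (lo_f - mu) / sigma, (hi_f - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(residual, x0=[mean, math.log(sd)], method="hybr")
    if sol.success and max(abs(r) for r in residual(sol.x)) < 1e-6 * max(1.0, sd):
        mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    else:
        # two-moment solve infeasible or non-convergent: match the mean
        # exactly with sigma fixed at the printed SD
        logger.info(
            "cell mean=%s sd=%s on [%s, %s] not two-moment matchable; "
            "matching the mean only", mean, sd, lo_f, hi_f,
        )

        def mean_residual(mu_x: float) -> float:
            a, b = (lo_f - mu_x) / sd, (hi_f - mu_x) / sd
            return float(stats.truncnorm.mean(a, b, loc=mu_x, scale=sd)) - mean

        span = 8 * sd + (0.0 if not math.isfinite(hi_f - lo_f) else (hi_f - lo_f))
        lo_mu, hi_mu = mean - span, mean + span
        while mean_residual(lo_mu) > 0:
            lo_mu -= span
        while mean_residual(hi_mu) < 0:
            hi_mu += span
        mu = float(optimize.brentq(mean_residual, lo_mu, hi_mu, xtol=1e-10))
        sigma = sd
    out = (mu, sigma, (lo_f - mu) / sigma, (hi_f - mu) / sigma)
    _moment_match_cache[key] = out
    return out


def _marginal_ppf(m: MarginalSpec, u: np.ndarray) -> np.ndarray:
    """Map copula uniforms through the cell's marginal distribution."""
    lo, hi = m.truncation
    if m.kind == "normal":
        mean, sd = m.params
        mu, sigma, a, b = _matched_truncnorm_params(mean, sd, lo, hi)
        return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
    median, q1, q3 = m.params
    sigma_low = (median - q1) / _Z_QUARTILE
    sigma_high = (q3 - median) / _Z_QUARTILE
    z = stats.norm.ppf(u)
    x = np.where(z < 0, median + sigma_low * z, median + sigma_high * z)
    lo_f = -np.inf if lo is None else lo
    hi_f = np.inf if hi is None else hi
    return np.clip(x, lo_f, hi_f)


def _block_correlation(schema: list[FeatureDef], feature_ids: list[str],
                       rho_within: float, rho_cross: float) -> np.ndarray:
    modality = {f.id: f.modality for f in schema}
    k = len(feature_ids)
    corr = np.full((k, k), rho_cross)
    for i, fi in enumerate(feature_ids):
        for j, fj in enumerate(feature_ids):
            if modality[fi] is modality[fj]:
                corr[i, j] = rho_within
        corr[i, i] = 1.0
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 1e-10:
        raise ValueError(
            "copula correlation matrix is not positive definite "
            f"(min eigenvalue {eigvals.min():.3g}); reduce the block correlations"
        )
    return corr


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate(spec: SyntheticSpec) -> Cohort:
    """Draw a full synthetic cohort; deterministic given ``spec.seed``.

    Per diagnosis group: correlated latent normals through the Gaussian
    copula, mapped through each feature's marginal; integer-valued
    scales (MMSE, GDS) rounded; completely-at-random missingness masks;
    sex Bernoulli; age from the group's normal.  A
    ``ccog_measured_fraction`` subset is labeled ``measured`` on the
    cCOG source and the rest ``simulated``, emulating the original
    cohort's composition; all cCOG values come from the calibrated
    marginals (so every published cell is recovered), and
    :func:`simulate_ccog_from_np` remains available as the explicit
    NP-to-cCOG imputation operation.
    """
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema
    feature_ids = [f.id for f in schema]
    integer_ids = {f.id for f in schema if f.integer_valued}
    corr = _block_correlation(schema, feature_ids,
                              spec.within_modality_rho, spec.cross_modality_rho)
    chol = np.linalg.cholesky(corr)

    records: list[PatientRecord] = []
    counter = 0
    for group in _GROUPS:
        n = spec.group_sizes.get(group, 0)
        if n == 0:
            continue
        z = rng.standard_normal((n, len(feature_ids))) @ chol.T
        u = stats.norm.cdf(z)
        # clamp away from 0/1 so ppf never returns +/-inf
        u = np.clip(u, 1e-12, 1 - 1e-12)
        values = np.empty_like(u)
        for j, fid in enumerate(feature_ids):
            m = spec.marginal(fid, group)
            if m is None:
                values[:, j] = MISSING
                continue
            col = _marginal_ppf(m, u[:, j])
            if fid in integer_ids:
                col = np.rint(col)
            values[:, j] = col
        age_mean, age_sd = spec.age_params[group]
        ages = np.clip(rng.normal(age_mean, age_sd, size=n), 30, 105)
        female = rng.random(n) < spec.sex_props[group]
        measured = rng.random(n) < spec.ccog_measured_fraction
        # completely-at-random missingness
        mask = np.zeros_like(values, dtype=bool)
        for j, fid in enumerate(feature_ids):
            rate = spec.missing_rates.get(fid, 0.0)
            if rate > 0:
                mask[:, j] = rng.random(n) < rate
        for i in range(n):
            counter += 1
            feats = {}
            for j, fid in enumerate(feature_ids):
                feats[fid] = MISSING if mask[i, j] else float(values[i, j])
            records.append(
                PatientRecord(
                    id=f"P{counter:04d}",
                    diagnosis=group,
                    age=float(np.round(ages[i], 1)),
                    sex=Sex.female if female[i] else Sex.male,
                    features=feats,
                    ccog_source=CcogSource.measured if measured[i] else CcogSource.simulated,
                )
            )
    return Cohort(schema, records)


# ---------------------------------------------------------------------------
# cCOG simulation from NP equivalents
# ---------------------------------------------------------------------------


def _midrank_percentile(sorted_vals: np.ndarray, x: float) -> float:
    n = len(sorted_vals)
    lo = np.searchsorted(sorted_vals, x, side="left")
    hi = np.searchsorted(sorted_vals, x, side="right")
    return (lo + hi) / (2.0 * n)


def simulate_ccog_from_np(record: PatientRecord, reference: Cohort,
                          min_group_pairs: int = 5) -> PatientRecord:
    """Fill missing cCOG tasks from NP equivalents by percentile matching.

    Each NP value's within-diagnosis empirical percentile in the
    reference is mapped to the same percentile of the matching cCOG
    task's reference distribution.  Groups with fewer than
    ``min_group_pairs`` reference records carrying both variables fall
    back to the pooled reference.  Measured cCOG values are never
    overwritten; the returned record has ``ccog_source='simulated'``
    only if at least one task was filled.
    """
    pairs_total = 0
    for ccog_id, np_id in CCOG_NP_EQUIVALENTS.items():
        pairs_total += sum(1 for r in reference if r.has(ccog_id) and r.has(np_id))
    if len(reference) < 30 or pairs_total == 0:
        raise ValueError(
            "reference cohort must contain >= 30 records with paired cCOG/NP data"
        )
    out = record.copy()
    filled_any = False
    for ccog_id, np_id in CCOG_NP_EQUIVALENTS.items():
        if out.has(ccog_id) or not out.has(np_id):
            continue
        group_ref = [
            r for r in reference
            if r.diagnosis is record.diagnosis and r.has(ccog_id) and r.has(np_id)
        ]
        if len(group_ref) < min_group_pairs:
            group_ref = [r for r in reference if r.has(ccog_id) and r.has(np_id)]
        if len(group_ref) < 2:
            continue
        np_vals = np.sort([r.get(np_id) for r in group_ref])
        ccog_vals = np.sort([r.get(ccog_id) for r in group_ref])
        pct = _midrank_percentile(np_vals, out.get(np_id))
        out.features[ccog_id] = float(np.quantile(ccog_vals, np.clip(pct, 0, 1)))
        filled_any = True
    if filled_any:
        out.ccog_source = CcogSource.simulated
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_by_group(cohort: Cohort) -> pd.DataFrame:
    """Per-(group, feature) n, mean, sd, median and quartiles.

    ``n`` counts non-missing values only; sd is MISSING for n < 2.
    """
    rows = []
    for group in _GROUPS:
        members = [r for r in cohort if r.diagnosis is group]
        if not members:
            continue
        for f in cohort.schema:
            vals = np.array([r.get(f.id) for r in members], dtype=float)
            vals = vals[~np.isnan(vals)]
            n = len(vals)
            rows.append(
                {
                    "group": group.value,
                    "feature": f.id,
                    "n": n,
                    "mean": float(np.mean(vals)) if n else MISSING,
                    "sd": float(np.std(vals, ddof=1)) if n >= 2 else MISSING,
                    "median": float(np.median(vals)) if n else MISSING,
                    "q1": float(np.quantile(vals, 0.25)) if n else MISSING,
                    "q3": float(np.quantile(vals, 0.75)) if n else MISSING,
                }
            )
    return pd.DataFrame(rows)
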