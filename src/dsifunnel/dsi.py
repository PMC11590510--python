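"""Disease state index (DSI) classifier.

The DSI compares one diagnostic group against another.  Each feature
value is mapped to a *fitness* in [0, 1] — the evidence that the value
came from the positive group, computed from the two groups' empirical
training distributions — and fitnesses are combined through a small
weighted tree (feature -> modality -> root), where every weight is a
*relevance*: the feature's (or node's) maximal Youden index J =
max_t (sensitivity + specificity - 1) on the training set.  The root
value is the DSI: ~1 means the positive group fits best, ~0.5 means
the feature carries no evidence either way.

Properties of this construction:

* **rank-based**: fitness and relevance depend on the data only through
  ranks (midrank empirical CDFs), so any strictly increasing transform
  of a feature leaves every DSI unchanged;
* **missing-data tolerant**: absent features simply drop out of the
  weighted means; a record with no observed feature yields an explicit
  indeterminate result (``None``), never a silent 0.5;
* **symmetric**: swapping the positive and negative groups maps every
  DSI x to 1 - x (when covariate normalization, which is fitted on the
  negative/control group, is disabled or applied identically).

Before fitting, features are normalized for age and sex by linear
residualization against the control (negative) group, so that group
contrasts are not driven by demographic imbalance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    DiagnosisLabel,
    MISSING,
    Modality,
    PatientRecord,
    Sex,
    is_missing,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitnessEstimator",
    "Relevance",
    "CovariateNormalizer",
    "DsiModel",
    "normalize_covariates",
    "fit_fitness",
    "fitness",
    "fit_relevance",
    "train_pairwise",
    "dsi",
    "dsi_batch",
    "multiclass_dsi",
    "predict_class",
    "DEFAULT_CLASS_ORDER",
]

MODEL_FORMAT_VERSION = 1

#: fixed tie-break order for multiclass prediction
DEFAULT_CLASS_ORDER = (
    DiagnosisLabel.AD,
    DiagnosisLabel.FTD,
    DiagnosisLabel.VaD,
    DiagnosisLabel.DLB,
)


# ---------------------------------------------------------------------------
# empirical CDF helpers (midrank convention: ties counted half)
# ---------------------------------------------------------------------------


def _ecdf(sorted_vals: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Midrank empirical CDF of ``sorted_vals`` evaluated at ``x``.

    F(x) = (#{v < x} + 0.5 * #{v == x}) / n.  Rank-based, hence exactly
    invariant under strictly increasing transforms applied jointly to
    the sample and the evaluation points.
    """
    lo = np.searchsorted(sorted_vals, x, side="left")
    hi = np.searchsorted(sorted_vals, x, side="right")
    return (lo + hi) / (2.0 * len(sorted_vals))


def _ecdf_below(sorted_vals: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Strict-below empirical CDF: #{v < x} / n."""
    return np.searchsorted(sorted_vals, x, side="left") / len(sorted_vals)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------


@dataclass
class FitnessEstimator:
    """Per-feature evidence map built from two training distributions."""

    feature_id: str
    pos_sorted: np.ndarray
    neg_sorted: np.ndarray
    direction: str  # "pos_high" | "pos_low"

    def __post_init__(self):
        self.pos_sorted = np.asarray(self.pos_sorted, dtype=float)
        self.neg_sorted = np.asarray(self.neg_sorted, dtype=float)
        if len(self.pos_sorted) < 2 or len(self.neg_sorted) < 2:
            raise ValueError(
                f"{self.feature_id}: need >= 2 finite training values per group"
            )

    def __call__(self, x) -> np.ndarray:
        """Vectorized fitness; see :func:`fitness`."""
        x = np.asarray(x, dtype=float)
        f_pos = _ecdf(self.pos_sorted, x)
        f_neg = _ecdf(self.neg_sorted, x)
        if self.direction == "pos_high":
            fnr, fpr = f_pos, 1.0 - f_neg
        else:
            fnr, fpr = 1.0 - f_pos, f_neg
        total = fnr + fpr
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(total > 0, fnr / np.where(total > 0, total, 1.0), 0.5)
        return np.where(np.isnan(x), np.nan, out)


def fit_fitness(pos_values: Sequence[float], neg_values: Sequence[float],
                feature_id: str = "") -> FitnessEstimator:
    """Build a fitness estimator; direction inferred from the medians.

    ``pos_high`` iff median(pos) >= median(neg) (ties default to
    pos_high).
    """
    pos = np.sort(np.asarray(pos_values, dtype=float))
    neg = np.sort(np.asarray(neg_values, dtype=float))
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(f"{feature_id or 'feature'}: need >= 2 finite values per group")
    direction = "pos_high" if np.median(pos) >= np.median(neg) else "pos_low"
    return FitnessEstimator(feature_id, pos, neg, direction)


def fitness(est: FitnessEstimator, x: float) -> float:
    """Evidence in [0,1] that ``x`` came from the positive group.

    With FNR(x) = fraction of positive training values on the negative
    side of x and FPR(x) = fraction of negative training values on the
    positive side, returns FNR / (FNR + FPR); 0.5 when both are zero
    (no training mass on the wrong side of x in either group).
    """
    return float(est(np.asarray([x]))[0])


# ---------------------------------------------------------------------------
# relevance (maximal Youden index)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Relevance:
    feature_id: str
    value: float

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("relevance must lie in [0, 1]")


def _max_youden(pos: np.ndarray, neg: np.ndarray) -> float:
    """Maximal J = sens + spec - 1 over midpoint thresholds, floored at 0.

    The scanning direction is fixed by the medians, matching the
    fitness direction convention.
    """
    pos = np.sort(pos[~np.isnan(pos)])
    neg = np.sort(neg[~np.isnan(neg)])
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 values per group")
    pooled = np.sort(np.concatenate([pos, neg]))
    candidates = (pooled[:-1] + pooled[1:]) / 2.0
    f_pos = _ecdf_below(pos, candidates)
    f_neg = _ecdf_below(neg, candidates)
    if np.median(pos) >= np.median(neg):  # positive class in the upper tail
        j = f_neg - f_pos
    else:
        j = f_pos - f_neg
    return float(max(0.0, j.max())) if len(j) else 0.0


def fit_relevance(pos_values: Sequence[float], neg_values: Sequence[float],
                  feature_id: str = "") -> Relevance:
    """Discriminative weight of a feature: its maximal Youden index."""
    return Relevance(
        feature_id,
        _max_youden(np.asarray(pos_values, dtype=float),
                    np.asarray(neg_values, dtype=float)),
    )


# ---------------------------------------------------------------------------
# covariate normalization
# ---------------------------------------------------------------------------


def _sex_code(sex: Sex) -> float:
    return 1.0 if sex is Sex.female else 0.0


@dataclass
class CovariateNormalizer:
    """Linear age/sex residualization, anchored at the control mean.

    For each feature, fits ``value ~ 1 + age + sex`` on the control
    records and replaces each value by ``value - (fitted - control
    mean)``.  Features with fewer than 3 control observations, or a
    degenerate design, pass through unchanged (zero slopes).
    """

    # feature id -> (b0, b_age, b_sex, control_mean)
    coefficients: dict[str, tuple] = field(default_factory=dict)

    @classmethod
    def fit(cls, controls: Sequence[PatientRecord], feature_ids: Iterable[str]) -> "CovariateNormalizer":
        controls = list(controls)
        if not controls:
            raise ValueError("need a non-empty control set")
        ages = np.array([r.age for r in controls], dtype=float)
        sexes = np.array([_sex_code(r.sex) for r in controls], dtype=float)
        coefs: dict[str, tuple] = {}
        for fid in feature_ids:
            y = np.array([r.get(fid) for r in controls], dtype=float)
            obs = ~np.isnan(y)
            if obs.sum() < 3 or np.ptp(y[obs]) == 0:
                coefs[fid] = (0.0, 0.0, 0.0, 0.0)  # identity
                continue
            design = np.column_stack([np.ones(obs.sum()), ages[obs], sexes[obs]])
            beta, *_ = np.linalg.lstsq(design, y[obs], rcond=None)
            coefs[fid] = (float(beta[0]), float(beta[1]), float(beta[2]),
                          float(y[obs].mean()))
        return cls(coefs)

    def adjust(self, fid: str, value, age, sex_code):
        b0, ba, bs, cmean = self.coefficients.get(fid, (0.0, 0.0, 0.0, 0.0))
        fitted = b0 + ba * np.asarray(age, dtype=float) + bs * np.asarray(sex_code, dtype=float)
        return np.asarray(value, dtype=float) - (fitted - cmean)

    def transform_record(self, record: PatientRecord) -> PatientRecord:
        out = record.copy()
        sc = _sex_code(record.sex)
        for fid, v in out.features.items():
            if fid in self.coefficients and not is_missing(v):
                out.features[fid] = float(self.adjust(fid, v, record.age, sc))
        return out


def normalize_covariates(cohort: Cohort, training_controls: Cohort) -> Cohort:
    """Residualize every feature for age and sex against the controls.

    Returns a new cohort; missing values stay missing.  Range checks are
    not re-applied: residualized values live on a shifted scale.
    """
    norm = CovariateNormalizer.fit(list(training_controls),
                                   [f.id for f in cohort.schema])
    out = Cohort.__new__(Cohort)  # skip range validation on residual scale
    out.schema = cohort.schema
    out.records = [norm.transform_record(r) for r in cohort.records]
    return out


# ---------------------------------------------------------------------------
# the trained model
# ---------------------------------------------------------------------------


@dataclass
class DsiModel:
    """Trained pairwise DSI classifier.

    Combination tree: feature leaves grouped by modality, modalities
    combined at the root; a relevance sits at every node.  A node whose
    observed children all carry zero relevance falls back to their
    unweighted mean (rather than an undefined 0/0).
    """

    pos_labels: frozenset
    neg_labels: frozenset
    features: list[str]
    estimators: dict[str, FitnessEstimator]
    relevances: dict[str, float]
    modality_of: dict[str, str]
    node_relevance: dict[str, float]
    normalizer: Optional[CovariateNormalizer] = None
    dropped_features: list[str] = field(default_factory=list)
    version: int = MODEL_FORMAT_VERSION

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "pos_labels": sorted(l.value for l in self.pos_labels),
            "neg_labels": sorted(l.value for l in self.neg_labels),
            "features": list(self.features),
            "estimators": {
                fid: {
                    "pos_sorted": est.pos_sorted.tolist(),
                    "neg_sorted": est.neg_sorted.tolist(),
                    "direction": est.direction,
                }
                for fid, est in self.estimators.items()
            },
            "relevances": dict(self.relevances),
            "modality_of": dict(self.modality_of),
            "node_relevance": dict(self.node_relevance),
            "normalizer": None if self.normalizer is None else {
                fid: list(c) for fid, c in self.normalizer.coefficients.items()
            },
            "dropped_features": list(self.dropped_features),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "DsiModel":
        if doc.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('version')!r}")
        estimators = {
            fid: FitnessEstimator(fid, np.asarray(e["pos_sorted"]),
                                  np.asarray(e["neg_sorted"]), e["direction"])
            for fid, e in doc["estimators"].items()
        }
        normalizer = None
        if doc["normalizer"] is not None:
            normalizer = CovariateNormalizer(
                {fid: tuple(c) for fid, c in doc["normalizer"].items()}
            )
        return cls(
            pos_labels=frozenset(DiagnosisLabel(l) for l in doc["pos_labels"]),
            neg_labels=frozenset(DiagnosisLabel(l) for l in doc["neg_labels"]),
            features=list(doc["features"]),
            estimators=estimators,
            relevances=dict(doc["relevances"]),
            modality_of=dict(doc["modality_of"]),
            node_relevance=dict(doc["node_relevance"]),
            normalizer=normalizer,
            dropped_features=list(doc.get("dropped_features", [])),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "DsiModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _combine(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Relevance-weighted mean over observed children, per row.

    ``values`` is (n, k) with NaN for unobserved; rows with no observed
    child yield NaN; rows whose observed children all have zero weight
    fall back to the unweighted mean.
    """
    obs = ~np.isnan(values)
    w = np.where(obs, weights[np.newaxis, :], 0.0)
    wsum = w.sum(axis=1)
    vsum = np.nansum(values * w, axis=1)
    count = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0),
                       np.nansum(values, axis=1) / np.where(count > 0, count, 1.0))
    return np.where(count > 0, out, np.nan)


def _leaf_fitness_matrix(model: "DsiModel", X: pd.DataFrame,
                         feature_subset: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    feats = [f for f in model.features if f in set(feature_subset)]
    n = len(X)
    F = np.full((n, len(feats)), np.nan)
    age = X["age"].to_numpy(dtype=float)
    sexc = X["sex_code"].to_numpy(dtype=float)
    for j, fid in enumerate(feats):
        vals = X[fid].to_numpy(dtype=float)
        if model.normalizer is not None:
            vals = model.normalizer.adjust(fid, vals, age, sexc)
        obs = ~np.isnan(vals)
        if obs.any():
            F[obs, j] = model.estimators[fid](vals[obs])
    return F, feats


def _frame(records: Sequence[PatientRecord], feature_ids: Sequence[str]) -> pd.DataFrame:
    data = {
        "age": [r.age for r in records],
        "sex_code": [_sex_code(r.sex) for r in records],
    }
    for fid in feature_ids:
        data[fid] = [r.get(fid) for r in records]
    return pd.DataFrame(data, index=[r.id for r in records])


def train_pairwise(cohort: Cohort,
                   pos_labels: Iterable[DiagnosisLabel],
                   neg_labels: Iterable[DiagnosisLabel],
                   features: Optional[Sequence[str]] = None,
                   normalize: bool = True) -> DsiModel:
    """Train a pairwise DSI model (positive group vs negative group).

    Covariates are residualized against the negative (control) group;
    per-feature fitness and relevance are fitted on observed values
    only; features observed in fewer than 2 records in either group are
    dropped with a warning.  Modality-node relevances are the Youden
    indices of the node values themselves over the training set.
    """
    pos_labels = frozenset(pos_labels)
    neg_labels = frozenset(neg_labels)
    if pos_labels & neg_labels:
        raise ValueError("positive and negative label sets overlap")
    features = list(features) if features is not None else [f.id for f in cohort.schema]
    modality_of = {f.id: f.modality.value for f in cohort.schema}

    pos_recs = [r for r in cohort if r.diagnosis in pos_labels]
    neg_recs = [r for r in cohort if r.diagnosis in neg_labels]
    for name, recs in (("positive", pos_recs), ("negative", neg_recs)):
        usable = [r for r in recs if any(r.has(f) for f in features)]
        if len(usable) < 5:
            raise ValueError(
                f"{name} group needs >= 5 records with at least one observed feature"
            )

    normalizer = CovariateNormalizer.fit(neg_recs, features) if normalize else None

    def observed(recs, fid):
        vals = np.array([r.get(fid) for r in recs], dtype=float)
        if normalizer is not None:
            ages = np.array([r.age for r in recs], dtype=float)
            sexc = np.array([_sex_code(r.sex) for r in recs], dtype=float)
            vals = normalizer.adjust(fid, vals, ages, sexc)
        return vals[~np.isnan(vals)]

    estimators: dict[str, FitnessEstimator] = {}
    relevances: dict[str, float] = {}
    kept: list[str] = []
    dropped: list[str] = []
    for fid in features:
        pv, nv = observed(pos_recs, fid), observed(neg_recs, fid)
        if len(pv) < 2 or len(nv) < 2:
            dropped.append(fid)
            logger.warning("feature %s observed in < 2 records per group; dropped", fid)
            continue
        estimators[fid] = fit_fitness(pv, nv, fid)
        relevances[fid] = fit_relevance(pv, nv, fid).value
        kept.append(fid)
    if not kept:
        raise ValueError("no feature has >= 2 observed values in both groups")

    model = DsiModel(
        pos_labels=pos_labels,
        neg_labels=neg_labels,
        features=kept,
        estimators=estimators,
        relevances=relevances,
        modality_of={f: modality_of[f] for f in kept},
        node_relevance={},
        normalizer=normalizer,
        dropped_features=dropped,
    )

    # modality-node relevance: Youden index of the node's own value
    train_recs = pos_recs + neg_recs
    X = _frame(train_recs, kept)
    F, feats = _leaf_fitness_matrix(model, X, kept)
    is_pos = np.array([r.diagnosis in pos_labels for r in train_recs])
    node_rel: dict[str, float] = {}
    for mod in sorted({model.modality_of[f] for f in kept}):
        idx = [j for j, f in enumerate(feats) if model.modality_of[f] == mod]
        w = np.array([relevances[feats[j]] for j in idx])
        node_vals = _combine(F[:, idx], w)
        pv = node_vals[is_pos]
        nv = node_vals[~is_pos]
        pv, nv = pv[~np.isnan(pv)], nv[~np.isnan(nv)]
        if len(pv) < 2 or len(nv) < 2:
            node_rel[mod] = 0.0
            logger.warning("modality node %s has < 2 observed node values per group", mod)
        else:
            node_rel[mod] = _max_youden(pv, nv)
    model.node_relevance = node_rel
    return model


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def dsi_batch(model: DsiModel, records: Sequence[PatientRecord],
              feature_subset: Optional[Sequence[str]] = None) -> np.ndarray:
    """DSI for many records at once; NaN marks indeterminate results."""
    subset = list(feature_subset) if feature_subset is not None else model.features
    unknown = set(subset) - set(model.features) - set(model.dropped_features)
    if unknown:
        raise ValueError(f"features not in model: {sorted(unknown)}")
    X = _frame(records, [f for f in subset if f in model.features])
    F, feats = _leaf_fitness_matrix(model, X, subset)
    if not feats:
        return np.full(len(records), np.nan)
    mods = sorted({model.modality_of[f] for f in feats})
    node_vals = np.full((len(records), len(mods)), np.nan)
    for k, mod in enumerate(mods):
        idx = [j for j, f in enumerate(feats) if model.modality_of[f] == mod]
        w = np.array([model.relevances[feats[j]] for j in idx])
        node_vals[:, k] = _combine(F[:, idx], w)
    node_w = np.array([model.node_relevance.get(m, 0.0) for m in mods])
    return _combine(node_vals, node_w)


def dsi(model: DsiModel, record: PatientRecord,
        feature_subset: Optional[Sequence[str]] = None) -> Optional[float]:
    """Root DSI in [0,1] for one record, or ``None`` if indeterminate.

    Observed leaf fitnesses are combined bottom-up by relevance-weighted
    means; masking a feature is exactly equivalent to removing it from
    the subset.
    """
    out = dsi_batch(model, [record], feature_subset)[0]
    return None if np.isnan(out) else float(out)


def multiclass_dsi(models: Mapping[tuple, DsiModel],
                   record: PatientRecord,
                   classes: Sequence[DiagnosisLabel],
                   feature_subset: Optional[Sequence[str]] = None) -> dict:
    """One-vs-each averaged DSI per class.

    ``models`` maps ordered pairs ``(pos, neg)`` to pairwise models; a
    single model per unordered pair suffices — the reverse orientation
    is obtained as 1 - DSI.  The score of class c is the mean of its
    oriented pairwise DSIs against every other class; indeterminate
    pairwise values are excluded from the mean, and a class with no
    determinate pairwise DSI gets ``None``.
    """
    scores: dict = {}
    for c in classes:
        vals = []
        for other in classes:
            if other == c:
                continue
            if (c, other) in models:
                v = dsi(models[(c, other)], record, feature_subset)
            elif (other, c) in models:
                v = dsi(models[(other, c)], record, feature_subset)
                v = None if v is None else 1.0 - v
            else:
                raise KeyError(f"no model for pair ({c}, {other})")
            if v is not None:
                vals.append(v)
        scores[c] = float(np.mean(vals)) if vals else None
    return scores


def predict_class(scores: Mapping[DiagnosisLabel, Optional[float]],
                  class_order: Sequence[DiagnosisLabel] = DEFAULT_CLASS_ORDER) -> DiagnosisLabel:
    """Argmax class; exact ties broken by the fixed class order."""
    determinate = {c: s for c, s in scores.items() if s is not None}
    if not determinate:
        raise ValueError("all class scores are indeterminate")
    best = max(determinate.values())
    winners = [c for c in class_order if determinate.get(c) == best]
    winners += [c for c in determinate if determinate[c] == best and c not in winners]
    if len([c for c in determinate if determinate[c] == best]) > 1:
        logger.warning("exact tie among %s; choosing %s by fixed order",
                       [c.value for c, s in determinate.items() if s == best],
                       winners[0].value)
    return winners[0]
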