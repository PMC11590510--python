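"""Repeated stratified k-fold cross-validation with out-of-fold DSI scores.

The protocol: tenfold cross-validation repeated with ten different
test/train divisions; each subject appears in exactly one test set and
nine training sets per repeat; the per-patient out-of-fold values are
averaged across repeats to give the final DSI.

Training (covariate normalization, fitness, relevance, node weights)
sees only the nine training folds of each split — the held-out fold
never influences the fitted model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, DiagnosisLabel, PatientRecord
from .dsi import DsiModel, dsi_batch, train_pairwise

logger = logging.getLogger(__name__)

__all__ = [
    "CvPlan",
    "PairwiseTask",
    "MulticlassTask",
    "OofScores",
    "make_folds",
    "run_cv",
]


@dataclass(frozen=True)
class CvPlan:
    n_folds: int = 10
    n_repeats: int = 10
    base_seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def repeat_seed(self, repeat_index: int) -> int:
        return self.base_seed + repeat_index


@dataclass(frozen=True)
class PairwiseTask:
    """Training recipe: one pairwise model, scored on named feature subsets."""

    name: str
    pos: frozenset
    neg: frozenset
    subsets: dict  # subset name -> list of feature ids
    normalize: bool = True

    def all_features(self) -> list[str]:
        seen: list[str] = []
        for feats in self.subsets.values():
            for f in feats:
                if f not in seen:
                    seen.append(f)
        return seen


@dataclass(frozen=True)
class MulticlassTask:
    """One model per unordered class pair, each scored on named subsets."""

    name: str
    classes: tuple
    subsets: dict
    normalize: bool = True

    def all_features(self) -> list[str]:
        seen: list[str] = []
        for feats in self.subsets.values():
            for f in feats:
                if f not in seen:
                    seen.append(f)
        return seen

    def pairs(self) -> list[tuple]:
        return [
            (self.classes[i], self.classes[j])
            for i in range(len(self.classes))
            for j in range(i + 1, len(self.classes))
        ]


@dataclass
class OofScores:
    """Out-of-fold DSI values, per repeat and averaged.

    ``per_repeat`` columns: id, repeat, subset, cls, dsi (NaN =
    indeterminate).  ``cls`` is ``"pairwise"`` for pairwise tasks, a
    class label for multiclass tasks.
    """

    task_name: str
    per_repeat: pd.DataFrame
    n_repeats: int
    model_hashes: dict = field(default_factory=dict)  # (repeat, fold) -> hash(es)

    def averaged(self) -> pd.DataFrame:
        """Per-patient mean across repeats; indeterminates excluded from
        the mean, all-indeterminate stays NaN."""
        return (
            self.per_repeat.groupby(["id", "subset", "cls"], sort=False)["dsi"]
            .mean()
            .unstack(["subset", "cls"])
        )

    def pairwise_series(self, subset: str) -> pd.Series:
        avg = self.averaged()
        return avg[(subset, "pairwise")]

    def class_frame(self, subset: str) -> pd.DataFrame:
        """Per-patient averaged score per class for one subset."""
        avg = self.averaged()
        return avg[subset]

    def write_tsv(self, per_repeat_path, averaged_path) -> None:
        self.per_repeat.to_csv(per_repeat_path, sep="\t", index=False)
        avg = self.averaged()
        avg.columns = [f"{s}:{c}" for s, c in avg.columns]
        avg.to_csv(averaged_path, sep="\t")


def make_folds(cohort: Cohort, plan: CvPlan, repeat_index: int) -> list[list[str]]:
    """Disjoint, exhaustive partition of patient ids into n_folds sets.

    Deterministic given (base_seed, repeat_index).  With
    ``plan.stratify``, each diagnosis label is spread across folds as
    evenly as possible (round-robin from a random offset); strata
    smaller than n_folds are allowed and logged.
    """
    if len(cohort) == 0:
        raise ValueError("cannot fold an empty cohort")
    rng = np.random.default_rng(plan.repeat_seed(repeat_index))
    folds: list[list[str]] = [[] for _ in range(plan.n_folds)]
    if not plan.stratify:
        ids = [r.id for r in cohort]
        order = rng.permutation(len(ids))
        for k, idx in enumerate(order):
            folds[k % plan.n_folds].append(ids[idx])
        return folds
    for label in DiagnosisLabel:
        members = [r.id for r in cohort if r.diagnosis is label]
        if not members:
            continue
        if len(members) < plan.n_folds:
            logger.info("stratum %s has %d members for %d folds",
                        label.value, len(members), plan.n_folds)
        order = rng.permutation(len(members))
        offset = int(rng.integers(plan.n_folds))
        for k, idx in enumerate(order):
            folds[(offset + k) % plan.n_folds].append(members[idx])
    return folds


def _fit_task(task, train_records: Sequence[PatientRecord], schema) -> dict:
    """Fit the task's model(s) on training records only."""
    train_cohort = Cohort(schema, list(train_records))
    if isinstance(task, PairwiseTask):
        model = train_pairwise(train_cohort, task.pos, task.neg,
                               features=task.all_features(),
                               normalize=task.normalize)
        return {"pairwise": model}
    models: dict = {}
    for a, b in task.pairs():
        models[(a, b)] = train_pairwise(train_cohort, {a}, {b},
                                        features=task.all_features(),
                                        normalize=task.normalize)
    return models


def _score_records(task, models: dict, records: Sequence[PatientRecord]) -> list[dict]:
    rows: list[dict] = []
    ids = [r.id for r in records]
    if isinstance(task, PairwiseTask):
        model: DsiModel = models["pairwise"]
        for subset_name, feats in task.subsets.items():
            vals = dsi_batch(model, records, feats)
            rows.extend(
                {"id": pid, "subset": subset_name, "cls": "pairwise", "dsi": v}
                for pid, v in zip(ids, vals)
            )
        return rows
    # multiclass: one-vs-each averaged per class
    for subset_name, feats in task.subsets.items():
        per_class_vals = {}
        for (a, b), model in models.items():
            per_class_vals[(a, b)] = dsi_batch(model, records, feats)
        for c in task.classes:
            acc = np.zeros(len(records))
            cnt = np.zeros(len(records))
            for (a, b), vals in per_class_vals.items():
                if c == a:
                    oriented = vals
                elif c == b:
                    oriented = 1.0 - vals
                else:
                    continue
                obs = ~np.isnan(oriented)
                acc[obs] += oriented[obs]
                cnt[obs] += 1
            with np.errstate(invalid="ignore", divide="ignore"):
                score = np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1), np.nan)
            rows.extend(
                {"id": pid, "subset": subset_name, "cls": c.value, "dsi": v}
                for pid, v in zip(ids, score)
            )
    return rows


def run_cv(cohort: Cohort, task, plan: CvPlan,
           collect_hashes: bool = False) -> OofScores:
    """Out-of-fold DSI for every patient under the repeated-CV protocol.

    Models are fitted on the task's label groups within the nine
    training folds; *all* records of the held-out fold are scored
    (including labels outside the training groups, e.g. MCI under a
    CN-vs-dementia classifier).  Per-patient final values are the means
    of the per-repeat out-of-fold values.
    """
    by_id = {r.id: r for r in cohort}
    all_rows: list[dict] = []
    hashes: dict = {}
    for rep in range(plan.n_repeats):
        folds = make_folds(cohort, plan, rep)
        for k, fold_ids in enumerate(folds):
            test_set = set(fold_ids)
            train_records = [r for r in cohort if r.id not in test_set]
            try:
                models = _fit_task(task, train_records, cohort.schema)
            except Exception as exc:
                raise RuntimeError(
                    f"training failed for task {task.name!r} "
                    f"(repeat {rep}, fold {k}): {exc}"
                ) from exc
            if collect_hashes:
                if isinstance(task, PairwiseTask):
                    hashes[(rep, k)] = models["pairwise"].content_hash()
                else:
                    hashes[(rep, k)] = {
                        f"{a.value}|{b.value}": m.content_hash()
                        for (a, b), m in models.items()
                    }
            test_records = [by_id[i] for i in fold_ids]
            for row in _score_records(task, models, test_records):
                row["repeat"] = rep
                all_rows.append(row)
    frame = pd.DataFrame(all_rows, columns=["id", "repeat", "subset", "cls", "dsi"])
    return OofScores(task.name, frame, plan.n_repeats, hashes)
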