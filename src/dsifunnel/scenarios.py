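"""Stepwise diagnostic scenarios: ordered tests, DSI bands, stop rules.

Three clinical scenarios are built in:

* **1A / 1B — syndrome diagnosis** (CN / MCI / dementia) over the full
  cohort with a CN-vs-dementia pairwise classifier.  1A is the base
  case (NP only, cutoffs 0.3/0.7); 1B adds the digital cCOG screen as a
  prescreening step (cutoffs 0.1/0.95, then 0.3/0.7).  MRI is a
  resource-only follow-up for non-CN outcomes: it is counted in tests
  consumed but never changes the syndrome label.
* **2 — etiological diagnosis** (AD / FTD / VaD / DLB) over CN +
  dementia patients (MCI excluded).  Step 1 screens CN out with the
  pairwise classifier (cutoff 0.25); steps 2 (MRI) and 3 (CSF) use the
  one-vs-each averaged multiclass DSI with a 0.6 decision cutoff; a
  still-indeterminate patient after CSF ends with "no diagnosis".
* **3 — DMT eligibility** over the full cohort, amyloid status as the
  gold standard.  cCOG (cutoff 0.1) and NP (0.3) screen out CN; after
  MRI an AD-vs-other pairwise DSI (cutoff 0.1) with a multiclass
  side-condition (another etiology > ``other_etiology_cut``) selects
  patients for confirmatory CSF testing.

Band endpoints follow the published operators exactly: middle bands are
closed, and each scenario uses <= where <= is printed and < where < is
printed; the bands always tile [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, DEMENTIA_LABELS, DiagnosisLabel, Modality, default_schema
from .crossval import CvPlan, MulticlassTask, OofScores, PairwiseTask, run_cv
from .dsi import DEFAULT_CLASS_ORDER, predict_class

__all__ = [
    "Action",
    "Band",
    "StepRule",
    "ScenarioConfig",
    "ClassifierSpec",
    "TrajectoryResult",
    "FunnelSummary",
    "ScenarioScores",
    "builtin_config",
    "compute_cv_scores",
    "run_stepwise",
    "funnel_counts",
    "trajectories_frame",
    "SCENARIO_IDS",
    "NO_DIAGNOSIS",
    "ELIGIBLE",
    "NOT_ELIGIBLE",
]

SCENARIO_IDS = ("1A", "1B", "2", "3")

NO_DIAGNOSIS = "no diagnosis"
ELIGIBLE = "eligible"
NOT_ELIGIBLE = "not eligible"

ETIOLOGY_CLASSES = DEFAULT_CLASS_ORDER  # AD, FTD, VaD, DLB


@dataclass(frozen=True)
class Action:
    """What a DSI band means: stop with an outcome, or continue."""

    kind: str  # "stop" | "continue"
    outcome: Optional[str] = None  # label / eligibility string when stopping
    extra_tests: tuple = ()  # resource-only tests triggered by this action

    def __post_init__(self):
        if self.kind not in ("stop", "continue"):
            raise ValueError(f"unknown action kind {self.kind!r}")
        if self.kind == "stop" and self.outcome is None:
            raise ValueError("stop action needs an outcome")


@dataclass(frozen=True)
class Band:
    """Interval over [0,1]; open flags control endpoint membership."""

    lo: float
    hi: float
    action: Action
    lo_open: bool = False
    hi_open: bool = False

    def contains(self, x: float) -> bool:
        above = x > self.lo if self.lo_open else x >= self.lo
        below = x < self.hi if self.hi_open else x <= self.hi
        return above and below


def _check_tiling(bands: Sequence[Band]) -> None:
    """Bands must exactly tile [0,1] without overlap."""
    bands = sorted(bands, key=lambda b: (b.lo, b.hi))
    if not bands:
        raise ValueError("no bands")
    first, last = bands[0], bands[-1]
    if first.lo != 0.0 or first.lo_open or last.hi != 1.0 or last.hi_open:
        raise ValueError("bands must cover [0,1] with closed outer endpoints")
    for a, b in zip(bands, bands[1:]):
        if a.hi != b.lo:
            raise ValueError(f"gap/overlap between bands at {a.hi} vs {b.lo}")
        if a.hi_open == (not b.lo_open):
            pass
        else:
            raise ValueError(f"boundary {a.hi} covered {'twice' if not a.hi_open else 'never'}")


@dataclass(frozen=True)
class StepRule:
    """One diagnostic step: tests performed, classifier, decision rule.

    ``kind``:
      * ``pairwise_bands`` — apply ``bands`` to a pairwise DSI;
      * ``multiclass_threshold`` — stop with the argmax class when the
        best one-vs-each score exceeds ``cutoff``;
      * ``ad_eligibility`` — AD-vs-other pairwise DSI + multiclass
        side-condition, always terminal.
    """

    name: str
    kind: str
    tests: tuple
    classifier: str
    subset: str
    bands: tuple = ()
    cutoff: float = math.nan
    side_classifier: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind == "pairwise_bands":
            _check_tiling(self.bands)
        elif self.kind == "multiclass_threshold":
            if not 0 < self.cutoff < 1:
                raise ValueError("cutoff must lie in (0,1)")
        elif self.kind != "ad_eligibility":
            raise ValueError(f"unknown step kind {self.kind!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    """Training recipe for one classifier used by a scenario."""

    kind: str  # "pairwise" | "multiclass"
    subsets: dict  # subset name -> feature ids
    pos: frozenset = frozenset()
    neg: frozenset = frozenset()
    classes: tuple = ()


@dataclass(frozen=True)
class ScenarioConfig:
    scenario_id: str
    included: frozenset  # diagnosis labels admitted to the scenario
    steps: tuple
    classifiers: dict

    def __post_init__(self):
        if not self.steps:
            raise ValueError("scenario needs at least one step")


@dataclass
class TrajectoryResult:
    """One patient's walk through the funnel."""

    patient_id: str
    step_scores: dict  # step name -> float | {label: float} | None
    stop_step: str
    outcome: str
    tests: tuple  # tests consumed, in order


@dataclass
class FunnelSummary:
    steps: pd.DataFrame  # per-step entered/stopped/continued counts+fractions
    tests: pd.DataFrame  # per-test consumption counts+fractions
    n: int


# ---------------------------------------------------------------------------
# built-in configurations (published threshold rules)
# ---------------------------------------------------------------------------


def _modality_features(*modalities: Modality) -> list[str]:
    wanted = set(modalities)
    return [f.id for f in default_schema() if f.modality in wanted]


# "NP" as a diagnostic step is the full cognitive/functional battery:
# neuropsychological tests, neuropsychiatric scales, DAD, and education.
_CCOG = _modality_features(Modality.CCOG)
_NP = _modality_features(Modality.NP, Modality.NEUROPSYCH, Modality.FUNC, Modality.DEMOG)
_MRI = _modality_features(Modality.MRI)
_CSF = _modality_features(Modality.CSF)

_CN_DEM = ClassifierSpec(
    kind="pairwise",
    pos=frozenset(DEMENTIA_LABELS),
    neg=frozenset({DiagnosisLabel.CN}),
    subsets={},  # filled per scenario
)


def _stop(outcome: str, *extra: str) -> Action:
    return Action("stop", outcome, tuple(extra))


_CONTINUE = Action("continue")


def builtin_config(scenario_id: str, thresholds: Optional[Mapping[str, float]] = None) -> ScenarioConfig:
    """The published scenario rules, with overridable thresholds.

    Recognized threshold keys per scenario —
    1A: ``cn_cut`` (0.3), ``dem_cut`` (0.7);
    1B: ``prescreen_low`` (0.1), ``prescreen_high`` (0.95), ``cn_cut``, ``dem_cut``;
    2:  ``cn_cut`` (0.25), ``etiology_cut`` (0.6);
    3:  ``step1_cut`` (0.1), ``step2_cut`` (0.3), ``ad_cut`` (0.1),
        ``other_etiology_cut`` (0.85; the published text prints 0.85 for
        exclusion but 0.8 for inclusion — a single configurable cut is
        used here).
    """
    sid = str(scenario_id).upper()
    t = dict(thresholds or {})

    def get(key: str, default: float) -> float:
        v = float(t.pop(key, default))
        if not 0 < v < 1:
            raise ValueError(f"threshold {key}={v} outside (0,1)")
        return v

    if sid == "1A":
        cn, dem = get("cn_cut", 0.3), get("dem_cut", 0.7)
        if not cn < dem:
            raise ValueError("cn_cut must be below dem_cut")
        steps = (
            StepRule(
                name="np", kind="pairwise_bands", tests=("NP",),
                classifier="cn_dem", subset="np",
                bands=(
                    Band(0.0, cn, _stop("CN"), hi_open=True),
                    Band(cn, dem, _stop("MCI", "MRI")),
                    Band(dem, 1.0, _stop("DEM", "MRI"), lo_open=True),
                ),
            ),
        )
        classifiers = {"cn_dem": replace(_CN_DEM, subsets={"np": list(_NP)})}
        return ScenarioConfig(sid, frozenset(DiagnosisLabel), steps, classifiers)

    if sid == "1B":
        low, high = get("prescreen_low", 0.1), get("prescreen_high", 0.95)
        cn, dem = get("cn_cut", 0.3), get("dem_cut", 0.7)
        if not (low < high and cn < dem):
            raise ValueError("bands out of order")
        steps = (
            StepRule(
                name="ccog", kind="pairwise_bands", tests=("cCOG",),
                classifier="cn_dem", subset="ccog",
                bands=(
                    Band(0.0, low, _stop("CN"), hi_open=True),
                    Band(low, high, _CONTINUE),
                    Band(high, 1.0, _stop("DEM", "MRI"), lo_open=True),
                ),
            ),
            StepRule(
                name="ccog_np", kind="pairwise_bands", tests=("NP",),
                classifier="cn_dem", subset="ccog_np",
                bands=(
                    Band(0.0, cn, _stop("CN"), hi_open=True),
                    Band(cn, dem, _stop("MCI", "MRI")),
                    Band(dem, 1.0, _stop("DEM", "MRI"), lo_open=True),
                ),
            ),
        )
        classifiers = {
            "cn_dem": replace(_CN_DEM, subsets={
                "ccog": list(_CCOG),
                "ccog_np": list(_CCOG) + list(_NP),
            })
        }
        return ScenarioConfig(sid, frozenset(DiagnosisLabel), steps, classifiers)

    if sid == "2":
        cn = get("cn_cut", 0.25)
        cut = get("etiology_cut", 0.6)
        steps = (
            StepRule(
                name="cognitive", kind="pairwise_bands", tests=("cCOG", "NP"),
                classifier="cn_dem", subset="cognitive",
                bands=(
                    Band(0.0, cn, _stop("CN")),  # <= cn, as printed
                    Band(cn, 1.0, _CONTINUE, lo_open=True),
                ),
            ),
            StepRule(
                name="mri", kind="multiclass_threshold", tests=("MRI",),
                classifier="etiology", subset="mri", cutoff=cut,
            ),
            StepRule(
                name="csf", kind="multiclass_threshold", tests=("CSF",),
                classifier="etiology", subset="csf", cutoff=cut,
            ),
        )
        cognitive = list(_CCOG) + list(_NP)
        classifiers = {
            "cn_dem": replace(_CN_DEM, subsets={"cognitive": cognitive}),
            "etiology": ClassifierSpec(
                kind="multiclass", classes=tuple(ETIOLOGY_CLASSES),
                subsets={
                    "mri": cognitive + list(_MRI),
                    "csf": cognitive + list(_MRI) + list(_CSF),
                },
            ),
        }
        included = frozenset({DiagnosisLabel.CN}) | DEMENTIA_LABELS
        return ScenarioConfig(sid, included, steps, classifiers)

    if sid == "3":
        s1, s2 = get("step1_cut", 0.1), get("step2_cut", 0.3)
        ad_cut = get("ad_cut", 0.1)
        other_cut = get("other_etiology_cut", 0.85)
        steps = (
            StepRule(
                name="ccog", kind="pairwise_bands", tests=("cCOG",),
                classifier="cn_dem", subset="ccog",
                bands=(
                    Band(0.0, s1, _stop(NOT_ELIGIBLE)),  # <= 0.1, as printed
                    Band(s1, 1.0, _CONTINUE, lo_open=True),
                ),
            ),
            StepRule(
                name="np", kind="pairwise_bands", tests=("NP",),
                classifier="cn_dem", subset="ccog_np",
                bands=(
                    Band(0.0, s2, _stop(NOT_ELIGIBLE)),
                    Band(s2, 1.0, _CONTINUE, lo_open=True),
                ),
            ),
            StepRule(
                name="mri", kind="ad_eligibility", tests=("MRI",),
                classifier="ad_other", subset="mri",
                side_classifier="etiology",
                params={"ad_cut": ad_cut, "other_etiology_cut": other_cut},
            ),
        )
        ccog_np = list(_CCOG) + list(_NP)
        mri_set = ccog_np + list(_MRI)
        classifiers = {
            "cn_dem": replace(_CN_DEM, subsets={
                "ccog": list(_CCOG), "ccog_np": ccog_np,
            }),
            "ad_other": ClassifierSpec(
                kind="pairwise",
                pos=frozenset({DiagnosisLabel.AD}),
                neg=frozenset({DiagnosisLabel.FTD, DiagnosisLabel.VaD, DiagnosisLabel.DLB}),
                subsets={"mri": mri_set},
            ),
            "etiology": ClassifierSpec(
                kind="multiclass", classes=tuple(ETIOLOGY_CLASSES),
                subsets={"mri": mri_set},
            ),
        }
        return ScenarioConfig(sid, frozenset(DiagnosisLabel), steps, classifiers)

    raise ValueError(f"unknown scenario id {scenario_id!r}; expected one of {SCENARIO_IDS}")


# ---------------------------------------------------------------------------
# score provider
# ---------------------------------------------------------------------------


class ScenarioScores:
    """Per-step DSI source backed by cross-validated out-of-fold scores."""

    def __init__(self, oof: Mapping[str, OofScores]):
        self._oof = dict(oof)
        self._pair_cache: dict = {}
        self._class_cache: dict = {}

    def pairwise(self, classifier: str, subset: str, patient_id: str) -> Optional[float]:
        key = (classifier, subset)
        if key not in self._pair_cache:
            self._pair_cache[key] = self._oof[classifier].pairwise_series(subset)
        try:
            v = self._pair_cache[key][patient_id]
        except KeyError as exc:
            raise KeyError(
                f"no {classifier}/{subset} score for patient {patient_id!r}"
            ) from exc
        return None if pd.isna(v) else float(v)

    def multiclass(self, classifier: str, subset: str, patient_id: str) -> dict:
        key = (classifier, subset)
        if key not in self._class_cache:
            self._class_cache[key] = self._oof[classifier].class_frame(subset)
        try:
            row = self._class_cache[key].loc[patient_id]
        except KeyError as exc:
            raise KeyError(
                f"no {classifier}/{subset} scores for patient {patient_id!r}"
            ) from exc
        return {
            DiagnosisLabel(c): (None if pd.isna(v) else float(v))
            for c, v in row.items()
        }


def compute_cv_scores(cohort: Cohort, config: ScenarioConfig, plan: CvPlan,
                      collect_hashes: bool = False) -> ScenarioScores:
    """Run the repeated-CV protocol for every classifier a scenario needs."""
    oof: dict[str, OofScores] = {}
    for cid, spec in config.classifiers.items():
        if spec.kind == "pairwise":
            task = PairwiseTask(cid, spec.pos, spec.neg, dict(spec.subsets))
        else:
            task = MulticlassTask(cid, tuple(spec.classes), dict(spec.subsets))
        oof[cid] = run_cv(cohort, task, plan, collect_hashes=collect_hashes)
    return ScenarioScores(oof)


# ---------------------------------------------------------------------------
# the walk
# ---------------------------------------------------------------------------


def _apply_step(step: StepRule, scores: ScenarioScores, pid: str,
                is_last: bool) -> tuple[object, Action]:
    """Evaluate one step; returns (recorded score, action)."""
    if step.kind == "pairwise_bands":
        x = scores.pairwise(step.classifier, step.subset, pid)
        if x is None:
            return None, (_stop(NO_DIAGNOSIS) if is_last else _CONTINUE)
        matching = [b for b in step.bands if b.contains(x)]
        if len(matching) != 1:
            raise RuntimeError(f"step {step.name}: {len(matching)} bands match DSI {x}")
        return x, matching[0].action

    if step.kind == "multiclass_threshold":
        cls_scores = scores.multiclass(step.classifier, step.subset, pid)
        determinate = {c: v for c, v in cls_scores.items() if v is not None}
        if not determinate:
            return cls_scores, (_stop(NO_DIAGNOSIS) if is_last else _CONTINUE)
        best = max(determinate.values())
        if best > step.cutoff:
            label = predict_class(cls_scores)
            return cls_scores, _stop(label.value)
        return cls_scores, (_stop(NO_DIAGNOSIS) if is_last else _CONTINUE)

    # ad_eligibility: terminal decision for confirmatory CSF selection
    ad = scores.pairwise(step.classifier, step.subset, pid)
    others = scores.multiclass(step.side_classifier, step.subset, pid)
    other_vals = [v for c, v in others.items()
                  if c is not DiagnosisLabel.AD and v is not None]
    max_other = max(other_vals) if other_vals else None
    ad_cut = step.params["ad_cut"]
    other_cut = step.params["other_etiology_cut"]
    recorded = {"ad_other": ad, "max_other_etiology": max_other}
    if ad is None:
        return recorded, _stop(NOT_ELIGIBLE)
    if ad < ad_cut and max_other is not None and max_other > other_cut:
        return recorded, _stop(NOT_ELIGIBLE)
    if ad > ad_cut:
        return recorded, _stop(ELIGIBLE, "CSF")  # confirmatory CSF testing
    return recorded, _stop(NOT_ELIGIBLE)


def run_stepwise(cohort: Cohort, config: ScenarioConfig,
                 scores: ScenarioScores) -> list[TrajectoryResult]:
    """Walk every patient through the scenario until a terminal band.

    Tests consumed accumulate the tests of every visited step plus any
    resource-rule additions (e.g. MRI after a non-CN syndrome outcome).
    Raises if the cohort contains diagnoses the scenario excludes.
    """
    outside = sorted({r.diagnosis.value for r in cohort if r.diagnosis not in config.included})
    if outside:
        raise ValueError(
            f"scenario {config.scenario_id} excludes diagnoses {outside}; "
            "filter the cohort first (e.g. cohort.with_labels(config.included))"
        )
    results: list[TrajectoryResult] = []
    last_idx = len(config.steps) - 1
    for rec in cohort:
        tests: list[str] = []
        step_scores: dict = {}
        outcome = NO_DIAGNOSIS
        stop_step = config.steps[-1].name
        for i, step in enumerate(config.steps):
            for tname in step.tests:
                if tname not in tests:
                    tests.append(tname)
            score, action = _apply_step(step, scores, rec.id, i == last_idx)
            step_scores[step.name] = score
            if action.kind == "stop":
                for tname in action.extra_tests:
                    if tname not in tests:
                        tests.append(tname)
                outcome = action.outcome
                stop_step = step.name
                break
        results.append(TrajectoryResult(rec.id, step_scores, stop_step, outcome, tuple(tests)))
    return results


def funnel_counts(trajectories: Sequence[TrajectoryResult],
                  config: ScenarioConfig) -> FunnelSummary:
    """Per-step continuing/stopping counts and per-test consumption.

    Fractions are over the scenario's included population; continuing
    counts are monotone non-increasing by construction.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    n = len(trajectories)
    step_names = [s.name for s in config.steps]
    order = {name: i for i, name in enumerate(step_names)}
    rows = []
    entered = n
    for i, name in enumerate(step_names):
        stopped = sum(1 for t in trajectories if t.stop_step == name)
        continued = entered - stopped
        rows.append({
            "step": name,
            "entered": entered,
            "stopped": stopped,
            "continued": continued,
            "frac_entered": entered / n,
            "frac_stopped": stopped / n,
        })
        entered = continued
    test_names = sorted({t for tr in trajectories for t in tr.tests})
    tests = pd.DataFrame(
        [
            {
                "test": tname,
                "count": sum(1 for tr in trajectories if tname in tr.tests),
            }
            for tname in test_names
        ]
    )
    if len(tests):
        tests["fraction"] = tests["count"] / n
    assert all(t.stop_step in order for t in trajectories)
    return FunnelSummary(pd.DataFrame(rows), tests, n)


def trajectories_frame(trajectories: Sequence[TrajectoryResult],
                       config: ScenarioConfig) -> pd.DataFrame:
    """Flat per-patient table: outcome, stop step, tests, per-step DSI."""
    rows = []
    for t in trajectories:
        row = {
            "id": t.patient_id,
            "scenario": config.scenario_id,
            "stop_step": t.stop_step,
            "outcome": t.outcome,
            "tests": "+".join(t.tests),
        }
        for name, score in t.step_scores.items():
            if score is None:
                row[f"dsi_{name}"] = np.nan
            elif isinstance(score, dict):
                for k, v in score.items():
                    key = k.value if isinstance(k, DiagnosisLabel) else str(k)
                    row[f"dsi_{name}_{key}"] = np.nan if v is None else v
            else:
                row[f"dsi_{name}"] = score
        rows.append(row)
    return pd.DataFrame(rows)
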