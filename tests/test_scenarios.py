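"""scenarios module: configs, band semantics, the stepwise walk, funnels."""

from __future__ import annotations

import numpy as np
import pytest

from dsifunnel.cohort import DiagnosisLabel
from dsifunnel.crossval import CvPlan
from dsifunnel.scenarios import (
    Action,
    Band,
    ELIGIBLE,
    NO_DIAGNOSIS,
    NOT_ELIGIBLE,
    SCENARIO_IDS,
    _check_tiling,
    builtin_config,
    compute_cv_scores,
    funnel_counts,
    run_stepwise,
    trajectories_frame,
)

AD, FTD, VaD, DLB = (DiagnosisLabel.AD, DiagnosisLabel.FTD,
                     DiagnosisLabel.VaD, DiagnosisLabel.DLB)


class StubScores:
    """Deterministic score provider for band-semantics tests."""

    def __init__(self, pairwise=None, multiclass=None):
        self._p = pairwise or {}
        self._m = multiclass or {}

    def pairwise(self, classifier, subset, pid):
        return self._p[(classifier, subset, pid)]

    def multiclass(self, classifier, subset, pid):
        return self._m[(classifier, subset, pid)]


def _one_patient_cohort(cohort, diagnosis=AD):
    rec = next(r for r in cohort if r.diagnosis is diagnosis)
    from dsifunnel.cohort import Cohort
    return Cohort(cohort.schema, [rec]), rec.id


# -- configs -----------------------------------------------------------------


def test_builtin_config_1a_bands():
    cfg = builtin_config("1A")
    bands = cfg.steps[0].bands
    cuts = sorted({b.lo for b in bands} | {b.hi for b in bands})
    assert cuts == [0.0, 0.3, 0.7, 1.0]


def test_builtin_config_2_and_3_cutoffs():
    cfg2 = builtin_config("2")
    assert cfg2.steps[0].bands[0].hi == 0.25
    assert cfg2.steps[1].cutoff == 0.6
    assert DiagnosisLabel.MCI not in cfg2.included
    cfg3 = builtin_config("3")
    assert cfg3.steps[1].bands[0].hi == 0.3
    assert cfg3.steps[2].params == {"ad_cut": 0.1, "other_etiology_cut": 0.85}


def test_builtin_config_unknown_id():
    with pytest.raises(ValueError, match="unknown scenario"):
        builtin_config("4X")


def test_threshold_overrides():
    cfg = builtin_config("1A", {"cn_cut": 0.35, "dem_cut": 0.65})
    assert cfg.steps[0].bands[0].hi == 0.35
    with pytest.raises(ValueError):
        builtin_config("1A", {"cn_cut": 0.8, "dem_cut": 0.7})  # out of order
    with pytest.raises(ValueError):
        builtin_config("1A", {"cn_cut": 1.5})  # outside (0,1)


def test_band_tiling_fuzz():
    rng = np.random.default_rng(0)
    xs = np.concatenate([rng.random(100_000),
                         [0.0, 0.1, 0.25, 0.3, 0.7, 0.95, 1.0]])
    for sid in SCENARIO_IDS:
        cfg = builtin_config(sid)
        for step in cfg.steps:
            if step.kind != "pairwise_bands":
                continue
            for x in xs:
                hits = sum(b.contains(float(x)) for b in step.bands)
                assert hits == 1, (sid, step.name, x)


def test_check_tiling_rejects_gaps_and_overlaps():
    stop = Action("stop", "CN")
    with pytest.raises(ValueError):
        _check_tiling((Band(0.0, 0.4, stop), Band(0.5, 1.0, stop)))  # gap
    with pytest.raises(ValueError):
        _check_tiling((Band(0.0, 0.5, stop), Band(0.5, 1.0, stop)))  # 0.5 twice
    # valid: boundary belongs to exactly one band
    _check_tiling((Band(0.0, 0.5, stop, hi_open=True), Band(0.5, 1.0, stop)))


# -- band application via stubs ----------------------------------------------


def test_scenario_1b_low_dsi_stops_at_ccog(small_cohort):
    cfg = builtin_config("1B")
    one, pid = _one_patient_cohort(small_cohort, DiagnosisLabel.CN)
    scores = StubScores(pairwise={("cn_dem", "ccog", pid): 0.05})
    (t,) = run_stepwise(one, cfg, scores)
    assert t.outcome == "CN" and t.tests == ("cCOG",)
    assert t.stop_step == "ccog"


def test_scenario_1b_high_dsi_dementia_with_mri(small_cohort):
    cfg = builtin_config("1B")
    one, pid = _one_patient_cohort(small_cohort)
    scores = StubScores(pairwise={("cn_dem", "ccog", pid): 0.97})
    (t,) = run_stepwise(one, cfg, scores)
    assert t.outcome == "DEM" and t.tests == ("cCOG", "MRI")


def test_scenario_1b_middle_continues_to_np(small_cohort):
    cfg = builtin_config("1B")
    one, pid = _one_patient_cohort(small_cohort)
    scores = StubScores(pairwise={("cn_dem", "ccog", pid): 0.5,
                                  ("cn_dem", "ccog_np", pid): 0.4})
    (t,) = run_stepwise(one, cfg, scores)
    assert t.outcome == "MCI" and t.tests == ("cCOG", "NP", "MRI")


def test_scenario_1a_boundaries_inclusive(small_cohort):
    cfg = builtin_config("1A")
    one, pid = _one_patient_cohort(small_cohort)
    for x, expect in ((0.3, "MCI"), (0.7, "MCI"), (0.29999, "CN"), (0.70001, "DEM")):
        (t,) = run_stepwise(one, cfg, StubScores(
            pairwise={("cn_dem", "np", pid): x}))
        assert t.outcome == expect, x


def test_scenario_2_worked_example(small_cohort):
    cfg = builtin_config("2")
    one, pid = _one_patient_cohort(small_cohort)
    mri = {AD: 0.55, FTD: 0.4, VaD: 0.3, DLB: 0.3}
    csf = {AD: 0.71, FTD: 0.3, VaD: 0.3, DLB: 0.3}
    scores = StubScores(
        pairwise={("cn_dem", "cognitive", pid): 0.9},
        multiclass={("etiology", "mri", pid): mri,
                    ("etiology", "csf", pid): csf})
    (t,) = run_stepwise(one, cfg, scores)
    assert t.outcome == "AD" and t.stop_step == "csf"
    assert t.tests == ("cCOG", "NP", "MRI", "CSF")


def test_scenario_2_boundary_and_no_diagnosis(small_cohort):
    cfg = builtin_config("2")
    one, pid = _one_patient_cohort(small_cohort)
    low = {AD: 0.6, FTD: 0.2, VaD: 0.2, DLB: 0.2}  # 0.6 is not > 0.6
    scores = StubScores(
        pairwise={("cn_dem", "cognitive", pid): 0.26},
        multiclass={("etiology", "mri", pid): low,
                    ("etiology", "csf", pid): low})
    (t,) = run_stepwise(one, cfg, scores)
    assert t.outcome == NO_DIAGNOSIS
    # indeterminate everywhere also ends in "no diagnosis"
    none_scores = {AD: None, FTD: None, VaD: None, DLB: None}
    scores = StubScores(
        pairwise={("cn_dem", "cognitive", pid): 0.26},
        multiclass={("etiology", "mri", pid): none_scores,
                    ("etiology", "csf", pid): none_scores})
    (t,) = run_stepwise(one, cfg, scores)
    assert t.outcome == NO_DIAGNOSIS


def test_scenario_2_cn_stop_inclusive(small_cohort):
    cfg = builtin_config("2")
    one, pid = _one_patient_cohort(small_cohort, DiagnosisLabel.CN)
    (t,) = run_stepwise(one, cfg, StubScores(
        pairwise={("cn_dem", "cognitive", pid): 0.25}))
    assert t.outcome == "CN" and t.tests == ("cCOG", "NP")


def test_scenario_2_rejects_mci(small_cohort):
    cfg = builtin_config("2")
    with pytest.raises(ValueError, match="excludes diagnoses.*MCI"):
        run_stepwise(small_cohort, cfg, StubScores())


def test_scenario_3_eligibility_rule(small_cohort):
    cfg = builtin_config("3")
    one, pid = _one_patient_cohort(small_cohort)

    def walk(ad, others):
        scores = StubScores(
            pairwise={("cn_dem", "ccog", pid): 0.5,
                      ("cn_dem", "ccog_np", pid): 0.5,
                      ("ad_other", "mri", pid): ad},
            multiclass={("etiology", "mri", pid): others})
        (t,) = run_stepwise(one, cfg, scores)
        return t

    others_high = {AD: 0.9, FTD: 0.9, VaD: 0.1, DLB: 0.1}
    others_low = {AD: 0.9, FTD: 0.5, VaD: 0.1, DLB: 0.1}
    # clear other etiology -> not eligible
    assert walk(0.05, others_high).outcome == NOT_ELIGIBLE
    # AD evidence above 0.1 -> eligible, confirmatory CSF consumed
    t = walk(0.4, others_low)
    assert t.outcome == ELIGIBLE and "CSF" in t.tests
    # the 0.1 gap value and the low/ambiguous case -> not eligible
    assert walk(0.1, others_low).outcome == NOT_ELIGIBLE
    assert walk(0.05, others_low).outcome == NOT_ELIGIBLE


def test_scenario_3_early_stops(small_cohort):
    cfg = builtin_config("3")
    one, pid = _one_patient_cohort(small_cohort, DiagnosisLabel.CN)
    (t,) = run_stepwise(one, cfg, StubScores(
        pairwise={("cn_dem", "ccog", pid): 0.1}))  # <= 0.1 inclusive
    assert t.outcome == NOT_ELIGIBLE and t.tests == ("cCOG",)
    (t,) = run_stepwise(one, cfg, StubScores(
        pairwise={("cn_dem", "ccog", pid): 0.2,
                  ("cn_dem", "ccog_np", pid): 0.3}))
    assert t.outcome == NOT_ELIGIBLE and t.tests == ("cCOG", "NP")


# -- cross-validated end to end ----------------------------------------------


@pytest.fixture(scope="module")
def cv_run_1a(small_cohort):
    cfg = builtin_config("1A")
    plan = CvPlan(n_folds=5, n_repeats=2, base_seed=0)
    scores = compute_cv_scores(small_cohort, cfg, plan)
    return cfg, run_stepwise(small_cohort, cfg, scores), scores


def test_stepwise_totality(small_cohort, cv_run_1a):
    cfg, trajectories, _ = cv_run_1a
    assert len(trajectories) == len(small_cohort)
    assert all(t.outcome in ("CN", "MCI", "DEM") or t.outcome == NO_DIAGNOSIS
               for t in trajectories)


def test_stepwise_deterministic(small_cohort, cv_run_1a):
    cfg, trajectories, scores = cv_run_1a
    again = run_stepwise(small_cohort, cfg, scores)
    assert [(t.patient_id, t.outcome, t.tests) for t in trajectories] == \
           [(t.patient_id, t.outcome, t.tests) for t in again]


def test_funnel_monotone_and_conserved(small_cohort, cv_run_1a):
    cfg, trajectories, _ = cv_run_1a
    f = funnel_counts(trajectories, cfg)
    cont = f.steps["continued"].to_numpy()
    assert all(b <= a for a, b in zip(cont, cont[1:]))
    assert f.steps["stopped"].sum() + cont[-1] == len(small_cohort)
    # scenario 1A: MRI fraction = fraction with step-1 DSI > 0.3
    mri_row = f.tests[f.tests.test == "MRI"]
    expect = sum(1 for t in trajectories
                 if t.step_scores["np"] is not None
                 and t.step_scores["np"] > 0.3) / len(small_cohort)
    assert float(mri_row["fraction"].iloc[0]) == pytest.approx(expect)


def test_trajectories_frame_shape(small_cohort, cv_run_1a):
    cfg, trajectories, _ = cv_run_1a
    frame = trajectories_frame(trajectories, cfg)
    assert len(frame) == len(small_cohort)
    assert {"id", "scenario", "stop_step", "outcome", "tests"} <= set(frame.columns)
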