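"""dsi module: fitness, relevance, normalization, combination, multiclass."""

from __future__ import annotations

import logging
import math

import numpy as np
import pytest

from dsifunnel.cohort import (
    CcogSource,
    Cohort,
    DEMENTIA_LABELS,
    DiagnosisLabel,
    PatientRecord,
    Sex,
    default_schema,
)
from dsifunnel.dsi import (
    CovariateNormalizer,
    DsiModel,
    FitnessEstimator,
    dsi,
    dsi_batch,
    fit_fitness,
    fit_relevance,
    fitness,
    multiclass_dsi,
    normalize_covariates,
    predict_class,
    train_pairwise,
)

AD, CN = DiagnosisLabel.AD, DiagnosisLabel.CN


def _record(pid="P1", diagnosis=AD, age=70.0, sex=Sex.female, **features):
    return PatientRecord(id=pid, diagnosis=diagnosis, age=age, sex=sex,
                         features=dict(features),
                         ccog_source=CcogSource.simulated)


# -- fitness ----------------------------------------------------------------


def test_fit_fitness_directions():
    assert fit_fitness([2, 3, 4], [0, 1, 2]).direction == "pos_high"
    assert fit_fitness([0, 1], [5, 6]).direction == "pos_low"
    assert fit_fitness([1, 2, 3], [1, 2, 3]).direction == "pos_high"  # tie rule


def test_fit_fitness_requires_two_values():
    with pytest.raises(ValueError):
        fit_fitness([1.0], [1, 2])
    with pytest.raises(ValueError):
        fit_fitness([1, 2], [float("nan"), 2.0])


def test_fitness_mirrored_gaussians():
    rng = np.random.default_rng(3)
    est = fit_fitness(rng.normal(1, 0.1, 1000), rng.normal(-1, 0.1, 1000))
    assert abs(fitness(est, 0.0) - 0.5) < 0.05
    assert fitness(est, 1.0) > 0.95
    assert fitness(est, -1.0) < 0.05


def test_fitness_bounds_random():
    rng = np.random.default_rng(4)
    for _ in range(50):
        est = fit_fitness(rng.normal(size=20), rng.normal(size=20))
        xs = rng.normal(scale=3, size=100)
        vals = est(xs)
        assert np.all((vals >= 0) & (vals <= 1))


def test_fitness_rank_invariance_exact():
    rng = np.random.default_rng(5)
    pos, neg = rng.normal(1, 1, 80), rng.normal(0, 1, 80)
    xs = rng.normal(0.5, 2, 200)
    base = fit_fitness(pos, neg)(xs)

    def transform(a):
        return np.exp(a) + a ** 3  # strictly increasing

    transformed = fit_fitness(transform(pos), transform(neg))(transform(xs))
    assert np.allclose(base, transformed, atol=1e-12)


# -- relevance --------------------------------------------------------------


def test_relevance_identical_distributions():
    vals = [1.0, 2.0, 3.0, 4.0]
    assert fit_relevance(vals, vals).value == 0.0


def test_relevance_disjoint_supports():
    assert fit_relevance([10, 11, 12], [0, 1, 2]).value == 1.0


def test_relevance_hand_oracle():
    # pos=[0,1,2,3], neg=[2,3,4,5]: best threshold separates {0,1} from
    # {4,5} plus half the overlap: sens 0.5 + spec 1.0 - 1 = 0.5
    assert fit_relevance([0, 1, 2, 3], [2, 3, 4, 5]).value == pytest.approx(0.5)


def test_relevance_noise_small():
    rng = np.random.default_rng(6)
    r = fit_relevance(rng.normal(size=200), rng.normal(size=200))
    assert r.value < 0.15


# -- covariate normalization -------------------------------------------------


def _controls_with_age_effect(n=500, seed=0):
    rng = np.random.default_rng(seed)
    schema = default_schema()
    recs = []
    for i in range(n):
        age = float(rng.uniform(55, 85))
        recs.append(_record(pid=f"C{i}", diagnosis=CN, age=age,
                            sex=Sex.female if rng.random() < 0.5 else Sex.male,
                            wmh=2 * age + float(rng.normal(0, 5)),
                            gds=3.0))
    return Cohort(schema, recs)


def test_normalization_constant_feature_unchanged():
    cohort = _controls_with_age_effect(50)
    out = normalize_covariates(cohort, cohort)
    assert all(r.get("gds") == pytest.approx(3.0) for r in out)


def test_normalization_removes_age_effect():
    cohort = _controls_with_age_effect(500)
    out = normalize_covariates(cohort, cohort)
    ages = np.array([r.age for r in out])
    resid = np.array([r.get("wmh") for r in out])
    assert abs(np.corrcoef(ages, resid)[0, 1]) < 0.1


def test_normalization_idempotent():
    cohort = _controls_with_age_effect(300)
    once = normalize_covariates(cohort, cohort)
    twice = normalize_covariates(once, once)
    for a, b in zip(once, twice):
        assert a.get("wmh") == pytest.approx(b.get("wmh"), abs=1e-6)


# -- combination tree (hand-built model) -------------------------------------


def _toy_model() -> DsiModel:
    # feature a: fitness at x=10 is 0.2 (FNR=0.2, FPR=0.8)
    est_a = FitnessEstimator("a", np.sort([5.0, 20, 30, 40, 50]),
                             np.sort([2.0, 15, 16, 17, 18]), "pos_high")
    # feature b: fitness at x=10 is 1.0 (FNR=1/3, FPR=0)
    est_b = FitnessEstimator("b", np.sort([5.0, 20, 30]),
                             np.sort([1.0, 2, 3]), "pos_high")
    return DsiModel(
        pos_labels=frozenset({AD}), neg_labels=frozenset({CN}),
        features=["a", "b"],
        estimators={"a": est_a, "b": est_b},
        relevances={"a": 1.0 / 3.0, "b": 1.0},  # weight ratio 1:3
        modality_of={"a": "M", "b": "M"},
        node_relevance={"M": 1.0},
        normalizer=None,
    )


def test_toy_fitness_values():
    m = _toy_model()
    assert fitness(m.estimators["a"], 10.0) == pytest.approx(0.2)
    assert fitness(m.estimators["b"], 10.0) == pytest.approx(1.0)


def test_dsi_weighted_combination_worked_example():
    # fitness (0.2, 1.0) with relevance ratio (1, 3) -> (0.2 + 3)/4 = 0.8
    m = _toy_model()
    rec = _record(a=10.0, b=10.0)
    assert dsi(m, rec) == pytest.approx(0.8)


def test_dsi_constant_fitness_ignores_weights():
    m = _toy_model()
    # both features at value 10 give different fitness; instead check the
    # single-feature case: one observed leaf returns its own fitness
    rec = _record(a=10.0)
    assert dsi(m, rec) == pytest.approx(0.2)


def test_dsi_missing_data_contract():
    m = _toy_model()
    masked = _record(a=10.0, b=float("nan"))
    removed = _record(a=10.0, b=5.0)
    assert dsi(m, masked) == dsi(m, removed, feature_subset=["a"])


def test_dsi_indeterminate_when_nothing_observed():
    m = _toy_model()
    assert dsi(m, _record()) is None


# -- training on cohorts -----------------------------------------------------


def test_train_pairwise_symmetry(small_cohort):
    feats = [f.id for f in small_cohort.schema]
    fwd = train_pairwise(small_cohort, DEMENTIA_LABELS, {CN},
                         features=feats, normalize=False)
    rev = train_pairwise(small_cohort, {CN}, DEMENTIA_LABELS,
                         features=feats, normalize=False)
    recs = list(small_cohort)[:60]
    a = dsi_batch(fwd, recs)
    b = dsi_batch(rev, recs)
    obs = ~np.isnan(a)
    assert np.array_equal(obs, ~np.isnan(b))
    assert np.allclose(a[obs], 1.0 - b[obs], atol=1e-9)


def test_train_pairwise_rank_invariance(small_cohort):
    feats = ["mmse", "tmt_a", "abeta42"]
    base_model = train_pairwise(small_cohort, DEMENTIA_LABELS, {CN},
                                features=feats, normalize=False)
    base = dsi_batch(base_model, list(small_cohort))

    def transform(rec):
        out = rec.copy()
        if out.has("tmt_a"):
            out.features["tmt_a"] = math.exp(out.get("tmt_a") / 50.0)
        return out

    warped = Cohort.__new__(Cohort)
    warped.schema = small_cohort.schema
    warped.records = [transform(r) for r in small_cohort]
    warped_model = train_pairwise(warped, DEMENTIA_LABELS, {CN},
                                  features=feats, normalize=False)
    warped_vals = dsi_batch(warped_model, list(warped))
    obs = ~np.isnan(base)
    assert np.allclose(base[obs], warped_vals[obs], atol=1e-9)


def test_train_pairwise_bounds_and_structure(small_cohort):
    model = train_pairwise(small_cohort, DEMENTIA_LABELS, {CN})
    assert set(model.features) | set(model.dropped_features) == {
        f.id for f in small_cohort.schema}
    vals = dsi_batch(model, list(small_cohort))
    obs = vals[~np.isnan(vals)]
    assert np.all((obs >= 0) & (obs <= 1))
    assert all(0 <= r <= 1 for r in model.relevances.values())
    assert all(0 <= r <= 1 for r in model.node_relevance.values())


def test_train_pairwise_too_few_records(small_cohort):
    few = Cohort(small_cohort.schema,
                 [r for r in small_cohort if r.diagnosis is CN][:3]
                 + [r for r in small_cohort if r.diagnosis is AD][:8])
    with pytest.raises(ValueError):
        train_pairwise(few, {AD}, {CN})


def test_training_auc_on_default_cohort(default_cohort):
    model = train_pairwise(default_cohort, DEMENTIA_LABELS, {CN})
    recs = [r for r in default_cohort
            if r.diagnosis is CN or r.diagnosis in DEMENTIA_LABELS]
    scores = dsi_batch(model, recs)
    y = np.array([r.diagnosis in DEMENTIA_LABELS for r in recs])
    obs = ~np.isnan(scores)
    from sklearn.metrics import roc_auc_score
    assert roc_auc_score(y[obs], scores[obs]) > 0.9


# -- serialization ------------------------------------------------------------


def test_model_save_load_round_trip(tmp_path, small_cohort):
    model = train_pairwise(small_cohort, DEMENTIA_LABELS, {CN})
    path = tmp_path / "model.json"
    model.save(path)
    back = DsiModel.load(path)
    assert back.content_hash() == model.content_hash()
    recs = list(small_cohort)[:20]
    assert np.allclose(dsi_batch(model, recs), dsi_batch(back, recs),
                       equal_nan=True)


def test_model_version_checked(tmp_path, small_cohort):
    model = train_pairwise(small_cohort, DEMENTIA_LABELS, {CN})
    doc = model.to_dict()
    doc["version"] = 999
    with pytest.raises(ValueError):
        DsiModel.from_dict(doc)


# -- multiclass ---------------------------------------------------------------


def _four_class_cohort(shift_ad=3.0, n=60, seed=7):
    """Toy cohort: AD's features shifted by ``shift_ad`` sigma."""
    rng = np.random.default_rng(seed)
    schema = default_schema()
    recs = []
    classes = [DiagnosisLabel.AD, DiagnosisLabel.FTD, DiagnosisLabel.VaD,
               DiagnosisLabel.DLB]
    for ci, cls in enumerate(classes):
        mu = shift_ad if cls is DiagnosisLabel.AD else 0.0
        for i in range(n):
            recs.append(_record(
                pid=f"{cls.value}{i}", diagnosis=cls,
                age=float(rng.uniform(55, 85)),
                wmh=float(rng.normal(50 + 10 * mu, 10)),
                aps=float(np.clip(rng.normal(0.5 + 0.05 * mu, 0.05), 0, 1)),
                ttau=float(np.clip(rng.normal(400 + 100 * mu, 100), 1, None)),
            ))
    return Cohort(schema, recs), classes


def _pairwise_models(cohort, classes, feats):
    return {
        (a, b): train_pairwise(cohort, {a}, {b}, features=feats, normalize=False)
        for i, a in enumerate(classes) for b in classes[i + 1:]
    }


def test_multiclass_orientation_consistency():
    cohort, classes = _four_class_cohort()
    feats = ["wmh", "aps", "ttau"]
    models = _pairwise_models(cohort, classes, feats)
    rec = cohort.records[0]
    for (a, b), model in models.items():
        fwd = dsi(model, rec)
        rev_model = train_pairwise(cohort, {b}, {a}, features=feats,
                                   normalize=False)
        assert fwd == pytest.approx(1.0 - dsi(rev_model, rec), abs=1e-9)


def test_multiclass_separated_class_wins():
    cohort, classes = _four_class_cohort(shift_ad=3.0)
    feats = ["wmh", "aps", "ttau"]
    models = _pairwise_models(cohort, classes, feats)
    ad_rec = next(r for r in cohort if r.diagnosis is DiagnosisLabel.AD)
    scores = multiclass_dsi(models, ad_rec, classes)
    assert scores[DiagnosisLabel.AD] > 0.9
    assert all(scores[c] < 0.6 for c in classes if c is not DiagnosisLabel.AD)
    assert predict_class(scores) is DiagnosisLabel.AD


def test_multiclass_identical_distributions_near_half():
    cohort, classes = _four_class_cohort(shift_ad=0.0, n=125)
    feats = ["wmh", "aps", "ttau"]
    models = _pairwise_models(cohort, classes, feats)
    recs = list(cohort)[:40]
    means = {c: [] for c in classes}
    for rec in recs:
        s = multiclass_dsi(models, rec, classes)
        for c in classes:
            means[c].append(s[c])
    for c in classes:
        assert abs(np.mean(means[c]) - 0.5) < 0.05


def test_predict_class_examples(caplog):
    s = {DiagnosisLabel.AD: 0.7, DiagnosisLabel.FTD: 0.3,
         DiagnosisLabel.VaD: 0.3, DiagnosisLabel.DLB: 0.2}
    assert predict_class(s) is DiagnosisLabel.AD
    tie = {DiagnosisLabel.AD: 0.5, DiagnosisLabel.FTD: 0.5,
           DiagnosisLabel.VaD: 0.1, DiagnosisLabel.DLB: 0.1}
    with caplog.at_level(logging.WARNING):
        assert predict_class(tie) is DiagnosisLabel.AD
    assert any("tie" in r.message.lower() for r in caplog.records)
    with pytest.raises(ValueError):
        predict_class({DiagnosisLabel.AD: None})
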