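# dsifunnel

A data-driven **stepwise diagnostic pathway for dementia**: a Disease
State Index (DSI) classifier trained on multimodal memory-clinic
features and applied *sequentially* — digital cognitive screening,
neuropsychology, MRI markers, CSF biomarkers — under explicit
probability-threshold rules, so that each test is only performed when
the previous step was inconclusive.

## The problem

Memory clinics face a growing mismatch between referral volume and
diagnostic capacity, while disease-modifying treatments (DMTs) make it
urgent to identify eligible patients early and cheaply. The idea
implemented here is a *diagnostic funnel*: cheap, scalable tests first
(a ~20-minute web-based cognitive screen usable at home), escalating to
neuropsychology, automated MRI biomarkers, and finally CSF only for the
patients whose diagnosis remains uncertain.

Three clinical scenarios are supported:

| Scenario | Question | Steps |
|---|---|---|
| 1A / 1B | Syndrome: CN / MCI / dementia | (cCOG →) NP, MRI as follow-up |
| 2 | Etiology: AD / FTD / VaD / DLB | cCOG+NP → MRI → CSF |
| 3 | DMT eligibility | cCOG → NP → MRI → confirmatory CSF |

## The model

For a feature $x$ with training distributions from a positive
(disease) and a negative (control) group, the **fitness** maps an
observed value to evidence in $[0,1]$:

$$\mathrm{fitness}(x) = \frac{\mathrm{FNR}(x)}{\mathrm{FNR}(x) + \mathrm{FPR}(x)}$$

where FNR/FPR are the fractions of positive/negative training values on
the "wrong" side of $x$ under midrank empirical CDFs (the form is
rank-based, hence invariant under any strictly increasing rescaling of
the feature). Each feature also gets a **relevance** weight — its
maximal Youden index $\max_\tau(\text{sens}_\tau + \text{spec}_\tau - 1)$
— and fitness values are combined through a two-level tree
(feature → modality → root) by relevance-weighted means over the
*observed* children only, which makes the index tolerant of missing
data. The root value is the DSI: ~0 fits the control group, ~1 fits
the disease group, and a patient with no observed features yields an
explicit indeterminate result, never a silent 0.5.

Multiclass (etiology) scores average each class's pairwise DSIs against
every other class. All out-of-sample scores come from 10×10 repeated
stratified cross-validation, averaged per patient across repeats.
Features are residualized for age and sex against the control group
before training.

Because the original clinical cohort was never deposited, the package
ships a **synthetic cohort generator**: a Gaussian copula with
block-wise correlations whose group-wise marginals (truncated normals
moment-matched to the published mean ± SD cells; two-piece normals
matched to the published median [IQR] cells), group sizes, sex/age
structure and missingness rates emulate the published cohort table.
The published confusion matrices are embedded as reference fixtures and
every derivable printed metric is recomputed against them.

## Worked example

```bash
$ dsifunnel simulate --seed 1 --out-dir out
wrote 883-patient cohort to out/cohort.csv

$ dsifunnel run --scenario 1A --cohort out/cohort.csv --out-dir out
scenario 1A: wrote reports to out/
```

This writes per-patient trajectories, the confusion matrix, funnel
step/test counts, metrics and letter-value summaries. The same run from
Python:

```python
from dsifunnel import (CvPlan, builtin_config, compute_cv_scores,
                       default_spec, generate, run_stepwise)

cohort = generate(default_spec(seed=1))        # 883 synthetic patients
config = builtin_config("1A")                  # published threshold rules
scores = compute_cv_scores(cohort, config, CvPlan(base_seed=0))
trajectories = run_stepwise(cohort, config, scores)
```

Scenario 2 requires a cohort without MCI patients
(`cohort.with_labels(config.included)`); passing MCI records raises a
clear error, mirroring the original cohort design's exclusion.

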