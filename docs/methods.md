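# Methods note

This note records the model as implemented, the parameter defaults and
the reasons behind them, the scope of the synthetic data generator, and
the numerical choices that affect results. Package modules referenced
below live in `src/dsifunnel/`.

## 1. Disease State Index (DSI)

### Fitness

For each feature, two training samples (positive = disease group,
negative = control group) define a fitness map. With a *direction*
inferred from the medians (`pos_high` iff median(pos) ≥ median(neg),
ties → `pos_high`), define at a point $x$:

* FNR(x) = fraction of positive training values on the negative side
  of $x$;
* FPR(x) = fraction of negative training values on the positive side.

Both use the **midrank empirical CDF** $F(x) = (\#\{v<x\} + \tfrac12
\#\{v=x\})/n$, and

$$\mathrm{fitness}(x) = \mathrm{FNR}/(\mathrm{FNR}+\mathrm{FPR}),$$

with the convention 0.5 when both error rates are zero (no training
mass on the wrong side in either group). The midrank step form — rather
than a linearly interpolated ECDF — was chosen deliberately: it depends
only on ranks, so applying any strictly increasing transform jointly to
training and test values leaves every fitness (and hence every DSI)
*exactly* unchanged, which the test suite asserts at 1e-9. An
interpolated ECDF satisfies this only approximately.

### Relevance

Each feature's weight is its maximal Youden index: the maximum of
sensitivity + specificity − 1 over thresholds placed at midpoints of
the pooled sorted training values, with the direction fixed by the
medians and the result floored at 0. Identical training distributions
give 0, disjoint supports give 1. Composite (modality) nodes reuse the
same rule applied to the node's own combined values over the training
set — one self-consistent weighting rule at every tree level.

### Combination tree and missing data

Leaves are features grouped by modality; modalities combine at the
root (two levels). Each node's value is the relevance-weighted mean of
its *observed* children; a node with no observed children is itself
missing. Masking a feature is therefore exactly equivalent to removing
it from the scored subset. If nothing is observed the DSI is an
explicit indeterminate (`None`), never an implicit 0.5 — downstream the
stepwise engine turns it into "continue" (or "no diagnosis" at a
terminal step). A node whose observed children all have zero relevance
falls back to their unweighted mean rather than 0/0.

### Covariate normalization

Before training, every feature is residualized for age and sex by an
OLS fit `value ~ 1 + age + sex` on the **negative (control) group**,
replacing values by `value − (fitted − control mean)`. Degenerate fits
(constant feature, < 3 control observations) pass values through.
The operation is idempotent up to refitting tolerance. Whether the
original work fit on controls only or the full training set is
unstated; controls-only was chosen because it leaves the control
distribution centered and is the common normative-data convention.
Note that normalization intentionally breaks the pos/neg swap symmetry
(the control group changes under the swap), so the symmetry invariant
(swap → 1 − x) is stated and tested with normalization disabled.

### Multiclass scores

One pairwise model per unordered class pair; the reverse orientation is
1 − DSI. A class's score is the mean of its oriented pairwise DSIs,
averaging over the determinate ones only. Argmax classification breaks
exact ties by the fixed order AD, FTD, VaD, DLB with a logged warning.

## 2. Cross-validation

Tenfold cross-validation repeated ten times (repeat *r* uses seed
`base_seed + r`), stratified by diagnosis (with 35 VaD patients,
unstratified folds risk empty strata). All fitting — normalization,
fitness, relevance, node weights — uses only the nine training folds;
a poisoning test asserts that corrupting held-out records never changes
the trained model's content hash. Every record of a held-out fold is
scored, including labels outside the training groups (e.g. MCI under
the CN-vs-dementia classifier — this is how scenario 1 places MCI
patients). Per-patient final scores are the arithmetic means of the
out-of-fold values across repeats; indeterminates are excluded from the
mean and an all-indeterminate patient stays indeterminate.

## 3. Stepwise scenarios

Threshold rules follow the published operators literally; middle bands
are closed and the bands always tile [0, 1] (checked at construction
and fuzz-tested):

* **1A**: NP battery, CN-vs-dementia DSI; `< 0.3` → CN, `[0.3, 0.7]` →
  MCI, `> 0.7` → dementia. MRI for every DSI > 0.3 is *resource-only*:
  counted in tests consumed, never changing the label (no published
  rule reclassifies after MRI, and the published accuracies match the
  NP-stage matrices).
* **1B**: prescreen on cCOG (`< 0.1` → CN, `> 0.95` → dementia,
  otherwise continue), then 1A's bands on cCOG+NP.
* **2** (CN + dementias only; MCI rejected with an explicit error):
  cognitive step `≤ 0.25` → CN; then multiclass DSI after MRI and, if
  still `≤ 0.6`, after CSF; any score `> 0.6` stops with that
  etiology; otherwise "no diagnosis".
* **3**: cCOG `≤ 0.1` and cCOG+NP `≤ 0.3` screen out; after MRI, not
  eligible iff AD-vs-other DSI `< 0.1` *and* some other etiology's
  multiclass score exceeds `other_etiology_cut`; eligible (confirmatory
  CSF) iff AD-vs-other `> 0.1`; the boundary value 0.1 itself falls to
  not-eligible. The source text prints 0.85 for the exclusion condition
  but 0.8 for the inclusion side; a single configurable
  `other_etiology_cut = 0.85` is used. "Other" = {FTD, VaD, DLB} (CN is
  already filtered by steps 1–2).

All thresholds are overridable (`--threshold key=value`); overrides are
validated to keep the bands tiling [0, 1].

## 4. Evaluation conventions

Confusion matrices store `counts[predicted_row][actual_column]`.
Overall accuracy = trace/total. Sensitivity = diagonal over the actual
column total. Specificity = fraction of non-class actuals *not*
assigned to the class. These conventions reproduce every published
MCI/DEM/etiology metric to two decimals (half-up display rounding);
the published CN entries match the transposed definition and are
treated as a printing anomaly, together with one accuracy (0.72
printed vs 631/883), one eligibility specificity (0.47 vs 310/647) and
four etiology specificities off by 0.01–0.02. All twelve are flagged
in `reproduce_reference_tables()`; any *other* disagreement is a
hard failure.

DMT eligibility ground truth: diagnosis in {MCI, AD} **and** CSF
t-tau/Aβ42 ≥ 0.46 **and** MMSE ≥ 22 **and** cFazekas < 2.5, with an
indeterminate result whenever a required input is missing (mirroring
the complete-data restriction in the source analysis).

Letter values (median, fourths, eighths, sixteenths) use the classic
depth recursion d₁ = (n+1)/2, d_{k+1} = (⌊d_k⌋+1)/2; for values 1..16
this gives median 8.5 and fourths (4.5, 12.5). Nesting of the boxes is
a tested invariant.

## 5. Synthetic cohort generator

Scope: the generator reproduces the published **group-wise univariate
marginals** (all six diagnosis groups × all tabulated features), group
sizes 188/191/302/107/35/60, sex proportions, age distributions and
missingness rates. It does **not** reproduce the real cohort's joint
dependence structure — no covariance information was published — so
cohort-level pipeline results on synthetic data are *behavioral*
analogues, not numeric reproductions.

* **Dependence**: Gaussian copula with block correlations — 0.3 within
  a modality, 0.1 across modalities — enough dependence for multimodal
  combination to behave realistically without inventing specific
  pairwise values. Both are configurable.
* **mean ± SD cells**: truncated normals on the feature's valid range
  with *latent parameters moment-matched* (two-dimensional root solve)
  so the truncated mean and SD equal the printed values. Three cells
  are mathematically infeasible for this family (coefficient of
  variation > 1 against a lower bound at 0, or a mean hard against a
  scale ceiling); for those the mean alone is matched exactly (the
  truncated mean is strictly increasing in the latent location, so a
  bracketed root always exists) and the SD comes as close as the family
  permits. This keeps the 3·SE mean-recovery guarantee for every cell.
* **median [IQR] cells**: a two-piece (split) normal with
  σ_low = (median − q1)/z₀.₇₅ and σ_high = (q3 − median)/z₀.₇₅, which
  reproduces all three printed quantiles exactly; values are clipped to
  the valid range (ceiling-effect cells such as a functional scale at
  its maximum are permitted to have median = q3).
* **Missingness**: completely at random at rates derived from the
  published per-feature Ns (e.g. ≈ 0.42 for the functional scale,
  ≈ 0.005 for MMSE). Only counts, not mechanisms, were published.
* **cCOG provenance**: 13% of records are labeled `measured` and the
  rest `simulated`, emulating the original cohort's composition; all
  generated values come from the calibrated marginals.
  `simulate_ccog_from_np` implements the NP→cCOG imputation as
  within-diagnosis percentile matching against a reference cohort
  (monotone, median-preserving, never overwriting measured values, with
  a pooled fallback for sparse groups) — the source text does not state
  how its simulated cCOG values were derived, so percentile matching is
  this package's explicit choice.
* Integer scales (MMSE, GDS) are rounded; everything is deterministic
  given the spec seed, byte-for-byte.

## 6. Numerical and design choices that affect results

* Midrank ECDFs (exact rank invariance) rather than interpolation.
* Youden relevance floored at 0; zero-relevance fallback to unweighted
  means.
* Demographics are used only for normalization, never as predictive
  leaves (education is a leaf; age/sex are not), to avoid
  double-counting.
* Boundary semantics of every band follow the printed operator
  (`<` vs `≤`) exactly.
* Display rounding is half-up to 2 decimals; machine outputs always
  keep raw fractions.
* Models serialize to a self-describing JSON file with a mandatory
  version field; the content hash is the SHA-256 of the sorted JSON.

## 7. Limitations

* The fitness/relevance functional forms follow the DSI lineage's
  published behavior but the original supplementary formulas were not
  available; the error-ratio fitness and Youden relevance are declared
  substitutes.
* Synthetic correlations are schematic; any metric that depends on the
  joint distribution (e.g. scenario-3 selectivity) will differ from the
  real cohort. In particular the synthetic scenario-3 funnel is far
  more permissive than the published one.
* MCAR missingness ignores any informative-missingness in the clinic.
* No probability calibration or confidence intervals on DSI values;
  no nested cross-validation for threshold tuning (thresholds were
  fixed a priori in the source design).
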