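"""Published reference confusion matrices for the original clinical cohort.

These are the printed cohort-level results of the stepwise diagnostic
pathway on the original 883-patient memory-clinic population (which was
never deposited).  They serve two purposes: worked examples pinning
down the metric conventions, and a consistency check of this package's
metric implementations against the printed sensitivity/specificity/
accuracy rows.

Convention: ``counts[predicted_row][actual_column]``.

Known internal anomalies of the printed tables (surfaced by
:func:`dsifunnel.evaluation.reproduce_reference_tables`, never silently
"fixed"):

* the CN sensitivity/specificity entries of the syndrome matrices are
  transposed relative to the convention the MCI/DEM entries satisfy;
* the combined syndrome-prescreening accuracy prints 0.72 while the
  matrix gives 631/883 ~= 0.71;
* the eligibility specificity prints 0.47 vs a recomputed 310/647 ~= 0.48;
* four of the five etiology specificities differ from recomputation by
  0.01-0.02 (the sensitivities and the 0.77 accuracy reproduce exactly).
"""

from __future__ import annotations

SYNDROME_LABELS = ("CN", "MCI", "DEM")
ETIOLOGY_LABELS = ("CN", "AD", "FTD", "VaD", "DLB")
ELIGIBILITY_LABELS = ("not eligible", "eligible")

#: Scenario 1A (syndrome diagnosis from NP alone), all 883 patients.
SYNDROME_1A = {
    "labels": SYNDROME_LABELS,
    "counts": [
        [147, 32, 24],
        [31, 65, 35],
        [10, 94, 445],
    ],
    "printed": {
        "sensitivity": {"CN": 0.92, "MCI": 0.34, "DEM": 0.88},
        "specificity": {"CN": 0.78, "MCI": 0.90, "DEM": 0.73},
        "accuracy": 0.74,
    },
}

#: Scenario 1B step 1 (cCOG prescreen); the MCI row holds the
#: indeterminate band (0.1-0.95) routed to NP testing.
SYNDROME_1B_STEP1 = {
    "labels": SYNDROME_LABELS,
    "counts": [
        [113, 19, 20],
        [69, 132, 175],
        [6, 40, 309],
    ],
    "printed": {
        "sensitivity": {"CN": 0.94, "MCI": 0.69, "DEM": 0.61},
        "specificity": {"CN": 0.60, "MCI": 0.65, "DEM": 0.88},
        "accuracy": 0.63,
    },
}

#: Scenario 1B combined final (step-1 stoppers + step-2 outcomes), all 883.
SYNDROME_1B_COMBINED = {
    "labels": SYNDROME_LABELS,
    "counts": [
        [148, 35, 33],
        [29, 56, 44],
        [11, 100, 427],
    ],
    "printed": {
        "sensitivity": {"CN": 0.90, "MCI": 0.29, "DEM": 0.85},
        "specificity": {"CN": 0.79, "MCI": 0.89, "DEM": 0.71},
        "accuracy": 0.72,  # text says 0.71; 631/883 = 0.7146
    },
}

#: Etiological diagnosis after stepwise cCOG/NP + MRI + CSF: the 556
#: patients (of 692 included; MCI excluded) who received a diagnosis.
ETIOLOGY_COMBINED = {
    "labels": ETIOLOGY_LABELS,
    "counts": [
        [141, 4, 12, 1, 3],
        [4, 182, 3, 2, 3],
        [14, 23, 51, 2, 2],
        [2, 12, 4, 19, 1],
        [5, 23, 8, 2, 33],
    ],
    "printed": {
        "sensitivity": {"CN": 0.85, "AD": 0.75, "FTD": 0.65, "VaD": 0.73, "DLB": 0.79},
        "specificity": {"CN": 0.93, "AD": 0.95, "FTD": 0.90, "VaD": 0.96, "DLB": 0.91},
        "accuracy": 0.77,
    },
    "n_included": 692,
}

#: DMT-eligibility selection after cCOG + NP + MRI (877 patients with
#: complete amyloid/MMSE/cFazekas data; gold standard = CSF amyloid).
ELIGIBILITY_COMBINED = {
    "labels": ELIGIBILITY_LABELS,
    "counts": [
        [310, 39],
        [337, 191],
    ],
    "printed": {"sensitivity": 0.83, "specificity": 0.47},  # 310/647 = 0.479
}

#: AD-diagnosis breakdown of the truly eligible patients: columns are
#: stable MCI due to AD, progressive MCI due to AD, AD dementia; rows are
#: selected for CSF vs classified not eligible.
ELIGIBLE_AD_SUBTYPES = {
    "labels": ("sMCI", "pMCI", "ADD"),
    "counts": [
        [42, 38, 150],
        [16, 6, 17],
    ],
    "printed": {"sensitivity": {"sMCI": 0.72, "pMCI": 0.86, "ADD": 0.90}},
}

#: Funnel counts quoted in the running text.
TEXT_COUNTS = {
    "cohort_n": 883,
    "syndrome_1a_classified": {"CN": 203, "MCI": 131, "DEM": 549},
    "syndrome_1b_step1_indeterminate": 376,
    "syndrome_1b_mri_n": 667,
    "etiology_included_n": 692,
    "etiology_diagnosed_n": 556,
    "eligibility_total_eligible": 230,
    "eligibility_selected_true_positive": 191,
}
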