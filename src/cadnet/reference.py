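"""Published marginal counts for the 195-patient CAD study cohort.

These are the sex-stratified top-20 diagnosis and top-20 comorbidity counts
reported for a single-hospital coronary-artery-disease cohort (138 male,
57 female hospitalizations). They serve two roles: as the ground-truth
2x2 tables for the detection-rate / odds-ratio statistics, and as the
calibration targets for the synthetic cohort generator. Only marginals are
published — the record-level data are not — so anything beyond marginal
rates and sex effects must come from the generator's own co-occurrence
model.

Each row: (canonical term, total count, male count, female count).

"Myocardial Infarction" appears in the published tables both as a diagnosis
and as a comorbidity; the comorbidity entry is labelled
"Myocardial Infarction (comorbid)" here so the two vocabularies stay
disjoint in generated cohorts. Counts are unchanged.
"""

from __future__ import annotations

from .records import Category

N_TOTAL = 195
N_MALE = 138
N_FEMALE = 57

DIAGNOSIS_ROWS: list[tuple[str, int, int, int]] = [
    ("Unstable Angina", 82, 55, 27),
    ("Braunwald Class II B", 45, 32, 13),
    ("Stable Angina", 38, 30, 8),
    ("Myocardial Infarction", 28, 23, 5),
    ("CCS Angina class II", 27, 20, 7),
    ("KILLIP Class I", 20, 20, 0),
    ("Braunwald Class III B", 19, 13, 6),
    ("Coronary Atherosclerosis", 16, 9, 7),
    ("CCS Angina class I", 7, 7, 0),
    ("Post-Percutaneous Coronary Intervention", 6, 3, 3),
    ("Acute Coronary Syndrome", 6, 5, 1),
    ("Myocardial Bridging", 6, 3, 3),
    ("NYHA Class III", 5, 3, 2),
    ("NYHA Class II", 5, 3, 2),
    ("KILLIP Class II", 5, 4, 1),
    ("CCS Angina class III", 5, 4, 1),
    ("Multiple Vessel Disease", 4, 2, 2),
    ("Braunwald Class I B", 4, 3, 1),
    ("KILLIP Classification IV", 3, 1, 2),
    ("Coronary Atherosclerotic Heart Disease", 3, 3, 0),
]

COMORBIDITY_ROWS: list[tuple[str, int, int, int]] = [
    ("Hypertension", 120, 81, 39),
    ("Metabolic Diseases", 43, 35, 8),
    ("Dyslipidemia", 41, 23, 18),
    ("Diabetes and Its Complications", 38, 28, 10),
    ("Fatty Liver Disease", 35, 29, 6),
    ("Cardiac Arrhythmias", 28, 23, 5),
    ("Renal Cysts", 23, 21, 2),
    ("Post PCI", 22, 18, 4),
    ("Renal Dysfunction", 18, 13, 5),
    ("Pulmonary Infections", 16, 11, 5),
    ("Hematologic Diseases", 15, 8, 7),
    ("Gastrointestinal Diseases", 15, 9, 6),
    ("Atherosclerosis and Stenotic", 15, 11, 4),
    ("Cerebral Infarction", 14, 9, 5),
    ("Gallbladder Diseases", 12, 8, 4),
    ("Tobacco dependence", 12, 12, 0),
    ("Myocardial Infarction (comorbid)", 11, 11, 0),
    ("Liver Cystic Lesions", 11, 10, 1),
    ("Skeletal Diseases", 10, 5, 5),
    ("Valvular Heart Diseases", 9, 7, 2),
]


def rows(category: Category | str) -> list[tuple[str, int, int, int]]:
    category = Category(category)
    return list(DIAGNOSIS_ROWS if category is Category.DIAGNOSIS else COMORBIDITY_ROWS)
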