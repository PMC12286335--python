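"""Printed summary counts from the published UK Biobank colorectal-cancer study.

The original analysis ran on controlled-access UK Biobank data, so its
participant-level inputs cannot ship here; what the publication does
print are cohort bookkeeping totals, per-category counts with
percentages (its cohort-description table) and per-covariate
significant-participant counts (its GWLR results table).  Those printed
counts and denominators are recorded below as plain data so that the
derived quantities — every percentage, and the case/control totals —
can be recomputed by this package's reporting rules and checked against
the printed values.

Only counts and denominators are stored; percentages are always
recomputed, never copied.
"""

from __future__ import annotations

COHORT_TOTALS = {
    "total": {"cases": 2_080, "controls": 8_062},
    "older": {"cases": 1_919, "controls": 7_368},   # age >= 50
    "younger": {"cases": 161, "controls": 694},      # age < 50
}

# Cohort-description table: categorical variables as {level: count} per dataset.
# Denominators are the dataset sizes (sum of cases + controls).
TABLE1_CATEGORICAL = {
    "older": {
        "sex": {"Female": 4_718, "Male": 4_569},
        "prs_group": {"Low PRS": 8_851, "High PRS": 436},
        "current_smoking": {"No": 8_609, "Yes": 678},
        "alcohol_daily": {"Non-daily": 6_838, "Daily": 2_449},
        "household_income": {"Above poverty line": 7_420, "Below poverty line": 1_867},
        "vehicles": {"Have cars": 8_777, "No car": 510},
        "maternal_smoking": {"No": 6_716, "Yes": 2_571},
        "education": {"University": 3_745, "Non-university": 5_542},
        "employment": {"Employed": 8_977, "Unemployed": 310},
    },
    "younger": {
        "sex": {"Female": 482, "Male": 373},
        "prs_group": {"Low PRS": 809, "High PRS": 46},
        "current_smoking": {"No": 761, "Yes": 94},
        "alcohol_daily": {"Non-daily": 706, "Daily": 149},
        "household_income": {"Above poverty line": 790, "Below poverty line": 65},
        "vehicles": {"Have cars": 807, "No car": 48},
        "maternal_smoking": {"No": 593, "Yes": 262},
        "education": {"University": 363, "Non-university": 492},
        "employment": {"Employed": 820, "Unemployed": 35},
    },
}

# Printed percentages for the same cells, used only as the comparison side
# of arithmetic-reproduction checks (never fed into any computation).
TABLE1_PRINTED_PERCENT = {
    "older": {
        "sex": {"Female": 50.8, "Male": 49.2},
        "prs_group": {"Low PRS": 95.3, "High PRS": 4.7},
        "current_smoking": {"No": 92.7, "Yes": 7.3},
        "alcohol_daily": {"Non-daily": 73.6, "Daily": 26.4},
        "household_income": {"Above poverty line": 79.9, "Below poverty line": 20.1},
        "vehicles": {"Have cars": 94.5, "No car": 5.5},
        "maternal_smoking": {"No": 72.3, "Yes": 27.7},
        "education": {"University": 40.3, "Non-university": 59.7},
        "employment": {"Employed": 96.7, "Unemployed": 3.3},
    },
    "younger": {
        "sex": {"Female": 56.4, "Male": 43.6},
        "prs_group": {"Low PRS": 94.6, "High PRS": 5.4},
        "current_smoking": {"No": 89.0, "Yes": 11.0},
        "alcohol_daily": {"Non-daily": 82.6, "Daily": 17.4},
        "household_income": {"Above poverty line": 92.4, "Below poverty line": 7.6},
        "vehicles": {"Have cars": 94.4, "No car": 5.6},
        "maternal_smoking": {"No": 69.4, "Yes": 30.6},
        "education": {"University": 42.5, "Non-university": 57.5},
        "employment": {"Employed": 95.9, "Unemployed": 4.1},
    },
}

# GWLR results table: per-covariate count of participants with a significant
# local odds ratio, with the printed proportion for the comparison side.
TABLE2_SIGNIFICANT = {
    "older": {
        "prs_group": {"count": 9_287, "printed_percent": 100.0},
        "employment": {"count": 9_286, "printed_percent": 99.9},
        "sex": {"count": 9_287, "printed_percent": 100.0},
        "alcohol_daily": {"count": 2_017, "printed_percent": 21.7},
        "age": {"count": 8_579, "printed_percent": 92.4},
        "bmi": {"count": 6_373, "printed_percent": 68.6},
    },
    "younger": {
        "prs_group": {"count": 855, "printed_percent": 100.0},
        "current_smoking": {"count": 104, "printed_percent": 12.2},
    },
}


def dataset_size(dataset: str) -> int:
    t = COHORT_TOTALS[dataset]
    return t["cases"] + t["controls"]
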