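"""Shared configuration for the numbered analysis drivers.

One synthetic study, fixed once: a UK-like cohort of 10,000 participants
clustered in five urban centres with 20-person shared-coordinate output
areas, a 140-variant risk panel, covariates mirroring the risk factors
the colorectal-cancer analysis adjusts for, and a polygenic-risk effect
whose log-odds surface peaks around one southern centre (odds ratio
rising from 2 towards 3+ near the peak) while the other covariate
effects are spatially flat.  Intermediate per-participant files go to
scratch/ (regenerable); the summary tables, model summary and map
exports land in results/.
"""

from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"

SEED = 73
N_PARTICIPANTS = 10_000
N_VARIANTS = 140
HIGH_PRS_FRACTION = 0.05

DOMAIN = (0.0, 1000.0)
# five "urban centres"; the PRS risk surface peaks around the southern one
CENTRES = np.array([
    [200.0, 850.0],
    [450.0, 700.0],
    [350.0, 450.0],
    [650.0, 350.0],
    [550.0, 120.0],
])
PRS_PEAK = (550.0, 120.0)

OA_GROUP_SIZE = 20
CENTRE_SPREAD = 40.0

# GWLR covariates, in the order they enter the model
COVARIATES = ["prs_high", "sex_male", "age", "bmi", "alcohol_daily", "smoking"]

DOSAGE_FILE = SCRATCH / "dosages.tsv"
VARIANT_FILE = SCRATCH / "risk_variants.txt"
PRS_FILE = SCRATCH / "prs.csv"
COHORT_FILE = SCRATCH / "cohort.csv"
MATCHED_FILE = SCRATCH / "matched_cohort.csv"
OLDER_FILE = SCRATCH / "dataset_older.csv"
YOUNGER_FILE = SCRATCH / "dataset_younger.csv"
FITS_FILE = SCRATCH / "gwlr_fits_older.csv"
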