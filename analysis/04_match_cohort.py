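"""Label cases, match controls 4:1 under the study constraints, split at age 50.

Cases are participants with a colorectal-cancer ICD-10 code; controls
are cancer-free participants within a 5-year age window living in the
same output area, up to four per case, each used once.  The matched
cohort is then split at age 50 into the older and younger datasets the
regression step analyses separately.
"""

from common import COHORT_FILE, MATCHED_FILE, OLDER_FILE, SEED, YOUNGER_FILE
from geoscreen import MatchSpec, label_cases, match_controls, split_by_age
from geoscreen.io import read_cohort_csv, write_cohort_csv


def main() -> None:
    cohort = label_cases(read_cohort_csv(COHORT_FILE))
    cases = cohort[cohort["y"] == 1]
    pool = cohort[(cohort["y"] == 0) & cohort["control_eligible"]]

    spec = MatchSpec(seed=SEED + 3)
    matched = match_controls(cases, pool, spec)
    write_cohort_csv(matched, MATCHED_FILE)

    n_cases = int((matched["y"] == 1).sum())
    n_ctrl = int((matched["y"] == 0).sum())
    print(f"{n_cases} cases, {n_ctrl} matched controls "
          f"({n_ctrl / n_cases:.2f} controls per case)")

    older, younger = split_by_age(matched, cutoff=50.0)
    write_cohort_csv(older, OLDER_FILE)
    write_cohort_csv(younger, YOUNGER_FILE)
    print(f"older dataset (age >= 50): {len(older)} participants "
          f"({int(older['y'].sum())} cases)")
    print(f"younger dataset (age < 50): {len(younger)} participants "
          f"({int(younger['y'].sum())} cases)")
    print(f"wrote {MATCHED_FILE}, {OLDER_FILE}, {YOUNGER_FILE}")


if __name__ == "__main__":
    main()
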