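"""Case labelling, constraint-based control matching and the age-50 split.

Cases are participants carrying a colorectal-cancer ICD-10 diagnosis
(C18.0-C18.9 colon, C19 rectosigmoid junction, C20 rectum, C26.0
intestinal tract unspecified).  Controls are cancer-free participants
matched to cases within a 5-year age window and, by default, living in
the same output area, at up to 4 controls per case sampled without
replacement.  The cohort is finally split at age 50 into an older
(age >= 50) and a younger (age < 50) dataset, reflecting the clinical
distinction between early-onset and late-onset colorectal cancer.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CRC_CASE_CODES

__all__ = ["MatchSpec", "label_cases", "match_controls", "split_by_age", "CRC_CASE_CODES"]

logger = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")


@dataclass
class MatchSpec:
    """Constraints for control matching."""

    case_codes: tuple[str, ...] = CRC_CASE_CODES
    age_window: float = 5.0
    require_same_area: bool = True
    controls_per_case: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_window < 0:
            raise ValueError("age_window must be >= 0")
        if self.controls_per_case < 1:
            raise ValueError("controls_per_case must be >= 1")


def _normalize_code(code) -> str:
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return ""
    return str(code).strip().upper()


def label_cases(
    cohort: pd.DataFrame, case_codes: tuple[str, ...] = CRC_CASE_CODES
) -> pd.DataFrame:
    """Derive ``y`` and ``control_eligible`` from the ``icd10_code`` column.

    ``y = 1`` iff the code is in the case set.  Rows with no diagnosis
    are control-eligible; rows carrying any other cancer code (C* or
    in-situ/uncertain D0*-D4*) are ineligible as controls, as are rows
    with malformed code strings (logged, never fatal).  Idempotent.
    """
    if "icd10_code" not in cohort.columns:
        raise ValueError("cohort lacks an icd10_code column")
    out = cohort.copy()
    codes = out["icd10_code"].map(_normalize_code)
    case_set = {c.upper() for c in case_codes}

    is_case = codes.isin(case_set)
    empty = codes == ""
    wellformed = codes.map(lambda c: bool(_CODE_RE.match(c)))
    malformed = ~empty & ~wellformed
    if malformed.any():
        bad = sorted(set(codes[malformed]))[:10]
        logger.warning("%d rows with malformed ICD-10 codes (e.g. %s); ineligible as controls",
                       int(malformed.sum()), bad)
    cancerous = wellformed & codes.map(
        lambda c: c.startswith("C") or bool(re.match(r"^D[0-4]", c))
    )
    out["y"] = is_case.astype(int)
    out["control_eligible"] = empty | (wellformed & ~cancerous & ~is_case)
    return out


def match_controls(
    cases: pd.DataFrame, pool: pd.DataFrame, spec: MatchSpec
) -> pd.DataFrame:
    """Greedy seeded 1:k control matching under age-window / same-area constraints.

    For each case (visited in randomized order) up to ``controls_per_case``
    controls are drawn uniformly without replacement from pool rows with
    ``|age_control - age_case| <= age_window`` and, when
    ``require_same_area``, the same ``area_id``.  Each control is used at
    most once globally.  Cases with no eligible control are retained with
    an empty match group and a logged warning, never dropped.  Returns
    cases plus matched controls with a ``match_group`` column.
    """
    if "control_eligible" in pool.columns and not pool["control_eligible"].all():
        raise ValueError("pool contains rows flagged ineligible as controls")
    rng = np.random.default_rng(spec.seed)

    pool = pool.reset_index(drop=True)
    pool_age = pool["age"].to_numpy(dtype=float)
    pool_area = pool["area_id"].to_numpy(dtype=object)
    used = np.zeros(len(pool), dtype=bool)

    case_order = rng.permutation(len(cases))
    case_rows = cases.reset_index(drop=True)

    picked_rows: list[pd.DataFrame] = []
    n_unmatched = 0
    for ci in case_order:
        case = case_rows.iloc[ci]
        ok = ~used & (np.abs(pool_age - float(case["age"])) <= spec.age_window)
        if spec.require_same_area:
            ok &= pool_area == case["area_id"]
        eligible = np.flatnonzero(ok)
        if eligible.size == 0:
            n_unmatched += 1
            continue
        take = rng.choice(eligible, size=min(spec.controls_per_case, eligible.size),
                          replace=False)
        used[take] = True
        sel = pool.iloc[np.sort(take)].copy()
        sel["match_group"] = case["participant_id"]
        picked_rows.append(sel)
    if n_unmatched:
        logger.warning("%d cases had zero eligible controls; retained unmatched", n_unmatched)

    out_cases = case_rows.copy()
    out_cases["match_group"] = out_cases["participant_id"]
    matched = pd.concat([out_cases] + picked_rows, ignore_index=True) if picked_rows else out_cases
    # deterministic output order regardless of the randomized matching order
    return matched.sort_values(["match_group", "y", "participant_id"],
                               ascending=[True, False, True]).reset_index(drop=True)


def split_by_age(cohort: pd.DataFrame, cutoff: float = 50.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (age >= cutoff, age < cutoff) tables."""
    if "age" not in cohort.columns:
        raise ValueError("cohort lacks an age column")
    older = cohort[cohort["age"] >= cutoff].reset_index(drop=True)
    younger = cohort[cohort["age"] < cutoff].reset_index(drop=True)
    return older, younger
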