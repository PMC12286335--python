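"""Independent oracles used by the tests, kept free of geoscreen internals."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize


def logistic_mle(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Numeric maximizer of the (weighted) Bernoulli log-likelihood.

    Deliberately independent of any IRLS code: plain BFGS on the
    negative log-likelihood with analytic gradient.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.ones(len(y)) if w is None else np.asarray(w, float)

    def nll(beta):
        eta = X @ beta
        return -(w * (y * eta - np.logaddexp(0.0, eta))).sum()

    def grad(beta):
        from scipy.special import expit

        return -X.T @ (w * (y - expit(X @ beta)))

    res = minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x


def verify_matching(matched: pd.DataFrame, spec) -> list[str]:
    """Brute-force re-check of every matching constraint; returns violations."""
    problems = []
    if matched["participant_id"].duplicated().any():
        problems.append("participant appears twice in matched output")
    cases = matched[matched["y"] == 1].set_index("participant_id")
    for gid, grp in matched.groupby("match_group"):
        ctrl = grp[grp["y"] == 0]
        if gid not in cases.index:
            problems.append(f"group {gid}: no case row")
            continue
        case = cases.loc[gid]
        if len(ctrl) > spec.controls_per_case:
            problems.append(f"group {gid}: {len(ctrl)} controls > ratio")
        for _, row in ctrl.iterrows():
            if abs(row["age"] - case["age"]) > spec.age_window:
                problems.append(f"group {gid}: control {row['participant_id']} outside age window")
            if spec.require_same_area and row["area_id"] != case["area_id"]:
                problems.append(f"group {gid}: control {row['participant_id']} from other area")
    return problems


def binomial_ci(n: int, p: float, level: float = 0.99) -> tuple[float, float]:
    """Exact central binomial interval for an observed proportion."""
    from scipy.stats import binom

    lo, hi = binom.interval(level, n, p)
    return lo / n, hi / n
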