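"""Geographically weighted logistic regression (GWLR) from first principles.

At each regression point i (taken to be each observation's location) a
logistic model

    logit P(y_j = 1) = beta_i0 + sum_k beta_ik x_jk

is fitted by maximizing the geographically weighted Bernoulli
log-likelihood  sum_j W_ij [ y_j eta_j - log(1 + exp(eta_j)) ],  where the
geographic weights come from the compact-support bi-square kernel

    W_ij = (1 - (d_ij / b)^2)^2   if d_ij < b,   else 0,

with d_ij the Euclidean distance between observations i and j and b the
bandwidth (a distance in fixed mode, a nearest-neighbour count in
adaptive mode).  Maximization is by iteratively reweighted least squares
(IRLS): each step solves the weighted-least-squares normal equations with
combined weights W_ij * mu_j (1 - mu_j) and the usual working response.
The coefficient covariance is the inverse weighted Fisher information at
convergence, giving local Wald z statistics, two-tailed p-values and odds
ratios exp(beta).

Model-level quantities follow the standard GWR conventions: the effective
number of parameters K is the trace of the hat matrix assembled from each
point's own fit (row i of S evaluated at observation i), the global
deviance stacks each observation's fitted probability from its own local
model, and bandwidths are chosen by minimizing the small-sample-corrected
AICc = deviance + 2K + 2K(K+1)/(n - K - 1) with a golden-section search.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "KernelSpec",
    "LocalFit",
    "GWLRResult",
    "bisquare_weight",
    "weight_vector",
    "local_logistic_fit",
    "fit_gwlr",
    "gwlr_aicc",
    "select_bandwidth",
    "local_inference",
]

logger = logging.getLogger(__name__)

_GEOGRAPHIC_NAMES = {"lat", "latitude", "lon", "lng", "long", "longitude"}


@dataclass(frozen=True)
class KernelSpec:
    """Bi-square kernel with a fixed (distance) or adaptive (k-NN) bandwidth."""

    bandwidth: float
    mode: str = "fixed"  # "fixed" | "adaptive"
    kind: str = "bisquare"

    def __post_init__(self) -> None:
        if self.kind != "bisquare":
            raise ValueError("only the bi-square kernel is supported")
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError("mode must be 'fixed' or 'adaptive'")
        if self.mode == "fixed" and not self.bandwidth > 0:
            raise ValueError("fixed bandwidth must be > 0")
        if self.mode == "adaptive" and int(self.bandwidth) < 2:
            raise ValueError("adaptive bandwidth (neighbour count) must be >= 2")


def bisquare_weight(d, b: float):
    """Bi-square weight (1 - (d/b)^2)^2 for d < b, 0 beyond the bandwidth."""
    if b <= 0:
        raise ValueError("bandwidth must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    w = np.where(d < b, (1.0 - (d / b) ** 2) ** 2, 0.0)
    return w if w.ndim else float(w)


def _adaptive_bandwidths(dist: np.ndarray, k: int) -> np.ndarray:
    """Per-point bandwidth = distance to the k-th nearest neighbour (excl. self)."""
    n = dist.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"adaptive neighbour count {k} must be in [1, n-1]")
    part = np.partition(dist, k, axis=1)  # column k = k-th NN excluding self (d_ii = 0)
    return part[:, k]


def weight_vector(points: np.ndarray, i: int, spec: KernelSpec) -> np.ndarray:
    """Kernel weights of every observation relative to regression point ``i``.

    Duplicate coordinates (shared output areas) get weight 1 relative to
    each other; weights vanish at and beyond the bandwidth.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("points must be an (n>=2, 2) coordinate array")
    d = np.sqrt(((pts - pts[i]) ** 2).sum(axis=1))
    if spec.mode == "adaptive":
        k = int(spec.bandwidth)
        b = float(np.partition(d, k)[k])
        if b <= 0:  # k-th neighbour coincides with i: degenerate duplicate pile
            b = np.finfo(float).tiny
    else:
        b = spec.bandwidth
    return np.asarray(bisquare_weight(d, b))


@dataclass
class LocalFit:
    """One regression point's local logistic fit."""

    location: tuple[float, float]
    names: list[str]
    beta: np.ndarray | None = None
    cov: np.ndarray | None = None
    converged: bool = False
    n_effective: float = 0.0
    leverage: float = np.nan  # S_ii, this point's diagonal hat-matrix entry
    mu_self: float = np.nan  # fitted probability at the point's own row
    n_iter: int = 0
    message: str = ""
    significant: np.ndarray | None = None

    @property
    def odds_ratios(self) -> np.ndarray | None:
        return None if self.beta is None else np.exp(self.beta)

    @property
    def se(self) -> np.ndarray | None:
        return None if self.cov is None else np.sqrt(np.diag(self.cov))

    @property
    def z(self) -> np.ndarray | None:
        se = self.se
        if self.beta is None or se is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / se

    @property
    def p_values(self) -> np.ndarray | None:
        z = self.z
        return None if z is None else 2.0 * norm.sf(np.abs(z))


_MAX_ETA = 30.0  # logistic link saturates well before this; guards overflow


def local_logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    location: tuple[float, float] = (np.nan, np.nan),
    names: list[str] | None = None,
    self_index: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LocalFit:
    """Weighted logistic fit by IRLS; never raises on degenerate subsamples.

    Rows with zero weight are dropped up front (they cannot influence the
    likelihood).  Rank deficiency on the positively weighted subsample or
    a single-class weighted outcome yields a non-estimable LocalFit
    (``converged=False``, empty coefficients) instead of an exception.
    ``self_index`` designates the row whose fitted probability and hat
    leverage are recorded for the model-level deviance and K.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    names = names or [f"b{k}" for k in range(X.shape[1])]
    fit = LocalFit(location=location, names=list(names), n_effective=float(w.sum()))

    pos = w > 0
    if self_index is not None and not pos[self_index]:
        pos = pos.copy()
        pos[self_index] = True  # keep the regression point itself in view
    Xs, ys, ws = X[pos], y[pos], w[pos]
    self_pos = int(np.flatnonzero(np.flatnonzero(pos) == self_index)[0]) if self_index is not None else None

    if ws @ ys <= 0 or ws @ (1 - ys) <= 0:
        fit.message = "single-class weighted outcome"
        return fit
    if np.linalg.matrix_rank(Xs * np.sqrt(ws)[:, None]) < X.shape[1]:
        fit.message = "rank-deficient design on weighted subsample"
        return fit

    p = X.shape[1]
    beta = np.zeros(p)
    info = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xs @ beta, -_MAX_ETA, _MAX_ETA)
        mu = expit(eta)
        v = mu * (1.0 - mu)
        cw = ws * v
        # working response for the logistic IRLS step
        z = eta + (ys - mu) / np.maximum(v, 1e-12)
        XtW = Xs.T * cw
        info = XtW @ Xs
        try:
            new_beta = np.linalg.solve(info, XtW @ z)
        except np.linalg.LinAlgError:
            fit.beta = None
            fit.message = "singular weighted information matrix"
            return fit
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if step < tol:
            converged = True
            break

    fit.n_iter = it
    fit.beta = beta
    fit.converged = converged
    if not converged:
        fit.message = f"IRLS did not converge in {max_iter} iterations"
    try:
        fit.cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        fit.cov = None
        fit.converged = False
        fit.message = "singular Fisher information at the last iterate"
        return fit

    if self_pos is not None:
        eta = np.clip(Xs @ beta, -_MAX_ETA, _MAX_ETA)
        mu = expit(eta)
        v = mu * (1.0 - mu)
        cw = ws * v
        xi = Xs[self_pos]
        # row i of the working-response hat matrix S = X (X'CX)^-1 X'C
        fit.leverage = float(xi @ fit.cov @ (xi * cw[self_pos]))
        fit.mu_self = float(mu[self_pos])
    return fit


def local_inference(fit: LocalFit, alpha: float = 0.05) -> LocalFit:
    """Annotate a fit with per-covariate significance flags (two-tailed Wald).

    Significance requires a converged fit and p strictly below alpha.
    """
    if not fit.converged or fit.p_values is None:
        fit.significant = np.zeros(len(fit.names), dtype=bool)
        if not fit.message:
            fit.message = "not converged; significance flags forced false"
        return fit
    fit.significant = fit.p_values < alpha
    return fit


@dataclass
class GWLRResult:
    """All local fits plus model-level bandwidth, AICc and effective parameters."""

    fits: list[LocalFit]
    kernel: KernelSpec
    names: list[str]
    effective_params: float
    global_deviance: float
    n_fitted: int
    aicc: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        """Per-participant tidy table: location, beta/OR/p/significant per term."""
        rows = []
        for f in self.fits:
            row: dict = {"x_coord": f.location[0], "y_coord": f.location[1],
                         "converged": f.converged, "n_effective": f.n_effective}
            beta = f.beta if f.beta is not None else [np.nan] * len(self.names)
            ors = f.odds_ratios if f.beta is not None else [np.nan] * len(self.names)
            ps = f.p_values if f.p_values is not None else [np.nan] * len(self.names)
            sig = f.significant if f.significant is not None else [False] * len(self.names)
            for k, name in enumerate(self.names):
                row[f"beta_{name}"] = beta[k]
                row[f"or_{name}"] = ors[k]
                row[f"p_{name}"] = ps[k]
                row[f"significant_{name}"] = bool(sig[k])
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "kernel": self.kernel.kind,
            "mode": self.kernel.mode,
            "bandwidth": float(self.kernel.bandwidth),
            "aicc": float(self.aicc),
            "effective_params": float(self.effective_params),
            "global_deviance": float(self.global_deviance),
            "n_fitted": int(self.n_fitted),
            "n_points": len(self.fits),
        }


def _design(data: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValueError(f"covariates absent from data: {missing}")
    X = data[covariates].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite numeric/binary-encoded values")
    X = np.column_stack([np.ones(len(data)), X])
    y = data["y"].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome y must be binary 0/1")
    return X, y, ["intercept"] + list(covariates)


def _coords(data: pd.DataFrame, x_col: str, y_col: str) -> np.ndarray:
    for col in (x_col, y_col):
        if col.lower() in _GEOGRAPHIC_NAMES:
            raise ValueError(
                f"coordinate column {col!r} looks geographic (lat/lon); project to a "
                "planar CRS first — kernel distances are Euclidean"
            )
    pts = data[[x_col, y_col]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    if np.unique(pts, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct coordinate locations")
    return pts


def fit_gwlr(
    data: pd.DataFrame,
    covariates: list[str],
    spec: KernelSpec,
    x_col: str = "x_coord",
    y_col: str = "y_coord",
    alpha: float = 0.05,
) -> GWLRResult:
    """Fit one local logistic model per observation location.

    Regression points are the observation locations themselves (the
    analysis reports per-participant odds ratios).  Per-point failures
    (separation, rank deficiency) are recorded on the LocalFit and
    excluded from the model-level deviance/K, never fatal.
    """
    X, y, names = _design(data, covariates)
    pts = _coords(data, x_col, y_col)
    n = len(data)
    dist = cdist(pts, pts)

    if spec.mode == "adaptive":
        k = int(spec.bandwidth)
        if k < X.shape[1] + 2:
            raise ValueError(
                f"adaptive neighbour count {k} must be >= number of parameters + 2 "
                f"(= {X.shape[1] + 2})"
            )
        bands = _adaptive_bandwidths(dist, k)
    else:
        bands = np.full(n, float(spec.bandwidth))

    fits: list[LocalFit] = []
    K = 0.0
    dev = 0.0
    n_fitted = 0
    for i in range(n):
        w = bisquare_weight(dist[i], max(bands[i], np.finfo(float).tiny))
        fit = local_logistic_fit(
            X, y, np.asarray(w), location=(pts[i, 0], pts[i, 1]), names=names,
            self_index=i,
        )
        local_inference(fit, alpha=alpha)
        fits.append(fit)
        if fit.converged and np.isfinite(fit.leverage):
            K += fit.leverage
            mu = min(max(fit.mu_self, 1e-12), 1 - 1e-12)
            dev += -2.0 * (y[i] * math.log(mu) + (1 - y[i]) * math.log(1 - mu))
            n_fitted += 1
    result = GWLRResult(
        fits=fits, kernel=spec, names=names, effective_params=K,
        global_deviance=dev, n_fitted=n_fitted,
    )
    result.aicc = gwlr_aicc(result)
    return result


def gwlr_aicc(result: GWLRResult) -> float:
    """Small-sample-corrected AIC: deviance + 2K + 2K(K+1)/(n - K - 1).

    Returns +inf (bandwidth rejected) when the correction denominator
    n - K - 1 is not positive or when no point could be fitted.
    """
    n = result.n_fitted
    K = result.effective_params
    if n == 0 or n - K - 1 <= 0:
        return float("inf")
    return result.global_deviance + 2.0 * K + 2.0 * K * (K + 1.0) / (n - K - 1.0)


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def select_bandwidth(
    data: pd.DataFrame,
    covariates: list[str],
    mode: str = "fixed",
    x_col: str = "x_coord",
    y_col: str = "y_coord",
    rel_tol: float = 1e-2,
) -> tuple[KernelSpec, list[tuple[float, float]]]:
    """Golden-section AICc minimization over the bandwidth.

    Fixed mode searches distances in [lower, upper] where ``lower`` is the
    smallest bandwidth under which every point's kernel strictly covers at
    least m+2 neighbours and ``upper`` is twice the maximum pairwise
    distance; adaptive mode searches neighbour counts in [m+2, n-1].
    Ties within tolerance resolve toward the larger (smoother) bandwidth.
    Returns the minimizing KernelSpec plus the (bandwidth, AICc) search
    trace.
    """
    X, _, _ = _design(data, covariates)
    pts = _coords(data, x_col, y_col)
    n = len(data)
    m_plus = X.shape[1]  # parameters incl. intercept
    dist = cdist(pts, pts)

    cache: dict[float, float] = {}

    def objective(b: float) -> float:
        if b in cache:
            return cache[b]
        spec = KernelSpec(bandwidth=b, mode=mode)
        val = fit_gwlr(data, covariates, spec, x_col=x_col, y_col=y_col).aicc
        cache[b] = val
        return val

    if mode == "fixed":
        kth = _adaptive_bandwidths(dist, min(m_plus + 2, n - 1))
        lower = float(kth.max()) * (1.0 + 1e-6)  # strictly cover the (m+2)-th NN
        upper = 2.0 * float(dist.max())
        if not upper > lower:
            upper = lower * 2.0
        snap = None
    elif mode == "adaptive":
        lower, upper = float(m_plus + 2), float(n - 1)
        snap = round
    else:
        raise ValueError("mode must be 'fixed' or 'adaptive'")

    def crop(b: float) -> float:
        return float(snap(b)) if snap else float(b)

    trace: list[tuple[float, float]] = []

    def f(b: float) -> float:
        b = crop(b)
        val = objective(b)
        trace.append((b, val))
        return val

    a, d = lower, upper
    tol = rel_tol * (upper - lower)
    b1 = d - _GOLDEN * (d - a)
    b2 = a + _GOLDEN * (d - a)
    f1, f2 = f(b1), f(b2)
    while d - a > tol:
        if f1 > f2:  # ties (f1 == f2) keep the upper sub-interval: smoother model
            a, b1, f1 = b1, b2, f2
            b2 = a + _GOLDEN * (d - a)
            f2 = f(b2)
        else:
            d, b2, f2 = b2, b1, f1
            b1 = d - _GOLDEN * (d - a)
            f1 = f(b1)
    best = crop(b2 if f2 <= f1 else b1)
    best_val = objective(best)
    if not math.isfinite(best_val):
        finite = [(b, v) for b, v in trace if math.isfinite(v)]
        if not finite:
            raise ValueError(
                "AICc is non-finite across the whole bandwidth range; "
                "try adaptive mode"
            )
        best, best_val = max(finite, key=lambda t: (-t[1], t[0]))
    return KernelSpec(bandwidth=best, mode=mode), trace
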