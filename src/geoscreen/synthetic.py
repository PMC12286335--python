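"""Synthetic spatially referenced case-control cohorts and genotype dosages.

The generator emulates the statistical structure a geographically weighted
logistic regression (GWLR) case-control analysis assumes: participants
clustered around urban centres, small shared-coordinate "output areas"
(the smallest UK census geography, here emulated by exact coordinate
duplication), mixed continuous/binary covariates, spatially varying
log-odds coefficient surfaces, and Bernoulli outcomes through a logistic
link.  Ground-truth coefficient surfaces are first-class objects so that
downstream parameter-recovery tests can compare estimates against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CoefficientSurface",
    "CovariateSpec",
    "SyntheticCohortSpec",
    "SyntheticGenotypeSpec",
    "simulate_cohort",
    "simulate_genotypes",
    "true_surface_at",
]

SURFACE_FAMILIES = ("constant", "linear-gradient", "gaussian-bump", "two-cluster-step")


@dataclass(frozen=True)
class CoefficientSurface:
    """A deterministic map (x, y) -> coefficient value, with a named family.

    Families
    --------
    constant
        ``beta(x, y) = value`` everywhere.
    linear-gradient
        ``beta(x, y) = base + slope_x * x + slope_y * y``.
    gaussian-bump
        ``beta(x, y) = base + amplitude * exp(-r^2 / (2 * width^2))`` with
        ``r`` the distance to ``centre``; bounded by ``base +/- |amplitude|``.
    two-cluster-step
        ``beta = level_a`` at points nearer ``centre_a`` than ``centre_b``,
        else ``level_b`` (ties go to A); a discontinuous surface.
    """

    variable_name: str
    family: str
    evaluator: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if self.family not in SURFACE_FAMILIES:
            raise ValueError(
                f"unknown surface family {self.family!r}; expected one of {SURFACE_FAMILIES}"
            )

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.asarray(self.evaluator(x, y), dtype=float)
        return np.broadcast_to(out, x.shape).copy()

    @classmethod
    def constant(cls, name: str, value: float) -> "CoefficientSurface":
        v = float(value)
        return cls(name, "constant", lambda x, y: np.full_like(np.asarray(x, float), v))

    @classmethod
    def linear_gradient(
        cls, name: str, slope_x: float = 0.0, slope_y: float = 0.0, base: float = 0.0
    ) -> "CoefficientSurface":
        return cls(
            name,
            "linear-gradient",
            lambda x, y: base + slope_x * np.asarray(x, float) + slope_y * np.asarray(y, float),
        )

    @classmethod
    def gaussian_bump(
        cls,
        name: str,
        amplitude: float,
        centre: tuple[float, float],
        width: float,
        base: float = 0.0,
    ) -> "CoefficientSurface":
        if width <= 0:
            raise ValueError("gaussian-bump width must be positive")
        cx, cy = centre

        def ev(x, y):
            r2 = (np.asarray(x, float) - cx) ** 2 + (np.asarray(y, float) - cy) ** 2
            return base + amplitude * np.exp(-r2 / (2.0 * width**2))

        return cls(name, "gaussian-bump", ev)

    @classmethod
    def two_cluster_step(
        cls,
        name: str,
        level_a: float,
        level_b: float,
        centre_a: tuple[float, float],
        centre_b: tuple[float, float],
    ) -> "CoefficientSurface":
        ax, ay = centre_a
        bx, by = centre_b

        def ev(x, y):
            x = np.asarray(x, float)
            y = np.asarray(y, float)
            da = (x - ax) ** 2 + (y - ay) ** 2
            db = (x - bx) ** 2 + (y - by) ** 2
            return np.where(da <= db, level_a, level_b)

        return cls(name, "two-cluster-step", ev)


def true_surface_at(
    surface: CoefficientSurface, points: Sequence[tuple[float, float]] | np.ndarray
) -> np.ndarray:
    """Evaluate a coefficient surface at each (x, y) point; returns a vector."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar coordinates")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return surface(pts[:, 0], pts[:, 1])


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: name plus sampling distribution.

    distribution: ``("bernoulli", p)``, ``("normal", mu, sd)``,
    ``("uniform", lo, hi)``, or ``("given", values)`` to inject an
    externally computed per-participant value (e.g. a polygenic score
    derived from simulated genotypes).
    """

    name: str
    distribution: tuple

    def validate(self) -> None:
        kind, *params = self.distribution
        if kind == "given":
            (values,) = params
            if not np.all(np.isfinite(np.asarray(values, dtype=float))):
                raise ValueError(f"covariate {self.name!r}: given values must be finite")
        elif kind == "bernoulli":
            (p,) = params
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"covariate {self.name!r}: bernoulli p={p} outside [0, 1]")
        elif kind == "normal":
            _, sd = params
            if sd <= 0:
                raise ValueError(f"covariate {self.name!r}: normal sd={sd} must be > 0")
        elif kind == "uniform":
            lo, hi = params
            if not lo < hi:
                raise ValueError(f"covariate {self.name!r}: uniform requires lo < hi")
        else:
            raise ValueError(f"covariate {self.name!r}: unknown distribution {kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        kind, *params = self.distribution
        if kind == "given":
            vals = np.asarray(params[0], dtype=float)
            if vals.shape != (n,):
                raise ValueError(
                    f"covariate {self.name!r}: given values have length {vals.size}, "
                    f"cohort needs {n}"
                )
            return vals.copy()
        if kind == "bernoulli":
            return rng.binomial(1, params[0], size=n).astype(float)
        if kind == "normal":
            return rng.normal(params[0], params[1], size=n)
        return rng.uniform(params[0], params[1], size=n)


@dataclass
class SyntheticCohortSpec:
    """Recipe for a spatially clustered synthetic case-control cohort.

    Participants are scattered around ``n_centres`` urban centres
    (Gaussian scatter with sd ``centre_spread``, in arbitrary planar
    units — GWLR only consumes Euclidean distances, so no CRS is
    attached).  Within each centre, consecutive blocks of
    ``oa_group_size`` participants form an output area: they share one
    exact coordinate (set ``jitter_within_oa=True`` to keep per-person
    coordinates instead).  ``surfaces`` must contain an ``"intercept"``
    surface plus exactly one surface per covariate.
    """

    n_participants: int
    surfaces: list[CoefficientSurface]
    covariate_specs: list[CovariateSpec] = field(default_factory=list)
    n_centres: int = 5
    centre_spread: float = 10.0
    oa_group_size: int = 5
    domain: tuple[float, float] = (0.0, 1000.0)
    jitter_within_oa: bool = False
    centres: np.ndarray | None = None  # optional explicit (n_centres, 2) locations
    assign_icd10: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_centres < 1:
            raise ValueError("n_centres must be >= 1")
        if self.oa_group_size < 1:
            raise ValueError("oa_group_size must be >= 1")
        for cov in self.covariate_specs:
            cov.validate()
        names = [s.variable_name for s in self.surfaces]
        expected = ["intercept"] + [c.name for c in self.covariate_specs]
        if sorted(names) != sorted(expected):
            raise ValueError(
                f"surfaces {names} must be exactly intercept + one per covariate {expected}"
            )


# ICD-10 codes defining colorectal cancer cases: colon (C18.0-C18.9),
# rectosigmoid junction (C19), rectum (C20), intestinal tract unspecified (C26.0).
CRC_CASE_CODES = tuple(
    [f"C18.{i}" for i in range(10)] + ["C19", "C20", "C26.0"]
)


def simulate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a cohort table from the spec's spatial logistic model.

    The outcome follows ``y ~ Bernoulli(expit(eta))`` with the local linear
    predictor ``eta(x, y) = beta_0(x, y) + sum_k beta_k(x, y) * x_k``
    evaluated at each participant's coordinates.  Returns one row per
    participant with columns ``participant_id, y, x_coord, y_coord,
    area_id, centre_id, true_eta, <covariates...>`` (plus ``age``/``sex``
    if supplied as covariates, and ``icd10_code`` when
    ``spec.assign_icd10``).  Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    lo, hi = spec.domain
    if spec.centres is not None:
        centres = np.asarray(spec.centres, dtype=float)
        if centres.shape != (spec.n_centres, 2):
            raise ValueError("centres must have shape (n_centres, 2)")
    else:
        centres = rng.uniform(lo, hi, size=(spec.n_centres, 2))

    centre_id = rng.integers(0, spec.n_centres, size=n)
    # sort by centre so that OA blocks never straddle two centres
    centre_id = np.sort(centre_id)

    coords = np.empty((n, 2))
    area_ids = np.empty(n, dtype=object)
    g = 0
    for c in range(spec.n_centres):
        idx = np.flatnonzero(centre_id == c)
        for start in range(0, idx.size, spec.oa_group_size):
            block = idx[start : start + spec.oa_group_size]
            anchor = centres[c] + rng.normal(0.0, spec.centre_spread, size=2)
            if spec.jitter_within_oa:
                coords[block] = anchor + rng.normal(
                    0.0, spec.centre_spread / 10.0, size=(block.size, 2)
                )
            else:
                coords[block] = anchor
            area_ids[block] = f"OA{g:06d}"
            g += 1

    cov_values = {c.name: c.sample(rng, n) for c in spec.covariate_specs}
    surf_by_name = {s.variable_name: s for s in spec.surfaces}
    eta = surf_by_name["intercept"](coords[:, 0], coords[:, 1])
    for c in spec.covariate_specs:
        eta = eta + surf_by_name[c.name](coords[:, 0], coords[:, 1]) * cov_values[c.name]

    y = rng.binomial(1, expit(eta)).astype(int)

    out = pd.DataFrame(
        {
            "participant_id": [f"P{i:06d}" for i in range(n)],
            "y": y,
            "x_coord": coords[:, 0],
            "y_coord": coords[:, 1],
            "area_id": area_ids,
            "centre_id": centre_id,
            "true_eta": eta,
        }
    )
    for name, vals in cov_values.items():
        out[name] = vals
    if spec.assign_icd10:
        codes = np.asarray(CRC_CASE_CODES, dtype=object)
        out["icd10_code"] = ""
        out.loc[out["y"] == 1, "icd10_code"] = rng.choice(codes, size=int(y.sum()))
    return out


@dataclass
class SyntheticGenotypeSpec:
    """Recipe for a dosage matrix over independent risk variants.

    Defaults to 140 variants, the size of the colorectal-cancer
    risk-SNP panel the polygenic score is built from.  ``hard-call``
    mode draws genotypes Binomial(2, freq); ``dosage`` mode perturbs
    the hard call with truncated-normal noise (sd 0.1) clipped to
    [0, 2], mimicking imputation dosages.
    """

    n_variants: int = 140
    allele_freqs: np.ndarray | float = 0.3
    dosage_mode: str = "hard-call"  # or "dosage"
    seed: int = 0

    def freqs(self) -> np.ndarray:
        f = np.asarray(self.allele_freqs, dtype=float)
        if f.ndim == 0:
            f = np.full(self.n_variants, float(f))
        if f.shape != (self.n_variants,):
            raise ValueError("allele_freqs length must equal n_variants")
        if np.any((f <= 0) | (f >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        return f


def simulate_genotypes(spec: SyntheticGenotypeSpec, n_samples: int) -> pd.DataFrame:
    """Sample an ``n_samples x n_variants`` dosage matrix.

    Rows are sample ids ``S...``, columns variant ids ``rs...``; every
    entry lies in [0, 2] and hard-call mode emits only {0, 1, 2}.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if spec.dosage_mode not in ("hard-call", "dosage"):
        raise ValueError(f"unknown dosage_mode {spec.dosage_mode!r}")
    freqs = spec.freqs()
    rng = np.random.default_rng(spec.seed)
    hard = rng.binomial(2, freqs, size=(n_samples, spec.n_variants)).astype(float)
    if spec.dosage_mode == "dosage":
        dos = np.clip(hard + rng.normal(0.0, 0.1, size=hard.shape), 0.0, 2.0)
    else:
        dos = hard
    return pd.DataFrame(
        dos,
        index=pd.Index([f"S{i:06d}" for i in range(n_samples)], name="sample_id"),
        columns=[f"rs{j + 1}" for j in range(spec.n_variants)],
    )
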