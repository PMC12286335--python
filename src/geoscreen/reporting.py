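"""Summary surfaces: cohort description, per-variable OR summaries, region maps.

Reproduces the three reporting layers of the analysis: a cohort summary
table (medians with ranges for continuous variables, counts with
percentages for categorical ones), per-covariate odds-ratio ranges and
significant-participant proportions from a GWLR fit, and per-region
median-OR aggregation exported as GeoJSON choropleth data.

Conventions (the printed tables do not state theirs, so ours are fixed
and documented): percentages round half-up to one decimal; the median of
an even count is the mean of the central pair; OR class bands are
lower-open/upper-closed ((2.0, 3.0]) so each value falls in exactly one
band; a boundary point belongs to the first region whose geometry covers
it, in feature order.
"""

from __future__ import annotations

import json
import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from shapely.geometry import Point, mapping, shape
from shapely.strtree import STRtree

from .gwlr import GWLRResult

__all__ = [
    "round_half_up",
    "summarize_cohort",
    "summarize_variables",
    "median_or_by_region",
    "or_band",
    "export_choropleth",
    "load_regions",
    "write_regions",
]

UNASSIGNED = "unassigned"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Printed percentage of a count: half-up rounding, with 100 reserved.

    A proportion that rounds up to exactly 100% while ``count < total``
    is reported one display unit below (99.9 at one decimal), so that a
    printed "100" always means every participant — the convention the
    published summary tables follow.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    pct = round_half_up(100.0 * count / total, ndigits)
    if pct == 100.0 and count < total:
        pct = round_half_up(100.0 - 10.0 ** (-ndigits), ndigits)
    return pct


def summarize_cohort(
    cohort: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Cohort description table.

    Continuous variables are summarized as median (min-max), categorical
    ones as count (percent of column total).  When the variable lists are
    omitted, numeric columns with more than 10 distinct values are
    treated as continuous and the rest as categorical; ids and
    coordinates are never summarized.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    skip = {"participant_id", "x_coord", "y_coord", "area_id", "centre_id",
            "true_eta", "icd10_code", "match_group"}
    if continuous is None and categorical is None:
        continuous, categorical = [], []
        for col in cohort.columns:
            if col in skip:
                continue
            if pd.api.types.is_numeric_dtype(cohort[col]) and cohort[col].nunique() > 10:
                continuous.append(col)
            else:
                categorical.append(col)
    continuous = continuous or []
    categorical = categorical or []

    rows = []
    for col in continuous:
        v = cohort[col].astype(float)
        med, lo, hi = float(v.median()), float(v.min()), float(v.max())
        rows.append({"variable": col, "level": "", "kind": "continuous",
                     "median": med, "min": lo, "max": hi,
                     "count": np.nan, "percent": np.nan,
                     "display": f"{round_half_up(med, 2):g} ({round_half_up(lo, 2):g}-{round_half_up(hi, 2):g})"})
    for col in categorical:
        counts = cohort[col].value_counts(dropna=False)
        total = int(counts.sum())
        for level, cnt in counts.sort_index().items():
            pct = percent(int(cnt), total)
            rows.append({"variable": col, "level": str(level), "kind": "categorical",
                         "median": np.nan, "min": np.nan, "max": np.nan,
                         "count": int(cnt), "percent": pct,
                         "display": f"{int(cnt):,} ({pct})"})
    return pd.DataFrame(rows)


def _fits_frame(result) -> pd.DataFrame:
    return result.to_frame() if isinstance(result, GWLRResult) else result


def summarize_variables(result, alpha: float = 0.05, include_intercept: bool = False) -> pd.DataFrame:
    """Per-covariate OR range/median over significant participants.

    The significant proportion divides the number of participants whose
    local coefficient has a two-tailed Wald p below ``alpha`` by the
    total number of participants in the fit (non-converged points stay
    in the denominator as non-significant).  Covariates with zero
    significant participants get missing OR statistics, the printed
    tables' "-" convention.
    """
    frame = _fits_frame(result)
    variables = sorted(
        {c[len("or_"):] for c in frame.columns if c.startswith("or_")}
    )
    if not include_intercept:
        variables = [v for v in variables if v != "intercept"]
    total = len(frame)
    rows = []
    for var in variables:
        sig = frame[f"significant_{var}"].fillna(False).astype(bool)
        if f"p_{var}" in frame:  # recompute against the requested alpha
            sig = frame[f"p_{var}"].lt(alpha).fillna(False) & frame["converged"]
        ors = frame.loc[sig, f"or_{var}"].astype(float)
        count = int(sig.sum())
        rows.append({
            "variable": var,
            "or_min": float(ors.min()) if count else np.nan,
            "or_max": float(ors.max()) if count else np.nan,
            "or_median": float(ors.median()) if count else np.nan,
            "significant_count": count,
            "total": total,
            "significant_percent": percent(count, total),
        })
    return pd.DataFrame(rows)


def load_regions(path) -> list[tuple[str, object]]:
    """Read region polygons from a GeoJSON FeatureCollection.

    Returns (region_id, shapely geometry) pairs in feature order; the id
    comes from the feature's ``id`` or its properties' ``region_id``/
    ``id``/``name``, falling back to the feature index.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    out = []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        rid = feat.get("id") or props.get("region_id") or props.get("id") or props.get("name")
        out.append((str(rid) if rid is not None else f"region_{k}", shape(feat["geometry"])))
    return out


def median_or_by_region(
    result,
    regions: list[tuple[str, object]],
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-region, per-variable median of participant-level odds ratios.

    Participants are assigned by point-in-polygon (``covers``, so
    boundary points belong to a region; overlaps resolve to the first
    matching feature in order).  Participants outside every polygon go
    to a catch-all 'unassigned' region with a warning.  Every region is
    emitted, empty ones with missing medians rather than zeros.
    """
    frame = _fits_frame(result)
    if variables is None:
        variables = sorted({c[len("or_"):] for c in frame.columns if c.startswith("or_")}
                           - {"intercept"})
    geoms = [g for _, g in regions]
    tree = STRtree(geoms)
    assign = np.full(len(frame), -1, dtype=int)
    pts = [Point(x, y) for x, y in zip(frame["x_coord"], frame["y_coord"])]
    for i, pt in enumerate(pts):
        cands = sorted(tree.query(pt, predicate="covered_by"))
        if len(cands):
            assign[i] = cands[0]
    n_out = int((assign == -1).sum())
    if n_out:
        warnings.warn(f"{n_out} participants fall outside every region polygon; "
                      f"assigned to '{UNASSIGNED}'")

    rows = []
    ids = [rid for rid, _ in regions]
    for j, rid in enumerate(ids + ([UNASSIGNED] if n_out else [])):
        mask = assign == (j if j < len(ids) else -1)
        sub = frame.loc[mask]
        row = {"region_id": rid, "participant_count": int(mask.sum())}
        for var in variables:
            vals = sub[f"or_{var}"].astype(float).dropna()
            row[f"median_or_{var}"] = float(vals.median()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# Choropleth class bands, lower-open/upper-closed so 3.0 sits in "2.0<OR<=3.0".
_BANDS = [
    (-np.inf, 1.0, "OR<=1.0"),
    (1.0, 2.0, "1.0<OR<=2.0"),
    (2.0, 3.0, "2.0<OR<=3.0"),
    (3.0, np.inf, "OR>3.0"),
]


def or_band(value: float) -> str | None:
    """Class band for a median OR; None for missing."""
    if value is None or not np.isfinite(value):
        return None
    for lo, hi, label in _BANDS:
        if lo < value <= hi:
            return label
    return None  # pragma: no cover


def export_choropleth(
    summaries: pd.DataFrame,
    regions: list[tuple[str, object]],
    variable: str,
    out_geojson,
    out_csv=None,
) -> dict:
    """Write per-region median ORs for one variable as GeoJSON (+ CSV twin).

    Each feature carries the region geometry with ``region_id``,
    ``median_or``, ``band`` and ``participant_count`` properties; empty
    regions get a null OR.  Returns the FeatureCollection dict.
    """
    col = f"median_or_{variable}"
    if col not in summaries.columns:
        avail = [c[len("median_or_"):] for c in summaries.columns if c.startswith("median_or_")]
        raise KeyError(f"unknown variable {variable!r}; available: {avail}")
    by_id = summaries.set_index("region_id")
    feats = []
    for rid, geom in regions:
        if rid in by_id.index:
            val = by_id.loc[rid, col]
            cnt = int(by_id.loc[rid, "participant_count"])
        else:
            val, cnt = np.nan, 0
        val_out = float(val) if np.isfinite(val) else None
        feats.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {
                "region_id": rid,
                "variable": variable,
                "median_or": val_out,
                "band": or_band(val),
                "participant_count": cnt,
                "band_convention": "lower-open, upper-closed",
            },
        })
    collection = {"type": "FeatureCollection", "features": feats}
    with open(out_geojson, "w") as fh:
        json.dump(collection, fh, indent=1)
    if out_csv is not None:
        cols = ["region_id", "participant_count", col]
        twin = summaries[cols].copy()
        twin["band"] = twin[col].map(or_band)
        twin.to_csv(out_csv, index=False)
    return collection


def write_regions(regions: list[tuple[str, object]], path) -> None:
    """Write (region_id, geometry) pairs as a plain GeoJSON FeatureCollection."""
    feats = [
        {"type": "Feature", "geometry": mapping(geom),
         "properties": {"region_id": rid}}
        for rid, geom in regions
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
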