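"""Environmental annotation of at-sea locations and habitat classification.

Each GPS location is annotated with gridded covariates by nearest-cell
lookup: daily variables are matched to the location's calendar date,
chlorophyll-a to its calendar month (ocean-colour products are too
cloud-gappy for daily matching), and depth spatially only. Locations on
land (per the land mask) are flagged and excluded from at-sea habitat
analysis; locations outside the raster extent get all covariates
missing-flagged — nothing is silently imputed.

Group membership (species-by-sex) is classified from the covariates with a
random forest; the report carries out-of-bag overall and per-class error
and mean-decrease-in-Gini variable importance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import ENV_VARIABLES, EnvironmentalFieldSet
from .tracks import _nearest_index

__all__ = [
    "ClassifierReport",
    "extract_environment",
    "completeness_report",
    "collinearity_screen",
    "classify_groups",
]


def _time_index(coord: pd.DatetimeIndex, wanted: pd.DatetimeIndex) -> np.ndarray:
    """Index of each wanted time in the coordinate; -1 when absent."""
    lookup = {t: i for i, t in enumerate(coord)}
    return np.array([lookup.get(t, -1) for t in wanted], dtype=int)


def extract_environment(
    locations: pd.DataFrame, fields: EnvironmentalFieldSet
) -> pd.DataFrame:
    """Annotate locations (columns: lon, lat, timestamp, plus any metadata)
    with the seven environmental covariates and per-covariate missing
    flags, plus an ``on_land`` flag from the land mask."""
    out = locations.reset_index(drop=True).copy()
    ds = fields.data
    lat = np.asarray(ds["lat"].values, dtype=float)
    lon = np.asarray(ds["lon"].values, dtype=float)
    ilat = _nearest_index(lat, out["lat"].to_numpy(dtype=float))
    ilon = _nearest_index(lon, out["lon"].to_numpy(dtype=float))
    inside = (ilat >= 0) & (ilon >= 0)
    ts = pd.to_datetime(out["timestamp"])
    days = ts.dt.normalize()
    months = ts.dt.to_period("M").dt.to_timestamp()
    iday = _time_index(pd.DatetimeIndex(ds["time"].values), pd.DatetimeIndex(days))
    imonth = _time_index(pd.DatetimeIndex(ds["time_month"].values), pd.DatetimeIndex(months))

    ilat_c = np.clip(ilat, 0, len(lat) - 1)
    ilon_c = np.clip(ilon, 0, len(lon) - 1)
    for var in ENV_VARIABLES:
        res = fields.temporal_resolution[var]
        arr = np.asarray(ds[var].values)
        if res == "static":
            vals = arr[ilat_c, ilon_c]
            ok = inside
        else:
            it = iday if res == "daily" else imonth
            vals = arr[np.clip(it, 0, arr.shape[0] - 1), ilat_c, ilon_c]
            ok = inside & (it >= 0)
        out[var] = np.where(ok, vals, np.nan)
        out[f"{var}_missing"] = ~ok
    land = np.asarray(fields.land_mask.values, dtype=bool)
    out["on_land"] = np.where(inside, land[ilat_c, ilon_c], False)
    out["outside_extent"] = ~inside
    return out


def completeness_report(annotated: pd.DataFrame) -> pd.Series:
    """Per-covariate count of missing-flagged locations."""
    cols = [c for c in annotated.columns if c.endswith("_missing")]
    rep = annotated[cols].sum()
    rep.index = [c.removesuffix("_missing") for c in cols]
    return rep.astype(int)


def collinearity_screen(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    threshold: float = 0.70,
) -> tuple[list[str], pd.DataFrame, list[str]]:
    """Screen covariates for pairwise Spearman collinearity.

    Computes the full |Spearman| matrix on complete cases and greedily
    drops one member of each pair exceeding ``threshold`` (the member with
    the larger mean absolute correlation to everything else). Returns
    (retained variables, correlation matrix, dropped variables).
    """
    vars_ = list(variables) if variables is not None else [
        v for v in ENV_VARIABLES if v in table.columns
    ]
    if len(vars_) < 2:
        raise ValueError("need at least 2 variables")
    complete = table[vars_].dropna()
    if len(complete) < 3:
        raise ValueError("need at least 3 complete rows")
    corr = complete.corr(method="spearman")
    retained = list(vars_)
    dropped: list[str] = []
    while True:
        sub = corr.loc[retained, retained].abs()
        np.fill_diagonal(sub.values, 0.0)
        worst = sub.stack().idxmax()
        if sub.loc[worst] <= threshold:
            break
        a, b = worst
        victim = a if sub.loc[a].mean() >= sub.loc[b].mean() else b
        retained.remove(victim)
        dropped.append(victim)
        if len(retained) < 2:
            break
    return retained, corr, dropped


@dataclass
class ClassifierReport:
    overall_oob_error: float
    per_class_error: dict[str, float]
    importance: pd.Series  # mean decrease in Gini, sorted descending
    n_trees: int
    n_rows: int


def classify_groups(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    label_col: str = "group",
    n_trees: int = 1000,
    seed: int = 0,
    min_per_group: int = 20,
) -> ClassifierReport:
    """Random-forest classification of group membership from environmental
    covariates, scored out-of-bag.

    Rows with any missing covariate are dropped; each group must keep at
    least ``min_per_group`` complete rows. Importance is the mean decrease
    in Gini index, sorted descending. Deterministic given the seed.
    """
    from sklearn.ensemble import RandomForestClassifier

    vars_ = list(variables) if variables is not None else [
        v for v in ENV_VARIABLES if v in table.columns
    ]
    data = table[vars_ + [label_col]].dropna()
    counts = data[label_col].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    low = counts[counts < min_per_group]
    if len(low):
        raise ValueError(
            f"groups below the {min_per_group}-row minimum: {dict(low)}"
        )
    X = data[vars_].to_numpy(dtype=float)
    y = data[label_col].to_numpy()
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    overall = 1.0 - float(rf.oob_score_)
    # per-class error from OOB votes (rows never OOB are skipped)
    votes = rf.oob_decision_function_
    voted = ~np.isnan(votes).any(axis=1)
    pred = np.asarray(rf.classes_)[np.argmax(votes[voted], axis=1)]
    truth = y[voted]
    per_class = {
        str(cls): float((pred[truth == cls] != cls).mean()) for cls in rf.classes_
    }
    importance = pd.Series(rf.feature_importances_, index=vars_).sort_values(
        ascending=False
    )
    return ClassifierReport(
        overall_oob_error=overall,
        per_class_error=per_class,
        importance=importance,
        n_trees=n_trees,
        n_rows=len(data),
    )
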