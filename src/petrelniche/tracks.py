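"""GPS-track processing for central-place foragers.

Cleaning (speed filter), foraging-trip delineation from nest displacement,
movement-strategy classification via 1-D natural breaks, and per-track
summaries (land occupancy, pooled step speeds).

All distances are great-circle on a sphere of radius 6 371 km; coordinates
are WGS-84 lon/lat degrees, timestamps UTC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "Track",
    "Trip",
    "StrategyAssignment",
    "LandOccupancy",
    "great_circle_distance",
    "step_speeds",
    "speed_filter",
    "segment_trips",
    "fisher_jenks_breaks",
    "classify_strategy",
    "speed_threshold_for_ud",
    "proportion_on_land",
]


def normalize_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class Track:
    """One individual's timestamped positions plus metadata.

    ``points`` holds columns ``timestamp`` (tz-naive UTC), ``lon``, ``lat``.
    ``strategy_truth`` is carried by the simulator so classifiers can be
    scored against ground truth; it is None for field data.
    """

    individual_id: str
    species: str
    sex: str
    year: int
    nest: tuple[float, float]  # (lon, lat)
    points: pd.DataFrame
    strategy_truth: str | None = None

    def __post_init__(self) -> None:
        pts = self.points
        required = {"timestamp", "lon", "lat"}
        missing = required - set(pts.columns)
        if missing:
            raise ValueError(f"track {self.individual_id}: missing columns {sorted(missing)}")
        ts = pd.to_datetime(pts["timestamp"])
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError(f"track {self.individual_id}: timestamps not increasing")
        if np.any(np.abs(pts["lat"].to_numpy()) > 90):
            raise ValueError(f"track {self.individual_id}: |lat| > 90")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lonlat(self) -> np.ndarray:
        return self.points[["lon", "lat"]].to_numpy(dtype=float)

    def distances_from_nest(self) -> np.ndarray:
        """Great-circle distance (m) of every point from the nest."""
        ll = self.lonlat
        nest = np.array(self.nest, dtype=float)
        return great_circle_distance(nest[None, :], ll)


@dataclass(frozen=True)
class Trip:
    """A contiguous away-from-nest excursion.

    ``start_index``/``end_index`` are inclusive positional indices into the
    parent track's points. Duration is the span last-away minus first-away.
    """

    individual_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    start_index: int
    end_index: int
    duration_h: float
    max_distance_km: float


@dataclass(frozen=True)
class StrategyAssignment:
    individual_id: str
    strategy: Literal["nearby", "distant"]
    max_trip_distance_km: float
    break_value_km: float


@dataclass(frozen=True)
class LandOccupancy:
    fraction: float
    n_land: int
    n_valid: int
    n_missing: int


def great_circle_distance(a, b) -> np.ndarray | float:
    """Haversine distance in metres between lon/lat points (degrees).

    ``a`` and ``b`` are (2,) or (n, 2) arrays of (lon, lat); broadcasting
    applies. Symmetric, zero iff coincident (antipodal degeneracy aside).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def step_speeds(track: Track) -> np.ndarray:
    """Preceding-displacement speed (m/s) for points 1..n-1."""
    ll = track.lonlat
    ts = pd.to_datetime(track.points["timestamp"]).to_numpy()
    if len(ll) < 2:
        return np.empty(0)
    d = great_circle_distance(ll[:-1], ll[1:])
    dt = np.diff(ts).astype("timedelta64[s]").astype(float)
    with np.errstate(divide="ignore"):
        return np.where(dt > 0, d / np.maximum(dt, 1e-9), np.inf)


def speed_filter(track: Track, vmax: float = 30.0) -> tuple[Track, float]:
    """Forward-pass speed filter.

    A point is dropped when the great-circle speed from the last *retained*
    point exceeds ``vmax`` (m/s); the first point is always retained.
    Returns the filtered track and the removed fraction. Idempotent.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    pts = track.points.reset_index(drop=True)
    n = len(pts)
    if n < 2:
        return replace(track, points=pts.copy()), 0.0
    ll = pts[["lon", "lat"]].to_numpy(dtype=float)
    ts = pd.to_datetime(pts["timestamp"]).to_numpy().astype("datetime64[s]").astype(float)
    keep = np.zeros(n, dtype=bool)
    keep[0] = True
    last = 0
    for i in range(1, n):
        dt = ts[i] - ts[last]
        d = great_circle_distance(ll[last], ll[i])
        if dt <= 0 or d / dt <= vmax:
            keep[i] = True
            last = i
    filtered = replace(track, points=pts.loc[keep].reset_index(drop=True))
    return filtered, float(1.0 - keep.mean())


def segment_trips(
    track: Track, nest_radius_m: float = 200.0, min_duration_h: float = 3.0
) -> list[Trip]:
    """Delineate foraging trips: maximal runs of consecutive points all
    further than ``nest_radius_m`` from the nest whose time span (last-away
    minus first-away) is at least ``min_duration_h`` hours. Shorter
    excursions are ignored; trips are non-overlapping and time-ordered.
    """
    if len(track) == 0:
        return []
    away = track.distances_from_nest() > nest_radius_m
    ts = pd.to_datetime(track.points["timestamp"]).reset_index(drop=True)
    trips: list[Trip] = []
    dist_km = track.distances_from_nest() / 1000.0
    i = 0
    n = len(away)
    while i < n:
        if not away[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and away[j + 1]:
            j += 1
        span_h = (ts[j] - ts[i]).total_seconds() / 3600.0
        if span_h >= min_duration_h:
            trips.append(
                Trip(
                    individual_id=track.individual_id,
                    start=ts[i],
                    end=ts[j],
                    start_index=i,
                    end_index=j,
                    duration_h=float(span_h),
                    max_distance_km=float(dist_km[i : j + 1].max()),
                )
            )
        i = j + 1
    return trips


def _fisher_jenks_partition(values: np.ndarray, k: int) -> list[np.ndarray]:
    """Exact optimal partition of sorted values into k contiguous classes
    minimizing total within-class sum of squared deviations (dynamic
    programme over prefix sums, O(k n^2))."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: int, j: int) -> float:
        # SSD of x[i:j]
        m = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / m

    INF = np.inf
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = INF, m - 1
            for i in range(m - 1, j):
                c = dp[m - 1, i] + cost(i, j)
                if c < best:
                    best, arg = c, i
            dp[m, j] = best
            back[m, j] = arg
    bounds = [n]
    j = n
    for m in range(k, 0, -1):
        j = back[m, j]
        bounds.append(j)
    bounds.reverse()  # [0, b1, ..., n]
    return [x[bounds[i] : bounds[i + 1]] for i in range(k)]


def fisher_jenks_breaks(values: Sequence[float], k: int) -> list[float]:
    """Exact Fisher–Jenks natural breaks.

    Returns the k-1 internal break values; each break is the midpoint
    between the maximum of one class and the minimum of the next, so
    classification is ``class = number of breaks below the value``.
    """
    x = np.asarray(list(values), dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(x))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds number of distinct values ({n_distinct})")
    if len(x) < k:
        raise ValueError("need at least k values")
    classes = _fisher_jenks_partition(x, k)
    return [float((classes[i][-1] + classes[i + 1][0]) / 2.0) for i in range(k - 1)]


def fisher_jenks_objective(values: Sequence[float], k: int) -> float:
    """Total within-class SSD of the optimal k-class partition."""
    classes = _fisher_jenks_partition(np.asarray(list(values), dtype=float), k)
    return float(sum(np.sum((c - c.mean()) ** 2) for c in classes))


def classify_strategy(
    max_trip_distances: Mapping[str, float],
    k: int = 2,
    method: Literal["quantile", "fisher_jenks"] = "fisher_jenks",
) -> list[StrategyAssignment]:
    """Classify individuals into movement strategies from their maximum
    trip distance (km). With k=2, individuals above the break are
    "distant", the rest "nearby" (an individual is nearby only when its
    every trip — hence its maximum — is below the break).

    Trip distances span orders of magnitude, so natural breaks are computed
    on log distance (the break is reported in km, i.e. as the geometric
    midpoint between the classes). Quantile classification is unaffected by
    the monotone transform.
    """
    ids = list(max_trip_distances)
    vals = np.array([max_trip_distances[i] for i in ids], dtype=float)
    if k == 1:
        return [
            StrategyAssignment(i, "nearby", float(v), float(np.inf)) for i, v in zip(ids, vals)
        ]
    if len(np.unique(vals)) < 2:
        raise ValueError("all trip distances identical; no break exists")
    if np.any(vals <= 0):
        raise ValueError("trip distances must be positive")
    if method == "fisher_jenks":
        breaks = [10.0**b for b in fisher_jenks_breaks(np.log10(vals), k)]
    elif method == "quantile":
        qs = np.quantile(vals, np.linspace(0, 1, k + 1)[1:-1])
        breaks = [float(q) for q in np.atleast_1d(qs)]
    else:
        raise ValueError(f"unknown method {method!r}")
    brk = breaks[-1]  # with k=2 the single break; with k>2 the top break
    return [
        StrategyAssignment(
            individual_id=i,
            strategy="distant" if v > brk else "nearby",
            max_trip_distance_km=float(v),
            break_value_km=float(brk),
        )
        for i, v in zip(ids, vals)
    ]


def speed_threshold_for_ud(tracks: Iterable[Track]) -> float:
    """Data-derived transit-speed threshold (m/s) for utilization
    distributions: the Fisher–Jenks k=2 break of the pooled
    preceding-displacement speed distribution. Locations faster than this
    are presumed transit and excluded before kernel density estimation.
    """
    speeds = np.concatenate([step_speeds(t) for t in tracks]) if tracks else np.empty(0)
    speeds = speeds[np.isfinite(speeds)]
    if len(speeds) < 2 or np.ptp(speeds) <= 1e-9 * max(1.0, float(np.abs(speeds).max())):
        raise ValueError("need at least 2 distinct speeds to place a break")
    return fisher_jenks_breaks(speeds, 2)[0]


def proportion_on_land(track: Track, land_mask, return_detail: bool = False):
    """Fraction of a track's points whose nearest land-mask cell is land.

    ``land_mask`` is a boolean xarray.DataArray with 1-D ``lat``/``lon``
    coordinates on a regular grid. Points outside the mask extent are
    counted as missing (and warned about), not as sea.
    """
    lat = np.asarray(land_mask["lat"].values, dtype=float)
    lon = np.asarray(land_mask["lon"].values, dtype=float)
    mask = np.asarray(land_mask.values, dtype=bool)
    ll = track.lonlat
    ilat = _nearest_index(lat, ll[:, 1])
    ilon = _nearest_index(lon, ll[:, 0])
    valid = (ilat >= 0) & (ilon >= 0)
    n_missing = int((~valid).sum())
    if n_missing:
        warnings.warn(
            f"track {track.individual_id}: {n_missing} point(s) outside land-mask extent",
            stacklevel=2,
        )
    n_valid = int(valid.sum())
    n_land = int(mask[ilat[valid], ilon[valid]].sum()) if n_valid else 0
    frac = n_land / n_valid if n_valid else float("nan")
    if return_detail:
        return LandOccupancy(frac, n_land, n_valid, n_missing)
    return frac


def _nearest_index(coord: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Nearest index into a regular ascending coordinate; -1 when x is more
    than half a cell outside the extent."""
    step = coord[1] - coord[0] if len(coord) > 1 else 1.0
    idx = np.round((np.asarray(x, dtype=float) - coord[0]) / step).astype(int)
    out = (idx < 0) | (idx >= len(coord))
    idx = np.clip(idx, 0, len(coord) - 1)
    idx[out] = -1
    return idx


def tracks_to_frame(tracks: Iterable[Track]) -> pd.DataFrame:
    """Flatten tracks to the CSV dialect (id, species, sex, year,
    timestamp, lon, lat, strategy_truth)."""
    rows = []
    for t in tracks:
        df = t.points.copy()
        df.insert(0, "id", t.individual_id)
        df.insert(1, "species", t.species)
        df.insert(2, "sex", t.sex)
        df.insert(3, "year", t.year)
        df["strategy_truth"] = t.strategy_truth if t.strategy_truth is not None else ""
        rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["id", "species", "sex", "year", "timestamp", "lon", "lat", "strategy_truth"]
    )


def frame_to_tracks(df: pd.DataFrame, nests: Mapping[str, tuple[float, float]] | None = None) -> list[Track]:
    """Rebuild Track objects from the flat CSV dialect. When ``nests`` is
    not given the first position of each individual is taken as the nest."""
    out = []
    for iid, g in df.groupby("id", sort=False):
        g = g.sort_values("timestamp").reset_index(drop=True)
        nest = nests[iid] if nests else (float(g["lon"].iloc[0]), float(g["lat"].iloc[0]))
        truth = None
        if "strategy_truth" in g.columns:
            v = str(g["strategy_truth"].iloc[0])
            truth = v if v in {"nearby", "distant"} else None
        out.append(
            Track(
                individual_id=str(iid),
                species=str(g["species"].iloc[0]),
                sex=str(g["sex"].iloc[0]),
                year=int(g["year"].iloc[0]),
                nest=nest,
                points=g[["timestamp", "lon", "lat"]].assign(
                    timestamp=pd.to_datetime(g["timestamp"])
                ),
                strategy_truth=truth,
            )
        )
    return out
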