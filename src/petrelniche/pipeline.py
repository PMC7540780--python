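"""End-to-end orchestration: simulate/load -> filter -> trips -> strategies
-> spatial overlap tests -> isotopic niche tests -> trophic residuals ->
habitat report, from a single flat config, with a run manifest.

Report tables mirror the standard presentation of such studies: a spatial
overlap table (comparison, observed BA, permuted mean +- sd, p, p CI) at
each contour level; pairwise MANOVA; per-group isotope means and SEAc;
SEAc-overlap permutation table; per-individual trophic residuals; and a
habitat classification report (OOB errors and Gini importances).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .synthetic import SimConfig, simulate_tracks, simulate_isotopes, simulate_env_fields
from .tracks import (
    Track,
    classify_strategy,
    frame_to_tracks,
    segment_trips,
    speed_filter,
    speed_threshold_for_ud,
    step_speeds,
)
from .spatial import grid_from_points, overlap_permutation_test
from .isotopes import (
    isotope_overlap_permutation_test,
    mardia_coefficients,
    standard_ellipse,
    trophic_residuals,
    wilks_manova,
)
from .habitat import classify_groups, collinearity_screen, extract_environment

COMPARISONS: tuple[tuple[str, str], ...] = (
    ("NGP_male", "SGP_male"),
    ("NGP_female", "SGP_female"),
    ("NGP_male", "NGP_female"),
    ("SGP_male", "SGP_female"),
)

ALL_STAGES = ("spatial", "isotopes", "habitat")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults carry the study's thresholds
    (30 m/s track filter, 200 m nest radius, 3 h minimum trip, 7.2 m/s
    fallback transit threshold, h = 0.8 deg, 50/95% contours, 1000
    permutations, |Spearman| 0.70 screen, 1000 trees)."""

    sim: SimConfig | None = None
    tracks_path: str | None = None
    isotopes_path: str | None = None
    outdir: str | None = None
    vmax: float = 30.0
    nest_radius_m: float = 200.0
    min_trip_h: float = 3.0
    ud_transit_speed: float | Literal["auto"] = "auto"
    ud_transit_fallback: float = 7.2
    h: float | Literal["auto"] = 0.8
    contour_levels: tuple[float, ...] = (95.0, 50.0)
    restrict_to_contour: bool = True
    n_perm: int = 1000
    spearman_threshold: float = 0.70
    n_trees: int = 1000
    min_per_group: int = 20
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        for name, v in [
            ("vmax", self.vmax),
            ("nest_radius_m", self.nest_radius_m),
            ("min_trip_h", self.min_trip_h),
            ("n_perm", self.n_perm),
            ("n_trees", self.n_trees),
        ]:
            if not v > 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class PipelineResult:
    config: PipelineConfig
    tracks: list[Track]
    removed_fractions: dict[str, float]
    trips: pd.DataFrame
    strategies: pd.DataFrame
    spatial_report: pd.DataFrame | None
    isotope_samples: pd.DataFrame | None
    group_stats: pd.DataFrame | None
    manova_report: pd.DataFrame | None
    isotope_overlap_report: pd.DataFrame | None
    residuals_report: pd.DataFrame | None
    habitat_report: dict | None
    manifest: dict


def _config_hash(cfg: PipelineConfig) -> str:
    d = asdict(cfg)
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _trip_points(track: Track, trips) -> np.ndarray:
    idx = np.concatenate(
        [np.arange(t.start_index, t.end_index + 1) for t in trips]
    ) if trips else np.empty(0, dtype=int)
    return track.lonlat[idx], idx


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages in order and (optionally) write the
    report bundle to ``config.outdir``. Deterministic under a fixed seed."""
    t0 = time.perf_counter()
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": list(config.stages),
        "warnings": [],
        "counts": {},
        "timings_s": {},
    }
    caught: list[str] = []

    # --- acquire tracks ---------------------------------------------------
    if config.sim is not None:
        tracks = simulate_tracks(config.sim)
    elif config.tracks_path is not None:
        tracks = frame_to_tracks(pd.read_csv(config.tracks_path, parse_dates=["timestamp"]))
    else:
        raise ValueError("stage input: provide either sim config or tracks_path")
    manifest["counts"]["individuals"] = len(tracks)
    manifest["counts"]["raw_locations"] = int(sum(len(t) for t in tracks))

    # --- filter + trips + strategies -------------------------------------
    filtered: list[Track] = []
    removed: dict[str, float] = {}
    for t in tracks:
        ft, rf = speed_filter(t, vmax=config.vmax)
        filtered.append(ft)
        removed[t.individual_id] = rf
    trips_by_id = {
        t.individual_id: segment_trips(t, config.nest_radius_m, config.min_trip_h * 1.0)
        for t in filtered
    }
    trip_rows = [
        {
            "id": tr.individual_id,
            "trip_index": k,
            "start": tr.start,
            "end": tr.end,
            "duration_h": tr.duration_h,
            "max_km": tr.max_distance_km,
        }
        for t in filtered
        for k, tr in enumerate(trips_by_id[t.individual_id])
    ]
    trips_df = pd.DataFrame(trip_rows)
    max_dist = {
        iid: max(tr.max_distance_km for tr in trs)
        for iid, trs in trips_by_id.items()
        if trs
    }
    assignments = classify_strategy(max_dist) if len(set(max_dist.values())) > 1 else []
    strategies_df = pd.DataFrame(
        [
            {
                "id": a.individual_id,
                "strategy": a.strategy,
                "max_trip_km": a.max_trip_distance_km,
                "break_km": a.break_value_km,
            }
            for a in assignments
        ]
    )
    manifest["counts"]["trips"] = len(trips_df)
    manifest["timings_s"]["tracks"] = round(time.perf_counter() - t0, 3)

    group_of = {t.individual_id: f"{t.species}_{t.sex}" for t in filtered}
    year_of = {t.individual_id: t.year for t in filtered}
    track_of = {t.individual_id: t for t in filtered}

    spatial_report = None
    if "spatial" in config.stages:
        ts = time.perf_counter()
        if config.ud_transit_speed == "auto":
            try:
                vthr = speed_threshold_for_ud(filtered)
            except ValueError:
                vthr = config.ud_transit_fallback
        else:
            vthr = float(config.ud_transit_speed)
        manifest["ud_transit_speed_mps"] = round(float(vthr), 4)
        points_by_id: dict[str, np.ndarray] = {}
        for iid, trs in trips_by_id.items():
            if not trs:
                continue
            tr = track_of[iid]
            pts, idx = _trip_points(tr, trs)
            sp = np.concatenate([[0.0], step_speeds(tr)])[idx]
            keep = sp <= vthr
            if keep.sum() >= 2:
                points_by_id[iid] = pts[keep]
        h = float(config.h) if config.h != "auto" else None
        if h is None:
            from .spatial import adhoc_bandwidth

            pooled = np.vstack(list(points_by_id.values()))
            h = adhoc_bandwidth(pooled, h0=3.2, shrink=0.5).h
        manifest["ud_bandwidth_deg"] = h
        pooled = np.vstack(list(points_by_id.values()))
        grid = grid_from_points(pooled, h)
        rows = []
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 10)))
        for level in config.contour_levels:
            for a, b in COMPARISONS:
                ids = [i for i, g in group_of.items() if g in (a, b) and i in points_by_id]
                if sum(group_of[i] == a for i in ids) < 2 or sum(group_of[i] == b for i in ids) < 2:
                    caught.append(f"spatial: too few individuals for {a} vs {b}; skipped")
                    continue
                res = overlap_permutation_test(
                    {i: points_by_id[i] for i in ids},
                    {i: group_of[i] for i in ids},
                    {i: year_of[i] for i in ids},
                    a,
                    b,
                    h=h,
                    grid=grid,
                    contour_level=level if config.restrict_to_contour else None,
                    n_perm=config.n_perm,
                    seed=rng,
                )
                rows.append(
                    {
                        "contour_level": level,
                        "comparison": f"{a} vs {b}",
                        "observed_overlap": res.observed_overlap,
                        "permuted_mean": res.permuted_mean,
                        "permuted_sd": res.permuted_sd,
                        "p_value": res.p_value,
                        "p_ci_low": res.p_ci[0],
                        "p_ci_high": res.p_ci[1],
                        "n_perm": res.n_permutations,
                    }
                )
        spatial_report = pd.DataFrame(rows)
        manifest["timings_s"]["spatial"] = round(time.perf_counter() - ts, 3)

    isotope_samples = group_stats = manova_report = iso_overlap = residuals_report = None
    if "isotopes" in config.stages:
        ts = time.perf_counter()
        if config.sim is not None:
            isotope_samples = simulate_isotopes(tracks, config.sim)
        elif config.isotopes_path is not None:
            isotope_samples = pd.read_csv(config.isotopes_path)
            if "group" not in isotope_samples.columns:
                isotope_samples["group"] = (
                    isotope_samples["species"] + "_" + isotope_samples["sex"]
                )
        else:
            raise ValueError("stage isotopes: no isotope input")
        xy_cols = ["d13C", "d15N"]
        grows = []
        for g, sub in isotope_samples.groupby("group"):
            ell = standard_ellipse(sub[xy_cols].to_numpy()) if len(sub) >= 3 else None
            grows.append(
                {
                    "group": g,
                    "n": len(sub),
                    "d13C_mean": sub["d13C"].mean(),
                    "d13C_sd": sub["d13C"].std(ddof=1),
                    "d15N_mean": sub["d15N"].mean(),
                    "d15N_sd": sub["d15N"].std(ddof=1),
                    "SEAc": ell.seac if ell else np.nan,
                }
            )
        group_stats = pd.DataFrame(grows)
        xy = isotope_samples[xy_cols].to_numpy()
        overall = wilks_manova(xy, isotope_samples["group"].to_numpy())
        mardia = mardia_coefficients(xy)
        mrows = [
            {
                "comparison": "all groups",
                "wilks_lambda": overall.lambda_,
                "F": overall.f_stat,
                "p_value": overall.p_value,
            }
        ]
        for a, b in COMPARISONS:
            sub = isotope_samples[isotope_samples["group"].isin([a, b])]
            try:
                w = wilks_manova(sub[xy_cols].to_numpy(), sub["group"].to_numpy())
                mrows.append(
                    {
                        "comparison": f"{a} vs {b}",
                        "wilks_lambda": w.lambda_,
                        "F": w.f_stat,
                        "p_value": w.p_value,
                    }
                )
            except ValueError as e:
                caught.append(f"isotopes MANOVA {a} vs {b}: {e}")
        manova_report = pd.DataFrame(mrows)
        manifest["mardia"] = {
            "skew_p": mardia.skew_p,
            "kurt_p": mardia.kurt_p,
        }
        orows = []
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 11)))
        for a, b in COMPARISONS:
            try:
                res = isotope_overlap_permutation_test(
                    isotope_samples, a, b, n_perm=config.n_perm, seed=rng
                )
            except ValueError as e:
                caught.append(f"isotope overlap {a} vs {b}: {e}")
                continue
            orows.append(
                {
                    "comparison": f"{a} vs {b}",
                    "observed_overlap": res.observed_metric,
                    "intersection_area": res.intersection_area,
                    "permuted_mean": res.permuted_mean,
                    "permuted_sd": res.permuted_sd,
                    "p_value": res.p_value,
                    "p_ci_low": res.p_ci[0],
                    "p_ci_high": res.p_ci[1],
                    "n_perm": res.n_permutations,
                }
            )
        iso_overlap = pd.DataFrame(orows)
        res_all = trophic_residuals(isotope_samples)
        residuals_report = isotope_samples[["id", "group"]].copy()
        residuals_report["residual_all"] = res_all.to_numpy()
        strat = dict(zip(strategies_df.get("id", []), strategies_df.get("strategy", [])))
        distant_ids = {i for i, s in strat.items() if s == "distant"}
        sub = isotope_samples[isotope_samples["id"].isin(distant_ids)]
        if len(sub) >= 4 and sub["d13C"].nunique() > 1:
            res_d = trophic_residuals(sub)
            residuals_report = residuals_report.merge(
                pd.DataFrame({"id": sub["id"].to_numpy(), "residual_distant": res_d.to_numpy()}),
                on="id",
                how="left",
            )
        manifest["timings_s"]["isotopes"] = round(time.perf_counter() - ts, 3)

    habitat_report = None
    if "habitat" in config.stages:
        ts = time.perf_counter()
        if config.sim is None:
            raise ValueError("stage habitat: requires a simulation config for synthetic fields")
        fields = simulate_env_fields(config.sim)
        loc_rows = []
        for iid, trs in trips_by_id.items():
            if not trs:
                continue
            tr = track_of[iid]
            pts, idx = _trip_points(tr, trs)
            loc_rows.append(
                pd.DataFrame(
                    {
                        "id": iid,
                        "group": group_of[iid],
                        "timestamp": tr.points["timestamp"].to_numpy()[idx],
                        "lon": pts[:, 0],
                        "lat": pts[:, 1],
                    }
                )
            )
        locations = pd.concat(loc_rows, ignore_index=True)
        annotated = extract_environment(locations, fields)
        at_sea = annotated[~annotated["on_land"] & ~annotated["outside_extent"]]
        manifest["counts"]["at_sea_locations"] = len(at_sea)
        retained, corr, dropped = collinearity_screen(
            at_sea, threshold=config.spearman_threshold
        )
        report = classify_groups(
            at_sea,
            variables=retained,
            n_trees=config.n_trees,
            seed=config.seed,
            min_per_group=config.min_per_group,
        )
        habitat_report = {
            "retained_variables": retained,
            "dropped_variables": dropped,
            "spearman": corr.round(4).to_dict(),
            "overall_oob_error": report.overall_oob_error,
            "per_class_error": report.per_class_error,
            "importance": report.importance.round(6).to_dict(),
            "n_trees": report.n_trees,
            "n_rows": report.n_rows,
        }
        manifest["timings_s"]["habitat"] = round(time.perf_counter() - ts, 3)

    manifest["warnings"] = caught
    manifest["timings_s"]["total"] = round(time.perf_counter() - t0, 3)
    result = PipelineResult(
        config=config,
        tracks=filtered,
        removed_fractions=removed,
        trips=trips_df,
        strategies=strategies_df,
        spatial_report=spatial_report,
        isotope_samples=isotope_samples,
        group_stats=group_stats,
        manova_report=manova_report,
        isotope_overlap_report=iso_overlap,
        residuals_report=residuals_report,
        habitat_report=habitat_report,
        manifest=manifest,
    )
    if config.outdir is not None:
        _write_bundle(result, Path(config.outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.trips.to_csv(outdir / "trips.csv", index=False)
    result.strategies.to_csv(outdir / "strategies.csv", index=False)
    named = {
        "spatial_overlap.csv": result.spatial_report,
        "isotope_groups.csv": result.group_stats,
        "manova.csv": result.manova_report,
        "isotope_overlap.csv": result.isotope_overlap_report,
        "trophic_residuals.csv": result.residuals_report,
    }
    for name, df in named.items():
        if df is not None:
            df.to_csv(outdir / name, index=False)
    if result.habitat_report is not None:
        (outdir / "habitat_report.json").write_text(
            json.dumps(result.habitat_report, indent=2, default=str)
        )
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))


# --- input validation -----------------------------------------------------

REQUIRED_TRACK_COLUMNS = ("id", "species", "sex", "year", "timestamp", "lon", "lat")
REQUIRED_ISOTOPE_COLUMNS = ("id", "species", "sex", "year", "d13C", "d15N")
SPECIES_VOCAB = {"NGP", "SGP"}
SEX_VOCAB = {"male", "female"}


@dataclass
class ValidationReport:
    fatal: list[str]
    warnings: list[str]
    n_rows: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(tracks_path: str | None = None, isotopes_path: str | None = None) -> ValidationReport:
    """Schema-check input CSVs without mutating them.

    Fatal errors (missing columns, unparseable or non-monotonic timestamps,
    out-of-range coordinates) are listed with 1-based data line numbers;
    unknown species/sex labels are non-fatal warnings.
    """
    fatal: list[str] = []
    warns: list[str] = []
    n_rows: dict[str, int] = {}
    if tracks_path is not None:
        df = pd.read_csv(tracks_path)
        n_rows["tracks"] = len(df)
        missing = set(REQUIRED_TRACK_COLUMNS) - set(df.columns)
        if missing:
            fatal.append(f"tracks: missing columns {sorted(missing)}")
        else:
            ts = pd.to_datetime(df["timestamp"], errors="coerce")
            bad = np.flatnonzero(ts.isna())
            for i in bad[:10]:
                fatal.append(f"tracks line {i + 1}: unparseable timestamp {df['timestamp'].iloc[i]!r}")
            lat = pd.to_numeric(df["lat"], errors="coerce")
            lon = pd.to_numeric(df["lon"], errors="coerce")
            for i in np.flatnonzero(~(np.abs(lat) <= 90))[:10]:
                fatal.append(f"tracks line {i + 1}: latitude {df['lat'].iloc[i]!r} out of range")
            for i in np.flatnonzero(~(np.abs(lon) <= 360))[:10]:
                fatal.append(f"tracks line {i + 1}: longitude {df['lon'].iloc[i]!r} out of range")
            for iid, g in df.assign(_ts=ts).groupby("id", sort=False):
                if g["_ts"].notna().all() and not g["_ts"].is_monotonic_increasing:
                    fatal.append(f"tracks: timestamps not increasing for individual {iid!r}")
            for col, vocab in (("species", SPECIES_VOCAB), ("sex", SEX_VOCAB)):
                unknown = set(df[col].astype(str).unique()) - vocab
                if unknown:
                    warns.append(f"tracks: unknown {col} labels {sorted(unknown)}")
    if isotopes_path is not None:
        df = pd.read_csv(isotopes_path)
        n_rows["isotopes"] = len(df)
        missing = set(REQUIRED_ISOTOPE_COLUMNS) - set(df.columns)
        if missing:
            fatal.append(f"isotopes: missing columns {sorted(missing)}")
        else:
            for col, (lo, hi) in (("d13C", (-60.0, 20.0)), ("d15N", (-20.0, 40.0))):
                vals = pd.to_numeric(df[col], errors="coerce")
                for i in np.flatnonzero(~vals.between(lo, hi))[:10]:
                    fatal.append(f"isotopes line {i + 1}: {col} value {df[col].iloc[i]!r} implausible")
    return ValidationReport(fatal=fatal, warnings=warns, n_rows=n_rows)
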