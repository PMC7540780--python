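"""Synthetic study generator: GPS tracks, isotope samples, environmental fields.

Emulates the data structure of a two-species, two-sex central-place foraging
study at a sub-Antarctic island: hourly GPS fixes with two movement
strategies (nearby trips that stay within tens of km of the colony versus
distant out-and-back excursions with a species-specific directional bias), a
latitudinal delta-13C isoscape with group-level trophic offsets in delta-15N,
and a seven-variable gridded environmental field set with a land mask.

Everything is a pure function of (config, seed): per-individual random
sub-streams are derived from the master seed so output is reproducible and
stable under group reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .tracks import EARTH_RADIUS_M, Track, normalize_lon

__all__ = [
    "GroupConfig",
    "SimConfig",
    "EnvironmentalFieldSet",
    "default_config",
    "simulate_tracks",
    "simulate_isotopes",
    "simulate_env_fields",
    "ENV_VARIABLES",
]

ENV_VARIABLES = ("sst", "chl", "depth", "ssh", "wind_u", "wind_v", "eke")


@dataclass
class GroupConfig:
    """One species-by-sex group's movement and trophic settings.

    ``p_distant`` is the per-individual probability of the distant strategy;
    ``bearing_deg``/``bearing_kappa`` give the mean bearing (degrees
    clockwise from north) and von Mises concentration of distant-trip
    directions; ``trophic_offset`` is the group's mean delta-15N elevation
    (permil) above the baseline.
    """

    species: str
    sex: str
    n_individuals: int = 10
    p_distant: float = 1.0
    bearing_deg: float = 0.0
    bearing_kappa: float = 4.0
    trophic_offset: float = 1.5

    @property
    def name(self) -> str:
        return f"{self.species}_{self.sex}"


@dataclass
class SimConfig:
    """Full simulation configuration (see module docstring).

    Distances in km, isotope values in permil, ``sampling_interval_min`` in
    minutes. ``isoscape_slope`` is permil delta-13C per degree latitude
    (positive: heavier carbon toward the equator); the delta-15N baseline is
    affine in delta-13C (``d15n_baseline_intercept + d15n_baseline_slope *
    d13C``) so a residual-based trophic correction has a recoverable signal.
    """

    groups: dict[str, GroupConfig]
    window_start: str | pd.Timestamp = "2016-10-01"
    window_end: str | pd.Timestamp = "2016-10-11"
    sampling_interval_min: float = 60.0
    colony_lon: float = 37.75
    colony_lat: float = -46.9
    island_radius_km: float = 25.0
    nearby_trip_min_km: float = 8.0
    nearby_trip_max_km: float = 50.0
    distant_trip_range_km: tuple[float, float] = (69.0, 2344.0)
    isoscape_slope: float = 0.38
    isoscape_intercept: float = -3.5
    d15n_baseline_slope: float = 0.5
    d15n_baseline_intercept: float = 22.0
    noise_sd: float = 0.5
    sst_gradient: float = 0.6  # degC per degree latitude (warmer equatorward)
    seed: int = 0

    def __post_init__(self) -> None:
        self.window_start = pd.Timestamp(self.window_start)
        self.window_end = pd.Timestamp(self.window_end)
        if self.window_end <= self.window_start:
            raise ValueError("study_window: window_end must be after window_start")
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling_interval_min must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.nearby_trip_max_km < self.distant_trip_range_km[0]:
            raise ValueError(
                "nearby_trip_max_km must be below the distant trip range "
                "(the two strategies must be separable by construction)"
            )
        for g in self.groups.values():
            if not 0.0 <= g.p_distant <= 1.0:
                raise ValueError(f"group {g.name}: p_distant must be in [0, 1]")
            if g.n_individuals < 0:
                raise ValueError(f"group {g.name}: negative n_individuals")

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.window_start, self.window_end, freq=pd.Timedelta(minutes=self.sampling_interval_min)
        )


def default_config(n_individuals_per_group: int = 10, seed: int = 0, **overrides) -> SimConfig:
    """Study-patterned defaults: four species-by-sex groups.

    Females of both species make only distant trips; a minority of males do
    (NGP 0.44, SGP 0.18). NGPs head northwest toward subtropical waters,
    SGPs south. Trophic offsets reproduce the observed group delta-15N
    ordering (NGP female > NGP male > SGP female > SGP male after the
    isoscape baseline is accounted for).
    """
    groups = {
        "NGP_female": GroupConfig("NGP", "female", n_individuals_per_group, 1.0, 325.0, 8.0, 2.35),
        "NGP_male": GroupConfig("NGP", "male", n_individuals_per_group, 0.44, 325.0, 8.0, 1.15),
        "SGP_female": GroupConfig("SGP", "female", n_individuals_per_group, 1.0, 185.0, 2.0, 2.05),
        "SGP_male": GroupConfig("SGP", "male", n_individuals_per_group, 0.18, 185.0, 2.0, 1.05),
    }
    return SimConfig(groups=groups, seed=seed, **overrides)


def _destination(lon: float, lat: float, bearing_rad, dist_km):
    """Spherical direct problem: point(s) at distance/bearing from (lon, lat)."""
    delta = np.asarray(dist_km, dtype=float) * 1000.0 / EARTH_RADIUS_M
    theta = np.asarray(bearing_rad, dtype=float)
    phi1 = math.radians(lat)
    lam1 = math.radians(lon)
    sin_phi2 = np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    phi2 = np.arcsin(np.clip(sin_phi2, -1.0, 1.0))
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * sin_phi2,
    )
    return normalize_lon(np.degrees(lam2)), np.degrees(phi2)


def _rest_jitter(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """At-nest positions: radius < ~60 m so they stay inside the nest radius."""
    r = np.abs(rng.normal(0.0, 0.02, n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return r, theta


def _build_trip(
    rng: np.random.Generator,
    apex_km: float,
    n_out: int,
    n_forage: int,
    bearing_rad: float,
    wander_sd_deg: float,
    forage_speed_kmh: float,
    dt_h: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius/bearing sequences for one out-and-back excursion.

    Outbound: radius grows linearly to exactly ``apex_km`` with small
    heading wander (so transit speed ~ apex / (n_out * dt)). Forage bout:
    slow random walk near the apex, clipped to radius <= apex. Inbound
    mirrors outbound. The trip's maximum displacement is exactly apex_km.
    """
    wander = np.radians(rng.normal(0.0, wander_sd_deg, n_out).cumsum())
    r_out = apex_km * np.arange(1, n_out + 1) / n_out
    th_out = bearing_rad + wander
    # forage: small angular drift + radial jitter, never beyond the apex
    th_f = th_out[-1] + (forage_speed_kmh * dt_h / max(apex_km, 1e-6)) * np.arange(
        1, n_forage + 1
    ) * rng.choice([-1.0, 1.0])
    # absolute (km) radial jitter: forage displacements stay slow even on
    # very long trips
    r_f = np.clip(apex_km - np.abs(rng.normal(0.0, 2.0, n_forage)), 0.0, apex_km)
    # inbound leg unwinds along the bird's current azimuth (the forage bout
    # may have drifted it), not the outbound one
    th_last = th_f[-1] if n_forage > 0 else th_out[-1]
    r_back = r_out[::-1][1:] if n_out > 1 else np.empty(0)
    th_back = th_last + np.radians(rng.normal(0.0, wander_sd_deg, len(r_back)).cumsum())
    r = np.concatenate([r_out, r_f, r_back, [0.0]])
    th = np.concatenate([th_out, th_f, th_back, [th_last]])
    return r, th


def _simulate_individual(
    rng: np.random.Generator, cfg: SimConfig, group: GroupConfig, n_steps: int, dt_h: float
) -> tuple[np.ndarray, np.ndarray, str]:
    """Radius (km) and bearing (rad) from the colony for every time step."""
    r = np.zeros(n_steps)
    th = np.zeros(n_steps)
    jr, jth = _rest_jitter(rng, n_steps)
    r[:], th[:] = jr, jth

    distant = bool(rng.random() < group.p_distant)
    gap_steps = max(4, int(math.ceil(3.5 / dt_h)))  # >= 3 h at-nest bouts between trips

    if distant:
        dmin, dmax = cfg.distant_trip_range_km
        n_trips = 1 if rng.random() < 0.6 else 2
        cursor = int(rng.integers(1, max(2, gap_steps)))
        placed = 0
        for _ in range(n_trips):
            tail = 1 + (gap_steps if placed + 1 < n_trips else 0)
            avail = n_steps - cursor - tail
            vt = rng.uniform(8.0, 12.0) * 3.6  # transit km/h
            feasible = (avail - 4) / 2.0 * vt * dt_h
            if feasible < dmin * 1.02:
                if placed == 0:
                    raise ValueError(
                        "study_window too short for distant trips at the configured range"
                    )
                break
            # lognormal trip extent: distant foraging has a characteristic
            # scale (bulk of trips a few hundred km) with a long tail,
            # clipped into the configured range
            apex = math.exp(rng.normal(math.log(650.0), 0.35))
            apex = float(np.clip(apex, dmin * 1.02, min(dmax * 0.98, feasible * 0.98)))
            n_out = max(2, int(math.ceil(apex / (vt * dt_h))))
            # multi-day foraging bout at the trip apex fills much of the
            # remaining window (less when a second trip must still fit)
            rem = avail - 2 * n_out
            frac = 0.8 if placed + 1 == n_trips else 0.45
            n_for = int(rng.integers(4, max(5, int(frac * rem) + 1)))
            bearing = rng.vonmises(math.radians(group.bearing_deg), group.bearing_kappa)
            tr, tth = _build_trip(rng, apex, n_out, n_for, bearing, 0.6, 3.0, dt_h)
            if cursor + len(tr) > n_steps - 1:
                tr, tth = tr[: n_steps - 1 - cursor], tth[: n_steps - 1 - cursor]
            r[cursor : cursor + len(tr)] = tr
            th[cursor : cursor + len(tr)] = tth
            cursor += len(tr) + int(rng.integers(gap_steps, gap_steps + 4))
            placed += 1
        return r, th, "distant"

    # nearby strategy: repeated short forays, never beyond nearby_trip_max
    cursor = int(rng.integers(1, gap_steps))
    min_trip = max(4, int(math.ceil(3.5 / dt_h)) + 1)
    while cursor + min_trip + 1 < n_steps:
        apex = rng.uniform(cfg.nearby_trip_min_km, cfg.nearby_trip_max_km * 0.96)
        v = rng.uniform(2.0, 6.0) * 3.6
        n_out = max(2, int(math.ceil(apex / (v * dt_h))))
        n_for = int(rng.integers(2, 8))
        bearing = rng.uniform(0.0, 2.0 * np.pi)
        tr, tth = _build_trip(rng, apex, n_out, n_for, bearing, 4.0, 1.5, dt_h)
        if cursor + len(tr) > n_steps - 1:
            break
        r[cursor : cursor + len(tr)] = tr
        th[cursor : cursor + len(tr)] = tth
        # long at-nest attendance between forays: a handful of nearby trips
        # per window, so per-individual maxima spread over the nearby range
        cursor += len(tr) + int(rng.integers(gap_steps, max(gap_steps + 2, n_steps // 3)))
    return r, th, "nearby"


def simulate_tracks(config: SimConfig) -> list[Track]:
    """Generate one Track per configured individual.

    Nearby individuals never exceed ``nearby_trip_max_km`` from the colony;
    distant individuals execute 1-2 out-and-back excursions whose maximum
    displacement lies within ``distant_trip_range_km`` along the group's
    mean bearing. Every track starts and ends at the nest. Identical seed
    gives identical output.
    """
    times = config.times
    n_steps = len(times)
    dt_h = config.sampling_interval_min / 60.0
    year = int(config.window_start.year)
    tracks: list[Track] = []
    idx = 0
    for gname in config.groups:
        group = config.groups[gname]
        for j in range(group.n_individuals):
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0, idx)))
            r, th, strategy = _simulate_individual(rng, config, group, n_steps, dt_h)
            lon, lat = _destination(config.colony_lon, config.colony_lat, th, r)
            pts = pd.DataFrame({"timestamp": times, "lon": lon, "lat": lat})
            tracks.append(
                Track(
                    individual_id=f"{gname}_{j:02d}",
                    species=group.species,
                    sex=group.sex,
                    year=year,
                    nest=(config.colony_lon, config.colony_lat),
                    points=pts,
                    strategy_truth=strategy,
                )
            )
            idx += 1
    return tracks


def simulate_isotopes(tracks: list[Track], config: SimConfig) -> pd.DataFrame:
    """Blood-plasma isotope sample per individual.

    d13C = isoscape_intercept + isoscape_slope * (mean position latitude)
    + Gaussian noise; d15N = affine baseline of the realized d13C + the
    group's trophic offset + Gaussian noise.
    """
    rows = []
    for i, t in enumerate(tracks):
        if len(t) == 0:
            raise ValueError(f"track {t.individual_id} has no positions")
        gname = f"{t.species}_{t.sex}"
        if gname not in config.groups:
            raise ValueError(f"unknown group label {gname!r} for {t.individual_id}")
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, i)))
        mean_lat = float(t.points["lat"].mean())
        d13c = (
            config.isoscape_intercept
            + config.isoscape_slope * mean_lat
            + rng.normal(0.0, config.noise_sd)
        )
        d15n = (
            config.d15n_baseline_intercept
            + config.d15n_baseline_slope * d13c
            + config.groups[gname].trophic_offset
            + rng.normal(0.0, config.noise_sd)
        )
        rows.append(
            {
                "id": t.individual_id,
                "species": t.species,
                "sex": t.sex,
                "year": t.year,
                "group": gname,
                "mean_lat": mean_lat,
                "d13C": d13c,
                "d15N": d15n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EnvironmentalFieldSet:
    """Named gridded environmental variables sharing one lon/lat grid.

    ``data`` holds sst, ssh, wind_u, wind_v, eke (daily), chl (monthly) and
    depth (static); ``land_mask`` is boolean on the same grid.
    """

    data: xr.Dataset
    land_mask: xr.DataArray
    temporal_resolution: dict[str, str]

    def to_netcdf(self, path) -> None:
        ds = self.data.copy()
        ds["land_mask"] = self.land_mask.astype("i1")
        ds.attrs["temporal_resolution"] = ";".join(
            f"{k}={v}" for k, v in self.temporal_resolution.items()
        )
        ds.to_netcdf(path, engine="scipy")


def simulate_env_fields(
    config: SimConfig,
    resolution_deg: float = 0.25,
    lat_halfwidth: float = 22.0,
    lon_halfwidth: float = 25.0,
) -> EnvironmentalFieldSet:
    """Seven synthetic environmental variables plus a circular-island mask.

    SST is a monotone latitudinal gradient (``sst_gradient`` degC per degree
    latitude, warmer equatorward) with smooth noise, daily. Chlorophyll-a is
    monthly with an island-associated enhancement and heavy lognormal noise
    (emulating cloud-contaminated ocean-colour products). Depth is a static
    seamount rising from an abyssal plain. SSH anomaly, wind components and
    eddy kinetic energy are daily noise fields without a systematic
    latitudinal trend.
    """
    if resolution_deg * 111.195 >= 2.0 * config.island_radius_km:
        raise ValueError(
            "grid resolution coarser than the island diameter; the island would vanish"
        )
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    lat = np.arange(
        config.colony_lat - lat_halfwidth, config.colony_lat + lat_halfwidth + 1e-9, resolution_deg
    )
    lon = np.arange(
        config.colony_lon - lon_halfwidth, config.colony_lon + lon_halfwidth + 1e-9, resolution_deg
    )
    lat = lat[np.abs(lat) <= 90.0]
    glon, glat = np.meshgrid(lon, lat)
    from .tracks import great_circle_distance

    d_km = (
        great_circle_distance(
            np.column_stack([glon.ravel(), glat.ravel()]),
            np.array([config.colony_lon, config.colony_lat]),
        ).reshape(glat.shape)
        / 1000.0
    )
    days = pd.date_range(config.window_start.normalize(), config.window_end.normalize(), freq="D")
    months = pd.period_range(config.window_start, config.window_end, freq="M").to_timestamp()

    from scipy.ndimage import gaussian_filter

    def smooth(shape, sigma=6.0):
        return gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")

    base_sst = 8.0 + config.sst_gradient * (glat - config.colony_lat)
    sst = np.stack(
        [base_sst + 0.2 * rng.standard_normal() + 0.4 * smooth(glat.shape) for _ in days]
    )
    chl_island = 0.5 * np.exp(-((d_km / 150.0) ** 2))
    chl = np.stack(
        [
            np.exp(rng.normal(math.log(0.3), 0.6, glat.shape)) + chl_island
            for _ in months
        ]
    )
    depth = -5000.0 + 5300.0 * np.exp(-((d_km / 105.0) ** 2))
    ssh = np.stack([0.8 * smooth(glat.shape) for _ in days])
    wind_u = np.stack([6.0 + 2.0 * smooth(glat.shape, 10.0) + rng.normal(0, 1) for _ in days])
    wind_v = np.stack([2.0 * smooth(glat.shape, 10.0) for _ in days])
    eke = np.stack([0.02 + np.abs(0.3 * smooth(glat.shape)) for _ in days])

    coords_d = {"time": days, "lat": lat, "lon": lon}
    data = xr.Dataset(
        {
            "sst": (("time", "lat", "lon"), sst),
            "ssh": (("time", "lat", "lon"), ssh),
            "wind_u": (("time", "lat", "lon"), wind_u),
            "wind_v": (("time", "lat", "lon"), wind_v),
            "eke": (("time", "lat", "lon"), eke),
            "chl": (("time_month", "lat", "lon"), chl),
            "depth": (("lat", "lon"), depth),
        },
        coords={**coords_d, "time_month": months},
    )
    land_mask = xr.DataArray(
        d_km <= config.island_radius_km, coords={"lat": lat, "lon": lon}, dims=("lat", "lon")
    )
    resolution = {
        "sst": "daily",
        "ssh": "daily",
        "wind_u": "daily",
        "wind_v": "daily",
        "eke": "daily",
        "chl": "monthly",
        "depth": "static",
    }
    return EnvironmentalFieldSet(data=data, land_mask=land_mask, temporal_resolution=resolution)
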