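"""Kernel utilization distributions and spatial-overlap permutation tests.

Utilization distributions (UDs) are isotropic bivariate Gaussian kernel
densities evaluated on a regular lon/lat grid in raw degrees (matching a
degree-valued bandwidth h); the caveat is longitudinal distortion at high
latitude. A group UD is the equal-weight mean of its individuals' UDs, so
long tracks do not dominate and the permutation unit is the individual.

Overlap is Bhattacharyya's affinity BA = sum sqrt(p_i q_i) over grid cells;
segregation is tested by permuting individual labels within year and
recomputing BA, with p = (# permutations where observed > permuted) / n_perm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "Grid",
    "UtilizationDistribution",
    "BandwidthResult",
    "OverlapTestResult",
    "grid_from_points",
    "kde_ud",
    "individual_density_matrix",
    "volume_contour",
    "bhattacharyya_affinity",
    "adhoc_bandwidth",
    "overlap_permutation_test",
]


@dataclass(frozen=True)
class Grid:
    """Regular lon/lat grid defined by 1-D cell-centre coordinates."""

    lon: np.ndarray
    lat: np.ndarray

    @property
    def cell_area(self) -> float:
        dlon = self.lon[1] - self.lon[0] if len(self.lon) > 1 else 1.0
        dlat = self.lat[1] - self.lat[0] if len(self.lat) > 1 else 1.0
        return float(dlon * dlat)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.lat), len(self.lon))

    def same_as(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lon, other.lon)
            and np.allclose(self.lat, other.lat)
        )


@dataclass
class UtilizationDistribution:
    """Nonnegative density on a regular grid integrating to 1.

    ``density`` has shape (n_lat, n_lon); sum(density) * cell_area == 1.
    """

    grid: Grid
    density: np.ndarray
    h: float
    source: str | None = None

    def probabilities(self) -> np.ndarray:
        return self.density * self.grid.cell_area

    def to_netcdf(self, path) -> None:
        """Write the density field as a single-band NetCDF raster."""
        import xarray as xr

        da = xr.DataArray(
            self.density,
            coords={"lat": self.grid.lat, "lon": self.grid.lon},
            dims=("lat", "lon"),
            name="ud_density",
            attrs={"bandwidth_deg": self.h, "source": self.source or ""},
        )
        da.to_netcdf(path, engine="scipy")


@dataclass(frozen=True)
class BandwidthResult:
    h: float
    flag: str | None = None  # None | "disconnected_at_h0" | "floor"


@dataclass
class OverlapTestResult:
    comparison: tuple[str, str]
    contour_level: float | None
    observed_overlap: float
    permuted: np.ndarray
    p_value: float
    p_ci: tuple[float, float]
    n_permutations: int

    @property
    def permuted_mean(self) -> float:
        return float(np.mean(self.permuted))

    @property
    def permuted_sd(self) -> float:
        return float(np.std(self.permuted, ddof=1))


def grid_from_points(
    points: np.ndarray,
    h: float,
    margin_factor: float = 3.0,
    cells_per_h: float = 3.0,
    min_cells: int = 150,
    max_cells: int = 400,
) -> Grid:
    """Grid covering the points with a ``margin_factor * h`` margin and cell
    side ~ h / cells_per_h, floored at ``min_cells`` per axis."""
    pts = np.asarray(points, dtype=float)
    lo = pts.min(axis=0) - margin_factor * h
    hi = pts.max(axis=0) + margin_factor * h
    grids = []
    for ax in range(2):
        span = max(hi[ax] - lo[ax], 1e-9)
        n = int(np.clip(np.ceil(span / (h / cells_per_h)), min_cells, max_cells))
        edges = np.linspace(lo[ax], hi[ax], n + 1)
        grids.append((edges[:-1] + edges[1:]) / 2.0)
    return Grid(lon=grids[0], lat=grids[1])


def _density_on_grid(points: np.ndarray, h: float, grid: Grid) -> np.ndarray:
    """Sum of isotropic Gaussian kernels, renormalized on the grid.

    Separable evaluation: the (n_lat, n_pts) and (n_pts, n_lon) kernel
    factors multiply into the full field via one matrix product.
    """
    pts = np.asarray(points, dtype=float)
    inv2h2 = 1.0 / (2.0 * h * h)
    a = np.exp(-((grid.lat[:, None] - pts[None, :, 1]) ** 2) * inv2h2)
    b = np.exp(-((pts[:, None, 0] - grid.lon[None, :]) ** 2) * inv2h2)
    dens = a @ b
    total = dens.sum() * grid.cell_area
    if total <= 0:
        raise ValueError("density vanishes on the grid; enlarge the grid or h")
    return dens / total


def kde_ud(points: np.ndarray, h: float, grid: Grid, source: str | None = None) -> UtilizationDistribution:
    """Kernel UD of a point set (lon/lat degrees) with bandwidth ``h``
    (degrees), renormalized to integrate to 1 on the grid."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty point set")
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    return UtilizationDistribution(grid=grid, density=_density_on_grid(pts, h, grid), h=h, source=source)


def individual_density_matrix(
    points_by_id: Mapping[str, np.ndarray], h: float, grid: Grid
) -> tuple[list[str], np.ndarray]:
    """Per-individual normalized density fields, flattened to rows of an
    (n_individuals, n_cells) matrix (the group UD is a row average)."""
    ids = list(points_by_id)
    mat = np.empty((len(ids), grid.shape[0] * grid.shape[1]))
    for i, iid in enumerate(ids):
        mat[i] = _density_on_grid(np.asarray(points_by_id[iid], dtype=float), h, grid).ravel()
    return ids, mat


def group_ud(mat: np.ndarray, rows: np.ndarray, grid: Grid, h: float) -> UtilizationDistribution:
    dens = mat[rows].mean(axis=0).reshape(grid.shape)
    return UtilizationDistribution(grid=grid, density=dens, h=h)


def volume_contour(ud: UtilizationDistribution, level: float) -> np.ndarray:
    """Boolean mask of the percent-volume contour region: the smallest set
    of cells (by descending density) whose cumulative probability reaches
    ``level``/100."""
    if not 0.0 < level < 100.0:
        raise ValueError("contour level must be in (0, 100)")
    p = ud.probabilities().ravel()
    order = np.argsort(p)[::-1]
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, level / 100.0)) + 1
    mask = np.zeros(p.size, dtype=bool)
    mask[order[: min(k, p.size)]] = True
    return mask.reshape(ud.grid.shape)


def _masked_probabilities(ud: UtilizationDistribution, restrict_level: float | None) -> np.ndarray:
    p = ud.probabilities().ravel()
    if restrict_level is None:
        return p
    m = volume_contour(ud, restrict_level).ravel()
    p = np.where(m, p, 0.0)
    return p / p.sum()


def bhattacharyya_affinity(
    ud1: UtilizationDistribution,
    ud2: UtilizationDistribution,
    restrict_level: float | None = None,
) -> float:
    """BA = sum sqrt(p q) over cells, in [0, 1]; 1 iff identical, 0 iff
    disjoint. With ``restrict_level``, each UD is first masked to its own
    percent-volume contour and renormalized."""
    if not ud1.grid.same_as(ud2.grid):
        raise ValueError("utilization distributions are on different grids")
    p = _masked_probabilities(ud1, restrict_level)
    q = _masked_probabilities(ud2, restrict_level)
    return float(np.minimum(np.sqrt(p * q).sum(), 1.0))


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _n_components(points: np.ndarray, h: float, contour: float) -> int:
    grid = grid_from_points(points, h, min_cells=80, max_cells=300)
    ud = kde_ud(points, h, grid)
    mask = volume_contour(ud, contour)
    _, n = ndimage.label(mask, structure=_FOUR_CONN)
    return n


def adhoc_bandwidth(
    points: np.ndarray,
    h0: float,
    shrink: float = 0.5,
    contour: float = 95.0,
    max_steps: int = 20,
) -> BandwidthResult:
    """Ad-hoc bandwidth selection: start high and shrink geometrically until
    the percent-volume contour region breaks into more than one connected
    component (4-connectivity); return the smallest h that keeps it whole.

    If the region is already disconnected at ``h0`` the result carries the
    ``disconnected_at_h0`` flag; if it never breaks within ``max_steps``
    shrinkage steps, the floor value is returned with the ``floor`` flag.
    """
    if h0 <= 0:
        raise ValueError("h0 must be positive")
    if not 0.0 < shrink < 1.0:
        raise ValueError("shrink must be in (0, 1)")
    pts = np.asarray(points, dtype=float)
    if _n_components(pts, h0, contour) > 1:
        warnings.warn("contour region already disconnected at h0", stacklevel=2)
        return BandwidthResult(h=h0, flag="disconnected_at_h0")
    h = h0
    for _ in range(max_steps):
        h_next = h * shrink
        if _n_components(pts, h_next, contour) > 1:
            return BandwidthResult(h=h)
        h = h_next
    return BandwidthResult(h=h, flag="floor")


def _year_constrained_permutations(
    labels: np.ndarray, years: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) array of label permutations shuffled within each year.

    Years whose individuals all carry one label cannot be shuffled; a
    warning is issued and they are carried through unchanged.
    """
    n = len(labels)
    perms = np.tile(labels, (n_perm, 1))
    for yr in np.unique(years):
        sel = np.flatnonzero(years == yr)
        if len(np.unique(labels[sel])) < 2:
            warnings.warn(f"year {yr}: single-label individuals cannot be shuffled", stacklevel=3)
            continue
        for p in range(n_perm):
            perms[p, sel] = labels[sel[rng.permutation(len(sel))]]
    return perms


def overlap_permutation_test(
    points_by_id: Mapping[str, np.ndarray],
    labels: Mapping[str, str],
    years: Mapping[str, int],
    label_a: str,
    label_b: str,
    h: float,
    grid: Grid | None = None,
    contour_level: float | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    plus_one: bool = False,
) -> OverlapTestResult:
    """Year-constrained label-permutation test of spatial segregation.

    The observed BA between the two labels' group UDs is compared with the
    BA distribution under label shuffles within each year (group sizes per
    year preserved). p = (# permutations with observed > permuted) / n_perm
    (raw proportion; ``plus_one`` applies the (k+1)/(n+1) correction), with
    a Clopper-Pearson 95% interval.
    """
    ids = [i for i in points_by_id if labels[i] in (label_a, label_b)]
    lab = np.array([labels[i] for i in ids])
    yrs = np.array([years[i] for i in ids])
    for side in (label_a, label_b):
        if (lab == side).sum() < 2:
            raise ValueError(f"need >= 2 individuals with label {side!r}")
    if grid is None:
        pooled = np.vstack([np.asarray(points_by_id[i], dtype=float) for i in ids])
        grid = grid_from_points(pooled, h)
    _, mat = individual_density_matrix({i: points_by_id[i] for i in ids}, h, grid)

    def ba_for(assignment: np.ndarray) -> float:
        ud_a = group_ud(mat, assignment == label_a, grid, h)
        ud_b = group_ud(mat, assignment == label_b, grid, h)
        return bhattacharyya_affinity(ud_a, ud_b, restrict_level=contour_level)

    observed = ba_for(lab)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = _year_constrained_permutations(lab, yrs, n_perm, rng)
    permuted = np.array([ba_for(perms[p]) for p in range(n_perm)])
    greater = int((observed > permuted).sum())
    p = (greater + 1) / (n_perm + 1) if plus_one else greater / n_perm
    ci = stats.binomtest(greater, n_perm).proportion_ci(confidence_level=0.95, method="exact")
    return OverlapTestResult(
        comparison=(label_a, label_b),
        contour_level=contour_level,
        observed_overlap=observed,
        permuted=permuted,
        p_value=float(p),
        p_ci=(float(ci.low), float(ci.high)),
        n_permutations=n_perm,
    )
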