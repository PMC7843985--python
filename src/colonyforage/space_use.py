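"""Kernel utilization distributions, overlap indices and randomization null.

Foraging locations are projected onto a colony-centred azimuthal
equidistant plane (km), smoothed with an isotropic bivariate normal
kernel on a regular grid, and summarised as a utilization distribution
(UD): per-cell probability mass summing to 1.  The smoothing bandwidth
is the ad hoc bivariate reference value

    h_ref = 0.5 * (sd_x + sd_y) * n^(-1/6).

Percent-volume contours (25/50/75/95%) are the smallest cell sets
holding that share of the mass.  Space-use sharing between two species
is measured by Bhattacharyya's affinity

    BA = Σ_cells sqrt(p1 * p2)                       (0–1, 1 = identical)

and the utilization distribution overlap index

    UDOI = A_overlap * Σ_cells d1 * d2 * cell_area   (0 disjoint; 1 for
                                                      identical uniform
                                                      UDs; >1 possible)

where d are densities (mass / cell area) and A_overlap the area where
both UDs are positive.  Significance of low observed overlap is assessed
by permuting species labels over whole foraging trips and rebuilding
both UDs each time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory import EARTH_RADIUS_KM, FORAGING, ForagingTrip

UD_LEVELS = (25.0, 50.0, 75.0, 95.0)


def project_points(lon, lat, colony_lon: float, colony_lat: float) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat to km on an azimuthal equidistant plane at the colony.

    Great-circle distances from the colony are preserved exactly; x is
    east, y is north.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lon0, lat0 = np.radians(colony_lon), np.radians(colony_lat)
    cos_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))  # angular distance
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 0, c / np.sin(c), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(lon - lon0)
    y = EARTH_RADIUS_KM * k * (np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0))
    return np.atleast_1d(x), np.atleast_1d(y)


def unproject_points(x, y, colony_lon: float, colony_lat: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_points`."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    lon0, lat0 = np.radians(colony_lon), np.radians(colony_lat)
    c = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.where(
            c > 0,
            np.arcsin(np.cos(c) * np.sin(lat0) + y * np.sin(c) * np.cos(lat0) / np.where(c > 0, c, 1.0)),
            lat0,
        )
        lon = lon0 + np.arctan2(
            x * np.sin(c), c * np.cos(lat0) * np.cos(c) - y * np.sin(lat0) * np.sin(c)
        )
    lon = np.where(c > 0, lon, lon0)
    return np.degrees(np.atleast_1d(lon)), np.degrees(np.atleast_1d(lat))


@dataclass(frozen=True)
class GridSpec:
    """Regular analysis grid in the projected plane (km units).

    ``origin_x``/``origin_y`` locate the centre of cell (0, 0).
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.n_x < 1 or self.n_y < 1:
            raise ValueError("invalid grid specification")

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinate vectors (xs of length n_x, ys of length n_y)."""
        xs = self.origin_x + self.cell_size * np.arange(self.n_x)
        ys = self.origin_y + self.cell_size * np.arange(self.n_y)
        return xs, ys

    @classmethod
    def covering(cls, x: np.ndarray, y: np.ndarray, pad: float, n_cells: int = 250) -> "GridSpec":
        """Square-celled grid covering the points padded by ``pad`` km."""
        x_min, x_max = float(np.min(x)) - pad, float(np.max(x)) + pad
        y_min, y_max = float(np.min(y)) - pad, float(np.max(y)) + pad
        cell = max(x_max - x_min, y_max - y_min) / (n_cells - 1)
        return cls(x_min, y_min, cell, n_cells, n_cells)


@dataclass
class UtilizationDistribution:
    """Gridded probability mass of a species' foraging locations."""

    species: str
    grid: GridSpec
    mass: np.ndarray  # shape (n_y, n_x), sums to 1
    bandwidth_km: float

    def __post_init__(self) -> None:
        if self.mass.shape != (self.grid.n_y, self.grid.n_x):
            raise ValueError("mass array does not match grid shape")
        if np.any(self.mass < 0) or abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValueError("mass must be non-negative and sum to 1")


def href_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Ad hoc reference bandwidth h = 0.5·(sd_x + sd_y)·n^(−1/6)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two points")
    h = 0.5 * (x.std(ddof=1) + y.std(ddof=1)) * x.size ** (-1.0 / 6.0)
    if h <= 0:
        raise ValueError("all points identical; supply a bandwidth manually")
    return float(h)


def kernel_ud(
    x: np.ndarray,
    y: np.ndarray,
    h_km: float,
    grid: GridSpec,
    species: str = "",
    check_coverage: bool = True,
) -> UtilizationDistribution:
    """Bivariate-normal kernel UD on a grid, renormalized to sum to 1.

    Cell mass is proportional to Σ_points exp(−r²/2h²) at the cell
    centre; discrete renormalization over the grid guarantees a proper
    distribution on any finite grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one point")
    if h_km <= 0:
        raise ValueError("bandwidth must be positive")
    xs, ys = grid.centres()
    if check_coverage:
        half = grid.cell_size / 2
        if (
            x.min() < xs[0] - half + 3 * h_km
            or x.max() > xs[-1] + half - 3 * h_km
            or y.min() < ys[0] - half + 3 * h_km
            or y.max() > ys[-1] + half - 3 * h_km
        ):
            raise ValueError("grid does not cover the points padded by 3 bandwidths")
    # separable Gaussian: (n_y, n_pts) x (n_pts, n_x) contraction
    gx = np.exp(-((xs[None, :] - x[:, None]) ** 2) / (2 * h_km**2))  # (pts, n_x)
    gy = np.exp(-((ys[None, :] - y[:, None]) ** 2) / (2 * h_km**2))  # (pts, n_y)
    dens = gy.T @ gx  # (n_y, n_x)
    total = dens.sum()
    if total <= 0:
        raise ValueError("kernel mass vanished on the grid")
    return UtilizationDistribution(species, grid, dens / total, float(h_km))


def ud_contour(ud: UtilizationDistribution, level: float) -> np.ndarray:
    """Boolean mask of the percent-volume contour at ``level`` (0–100).

    The smallest set of cells — by descending density, ties broken by
    flat cell index for reproducibility — whose cumulative mass reaches
    level/100.
    """
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    flat = ud.mass.ravel()
    # stable sort on negated mass gives descending density, index-ordered ties
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    n_keep = int(np.searchsorted(csum, level / 100.0 - 1e-12)) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_keep]] = True
    return mask.reshape(ud.mass.shape)


def conditional_ud(ud: UtilizationDistribution, level: float) -> UtilizationDistribution:
    """UD restricted to its ``level``% contour and renormalized."""
    mask = ud_contour(ud, level)
    mass = np.where(mask, ud.mass, 0.0)
    return UtilizationDistribution(ud.species, ud.grid, mass / mass.sum(), ud.bandwidth_km)


def _check_same_grid(ud1: UtilizationDistribution, ud2: UtilizationDistribution) -> None:
    if ud1.grid != ud2.grid:
        raise ValueError("overlap indices require UDs on the same grid")


def ba_index(ud1: UtilizationDistribution, ud2: UtilizationDistribution) -> float:
    """Bhattacharyya's affinity Σ√(p1·p2) ∈ [0, 1]."""
    _check_same_grid(ud1, ud2)
    return float(np.sqrt(ud1.mass * ud2.mass).sum())


def udoi_index(ud1: UtilizationDistribution, ud2: UtilizationDistribution) -> float:
    """Utilization distribution overlap index (≥ 0)."""
    _check_same_grid(ud1, ud2)
    area = ud1.grid.cell_area
    both = (ud1.mass > 0) & (ud2.mass > 0)
    a_overlap = float(both.sum()) * area
    integral = float((ud1.mass / area * ud2.mass / area * area).sum())
    return a_overlap * integral


def _foraging_xy(trip: ForagingTrip, colony: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    mask = trip.fixes["behaviour"] == FORAGING
    return project_points(
        trip.fixes.loc[mask, "lon"].to_numpy(),
        trip.fixes.loc[mask, "lat"].to_numpy(),
        colony[0],
        colony[1],
    )


def species_ud_pair(
    trips_a: list[ForagingTrip],
    trips_b: list[ForagingTrip],
    colony: tuple[float, float],
    level: float | None = None,
    n_cells: int = 250,
    h_a: float | None = None,
    h_b: float | None = None,
) -> tuple[UtilizationDistribution, UtilizationDistribution]:
    """Per-group UDs of foraging fixes on a common grid.

    The grid is the union bounding box of both groups' foraging points,
    padded by three times the larger bandwidth.  With ``level`` set, each
    UD is conditioned on (restricted to and renormalized within) its own
    percent-volume contour.
    """
    xa, ya = map(np.concatenate, zip(*[_foraging_xy(t, colony) for t in trips_a]))
    xb, yb = map(np.concatenate, zip(*[_foraging_xy(t, colony) for t in trips_b]))
    if h_a is None:
        h_a = href_bandwidth(xa, ya)
    if h_b is None:
        h_b = href_bandwidth(xb, yb)
    grid = GridSpec.covering(
        np.concatenate([xa, xb]), np.concatenate([ya, yb]), pad=3.0 * max(h_a, h_b), n_cells=n_cells
    )
    name_a = trips_a[0].species if trips_a else "A"
    name_b = trips_b[0].species if trips_b else "B"
    ud_a = kernel_ud(xa, ya, h_a, grid, species=name_a)
    ud_b = kernel_ud(xb, yb, h_b, grid, species=name_b)
    if level is not None:
        ud_a = conditional_ud(ud_a, level)
        ud_b = conditional_ud(ud_b, level)
    return ud_a, ud_b


@dataclass
class OverlapResult:
    """Observed BA/UDOI for a species pair plus their permutation null."""

    pair: tuple[str, str]
    level: float | None
    ba: float
    udoi: float
    null_ba: np.ndarray
    null_udoi: np.ndarray
    p_ba: float
    p_udoi: float
    wilcoxon_ba: tuple[float, float] = field(default=(np.nan, np.nan))
    wilcoxon_udoi: tuple[float, float] = field(default=(np.nan, np.nan))
    n_iter: int = 0
    seed: int | None = None


def overlap_randomization(
    trips_a: list[ForagingTrip],
    trips_b: list[ForagingTrip],
    colony: tuple[float, float],
    level: float | None = 95.0,
    n_iter: int = 1000,
    seed: int | None = None,
    n_cells: int = 100,
    freeze_bandwidth: bool = False,
) -> OverlapResult:
    """Trip-label randomization test for space-use overlap.

    The null reassigns species labels to whole foraging trips (keeping
    per-group trip counts), rebuilds both UDs — re-estimating h_ref per
    permuted group unless ``freeze_bandwidth`` — and recomputes BA and
    UDOI each of ``n_iter`` times.  The one-sided p-value for the
    observed overlap being *lower* than expected under exchangeability is
    (1 + #{null ≤ observed}) / (n_iter + 1).  A Mann–Whitney rank test of
    the observed value against the null sample is also reported.
    """
    if len(trips_a) < 2 or len(trips_b) < 2:
        raise ValueError("need at least 2 trips per group")
    rng = np.random.default_rng(seed)

    def pair_indices(ta, tb, h_a=None, h_b=None):
        ud_a, ud_b = species_ud_pair(ta, tb, colony, level=level, n_cells=n_cells, h_a=h_a, h_b=h_b)
        return ba_index(ud_a, ud_b), udoi_index(ud_a, ud_b), ud_a.bandwidth_km, ud_b.bandwidth_km

    ba_obs, udoi_obs, h_a_obs, h_b_obs = pair_indices(trips_a, trips_b)

    all_trips = list(trips_a) + list(trips_b)
    n_a = len(trips_a)
    null_ba = np.empty(n_iter)
    null_udoi = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(len(all_trips))
        grp_a = [all_trips[j] for j in perm[:n_a]]
        grp_b = [all_trips[j] for j in perm[n_a:]]
        if freeze_bandwidth:
            b, u, _, _ = pair_indices(grp_a, grp_b, h_a=h_a_obs, h_b=h_b_obs)
        else:
            b, u, _, _ = pair_indices(grp_a, grp_b)
        null_ba[i] = b
        null_udoi[i] = u

    p_ba = (1.0 + np.sum(null_ba <= ba_obs)) / (n_iter + 1.0)
    p_udoi = (1.0 + np.sum(null_udoi <= udoi_obs)) / (n_iter + 1.0)
    w_ba = stats.mannwhitneyu([ba_obs], null_ba, alternative="less", method="asymptotic")
    w_udoi = stats.mannwhitneyu([udoi_obs], null_udoi, alternative="less", method="asymptotic")

    name_a = trips_a[0].species
    name_b = trips_b[0].species
    return OverlapResult(
        pair=(name_a, name_b),
        level=level,
        ba=ba_obs,
        udoi=udoi_obs,
        null_ba=null_ba,
        null_udoi=null_udoi,
        p_ba=float(p_ba),
        p_udoi=float(p_udoi),
        wilcoxon_ba=(float(w_ba.statistic), float(w_ba.pvalue)),
        wilcoxon_udoi=(float(w_udoi.statistic), float(w_udoi.pvalue)),
        n_iter=n_iter,
        seed=seed,
    )


def export_ud_ascii(ud: UtilizationDistribution, path) -> None:
    """Write a UD as an ESRI ASCII grid (km coordinates, row 0 at top)."""
    g = ud.grid
    header = (
        f"ncols {g.n_x}\nnrows {g.n_y}\n"
        f"xllcorner {g.origin_x - g.cell_size / 2}\n"
        f"yllcorner {g.origin_y - g.cell_size / 2}\n"
        f"cellsize {g.cell_size}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, ud.mass[::-1], fmt="%.10e")


def contour_geojson(ud: UtilizationDistribution, levels, colony: tuple[float, float]) -> dict:
    """Contour masks as a GeoJSON FeatureCollection of cell polygons."""
    feats = []
    xs, ys = ud.grid.centres()
    half = ud.grid.cell_size / 2
    for level in levels:
        mask = ud_contour(ud, level)
        polys = []
        for iy, ix in zip(*np.nonzero(mask)):
            cx, cy = xs[ix], ys[iy]
            corners_x = [cx - half, cx + half, cx + half, cx - half, cx - half]
            corners_y = [cy - half, cy - half, cy + half, cy + half, cy - half]
            lon, lat = unproject_points(corners_x, corners_y, colony[0], colony[1])
            polys.append([[[float(a), float(b)] for a, b in zip(lon, lat)]])
        feats.append(
            {
                "type": "Feature",
                "properties": {"species": ud.species, "level": level},
                "geometry": {"type": "MultiPolygon", "coordinates": polys},
            }
        )
    return {"type": "FeatureCollection", "features": feats}
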