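"""Per-trip foraging metrics.

Seven metrics summarise each complete foraging trip and feed the PCA and
group comparisons:

* maximum distance from the colony (km)
* trip duration (h)
* Foraging Range Index, FRI (km): mean distance from the colony over
  foraging-classified fixes — the typical distance at which the bird
  actually foraged
* distance at which the bird first stops (km)
* number of patches visited (maximal runs of consecutive foraging fixes)
* departure time (local hour of day)
* commuting index, CI = 1 − 2·MAD, where MAD is the mean absolute
  deviation of relative foraging distances (distance to colony scaled by
  the trip's maximum: 0 at the colony, 1 at the furthest point).  CI = 1
  means all foraging happened at one distance (pure commuting out and
  back); values near 0.5 arise when foraging is spread uniformly along
  the route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .trajectory import FORAGING, ForagingTrip


@dataclass
class TripMetrics:
    trip_id: str
    bird_id: str
    species: str
    max_distance_km: float
    duration_h: float
    fri_km: float
    first_stop_km: float
    n_patches: int
    departure_time_h: float
    ci: float

    def as_dict(self) -> dict:
        return asdict(self)


#: Columns fed to the PCA, in a fixed order.
METRIC_COLUMNS = [
    "departure_time_h",
    "max_distance_km",
    "duration_h",
    "fri_km",
    "first_stop_km",
    "n_patches",
    "ci",
]


def _foraging_distances(trip: ForagingTrip) -> np.ndarray:
    mask = trip.fixes["behaviour"] == FORAGING
    return trip.fixes.loc[mask, "dist_to_colony_km"].to_numpy()


def fri(trip: ForagingTrip) -> float:
    """Foraging Range Index: mean colony distance over foraging fixes.

    NaN (undefined) when the trip contains no foraging-classified fix;
    such trips are excluded from FRI comparisons.
    """
    d = _foraging_distances(trip)
    return float(np.mean(d)) if d.size else math.nan


def commuting_index(trip: ForagingTrip) -> float:
    """CI = 1 − 2·MAD of relative foraging distances, in [0, 1]."""
    d = _foraging_distances(trip)
    if d.size == 0:
        return math.nan
    max_d = float(trip.fixes["dist_to_colony_km"].max())
    if max_d <= 0:
        return math.nan
    x = d / max_d
    mad = float(np.mean(np.abs(x - x.mean())))
    return 1.0 - 2.0 * mad


def count_patches(trip: ForagingTrip, merge_radius_km: float | None = None) -> int:
    """Number of food patches visited: maximal runs of foraging fixes.

    With ``merge_radius_km`` set, consecutive runs whose mean positions
    lie within that distance are merged into one patch (off by default;
    a stop is a stop).
    """
    is_f = (trip.fixes["behaviour"] == FORAGING).to_numpy()
    if not is_f.any():
        return 0
    run_start = is_f & ~np.concatenate([[False], is_f[:-1]])
    if merge_radius_km is None:
        return int(run_start.sum())
    # merge successive runs by centroid proximity
    runs = []
    run_id = np.cumsum(run_start)
    for _, block in trip.fixes[is_f].groupby(run_id[is_f]):
        runs.append((block["lon"].mean(), block["lat"].mean()))
    from .trajectory import haversine_km

    n = 1
    for (lo1, la1), (lo2, la2) in zip(runs, runs[1:]):
        if haversine_km(lo1, la1, lo2, la2) > merge_radius_km:
            n += 1
    return n


def first_stop_distance(trip: ForagingTrip) -> float:
    """Colony distance of the first fix of the first foraging run."""
    is_f = (trip.fixes["behaviour"] == FORAGING).to_numpy()
    if not is_f.any():
        return math.nan
    return float(trip.fixes["dist_to_colony_km"].iloc[int(np.argmax(is_f))])


def compute_trip_metrics(trip: ForagingTrip, local_utc_offset_h: float = -4.0) -> TripMetrics:
    """All seven metrics for one complete trip.

    ``local_utc_offset_h`` converts UTC departure instants to local hour
    of day (default −4, the study region's offset).
    """
    dist = trip.fixes["dist_to_colony_km"]
    duration = (trip.end - trip.start).total_seconds() / 3600.0
    dep_utc = trip.start
    departure = (dep_utc.hour + dep_utc.minute / 60.0 + dep_utc.second / 3600.0 + local_utc_offset_h) % 24.0
    return TripMetrics(
        trip_id=trip.trip_id,
        bird_id=trip.bird_id,
        species=trip.species,
        max_distance_km=float(dist.max()),
        duration_h=float(duration),
        fri_km=fri(trip),
        first_stop_km=first_stop_distance(trip),
        n_patches=count_patches(trip),
        departure_time_h=float(departure),
        ci=commuting_index(trip),
    )


def metrics_table(trips: list[ForagingTrip], local_utc_offset_h: float = -4.0) -> pd.DataFrame:
    """One row of metrics per trip, ready for PCA / group statistics."""
    rows = [compute_trip_metrics(t, local_utc_offset_h).as_dict() for t in trips]
    return pd.DataFrame(rows)
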