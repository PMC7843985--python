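"""GPS fix cleaning, geometry, behaviour classification and trip splitting.

A track is a time-sorted table of GPS fixes for one bird.  Behaviour at
each fix is classified with two rules:

1. *colony* — the fix lies within the species' splash-down radius of the
   colony (birds rest, wash and preen on the water near the colony, so
   near-colony positions are not foraging);
2. otherwise *flying* if the instantaneous speed from the previous fix is
   at or above a speed threshold, else *foraging*.

The threshold is the harmonic mean of a species' typical drift speed and
average flight speed,

    v* = 2 * drift * flight / (drift + flight),

which sits between the two speed regimes and is conservative for the
slower one.  Per-species thresholds may be averaged into a common
threshold applied to all species.

Maximal runs of consecutive non-colony fixes form candidate foraging
trips; candidates with at least ``min_fixes`` positions (default 5) are
kept as complete trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

FIX_COLUMNS = ["bird_id", "species", "timestamp", "lon", "lat", "n_satellites"]

#: Behaviour labels used throughout the package.
COLONY, FLYING, FORAGING = "colony", "flying", "foraging"


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species configuration for classification and diet estimation.

    Parameters
    ----------
    species:
        Species label as it appears in the fix table.
    colony_lon, colony_lat:
        Colony coordinates, degrees WGS84.
    splash_radius_m:
        Colony-centred exclusion radius in metres; fixes inside it are
        classified ``colony``.
    flight_speed_kmh, drift_speed_kmh:
        Average flight speed and on-water drift speed in km/h; inputs to
        the speed threshold.
    bill_length_mm:
        Mean culmen length, used by the diet module to convert pixel
        ratios to prey lengths.
    """

    species: str
    colony_lon: float
    colony_lat: float
    splash_radius_m: float
    flight_speed_kmh: float
    drift_speed_kmh: float = 5.0
    bill_length_mm: float | None = None

    def __post_init__(self) -> None:
        if self.splash_radius_m <= 0:
            raise ValueError("splash_radius_m must be positive")
        if not (self.flight_speed_kmh > self.drift_speed_kmh > 0):
            raise ValueError("require flight_speed > drift_speed > 0")

    @property
    def colony(self) -> tuple[float, float]:
        return (self.colony_lon, self.colony_lat)


# Betchouanes colony (50°11' N, 63°13' W), the GPS-tracked sub-colony.
BETCHOUANES = (-63.0 - 13.0 / 60.0, 50.0 + 11.0 / 60.0)
# Île de la Maison (50°13' N, 64°12' W), the second diet-watch island.
ILE_DE_LA_MAISON = (-64.0 - 12.0 / 60.0, 50.0 + 13.0 / 60.0)

DEFAULT_SPECIES_PARAMS: dict[str, SpeciesParams] = {
    "razorbill": SpeciesParams(
        "razorbill", *BETCHOUANES, splash_radius_m=1000.0,
        flight_speed_kmh=80.0, drift_speed_kmh=5.0, bill_length_mm=34.3,
    ),
    "murre": SpeciesParams(
        "murre", *BETCHOUANES, splash_radius_m=3000.0,
        flight_speed_kmh=80.0, drift_speed_kmh=5.0, bill_length_mm=43.9,
    ),
    "kittiwake": SpeciesParams(
        "kittiwake", *BETCHOUANES, splash_radius_m=5000.0,
        flight_speed_kmh=47.0, drift_speed_kmh=5.0, bill_length_mm=None,
    ),
    # Puffins were diet-watched but not GPS-tracked; bill length only.
    "puffin": SpeciesParams(
        "puffin", *BETCHOUANES, splash_radius_m=1000.0,
        flight_speed_kmh=80.0, drift_speed_kmh=5.0, bill_length_mm=49.1,
    ),
}


@dataclass
class ForagingTrip:
    """One complete at-sea excursion beyond the splash-down radius.

    ``fixes`` is a labelled-fix DataFrame slice (columns of
    :func:`classify_behaviour`) whose rows are all non-colony.
    """

    trip_id: str
    bird_id: str
    species: str
    fixes: pd.DataFrame
    complete: bool = True

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[-1]

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km between WGS84 points (vectorized).

    Uses the haversine formula with mean Earth radius 6371.0088 km.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def speed_threshold(drift_kmh: float, flight_kmh: float) -> float:
    """Flying/foraging speed threshold: harmonic mean of drift and flight speed."""
    if drift_kmh <= 0 or flight_kmh <= 0:
        raise ValueError("speeds must be positive")
    return 2.0 * drift_kmh * flight_kmh / (drift_kmh + flight_kmh)


def common_threshold(params: Iterable[SpeciesParams]) -> float:
    """Arithmetic mean of the per-species speed thresholds."""
    thresholds = [speed_threshold(p.drift_speed_kmh, p.flight_speed_kmh) for p in params]
    if not thresholds:
        raise ValueError("at least one species required")
    return float(np.mean(thresholds))


def clean_fixes(raw: pd.DataFrame) -> pd.DataFrame:
    """Apply the standard cleaning rules to a raw fix table.

    Removes fixes with fewer than four satellites, exact duplicated
    (bird, timestamp) rows and consecutive repeats of an identical
    position + timestamp, then sorts by bird and time.  Unparseable
    timestamp rows are dropped with a logged count.
    """
    df = raw.copy()
    n0 = len(df)
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = ts.isna() | df["lon"].isna() | df["lat"].isna()
    if bad.any():
        logger.warning("dropping %d unparseable fix rows", int(bad.sum()))
    df = df.loc[~bad].copy()
    df["timestamp"] = ts.loc[~bad]

    df = df[df["n_satellites"] >= 4]
    df = df.sort_values(["bird_id", "timestamp"], kind="stable")
    df = df.drop_duplicates(subset=["bird_id", "timestamp"], keep="first")
    # consecutive identical position repeats within a bird
    same_pos = (
        df["bird_id"].eq(df["bird_id"].shift())
        & df["lon"].eq(df["lon"].shift())
        & df["lat"].eq(df["lat"].shift())
        & df["timestamp"].eq(df["timestamp"].shift())
    )
    df = df.loc[~same_pos].reset_index(drop=True)
    logger.info("clean_fixes: %d -> %d rows", n0, len(df))
    return df


def classify_behaviour(
    fixes: pd.DataFrame,
    params: SpeciesParams,
    threshold_kmh: float | None = None,
) -> pd.DataFrame:
    """Label each fix of one bird colony / flying / foraging.

    Adds ``dist_to_colony_km``, ``speed_kmh`` (from the previous fix;
    NaN on the first fix) and ``behaviour``.  A fix is ``colony`` iff its
    distance to the colony is within the splash-down radius; otherwise it
    is ``flying`` when its arrival speed is at or above the threshold and
    ``foraging`` when below.  The first fix of a track, whose speed is
    undefined, is labelled by the distance rule alone (colony if inside
    the radius, foraging otherwise).

    ``threshold_kmh`` defaults to the species' own harmonic-mean
    threshold; pass :func:`common_threshold` output to use a shared one.
    """
    if fixes["bird_id"].nunique() > 1:
        raise ValueError("classify_behaviour expects fixes for a single bird")
    ts = fixes["timestamp"]
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing within a bird")
    if threshold_kmh is None:
        threshold_kmh = speed_threshold(params.drift_speed_kmh, params.flight_speed_kmh)

    out = fixes.copy()
    out["dist_to_colony_km"] = haversine_km(
        out["lon"].to_numpy(), out["lat"].to_numpy(), params.colony_lon, params.colony_lat
    )
    step_km = haversine_km(
        out["lon"].to_numpy()[:-1], out["lat"].to_numpy()[:-1],
        out["lon"].to_numpy()[1:], out["lat"].to_numpy()[1:],
    )
    dt_h = np.diff(ts.astype("int64").to_numpy()) / 3.6e12
    speed = np.full(len(out), np.nan)
    if len(out) > 1:
        speed[1:] = step_km / dt_h
    out["speed_kmh"] = speed

    at_colony = out["dist_to_colony_km"].to_numpy() * 1000.0 <= params.splash_radius_m
    behaviour = np.where(speed >= threshold_kmh, FLYING, FORAGING)
    behaviour[np.isnan(speed)] = FORAGING  # first fix: distance rule only
    behaviour = np.where(at_colony, COLONY, behaviour)
    out["behaviour"] = behaviour
    return out


def split_trips(
    labelled: pd.DataFrame,
    params: SpeciesParams,
    min_fixes: int = 5,
    max_gap_factor: float = 3.0,
    sampling_interval_min: float | None = None,
    include_incomplete: bool = False,
) -> list[ForagingTrip]:
    """Split one bird's labelled fixes into complete foraging trips.

    Candidate trips are maximal runs of consecutive non-colony fixes;
    time gaps longer than ``max_gap_factor`` times the sampling interval
    (inferred as the median fix spacing when not given) additionally break
    a run.  Candidates with at least ``min_fixes`` positions are returned.
    A trip that is still at sea when the record ends (not followed by a
    colony fix) is tagged incomplete and dropped unless
    ``include_incomplete`` is set.
    """
    if labelled.empty:
        return []
    ts = labelled["timestamp"]
    dt_min = ts.diff().dt.total_seconds().to_numpy() / 60.0
    if sampling_interval_min is None:
        with np.errstate(invalid="ignore"):
            sampling_interval_min = float(np.nanmedian(dt_min)) if len(labelled) > 1 else 15.0
    gap_break = np.nan_to_num(dt_min, nan=0.0) > max_gap_factor * sampling_interval_min

    at_sea = (labelled["behaviour"] != COLONY).to_numpy()
    new_run = at_sea & (~np.roll(at_sea, 1) | gap_break)
    new_run[0] = at_sea[0]
    run_id = np.cumsum(new_run)

    bird = str(labelled["bird_id"].iloc[0])
    species = str(labelled["species"].iloc[0])
    trips: list[ForagingTrip] = []
    n_discarded = 0
    for rid, block in labelled[at_sea].groupby(run_id[at_sea]):
        if len(block) < min_fixes:
            n_discarded += 1
            continue
        last_pos = labelled.index.get_loc(block.index[-1])
        complete = last_pos + 1 < len(labelled)  # a later (colony) fix exists
        if not complete and not include_incomplete:
            n_discarded += 1
            continue
        trips.append(
            ForagingTrip(
                trip_id=f"{bird}_trip{len(trips) + 1:03d}",
                bird_id=bird,
                species=species,
                fixes=block.reset_index(drop=True),
                complete=complete,
            )
        )
    if n_discarded:
        logger.info("split_trips(%s): discarded %d short/incomplete candidates", bird, n_discarded)
    return trips


def segment_tracks(
    fixes: pd.DataFrame,
    params_by_species: dict[str, SpeciesParams],
    threshold: str | float = "common",
    **split_kwargs,
) -> tuple[pd.DataFrame, list[ForagingTrip]]:
    """Clean, classify and split a multi-bird fix table.

    ``threshold`` is ``"common"`` (average of per-species thresholds over
    the species present, the default), ``"per-species"``, or an explicit
    km/h value.  Returns the labelled fix table (all birds) and the list
    of complete trips.
    """
    cleaned = clean_fixes(fixes)
    species_present = [s for s in params_by_species if s in set(cleaned["species"])]
    if threshold == "common":
        thr_value: float | None = common_threshold([params_by_species[s] for s in species_present])
    elif threshold == "per-species":
        thr_value = None
    else:
        thr_value = float(threshold)

    labelled_parts = []
    trips: list[ForagingTrip] = []
    for bird, track in cleaned.groupby("bird_id", sort=True):
        species = str(track["species"].iloc[0])
        params = params_by_species[species]
        lab = classify_behaviour(track.reset_index(drop=True), params, thr_value)
        labelled_parts.append(lab)
        trips.extend(split_trips(lab, params, **split_kwargs))
    labelled = pd.concat(labelled_parts, ignore_index=True) if labelled_parts else cleaned
    return labelled, trips
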