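import numpy as np
import pandas as pd
import pytest

from colonyforage.synthetic import SimScenario, simulate_tracks
from colonyforage.trajectory import SpeciesParams, classify_behaviour, segment_tracks

COLONY = (-63.2167, 50.1833)


def make_labelled_trip(distances_km, behaviours, start="2019-06-15 06:00:00",
                       step_min=5, bird="B1", species="murre"):
    """Hand-built labelled-fix frame -> ForagingTrip, bypassing geometry.

    ``distances_km`` are colony distances; lon/lat are placed due north of
    the colony at those distances so geometry stays consistent.
    """
    from colonyforage.trajectory import ForagingTrip

    n = len(distances_km)
    ts = pd.date_range(start, periods=n, freq=f"{step_min}min", tz="UTC")
    lat = COLONY[1] + np.asarray(distances_km) / 111.19492664455873
    df = pd.DataFrame({
        "bird_id": bird, "species": species, "timestamp": ts,
        "lon": COLONY[0], "lat": lat, "n_satellites": 9,
        "dist_to_colony_km": np.asarray(distances_km, dtype=float),
        "speed_kmh": np.nan,
        "behaviour": list(behaviours),
    })
    return ForagingTrip(trip_id="T1", bird_id=bird, species=species, fixes=df)


@pytest.fixture(scope="session")
def default_scenario():
    return SimScenario(
        "murre",
        splash_radius_m=3000.0,
        patch_centers=((15.0, 8.0), (20.0, -5.0), (12.0, -12.0)),
        patch_visit_rate=2.0,
        n_birds=4,
        n_days=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def simulated(default_scenario):
    return simulate_tracks(default_scenario)


@pytest.fixture(scope="session")
def murre_params(default_scenario):
    sc = default_scenario
    return SpeciesParams("murre", sc.colony_lon, sc.colony_lat,
                         sc.splash_radius_m, sc.flight_speed_kmh, sc.drift_speed_kmh,
                         bill_length_mm=43.9)


@pytest.fixture(scope="session")
def segmented(simulated, murre_params):
    fixes, _ = simulated
    labelled, trips = segment_tracks(fixes, {"murre": murre_params})
    return labelled, trips
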