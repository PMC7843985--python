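"""Cleaning rules, great-circle geometry, speed threshold, trip splitting."""

import numpy as np
import pandas as pd
import pytest

from colonyforage.trajectory import (
    BETCHOUANES,
    DEFAULT_SPECIES_PARAMS,
    ILE_DE_LA_MAISON,
    SpeciesParams,
    classify_behaviour,
    clean_fixes,
    common_threshold,
    haversine_km,
    speed_threshold,
    split_trips,
)

COLONY = BETCHOUANES


def _fix_frame(rows):
    return pd.DataFrame(rows, columns=["bird_id", "species", "timestamp", "lon", "lat", "n_satellites"])


class TestHaversine:
    def test_identity(self):
        assert haversine_km(-63.2, 50.2, -63.2, 50.2) == 0.0

    def test_subcolony_separation_about_70km(self):
        d = haversine_km(*BETCHOUANES, *ILE_DE_LA_MAISON)
        assert d == pytest.approx(70.0, abs=1.5)

    def test_one_degree_latitude(self):
        assert haversine_km(-63.0, 50.0, -63.0, 51.0) == pytest.approx(111.19, abs=0.1)

    def test_symmetry_vectorized(self):
        lon = np.array([-63.0, -64.0])
        lat = np.array([50.0, 50.5])
        fwd = haversine_km(lon, lat, -63.5, 50.2)
        back = haversine_km(-63.5, 50.2, lon, lat)
        np.testing.assert_allclose(fwd, back)


class TestSpeedThreshold:
    @pytest.mark.parametrize(
        "drift, flight, expected",
        [(5.0, 80.0, 9.41), (5.0, 47.0, 9.04)],
    )
    def test_published_thresholds(self, drift, flight, expected):
        assert speed_threshold(drift, flight) == pytest.approx(expected, abs=0.005)

    def test_harmonic_mean_of_equal_speeds(self):
        assert speed_threshold(12.0, 12.0) == pytest.approx(12.0)

    def test_common_threshold_of_three_study_species(self):
        params = [DEFAULT_SPECIES_PARAMS[s] for s in ("murre", "razorbill", "kittiwake")]
        assert common_threshold(params) == pytest.approx(9.29, abs=0.005)

    def test_common_threshold_single_species(self):
        p = DEFAULT_SPECIES_PARAMS["murre"]
        assert common_threshold([p]) == speed_threshold(p.drift_speed_kmh, p.flight_speed_kmh)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            speed_threshold(0.0, 80.0)
        with pytest.raises(ValueError):
            common_threshold([])


class TestCleanFixes:
    def test_low_satellite_rows_removed_and_duplicates_collapsed(self):
        raw = _fix_frame([
            ("b1", "murre", "2019-06-15T00:00:00Z", -63.0, 50.0, 3),
            ("b1", "murre", "2019-06-15T00:05:00Z", -63.0, 50.1, 8),
            ("b1", "murre", "2019-06-15T00:05:00Z", -63.0, 50.1, 8),
            ("b1", "murre", "2019-06-15T00:10:00Z", -63.0, 50.2, 4),
        ])
        out = clean_fixes(raw)
        assert len(out) == 2
        assert (out["n_satellites"] >= 4).all()

    def test_idempotent_on_clean_input(self):
        raw = _fix_frame([
            ("b1", "murre", "2019-06-15T00:00:00Z", -63.0, 50.0, 7),
            ("b1", "murre", "2019-06-15T00:05:00Z", -63.1, 50.1, 7),
        ])
        once = clean_fixes(raw)
        twice = clean_fixes(once.assign(timestamp=once["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")))
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_sorted_by_bird_then_time(self):
        raw = _fix_frame([
            ("b2", "murre", "2019-06-15T00:05:00Z", -63.0, 50.0, 7),
            ("b1", "murre", "2019-06-15T00:10:00Z", -63.0, 50.0, 7),
            ("b1", "murre", "2019-06-15T00:00:00Z", -63.0, 50.1, 7),
        ])
        out = clean_fixes(raw)
        assert list(out["bird_id"]) == ["b1", "b1", "b2"]
        assert out.groupby("bird_id")["timestamp"].is_monotonic_increasing.all()


class TestClassifyBehaviour:
    def _track(self, dist_km, minutes):
        lat = [COLONY[1] + d / 111.19492664455873 for d in dist_km]
        ts = [pd.Timestamp("2019-06-15 00:00:00", tz="UTC") + pd.Timedelta(minutes=m) for m in minutes]
        return pd.DataFrame({
            "bird_id": "b1", "species": "razorbill", "timestamp": ts,
            "lon": COLONY[0], "lat": lat, "n_satellites": 8,
        })

    def test_splash_radius_rules(self):
        params = DEFAULT_SPECIES_PARAMS["razorbill"]
        track = self._track([0.5, 10.0], [0, 10])
        lab = classify_behaviour(track, params, 9.29)
        assert lab["behaviour"].iloc[0] == "colony"  # 500 m < 1 km radius

    def test_speed_at_threshold_is_flying(self):
        params = DEFAULT_SPECIES_PARAMS["razorbill"]
        # second fix exactly 9.29 km/h: 9.29 km in 60 min
        track = self._track([10.0, 19.29], [0, 60])
        lab = classify_behaviour(track, params, 9.29)
        assert lab["behaviour"].iloc[1] == "flying"
        below = classify_behaviour(self._track([10.0, 19.28], [0, 60]), params, 9.29)
        assert below["behaviour"].iloc[1] == "foraging"

    def test_first_fix_labelled_by_distance_only(self):
        params = DEFAULT_SPECIES_PARAMS["razorbill"]
        lab = classify_behaviour(self._track([10.0, 11.0], [0, 5]), params, 9.29)
        assert np.isnan(lab["speed_kmh"].iloc[0])
        assert lab["behaviour"].iloc[0] == "foraging"

    def test_nonmonotone_timestamps_rejected(self):
        params = DEFAULT_SPECIES_PARAMS["razorbill"]
        track = self._track([10.0, 11.0], [10, 0])
        with pytest.raises(ValueError):
            classify_behaviour(track, params, 9.29)


class TestSplitTrips:
    def _labelled(self, behaviours, minutes=None):
        n = len(behaviours)
        minutes = minutes or [5 * i for i in range(n)]
        ts = [pd.Timestamp("2019-06-15 00:00:00", tz="UTC") + pd.Timedelta(minutes=m) for m in minutes]
        return pd.DataFrame({
            "bird_id": "b1", "species": "razorbill", "timestamp": ts,
            "lon": COLONY[0], "lat": COLONY[1], "n_satellites": 8,
            "dist_to_colony_km": [0.1 if b == "colony" else 10.0 for b in behaviours],
            "speed_kmh": np.nan, "behaviour": behaviours,
        })

    def test_four_at_sea_fixes_discarded_five_kept(self):
        params = DEFAULT_SPECIES_PARAMS["razorbill"]
        four = self._labelled(["colony"] + ["foraging"] * 4 + ["colony"])
        five = self._labelled(["colony"] + ["foraging"] * 5 + ["colony"])
        assert split_trips(four, params) == []
        trips = split_trips(five, params)
        assert len(trips) == 1 and trips[0].n_fixes == 5

    def test_incomplete_trailing_trip_excluded_by_default(self):
        params = DEFAULT_SPECIES_PARAMS["razorbill"]
        lab = self._labelled(["colony"] + ["foraging"] * 6)
        assert split_trips(lab, params) == []
        kept = split_trips(lab, params, include_incomplete=True)
        assert len(kept) == 1 and not kept[0].complete

    def test_time_gap_breaks_trip(self):
        params = DEFAULT_SPECIES_PARAMS["razorbill"]
        minutes = [0, 5, 10, 15, 20, 25, 120, 125, 130, 135, 140, 145, 150]
        behaviours = ["colony"] + ["foraging"] * 11 + ["colony"]
        lab = self._labelled(behaviours, minutes)
        trips = split_trips(lab, params, sampling_interval_min=5)
        assert len(trips) == 2  # the 95-min gap splits the at-sea run

    def test_trips_time_disjoint_and_beyond_splash(self, segmented, murre_params):
        _, trips = segmented
        assert trips, "scenario should produce trips"
        for t in trips:
            assert (t.fixes["dist_to_colony_km"] * 1000 > murre_params.splash_radius_m).all()
        spans = sorted((t.start, t.end) for t in trips if t.bird_id == trips[0].bird_id)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
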