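"""Synthetic GPS tracks and feeding observations with retained ground truth.

The track generator emulates central-place foraging trips sampled at a
fixed GPS cadence (5 or 15 min): each trip leaves the colony, commutes
in a straight line at the species' flight speed (with mild speed noise)
to one or more prey patches, random-walks at drift speed while in a
patch, and commutes home.  Between trips the bird sits at the colony,
emitting positions inside the splash-down radius.  Two features of real
receiver data are injected so the cleaning rules have work to do: a
small fraction of fixes report fewer than four satellites, and a small
fraction of rows are duplicated.

Positions are generated on a local tangent plane centred at the colony
(east/north km) and converted to lon/lat; at the ≤100 km scales involved
the error is sub-metre.  Every emitted fix carries a truth label
(colony / flying / foraging, and the patch id while foraging), so
downstream classification and metric recovery can be scored.

The diet generator mirrors the feeding-watch schema: per observation a
prey species is drawn from the predator's prey multinomial, a load size
from its count distribution (single-prey loaders are degenerate at 1), a
true length from the prey species' length distribution, and pixel
measurements consistent with the bill-ratio length equation plus
relative pixel noise.  Certainty scores are uniform on [30, 100] so the
<50 filter removes some records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trajectory import EARTH_RADIUS_KM

KM_PER_DEG_LAT = np.pi * EARTH_RADIUS_KM / 180.0


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one simulated species deployment.

    Distances in km unless noted; ``patch_centers`` are (east, north) km
    offsets from the colony.
    """

    species_name: str
    colony_lon: float = -63.2167
    colony_lat: float = 50.1833
    splash_radius_m: float = 1000.0
    flight_speed_kmh: float = 80.0
    drift_speed_kmh: float = 5.0
    sampling_interval_min: int = 5
    patch_centers: tuple[tuple[float, float], ...] = ((10.0, 5.0),)
    patch_visit_rate: float = 2.0  # mean patches per trip (>=1)
    trip_rate_per_day: float = 2.0
    dwell_time_min: float = 60.0
    n_birds: int = 5
    n_days: int = 2
    seed: int = 0
    speed_noise: float = 0.05  # relative sd of commute speed (<=10%)
    bad_satellite_rate: float = 0.02
    duplicate_rate: float = 0.01
    patch_sigma_km: float = 0.5  # spatial scatter of a patch

    def __post_init__(self) -> None:
        if not (self.flight_speed_kmh > self.drift_speed_kmh > 0):
            raise ValueError("require flight_speed > drift_speed > 0")
        if self.sampling_interval_min not in (5, 15):
            raise ValueError("sampling_interval_min must be 5 or 15")
        if self.splash_radius_m <= 0:
            raise ValueError("splash_radius_m must be positive")
        if len(self.patch_centers) == 0:
            raise ValueError("at least one patch required")
        if self.patch_visit_rate < 1 or self.trip_rate_per_day <= 0 or self.dwell_time_min <= 0:
            raise ValueError("rates and durations must be positive (patch_visit_rate >= 1)")
        if self.n_birds < 1 or self.n_days < 1:
            raise ValueError("n_birds and n_days must be >= 1")


def _to_lonlat(x_km, y_km, lon0, lat0):
    lat = lat0 + np.asarray(y_km) / KM_PER_DEG_LAT
    lon = lon0 + np.asarray(x_km) / (KM_PER_DEG_LAT * np.cos(np.radians(lat0)))
    return lon, lat


def simulate_tracks(scenario: SimScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate GPS fixes and 1:1 truth labels for one scenario.

    Returns ``(fixes, truth)``: ``fixes`` has the raw-table schema
    (bird_id, species, timestamp, lon, lat, n_satellites) and ``truth``
    one row per fix (fix_index, true_behaviour, true_patch_id) aligned
    by position *before* duplicate-row injection; injected duplicates
    carry the truth of the row they copy.
    """
    rng = np.random.default_rng(scenario.seed)
    dt_min = scenario.sampling_interval_min
    dt_h = dt_min / 60.0
    t0 = pd.Timestamp("2019-06-15 00:00:00", tz="UTC")
    splash_km = scenario.splash_radius_m / 1000.0

    rows = []
    truth = []
    horizon = scenario.n_days * 24 * 60.0
    for b in range(scenario.n_birds):
        bird = f"{scenario.species_name[:4].upper()}{b + 1:02d}"
        t_min = 0.0

        def emit(x_km: float, y_km: float, behaviour: str, patch: int) -> None:
            nonlocal t_min
            rows.append((bird, t_min, x_km, y_km))
            truth.append((behaviour, patch))
            t_min += dt_min

        while t_min < horizon:
            # colony rest period between trips (exponential around the trip tempo)
            rest = rng.exponential(24.0 * 60.0 / scenario.trip_rate_per_day / 2.0) + 30.0
            for _ in range(max(1, int(rest / dt_min))):
                if t_min >= horizon:
                    break
                r = 0.3 * splash_km * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                emit(r * np.cos(th), r * np.sin(th), "colony", -1)
            if t_min >= horizon:
                break
            # one foraging trip: commute -> patch(es) -> commute home
            n_patches = min(len(scenario.patch_centers),
                            1 + rng.poisson(max(scenario.patch_visit_rate - 1.0, 0.0)))
            patch_ids = rng.choice(len(scenario.patch_centers), size=n_patches, replace=False)
            cur = np.array([0.0, 0.0])
            legs: list[tuple[str, int, np.ndarray]] = []
            for pid in patch_ids:
                target = np.asarray(scenario.patch_centers[pid], dtype=float)
                legs.append(("commute", -1, target.copy()))
                legs.append(("patch", int(pid), target.copy()))
            legs.append(("commute", -1, np.array([0.0, 0.0])))

            for kind, pid, target in legs:
                if t_min >= horizon:
                    break
                if kind == "commute":
                    # quantize the leg to whole sampling steps so arrival
                    # coincides with a fix and step speeds stay in the
                    # flight regime (speed noise absorbs the rounding)
                    d = float(np.linalg.norm(target - cur))
                    speed = scenario.flight_speed_kmh * (
                        1.0 + scenario.speed_noise * float(rng.standard_normal())
                    )
                    n_steps = max(1, int(round(d / (max(speed, 1.0) * dt_h))))
                    start = cur.copy()
                    for s in range(1, n_steps + 1):
                        if t_min >= horizon:
                            break
                        pos = start + (target - start) * (s / n_steps)
                        at_colony = float(np.linalg.norm(pos)) <= splash_km
                        emit(pos[0], pos[1], "colony" if at_colony else "flying", -1)
                    cur = target.copy()
                else:
                    dwell = max(dt_min, rng.exponential(scenario.dwell_time_min))
                    pos = cur + scenario.patch_sigma_km * 0.3 * rng.standard_normal(2)
                    step_km = scenario.drift_speed_kmh * dt_h
                    for _ in range(max(1, int(round(dwell / dt_min)))):
                        if t_min >= horizon:
                            break
                        pos = pos + rng.standard_normal(2) * step_km / np.sqrt(2)
                        off = pos - target
                        r = float(np.linalg.norm(off))
                        # keep the walk tethered to the patch centre
                        if r > 3 * scenario.patch_sigma_km + step_km:
                            pos = target + off / r * (3 * scenario.patch_sigma_km)
                        emit(pos[0], pos[1], "foraging", int(pid))
                    cur = pos

    x_km = np.array([r[2] for r in rows])
    y_km = np.array([r[3] for r in rows])
    lon, lat = _to_lonlat(x_km, y_km, scenario.colony_lon, scenario.colony_lat)
    n = len(rows)
    sats = np.where(rng.uniform(size=n) < scenario.bad_satellite_rate,
                    rng.integers(0, 4, size=n), rng.integers(4, 13, size=n))
    fixes = pd.DataFrame({
        "bird_id": [r[0] for r in rows],
        "species": scenario.species_name,
        "timestamp": t0 + pd.to_timedelta([r[1] for r in rows], unit="m"),
        "lon": lon,
        "lat": lat,
        "n_satellites": sats,
    })
    truth_df = pd.DataFrame({
        "fix_index": np.arange(n),
        "true_behaviour": [t[0] for t in truth],
        "true_patch_id": [t[1] if t[0] == "foraging" else None for t in truth],
    })
    # duplicate-row injection (exercises the dedup cleaning rule)
    dup = np.flatnonzero(rng.uniform(size=n) < scenario.duplicate_rate)
    if dup.size:
        fixes = pd.concat([fixes, fixes.iloc[dup]], ignore_index=False)
        truth_df = pd.concat([truth_df, truth_df.iloc[dup]], ignore_index=False)
        order = np.argsort(fixes.index.to_numpy(), kind="stable")
        fixes = fixes.iloc[order].reset_index(drop=True)
        truth_df = truth_df.iloc[order].reset_index(drop=True)
        truth_df["fix_index"] = np.arange(len(truth_df))
    return fixes, truth_df


# ---------------------------------------------------------------------------
# diet

#: Default prey multinomials per predator species (probabilities sum to 1).
DEFAULT_PREY_PROBS: dict[str, dict[str, float]] = {
    "puffin": {"capelin": 0.40, "sandlance": 0.45, "larval": 0.14, "unknown": 0.01},
    "razorbill": {"capelin": 0.22, "sandlance": 0.70, "herring": 0.04, "unknown": 0.04},
    "murre": {"capelin": 0.51, "sandlance": 0.13, "gadid": 0.15, "herring": 0.05,
              "other": 0.07, "unknown": 0.09},
}

#: True prey length distributions, mm (mean, sd).
DEFAULT_LENGTH_PARAMS: dict[str, tuple[float, float]] = {
    "capelin": (110.0, 20.0),
    "sandlance": (95.0, 18.0),
    "herring": (120.0, 20.0),
    "gadid": (120.0, 25.0),
    "other": (100.0, 25.0),
    "larval": (35.0, 8.0),
    "unknown": (90.0, 25.0),
}

#: Load-size models: ("fixed", k) or ("poisson1", mean) = 1 + Poisson(mean-1).
DEFAULT_LOAD_SIZE: dict[str, tuple[str, float]] = {
    "puffin": ("poisson1", 3.1),
    "razorbill": ("poisson1", 3.0),
    "murre": ("fixed", 1.0),
}

DEFAULT_BILL_LENGTHS_MM: dict[str, float] = {
    "puffin": 49.1,
    "razorbill": 34.3,
    "murre": 43.9,
}


def simulate_diet(
    n_obs: int,
    species_prey_probs: dict[str, dict[str, float]] | None = None,
    length_params: dict[str, tuple[float, float]] | None = None,
    load_size_params: dict[str, tuple[str, float]] | None = None,
    bill_lengths_mm: dict[str, float] | None = None,
    pixel_noise: float = 0.03,
    blurry_rate: float = 0.05,
    island: str = "Betchouanes",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a feeding-watch observation table with truth columns.

    Each row is one photographed bill load: predator species drawn
    uniformly over the configured species, prey species from that
    predator's multinomial, load size from its count model, and a true
    length (mm) from the prey species' normal distribution (resampled
    until positive).  Pixel columns satisfy
    ``prey_px = bill_px * (true_length / bill_mm) * (1 + noise)`` so the
    bill-ratio length estimate recovers the truth exactly at
    ``pixel_noise=0``.  Certainty is uniform on [30, 100].

    The returned frame has the observation schema plus ``true_length_mm``.
    """
    probs = DEFAULT_PREY_PROBS if species_prey_probs is None else species_prey_probs
    lengths = DEFAULT_LENGTH_PARAMS if length_params is None else length_params
    loads = DEFAULT_LOAD_SIZE if load_size_params is None else load_size_params
    bills = DEFAULT_BILL_LENGTHS_MM if bill_lengths_mm is None else bill_lengths_mm
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    for sp, p in probs.items():
        total = sum(p.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in p.values()):
            raise ValueError(f"prey probabilities for {sp!r} must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    bird_species = list(probs)

    rows = []
    for i in range(n_obs):
        bird = bird_species[int(rng.integers(len(bird_species)))]
        prey_names = list(probs[bird])
        prey = prey_names[int(rng.choice(len(prey_names), p=list(probs[bird].values())))]
        kind, param = loads[bird]
        count = int(param) if kind == "fixed" else 1 + int(rng.poisson(max(param - 1.0, 0.0)))
        mu, sd = lengths[prey]
        true_len = float(rng.normal(mu, sd))
        while true_len <= 0:
            true_len = float(rng.normal(mu, sd))
        bill_mm = bills[bird]
        bill_px = float(rng.uniform(80.0, 160.0))
        prey_px = bill_px * (true_len / bill_mm) * (1.0 + pixel_noise * rng.standard_normal())
        while prey_px <= 0:
            prey_px = bill_px * (true_len / bill_mm) * (1.0 + pixel_noise * rng.standard_normal())
        rows.append({
            "obs_id": f"obs{i + 1:05d}",
            "bird_species": bird,
            "island": island,
            "prey_species": prey,
            "prey_count": count,
            "prey_length_px": prey_px,
            "bill_length_px": bill_px,
            "certainty": float(rng.uniform(30.0, 100.0)),
            "blurry": bool(rng.uniform() < blurry_rate),
            "true_length_mm": true_len,
        })
    return pd.DataFrame(rows)


def write_scenario_outputs(scenario: SimScenario, out_dir) -> dict:
    """Write fixes and truth CSVs for a scenario; returns the file paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixes, truth = simulate_tracks(scenario)
    fixes_path = out / f"fixes_{scenario.species_name}.csv"
    truth_path = out / f"truth_{scenario.species_name}.csv"
    fx = fixes.copy()
    fx["timestamp"] = fx["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    fx.to_csv(fixes_path, index=False)
    truth.to_csv(truth_path, index=False)
    return {"fixes": str(fixes_path), "truth": str(truth_path)}
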