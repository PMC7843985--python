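"""Chick-provisioning diet: prey lengths, allometric masses, composition.

Feeding-watch photographs yield, per observation, the prey species, the
number of items carried, and prey and bill lengths in pixels.  Prey
length in mm follows from the pixel ratio scaled by the species' known
culmen length:

    length_mm = (prey_px / bill_px) * bill_mm.

Item mass uses a length–mass allometry mass = a·L^b per prey species
(capelin: a = 2.7e-5 g·mm⁻ᵇ, b = 2.76).  Larval prey are assigned a
fixed 2 g; "unknown" prey get the mean of all identified item masses in
the dataset (a two-pass computation).

Composition per predator species is summarised three ways: frequency of
occurrence (FO — observations in which the prey species appears, once
per species per observation), numerical abundance (NA — total items),
and total estimated mass, each with percentages of the species totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OBS_COLUMNS = [
    "obs_id",
    "bird_species",
    "island",
    "prey_species",
    "prey_count",
    "prey_length_px",
    "bill_length_px",
    "certainty",
    "blurry",
]

LARVAL_MASS_G = 2.0
UNKNOWN = "unknown"
LARVAL = "larval"


@dataclass(frozen=True)
class AllometricModel:
    """Length–mass model mass_g = coef_a · (length_mm ** exponent_b)."""

    prey_species: str
    coef_a: float
    exponent_b: float

    def __post_init__(self) -> None:
        if self.coef_a <= 0 or self.exponent_b <= 0:
            raise ValueError("allometric coefficients must be positive")

    def mass_g(self, length_mm: float) -> float:
        if length_mm <= 0:
            raise ValueError("length must be positive")
        return self.coef_a * length_mm**self.exponent_b


#: Built-in allometry.  Capelin is the only species whose coefficients
#: are fixed here; other prey must be supplied by the user (the
#: published length–mass sources vary by region and season).
DEFAULT_ALLOMETRY: dict[str, AllometricModel] = {
    "capelin": AllometricModel("capelin", 2.7e-5, 2.76),
}


def filter_observations(obs: pd.DataFrame, min_certainty: float = 50.0) -> pd.DataFrame:
    """Discard blurry photographs and low-certainty identifications.

    Rows with ``certainty`` below ``min_certainty`` (default 50 of 100)
    or a truthy ``blurry`` flag are removed; counts are logged.
    """
    blurry = obs["blurry"].fillna(False).astype(bool) if "blurry" in obs else pd.Series(False, index=obs.index)
    low = obs["certainty"] < min_certainty
    keep = ~(blurry | low)
    logger.info(
        "filter_observations: %d blurry, %d low-certainty removed, %d kept",
        int(blurry.sum()), int((low & ~blurry).sum()), int(keep.sum()),
    )
    return obs.loc[keep].reset_index(drop=True)


def estimate_prey_length(prey_px, bill_px, bill_mm) -> np.ndarray | float:
    """Prey length in mm from the photo pixel ratio (vectorized)."""
    prey_px = np.asarray(prey_px, dtype=float)
    bill_px = np.asarray(bill_px, dtype=float)
    bill_mm = np.asarray(bill_mm, dtype=float)
    if np.any(prey_px <= 0) or np.any(bill_px <= 0) or np.any(bill_mm <= 0):
        raise ValueError("pixel and bill lengths must be positive")
    out = prey_px / bill_px * bill_mm
    return float(out) if np.ndim(out) == 0 else out


def estimate_mass(
    prey_species: str,
    length_mm: float,
    models: dict[str, AllometricModel],
    mean_known_mass_g: float | None = None,
) -> float:
    """Single-item mass in g for one prey record.

    ``mean_known_mass_g`` must be supplied for ``unknown`` prey (the
    dataset-wide mean of identified item masses; see
    :func:`build_diet_records` for the two-pass computation).
    """
    key = prey_species.strip().lower()
    if key == LARVAL or key.startswith("larval"):
        return LARVAL_MASS_G
    if key == UNKNOWN:
        if mean_known_mass_g is None:
            raise ValueError("mean of known masses required for 'unknown' prey")
        return float(mean_known_mass_g)
    if key not in models:
        raise KeyError(
            f"no allometric model for prey species {prey_species!r}; "
            f"available: {sorted(models)}"
        )
    return models[key].mass_g(length_mm)


def build_diet_records(
    obs: pd.DataFrame,
    bill_lengths_mm: dict[str, float],
    models: dict[str, AllometricModel] | None = None,
    unknown_scope: str = "dataset",
) -> pd.DataFrame:
    """Filtered observations -> per-observation length and mass estimates.

    Adds ``prey_length_mm`` (pixel-ratio estimate) and ``item_mass_g``
    (allometric, per item).  Unknown prey receive the mean identified
    item mass — dataset-wide by default, or within each bird species
    when ``unknown_scope="bird_species"``.
    """
    models = dict(DEFAULT_ALLOMETRY) if models is None else models
    rec = obs.copy()
    bill_mm = rec["bird_species"].map(bill_lengths_mm)
    if bill_mm.isna().any():
        missing = sorted(rec.loc[bill_mm.isna(), "bird_species"].unique())
        raise KeyError(f"no bill length for bird species: {missing}")
    rec["prey_length_mm"] = estimate_prey_length(
        rec["prey_length_px"].to_numpy(), rec["bill_length_px"].to_numpy(), bill_mm.to_numpy()
    )

    key = rec["prey_species"].str.strip().str.lower()
    is_larval = key.str.startswith(LARVAL)
    is_unknown = key == UNKNOWN
    mass = np.full(len(rec), np.nan)
    mass[is_larval.to_numpy()] = LARVAL_MASS_G
    known = ~(is_larval | is_unknown)
    for sp in key[known].unique():
        rows = (key == sp) & known
        if sp not in models:
            raise KeyError(f"no allometric model for prey species {sp!r}")
        m = models[sp]
        mass[rows.to_numpy()] = m.coef_a * rec.loc[rows, "prey_length_mm"].to_numpy() ** m.exponent_b
    # second pass: unknowns get the mean identified (non-larval counted too)
    if is_unknown.any():
        identified = ~is_unknown
        if unknown_scope == "bird_species":
            for sp_bird in rec["bird_species"].unique():
                of_bird = rec["bird_species"] == sp_bird
                sel_u = (is_unknown & of_bird).to_numpy()
                sel_k = (identified & of_bird).to_numpy()
                mass[sel_u] = float(np.nanmean(mass[sel_k]))
        else:
            mass[is_unknown.to_numpy()] = float(np.nanmean(mass[identified.to_numpy()]))
    rec["item_mass_g"] = mass
    return rec


def aggregate_composition(records: pd.DataFrame, by_island: bool = False) -> pd.DataFrame:
    """Raw FO / NA / mass counts per bird species × prey species.

    FO counts an observation once per prey species present; NA sums
    ``prey_count``; mass sums per-item mass × count.
    """
    rec = records.copy()
    rec["total_mass_g"] = rec["item_mass_g"] * rec["prey_count"]
    keys = ["bird_species"] + (["island"] if by_island else []) + ["prey_species"]
    agg = rec.groupby(keys, sort=True).agg(
        fo=("obs_id", "nunique"),
        na=("prey_count", "sum"),
        mass_g=("total_mass_g", "sum"),
    )
    return agg.reset_index()


def add_percentages(counts: pd.DataFrame, by_island: bool = False) -> pd.DataFrame:
    """Add FO/NA/mass percentage columns relative to bird-species totals.

    ``counts`` has columns bird_species, [island,] prey_species, fo, na,
    mass_g — e.g. the output of :func:`aggregate_composition` or a table
    of published counts.
    """
    keys = ["bird_species"] + (["island"] if by_island else [])
    out = counts.copy()
    for col, pct in [("fo", "fo_pct"), ("na", "na_pct"), ("mass_g", "mass_pct")]:
        totals = out.groupby(keys)[col].transform("sum")
        out[pct] = 100.0 * out[col] / totals
    return out


def diet_table(
    records: pd.DataFrame,
    by_island: bool = False,
    with_totals: bool = True,
) -> pd.DataFrame:
    """Composition table: FO, NA and mass with percentages, plus totals.

    One row per bird species × prey species (× island when requested),
    with a ``Total`` prey row per bird species.  Percent columns sum to
    100 within each bird species.
    """
    counts = aggregate_composition(records, by_island=by_island)
    table = add_percentages(counts, by_island=by_island)
    if not with_totals:
        return table
    keys = ["bird_species"] + (["island"] if by_island else [])
    totals = table.groupby(keys, as_index=False)[["fo", "na", "mass_g", "fo_pct", "na_pct", "mass_pct"]].sum()
    totals["prey_species"] = "Total"
    out = pd.concat([table, totals], ignore_index=True)
    return out.sort_values(keys + ["prey_species"], key=lambda s: s.eq("Total") if s.name == "prey_species" else s).reset_index(drop=True)
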