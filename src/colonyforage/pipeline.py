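"""End-to-end orchestration: fixes + observations -> all analysis tables.

A single :class:`RunConfig` (constructed in Python or loaded from YAML)
drives the sequential pipeline: clean -> classify -> split trips ->
trip metrics -> utilization distributions and overlap -> group
statistics, plus the diet arm (filter -> lengths/masses -> composition
tables -> diet statistics) when observations are supplied.  Either arm
may be run alone — the GPS and diet data come from different field
protocols and need not coexist.  Every stage writes its table to the
output directory and a JSON manifest records versions, seeds and a
config hash so any artifact can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trajectory import DEFAULT_SPECIES_PARAMS, SpeciesParams, segment_tracks
from .trip_metrics import METRIC_COLUMNS, metrics_table
from .space_use import UD_LEVELS, overlap_randomization, species_ud_pair, export_ud_ascii
from .diet import DEFAULT_ALLOMETRY, AllometricModel, build_diet_records, diet_table, filter_observations
from . import group_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str
    fixes_path: str | None = None
    observations_path: str | None = None
    species_params: dict[str, SpeciesParams] = field(default_factory=lambda: dict(DEFAULT_SPECIES_PARAMS))
    threshold_mode: str = "common"  # "common" | "per-species" | numeric km/h
    ud_levels: tuple[float, ...] = UD_LEVELS
    overlap_pairs: tuple[tuple[str, str], ...] = ()
    overlap_level: float = 95.0
    n_iter: int = 1000
    seed: int = 0
    tz_offset_h: float = -4.0
    allometry: dict[str, AllometricModel] = field(default_factory=lambda: dict(DEFAULT_ALLOMETRY))
    ud_n_cells: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sp = {
            name: SpeciesParams(species=name, **p)
            for name, p in raw.pop("species_params", {}).items()
        } or dict(DEFAULT_SPECIES_PARAMS)
        allo = {
            name: AllometricModel(name, a["coef_a"], a["exponent_b"])
            for name, a in raw.pop("allometry", {}).items()
        } or dict(DEFAULT_ALLOMETRY)
        pairs = tuple(tuple(p) for p in raw.pop("overlap_pairs", []))
        return cls(species_params=sp, allometry=allo, overlap_pairs=pairs, **raw)

    def digest(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for which inputs are configured.

    Returns a summary dict (also written as ``manifest.json``) with the
    paths of all artifacts, stage timings, and the seeds used.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["stages"][name] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s finished in %.2fs", name, manifest["stages"][name])

        return done

    trips = []
    if config.fixes_path is not None:
        done = stage("segment")
        fixes = pd.read_csv(config.fixes_path)
        labelled, trips = segment_tracks(fixes, config.species_params, threshold=config.threshold_mode)
        _write_csv(labelled, out / "labelled_fixes.csv")
        trips_summary = pd.DataFrame(
            [
                {
                    "trip_id": t.trip_id, "bird_id": t.bird_id, "species": t.species,
                    "start": t.start, "end": t.end, "n_fixes": t.n_fixes,
                }
                for t in trips
            ]
        )
        _write_csv(trips_summary, out / "trips.csv")
        manifest["artifacts"]["labelled_fixes"] = str(out / "labelled_fixes.csv")
        manifest["artifacts"]["trips"] = str(out / "trips.csv")
        done()

        done = stage("trip_metrics")
        metrics = metrics_table(trips, config.tz_offset_h)
        _write_csv(metrics, out / "trip_metrics.csv")
        manifest["artifacts"]["trip_metrics"] = str(out / "trip_metrics.csv")
        done()

        done = stage("group_stats_spatial")
        spatial_tests = []
        complete = metrics.dropna(subset=METRIC_COLUMNS)
        if complete["species"].nunique() >= 2:
            for metric in ["fri_km", "max_distance_km", "duration_h", "ci"]:
                sub = complete.dropna(subset=[metric])
                spatial_tests.append(
                    {"metric": metric, **group_stats.kruskal_by_group(sub[metric], sub["species"]).as_dict()}
                )
                for r in group_stats.pairwise_wilcoxon(sub[metric], sub["species"]):
                    spatial_tests.append({"metric": metric, **r.as_dict()})
                if (sub[metric] > 0).all() and sub.groupby("bird_id").size().max() >= 1:
                    spatial_tests.append(
                        {"metric": metric,
                         **group_stats.lmm_species_effect(sub[metric], sub["species"], sub["bird_id"]).as_dict()}
                    )
            try:
                pca = group_stats.pca_metrics(complete, METRIC_COLUMNS)
                pca.scores.assign(species=complete["species"].to_numpy()).to_csv(out / "pca_scores.csv", index=False)
                np.savetxt(out / "pca_eigenvalues.txt", pca.eigenvalues)
                manifest["artifacts"]["pca_scores"] = str(out / "pca_scores.csv")
                for pc in ("PC1", "PC2"):
                    spatial_tests.append(
                        {"metric": pc,
                         **group_stats.kruskal_by_group(pca.scores[pc], complete["species"]).as_dict()}
                    )
            except ValueError as exc:
                logger.warning("PCA skipped: %s", exc)
        pd.DataFrame(spatial_tests).to_json(out / "spatial_tests.json", orient="records", indent=1)
        manifest["artifacts"]["spatial_tests"] = str(out / "spatial_tests.json")
        done()

        done = stage("space_use")
        overlap_out = []
        by_species: dict[str, list] = {}
        for t in trips:
            by_species.setdefault(t.species, []).append(t)
        pairs = config.overlap_pairs or tuple(
            (a, b) for i, a in enumerate(sorted(by_species)) for b in sorted(by_species)[i + 1:]
        )
        rng = np.random.default_rng(config.seed)
        for a, b in pairs:
            if len(by_species.get(a, [])) < 2 or len(by_species.get(b, [])) < 2:
                logger.warning("overlap %s/%s skipped: <2 trips in a group", a, b)
                continue
            colony = config.species_params[a].colony
            ud_a, ud_b = species_ud_pair(by_species[a], by_species[b], colony, n_cells=config.ud_n_cells)
            export_ud_ascii(ud_a, out / f"ud_{a}.asc")
            export_ud_ascii(ud_b, out / f"ud_{b}.asc")
            res = overlap_randomization(
                by_species[a], by_species[b], colony,
                level=config.overlap_level, n_iter=config.n_iter,
                seed=int(rng.integers(2**31 - 1)), n_cells=config.ud_n_cells,
            )
            overlap_out.append({
                "pair": list(res.pair), "level": res.level,
                "ba": res.ba, "udoi": res.udoi,
                "p_ba": res.p_ba, "p_udoi": res.p_udoi,
                "wilcoxon_ba": res.wilcoxon_ba, "wilcoxon_udoi": res.wilcoxon_udoi,
                "n_iter": res.n_iter, "seed": res.seed,
                "null_ba_mean": float(res.null_ba.mean()), "null_udoi_mean": float(res.null_udoi.mean()),
            })
        with open(out / "overlap.json", "w") as fh:
            json.dump(overlap_out, fh, indent=1)
        manifest["artifacts"]["overlap"] = str(out / "overlap.json")
        done()
    else:
        logger.info("no fixes configured; spatial stages skipped")
        manifest["stages"]["spatial"] = "skipped (no fixes input)"

    if config.observations_path is not None:
        done = stage("diet")
        obs = pd.read_csv(config.observations_path)
        kept = filter_observations(obs)
        bills = {
            s: p.bill_length_mm for s, p in config.species_params.items() if p.bill_length_mm
        }
        records = build_diet_records(kept, bills, config.allometry)
        _write_csv(records, out / "diet_records.csv")
        table = diet_table(records)
        _write_csv(table, out / "diet_table.csv")
        manifest["artifacts"]["diet_records"] = str(out / "diet_records.csv")
        manifest["artifacts"]["diet_table"] = str(out / "diet_table.csv")

        diet_tests = []
        try:
            diet_tests.append(group_stats.diet_chisq(records).as_dict())
        except ValueError as exc:
            logger.warning("diet chi-square skipped: %s", exc)
        if records["bird_species"].nunique() >= 2:
            diet_tests.append(group_stats.prey_count_glm(records["prey_count"], records["bird_species"]).as_dict())
        loaders = records[records["prey_count"].gt(0)]
        if loaders["prey_count"].nunique() > 1 and len(loaders) >= 3:
            diet_tests.append(
                group_stats.size_vs_number_regression(loaders["prey_length_mm"], loaders["prey_count"]).as_dict()
            )
        with open(out / "diet_tests.json", "w") as fh:
            json.dump(diet_tests, fh, indent=1, default=str)
        manifest["artifacts"]["diet_tests"] = str(out / "diet_tests.json")
        done()
    else:
        logger.info("no observations configured; diet stages skipped")
        manifest["stages"]["diet"] = "skipped (no observations input)"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
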