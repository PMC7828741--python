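"""End-to-end orchestration: simulate -> entropy -> trajectories ->
exposure -> survey.

Stages hand off through plain files (GeoJSON / CSV / JSON) in one output
directory, so every intermediate is inspectable and each stage can be
re-run in isolation.  A machine-readable run report records parameters,
the seed, per-file SHA-256 digests and headline summaries; identical
config + seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString, mapping

from . import exposure as expo
from . import harmonize as harm
from . import segregation as seg
from . import synthetic_city as synth
from .core import (Route, StreetNetwork, ValidationError,
                   participants_from_csv, participants_to_csv,
                   units_from_geojson, units_to_geojson)

log = logging.getLogger("ciclovia")

STAGES = ("simulate", "entropy", "trajectories", "exposure", "survey")


class DependencyError(ValidationError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    city: dict = field(default_factory=dict)
    n_participants: int = 800
    segment_len_m: float = 500.0
    min_n: int = 10
    permutations: int = 199
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValidationError(f"unknown stages {bad}")
        # stages always execute in DAG order regardless of listing order
        self.stages = tuple(s for s in STAGES if s in self.stages)

    @classmethod
    def from_yaml(cls, path: str, outdir: str | None = None,
                  seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            outdir=outdir or raw.get("outdir", "ciclovia_run"),
            seed=seed if seed is not None else int(raw.get("seed", 0)),
            city=raw.get("city", {}),
            n_participants=int(raw.get("participants", 800)),
            segment_len_m=float(raw.get("segment_len_m", 500.0)),
            min_n=int(raw.get("min_n", 10)),
            permutations=int(raw.get("permutations", 199)),
            stages=tuple(raw.get("stages", STAGES)),
        )
        return cfg

    def city_config(self) -> synth.CityConfig:
        return synth.CityConfig(seed=self.seed, **self.city)

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _require(config: RunConfig, names: Sequence[str], stage: str) -> None:
    missing = [n for n in names if not os.path.exists(config.path(n))]
    if missing:
        raise DependencyError(
            f"stage {stage!r} is missing upstream artifacts: {missing}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> dict:
    log.info("simulate: generating synthetic city (seed=%d)", config.seed)
    city = synth.generate_city(config.city_config())
    participants = synth.generate_participants(city, config.n_participants,
                                               seed=config.seed)
    surveys = synth.generate_survey(participants, seed=config.seed)
    units_to_geojson(city.units, config.path("units.geojson"))
    city.network.to_csv(config.path("network.csv"))
    city.route.to_geojson(config.path("route.geojson"))
    participants_to_csv(participants, config.path("participants.csv"))
    for cname, df in surveys.items():
        df.to_csv(config.path(f"survey_{cname}.csv"), index=False)
    return {"n_units": len(city.units),
            "route_length_m": city.route.length_m,
            "n_participants": len(participants)}


def stage_entropy(config: RunConfig) -> dict:
    _require(config, ["units.geojson"], "entropy")
    units = units_from_geojson(config.path("units.geojson"))
    result = seg.theil_index(seg.CompositionTable.from_units(units))
    result.to_files(config.path("entropy.csv"),
                    config.path("entropy_summary.json"))
    return {"H": result.H, "mean_e": result.mean_e, "sd_e": result.sd_e}


def stage_trajectories(config: RunConfig) -> dict:
    _require(config, ["network.csv", "participants.csv"], "trajectories")
    network = StreetNetwork.from_csv(config.path("network.csv"))
    participants = participants_from_csv(config.path("participants.csv"))
    features = []
    lengths = []
    for p in participants:
        t = expo.shortest_path_trajectory(network, p.origin_node,
                                          p.destination_node,
                                          p.participant_id, p.ses_of_origin)
        geom = t.geometry if t.geometry is not None else LineString()
        features.append({
            "type": "Feature",
            "geometry": mapping(geom) if not geom.is_empty else None,
            "properties": {"participant_id": p.participant_id,
                           "nodes": list(t.nodes),
                           "total_length_m": t.total_length_m,
                           "ses_of_origin": p.ses_of_origin},
        })
        lengths.append(t.total_length_m)
    with open(config.path("trajectories.geojson"), "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  sort_keys=True)
    return {"n_trajectories": len(features),
            "mean_length_m": float(np.mean(lengths))}


def _load_trajectories(config: RunConfig) -> list[expo.Trajectory]:
    with open(config.path("trajectories.geojson")) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj["features"]:
        props = feat["properties"]
        geom = (LineString(feat["geometry"]["coordinates"])
                if feat["geometry"] else None)
        out.append(expo.Trajectory(
            participant_id=int(props["participant_id"]),
            nodes=tuple(props["nodes"]),
            geometry=geom,
            total_length_m=float(props["total_length_m"]),
            ses_of_origin=props["ses_of_origin"]))
    return out


def stage_exposure(config: RunConfig) -> dict:
    _require(config, ["units.geojson", "network.csv", "route.geojson",
                      "participants.csv", "trajectories.geojson"], "exposure")
    units = units_from_geojson(config.path("units.geojson"))
    network = StreetNetwork.from_csv(config.path("network.csv"))
    route = Route.from_geojson(config.path("route.geojson"))
    participants = participants_from_csv(config.path("participants.csv"))
    trajectories = _load_trajectories(config)

    pmap = expo.ses_percentile_map(units)
    assignment = expo.EdgeUnitAssignment(network, units)
    dataset = expo.ExposureDataset.build(
        trajectories, assignment, pmap,
        origin_units=[p.origin_unit for p in participants],
        segment_len_m=config.segment_len_m)

    seg_rows = []
    for t in trajectories:
        for k, val in expo.segment_trajectory(t, assignment, pmap,
                                              config.segment_len_m):
            seg_rows.append({"participant_id": t.participant_id,
                             "k": k, "value": val})
    pd.DataFrame(seg_rows).to_csv(config.path("segments.csv"), index=False)

    prof_rows, maxdiff = [], {}
    for group in ("low", "middle", "high"):
        if not (dataset.labels == group).any():
            continue
        prof = dataset.profile(group)
        for k in range(len(prof.mean_percentile)):
            prof_rows.append({"group": group, "k": k,
                              "mean_percentile": prof.mean_percentile[k],
                              "variance": prof.variance[k],
                              "n_participants": int(prof.n_participants[k])})
        md = dataset.max_difference(group, config.min_n, config.segment_len_m)
        p_val = None
        if md.defined and config.permutations >= 99:
            p_val = dataset.permutation_test(group, config.permutations,
                                             seed=config.seed,
                                             min_n=config.min_n,
                                             segment_len_m=config.segment_len_m)
        maxdiff[group] = {
            "baseline_percentile": md.baseline_percentile,
            "max_diff": md.max_diff if md.defined else None,
            "distance_km": md.distance_km if md.defined else None,
            "p_value": p_val,
            "defined": md.defined,
        }
    pd.DataFrame(prof_rows).to_csv(config.path("profiles.csv"), index=False)
    with open(config.path("maxdiff.json"), "w") as fh:
        json.dump(maxdiff, fh, indent=2, sort_keys=True)

    entropy_classes = None
    if os.path.exists(config.path("entropy.csv")):
        ecsv = pd.read_csv(config.path("entropy.csv"))
        entropy_classes = dict(zip(ecsv["unit_id"], ecsv["entropy_class"]))
    else:
        result = seg.theil_index(seg.CompositionTable.from_units(units))
        entropy_classes = dict(zip(result.per_unit["unit_id"],
                                   result.per_unit["entropy_class"]))
    overlay = expo.route_overlay(route, units, entropy_classes)
    shares = expo.trajectory_ses_shares(trajectories, assignment)
    with open(config.path("overlay.json"), "w") as fh:
        json.dump({"route_by_ses": overlay.by_ses,
                   "route_by_class": overlay.by_class,
                   "trajectory_shares": shares}, fh, indent=2, sort_keys=True)
    return {"maxdiff": maxdiff, "route_by_ses": overlay.by_ses}


def stage_survey(config: RunConfig) -> dict:
    tables = {}
    for city in harm.CITIES:
        path = config.path(f"survey_{city}.csv")
        if os.path.exists(path):
            tables[city] = pd.read_csv(path)
    if not tables:
        raise DependencyError("stage 'survey' found no survey_<city>.csv files")
    harmonized = harm.harmonize_surveys(tables)
    harmonized.to_csv(config.path("harmonized.csv"), index=False)
    table3 = harm.descriptive_table(harmonized)
    table3.to_csv(config.path("table3.csv"), index=False)
    model = harm.fit_two_level_logistic(harmonized)
    with open(config.path("model_table4.json"), "w") as fh:
        json.dump({
            "terms": model.table.to_dict(orient="records"),
            "sigma_city": model.sigma_group,
            "random_intercept_variance": model.random_intercept_variance,
            "loglik": model.loglik,
            "n_obs": model.n_obs,
            "dropped": list(model.dropped),
        }, fh, indent=2, sort_keys=True)
    return {"n_harmonized": len(harmonized),
            "sigma_city": model.sigma_group}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "entropy": stage_entropy,
    "trajectories": stage_trajectories,
    "exposure": stage_exposure,
    "survey": stage_survey,
}

_STAGE_OUTPUTS = {
    "simulate": ["units.geojson", "network.csv", "route.geojson",
                 "participants.csv"],
    "entropy": ["entropy.csv", "entropy_summary.json"],
    "trajectories": ["trajectories.geojson"],
    "exposure": ["segments.csv", "profiles.csv", "maxdiff.json",
                 "overlay.json"],
    "survey": ["harmonized.csv", "table3.csv", "model_table4.json"],
}


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in order, fail fast with stage-named
    errors, and write ``report.json`` with parameters and output digests."""
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "parameters": {
            "city": config.city,
            "n_participants": config.n_participants,
            "segment_len_m": config.segment_len_m,
            "min_n": config.min_n,
            "permutations": config.permutations,
        },
        "stages": {},
    }
    for stage in config.stages:
        log.info("running stage %s", stage)
        try:
            summary = _STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        digests = {}
        for name in _STAGE_OUTPUTS[stage]:
            path = config.path(name)
            if os.path.exists(path):
                digests[name] = _sha256(path)
        for extra in os.listdir(config.outdir):
            if stage == "simulate" and extra.startswith("survey_"):
                digests[extra] = _sha256(config.path(extra))
        report["stages"][stage] = {"summary": summary, "digests": digests}
    with open(config.path("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
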