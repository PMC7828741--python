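"""Shared domain types and plain-file I/O.

All geometry is planar and in meters: the 500-m segmentation, route lengths
and overlays only need metric geometry, so no geodesy is involved anywhere.
Geographic units are polygons carrying per-SES-group population counts; the
street network is an undirected weighted graph whose edge weights are
Euclidean lengths.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, mapping, shape

#: Harmonized SES levels, in rank order (rank 1 = low ... rank 3 = high).
SES_LEVELS: tuple[str, ...] = ("low", "middle", "high")


def substream(seed: int, label: str) -> np.random.Generator:
    """Named RNG substream: one stream per (seed, label).

    Deterministic and independent across labels, so e.g. adding participants
    does not perturb unit generation under the same seed.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF,
                                  zlib.crc32(label.encode()) & 0x7FFFFFFF])


class ValidationError(ValueError):
    """Raised for invalid inputs (bad configs, malformed tables, ...)."""


# ---------------------------------------------------------------------------
# Geographic units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeographicUnit:
    """A polygonal areal unit with per-SES-group population counts.

    ``counts[r]`` is the population of SES group ``SES_LEVELS[r]``;
    ``ses_score`` is the population-weighted mean of the group ranks
    (1, 2, 3), a minimal monotone ordinal score.
    """

    unit_id: int
    polygon: Polygon
    counts: tuple[int, int, int]
    ses_score: float

    @property
    def population(self) -> int:
        return int(sum(self.counts))

    @property
    def proportions(self) -> np.ndarray:
        t = self.population
        if t == 0:
            return np.full(len(self.counts), 1.0 / len(self.counts))
        return np.asarray(self.counts, dtype=float) / t

    @property
    def dominant_ses(self) -> str:
        """Modal SES group; ties resolved toward the lowest rank."""
        c = np.asarray(self.counts)
        return SES_LEVELS[int(np.argmax(c))]


def ses_score_from_counts(counts: Sequence[int]) -> float:
    t = sum(counts)
    if t == 0:
        return float(np.mean(np.arange(1, len(counts) + 1)))
    ranks = np.arange(1, len(counts) + 1)
    return float(np.dot(ranks, counts) / t)


def units_to_frame(units: Iterable[GeographicUnit]) -> pd.DataFrame:
    rows = []
    for u in units:
        rows.append({
            "unit_id": u.unit_id,
            "pop_low": u.counts[0],
            "pop_mid": u.counts[1],
            "pop_high": u.counts[2],
            "ses_score": u.ses_score,
        })
    return pd.DataFrame(rows)


def units_to_geojson(units: Iterable[GeographicUnit], path: str) -> None:
    features = []
    for u in units:
        features.append({
            "type": "Feature",
            "geometry": mapping(u.polygon),
            "properties": {
                "id": u.unit_id,
                "pop_low": int(u.counts[0]),
                "pop_mid": int(u.counts[1]),
                "pop_high": int(u.counts[2]),
                "ses_score": u.ses_score,
            },
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def units_from_geojson(path: str) -> list[GeographicUnit]:
    with open(path) as fh:
        gj = json.load(fh)
    units = []
    for feat in gj["features"]:
        p = feat["properties"]
        units.append(GeographicUnit(
            unit_id=int(p["id"]),
            polygon=shape(feat["geometry"]),
            counts=(int(p["pop_low"]), int(p["pop_mid"]), int(p["pop_high"])),
            ses_score=float(p["ses_score"]),
        ))
    return units


# ---------------------------------------------------------------------------
# Street network
# ---------------------------------------------------------------------------

@dataclass
class StreetNetwork:
    """Planar metric street graph: nodes with (x, y) in meters, undirected
    edges weighted by Euclidean length (``length_m``)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop at node {u}")
            if d.get("length_m", 0.0) <= 0.0:
                raise ValidationError(f"non-positive edge length on ({u}, {v})")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def coords(self, node: int) -> tuple[float, float]:
        d = self.graph.nodes[node]
        return (d["x"], d["y"])

    def edge_length(self, u: int, v: int) -> float:
        return float(self.graph.edges[u, v]["length_m"])

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# nodes\nnode_id,x,y\n")
            for n, d in sorted(self.graph.nodes(data=True)):
                fh.write(f"{n},{d['x']},{d['y']}\n")
            fh.write("# edges\nu,v,length_m\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u},{v},{d['length_m']}\n")

    @classmethod
    def from_csv(cls, path: str) -> "StreetNetwork":
        g = nx.Graph()
        section = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    section = line.lstrip("# ").strip()
                    continue
                if line.startswith(("node_id", "u,")):
                    continue
                parts = line.split(",")
                if section == "nodes":
                    g.add_node(int(parts[0]), x=float(parts[1]), y=float(parts[2]))
                else:
                    g.add_edge(int(parts[0]), int(parts[1]), length_m=float(parts[2]))
        return cls(g)


# ---------------------------------------------------------------------------
# Routes and trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Route:
    """An open-streets route: a node path along the street network."""

    nodes: tuple[int, ...]
    geometry: LineString
    length_m: float

    def to_geojson(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "type": "Feature",
                "geometry": mapping(self.geometry),
                "properties": {"nodes": list(self.nodes),
                               "length_m": self.length_m},
            }, fh)

    @classmethod
    def from_geojson(cls, path: str) -> "Route":
        with open(path) as fh:
            feat = json.load(fh)
        geom = shape(feat["geometry"])
        return cls(nodes=tuple(feat["properties"]["nodes"]),
                   geometry=geom,
                   length_m=float(feat["properties"]["length_m"]))


def route_from_nodes(network: StreetNetwork, nodes: Sequence[int]) -> Route:
    nodes = tuple(int(n) for n in nodes)
    coords = [network.coords(n) for n in nodes]
    length = sum(network.edge_length(a, b) for a, b in zip(nodes[:-1], nodes[1:]))
    return Route(nodes=nodes, geometry=LineString(coords), length_m=float(length))


@dataclass(frozen=True)
class ParticipantRecord:
    """One surveyed program participant.

    ``origin_node``/``origin_unit`` locate the start of the *measured
    journey* (home intersection in home-origin designs, journey-start
    intersection in on-route intercept designs); ``home_unit`` is the unit
    whose harmonized SES defines ``ses_of_origin``.  In home-origin designs
    the two units coincide.
    """

    participant_id: int
    origin_node: int
    origin_unit: int
    home_unit: int
    destination_node: int
    ses_of_origin: str
    city: str

    def __post_init__(self) -> None:
        if self.ses_of_origin not in SES_LEVELS:
            raise ValidationError(f"unknown SES level {self.ses_of_origin!r}")


def participants_to_csv(participants: Iterable[ParticipantRecord], path: str) -> None:
    pd.DataFrame([p.__dict__ for p in participants]).to_csv(path, index=False)


def participants_from_csv(path: str) -> list[ParticipantRecord]:
    df = pd.read_csv(path)
    return [ParticipantRecord(
        participant_id=int(r.participant_id),
        origin_node=int(r.origin_node),
        origin_unit=int(r.origin_unit),
        home_unit=int(r.home_unit),
        destination_node=int(r.destination_node),
        ses_of_origin=str(r.ses_of_origin),
        city=str(r.city),
    ) for r in df.itertuples()]


def point_in_unit(units: Sequence[GeographicUnit], x: float, y: float,
                  tol: float = 1e-9) -> int:
    """Smallest unit id whose (closed) polygon contains the point."""
    pt = Point(x, y)
    hits = [u.unit_id for u in units if u.polygon.distance(pt) <= tol]
    if not hits:
        raise ValidationError(f"point ({x}, {y}) lies outside all units")
    return min(hits)
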