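"""Shortest-path trajectories and SES-exposure profiles.

Each participant's journey is routed through the street network by shortest
path (origin -> destination).  Trajectories are cut into 500-m distance
bands measured from the origin; each band's value is the length-weighted
mean SES *percentile* of the geographic units the sub-polyline crosses.
Units are ranked by their SES score with population-weighted midpoint
percentiles, so the percentile scale is invariant to any monotone rescaling
of the raw score.  Participants grouped by SES-of-origin yield per-band
mean/variance exposure profiles; the headline statistic is the signed
maximum deviation of a group's band mean from its origin baseline, with the
distance (band midpoint, km) at which it occurs and a permutation p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree

from .core import (GeographicUnit, Route, SES_LEVELS, StreetNetwork,
                   ValidationError)

SEGMENT_LEN_M = 500.0     # band length along the trajectory
MIN_TAIL_M = 50.0         # shorter final partial bands are dropped
DEFAULT_MIN_N = 10        # bands with fewer participants are ineligible


class RoutingError(ValidationError):
    pass


class JoinError(ValidationError):
    pass


# ---------------------------------------------------------------------------
# Shortest-path trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    participant_id: int
    nodes: tuple[int, ...]
    geometry: LineString | None
    total_length_m: float
    ses_of_origin: str | None = None


def shortest_path_trajectory(network: StreetNetwork, origin: int,
                             destination: int,
                             participant_id: int = -1,
                             ses_of_origin: str | None = None) -> Trajectory:
    """Minimal-length path, ties broken by the lexicographically smallest
    node sequence (hence fully deterministic).

    Implemented as a Dijkstra pass from the destination followed by a greedy
    forward walk that always steps to the smallest-id neighbor lying on some
    shortest path.
    """
    g = network.graph
    if origin not in g or destination not in g:
        raise RoutingError(f"unknown node(s): {origin}, {destination}")
    if origin == destination:
        pt = Point(network.coords(origin))
        return Trajectory(participant_id, (origin,), None, 0.0, ses_of_origin)
    dist = nx.single_source_dijkstra_path_length(g, destination, weight="length_m")
    if origin not in dist:
        raise RoutingError(
            f"nodes {origin} and {destination} are not connected")
    nodes = [origin]
    u = origin
    tol = 1e-9 * max(dist[origin], 1.0)
    while u != destination:
        candidates = [v for v in g.neighbors(u)
                      if v in dist and
                      abs(dist[v] + g.edges[u, v]["length_m"] - dist[u]) <= tol]
        u = min(candidates)
        nodes.append(u)
    coords = [network.coords(n) for n in nodes]
    length = sum(g.edges[a, b]["length_m"] for a, b in zip(nodes[:-1], nodes[1:]))
    return Trajectory(participant_id, tuple(nodes), LineString(coords),
                      float(length), ses_of_origin)


def brute_force_shortest_length(network: StreetNetwork, origin: int,
                                destination: int) -> float:
    """Independent oracle: exhaustive simple-path enumeration (tiny graphs)."""
    g = network.graph
    if origin == destination:
        return 0.0
    best = math.inf
    for path in nx.all_simple_paths(g, origin, destination):
        length = sum(g.edges[a, b]["length_m"]
                     for a, b in zip(path[:-1], path[1:]))
        best = min(best, length)
    if math.isinf(best):
        raise RoutingError(f"nodes {origin} and {destination} are not connected")
    return best


# ---------------------------------------------------------------------------
# SES percentile map
# ---------------------------------------------------------------------------

def ses_percentile_map(units: Sequence[GeographicUnit]) -> dict[int, float]:
    """Population-weighted midpoint percentile rank of unit SES score.

    Units sorted by score; percentile = 100 * (cum_pop_below + own_pop/2) / T,
    with score ties sharing their block's midpoint percentile.  The
    population-weighted mean percentile is 50 by construction (up to
    discreteness).
    """
    pops = np.array([u.population for u in units], dtype=float)
    T = pops.sum()
    if T <= 0:
        raise ValidationError("all unit populations are zero")
    scores = np.array([u.ses_score for u in units])
    ids = np.array([u.unit_id for u in units])
    order = np.argsort(scores, kind="stable")
    pmap: dict[int, float] = {}
    cum = 0.0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            j += 1
        block = order[i:j]
        block_pop = pops[block].sum()
        pct = 100.0 * (cum + 0.5 * block_pop) / T
        for k in block:
            pmap[int(ids[k])] = float(pct)
        cum += block_pop
        i = j
    return pmap


# ---------------------------------------------------------------------------
# Spatial join: polylines -> (length, unit) pieces
# ---------------------------------------------------------------------------

def polyline_pieces(line: LineString,
                    units: Sequence[GeographicUnit],
                    tol: float = 1e-6) -> list[tuple[float, int]]:
    """Split a polyline at unit boundaries into (length_m, unit_id) pieces.

    Each elementary piece is assigned by its midpoint; when the midpoint lies
    on a shared boundary the smallest unit id wins (deterministic tie-break).
    Raises :class:`JoinError` if any piece lies outside the tessellation.
    """
    total = line.length
    if total <= 0:
        return []
    tree = STRtree([u.polygon for u in units])
    cand_idx = tree.query(line)
    cuts = {0.0, total}
    for i in cand_idx:
        inter = units[int(i)].polygon.intersection(line)
        for frag in getattr(inter, "geoms", [inter]):
            if isinstance(frag, LineString) and frag.length > 0:
                for cp in (frag.coords[0], frag.coords[-1]):
                    cuts.add(float(line.project(Point(cp))))
    positions = sorted(cuts)
    pieces: list[tuple[float, int]] = []
    for a, b in zip(positions[:-1], positions[1:]):
        if b - a <= tol:
            continue
        mid = line.interpolate(0.5 * (a + b))
        hits = [units[int(i)].unit_id for i in cand_idx
                if units[int(i)].polygon.distance(mid) <= tol]
        if not hits:
            raise JoinError(
                f"polyline piece at arc position {0.5 * (a + b):.1f} m lies "
                "outside the unit tessellation")
        pieces.append((b - a, min(hits)))
    return pieces


class EdgeUnitAssignment:
    """Cache of per-edge (length, unit_id) pieces for a (network, units)
    pair, so trajectory segmentation never re-runs geometry predicates."""

    def __init__(self, network: StreetNetwork, units: Sequence[GeographicUnit]):
        self.network = network
        self.units = {u.unit_id: u for u in units}
        self._pieces: dict[tuple[int, int], list[tuple[float, int]]] = {}
        unit_list = list(units)
        for u, v in network.graph.edges():
            a, b = (u, v) if u <= v else (v, u)
            line = LineString([network.coords(a), network.coords(b)])
            self._pieces[(a, b)] = polyline_pieces(line, unit_list)

    def pieces(self, u: int, v: int) -> list[tuple[float, int]]:
        if u <= v:
            return self._pieces[(u, v)]
        return list(reversed(self._pieces[(v, u)]))

    def trajectory_pieces(self, traj: Trajectory) -> list[tuple[float, int]]:
        out: list[tuple[float, int]] = []
        for a, b in zip(traj.nodes[:-1], traj.nodes[1:]):
            out.extend(self.pieces(a, b))
        return out


# ---------------------------------------------------------------------------
# 500-m segmentation
# ---------------------------------------------------------------------------

def segment_values(pieces: Sequence[tuple[float, int]],
                   pmap: Mapping[int, float],
                   segment_len_m: float = SEGMENT_LEN_M,
                   min_tail_m: float = MIN_TAIL_M) -> list[float]:
    """Per-band length-weighted mean unit percentile along a trajectory.

    Bands are half-open [k*L, (k+1)*L) from the origin; a final partial band
    shorter than ``min_tail_m`` is dropped.
    """
    total = sum(length for length, _ in pieces)
    if total <= 0:
        return []
    n_full = int(total // segment_len_m)
    tail = total - n_full * segment_len_m
    n_bands = n_full + (1 if tail >= min_tail_m else 0)
    if n_bands == 0:
        return []
    sums = np.zeros(n_bands)
    lens = np.zeros(n_bands)
    pos = 0.0
    for length, unit_id in pieces:
        pct = pmap[unit_id]
        remaining = length
        while remaining > 1e-12:
            k = int(pos // segment_len_m)
            band_end = (k + 1) * segment_len_m
            step = min(remaining, band_end - pos)
            if k < n_bands:
                sums[k] += step * pct
                lens[k] += step
            pos += step
            remaining -= step
    return list(sums / np.where(lens > 0, lens, 1.0))


def segment_trajectory(traj: Trajectory, assignment: EdgeUnitAssignment,
                       pmap: Mapping[int, float],
                       segment_len_m: float = SEGMENT_LEN_M,
                       min_tail_m: float = MIN_TAIL_M) -> list[tuple[int, float]]:
    vals = segment_values(assignment.trajectory_pieces(traj), pmap,
                          segment_len_m, min_tail_m)
    return list(enumerate(vals))


# ---------------------------------------------------------------------------
# Group exposure profiles and the maximum-difference statistic
# ---------------------------------------------------------------------------

@dataclass
class SegmentExposureProfile:
    group: str
    mean_percentile: np.ndarray   # per band k
    variance: np.ndarray          # sample variance per band (0 when n=1)
    n_participants: np.ndarray    # participants reaching band k


@dataclass
class MaxDifferenceResult:
    group: str
    baseline_percentile: float
    max_diff: float           # signed, percentile points
    distance_km: float        # band midpoint: (k* + 0.5) * L / 1000
    band_index: int
    p_value: float | None = None
    defined: bool = True


def add_one_p_value(count_ge: int, B: int) -> float:
    """Add-one permutation p-value: (1 + #{perm >= observed}) / (B + 1)."""
    if not 0 <= count_ge <= B:
        raise ValidationError("count_ge must lie in [0, B]")
    return (1 + count_ge) / (B + 1)


@dataclass
class ExposureDataset:
    """Dense per-participant band-value matrix plus origin percentiles.

    ``values[i, k]`` is participant i's band-k exposure (NaN beyond their
    traveled distance); this is the shared substrate for group profiles,
    max-difference statistics and vectorized permutation tests.
    """

    values: np.ndarray          # (n_participants, K), NaN-padded
    origin_percentile: np.ndarray
    labels: np.ndarray          # SES-of-origin label per participant
    participant_ids: np.ndarray

    @classmethod
    def build(cls, trajectories: Sequence[Trajectory],
              assignment: EdgeUnitAssignment,
              pmap: Mapping[int, float],
              origin_units: Sequence[int],
              segment_len_m: float = SEGMENT_LEN_M,
              min_tail_m: float = MIN_TAIL_M) -> "ExposureDataset":
        rows = [segment_values(assignment.trajectory_pieces(t), pmap,
                               segment_len_m, min_tail_m)
                for t in trajectories]
        K = max((len(r) for r in rows), default=0)
        values = np.full((len(rows), K), np.nan)
        for i, r in enumerate(rows):
            values[i, :len(r)] = r
        return cls(
            values=values,
            origin_percentile=np.array([pmap[u] for u in origin_units], float),
            labels=np.array([t.ses_of_origin for t in trajectories]),
            participant_ids=np.array([t.participant_id for t in trajectories]),
        )

    # -- profiles -----------------------------------------------------------

    def profile(self, group: str,
                labels: np.ndarray | None = None) -> SegmentExposureProfile:
        labels = self.labels if labels is None else labels
        mask = labels == group
        if not mask.any():
            warnings.warn(f"empty SES-of-origin group {group!r}: skipped",
                          stacklevel=2)
            return SegmentExposureProfile(group, np.empty(0), np.empty(0),
                                          np.empty(0, dtype=int))
        sub = self.values[mask]
        n = np.sum(~np.isnan(sub), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(sub, axis=0)
            var = np.nanvar(sub, axis=0, ddof=1)
        var = np.where(n > 1, var, 0.0)
        return SegmentExposureProfile(group, mean, var, n)

    def baseline(self, group: str, labels: np.ndarray | None = None) -> float:
        labels = self.labels if labels is None else labels
        mask = labels == group
        if not mask.any():
            raise ValidationError(f"no participants with SES-of-origin {group!r}")
        return float(self.origin_percentile[mask].mean())

    def max_difference(self, group: str, min_n: int = DEFAULT_MIN_N,
                       segment_len_m: float = SEGMENT_LEN_M,
                       labels: np.ndarray | None = None) -> MaxDifferenceResult:
        prof = self.profile(group, labels)
        base = self.baseline(group, labels)
        return max_percentile_difference(prof, base, min_n, segment_len_m)

    # -- permutation test ---------------------------------------------------

    def permutation_test(self, group: str, B: int, seed: int,
                         min_n: int = DEFAULT_MIN_N,
                         segment_len_m: float = SEGMENT_LEN_M) -> float:
        """p-value for |max_diff| of ``group`` under random relabeling.

        Labels are permuted across participants B times; the add-one estimate
        p = (1 + #{perm >= observed}) / (B + 1) is returned.
        """
        if B < 99:
            raise ValidationError("B must be >= 99")
        if len(np.unique(self.labels)) < 2:
            raise ValidationError("degenerate roster: a single SES label")
        obs = self.max_difference(group, min_n, segment_len_m)
        if not obs.defined:
            raise ValidationError("observed max difference undefined")
        rng = np.random.default_rng(seed)
        observed = abs(obs.max_diff)
        reach = ~np.isnan(self.values)
        filled = np.where(reach, self.values, 0.0)
        count_ge = 0
        for _ in range(B):
            perm = rng.permutation(self.labels)
            mask = perm == group
            if not mask.any():
                continue  # statistic undefined; never exceeds observed
            n_k = reach[mask].sum(axis=0)
            with np.errstate(invalid="ignore"):
                mean_k = filled[mask].sum(axis=0) / np.where(n_k > 0, n_k, 1)
            eligible = n_k >= min_n
            base = self.origin_percentile[mask].mean()
            if not eligible.any():
                continue
            stat = np.max(np.abs(mean_k[eligible] - base))
            if stat >= observed - 1e-12:
                count_ge += 1
        return add_one_p_value(count_ge, B)


def max_percentile_difference(profile: SegmentExposureProfile,
                              baseline: float,
                              min_n: int = DEFAULT_MIN_N,
                              segment_len_m: float = SEGMENT_LEN_M) -> MaxDifferenceResult:
    """Signed largest deviation of the band means from the origin baseline.

    Only bands with at least ``min_n`` participants are eligible; ties go to
    the smallest band index; the distance reported is the band midpoint.
    """
    if min_n < 1:
        raise ValidationError("min_n must be >= 1")
    eligible = np.flatnonzero(profile.n_participants >= min_n)
    if eligible.size == 0:
        return MaxDifferenceResult(profile.group, baseline, np.nan, np.nan,
                                   -1, defined=False)
    diffs = profile.mean_percentile[eligible] - baseline
    k_star = int(eligible[np.argmax(np.abs(diffs))])
    diff = float(profile.mean_percentile[k_star] - baseline)
    return MaxDifferenceResult(
        group=profile.group,
        baseline_percentile=float(baseline),
        max_diff=diff,
        distance_km=(k_star + 0.5) * segment_len_m / 1000.0,
        band_index=k_star,
    )


# ---------------------------------------------------------------------------
# Length shares and route overlay
# ---------------------------------------------------------------------------

def trajectory_ses_shares(trajectories: Sequence[Trajectory],
                          assignment: EdgeUnitAssignment) -> dict[str, dict[str, float]]:
    """Per-group mean fraction of trajectory length in low/middle/high units.

    A unit's SES category is its dominant (modal) group.  Zero-length
    trajectories are excluded with a warning.  Per-participant shares sum
    to 1.
    """
    per_group: dict[str, list[np.ndarray]] = {}
    for t in trajectories:
        if t.total_length_m <= 0:
            warnings.warn(f"zero-length trajectory {t.participant_id}: excluded",
                          stacklevel=2)
            continue
        shares = np.zeros(len(SES_LEVELS))
        for length, unit_id in assignment.trajectory_pieces(t):
            cat = assignment.units[unit_id].dominant_ses
            shares[SES_LEVELS.index(cat)] += length
        shares /= shares.sum()
        per_group.setdefault(t.ses_of_origin or "all", []).append(shares)
    return {g: dict(zip(SES_LEVELS, np.mean(v, axis=0)))
            for g, v in per_group.items()}


@dataclass
class RouteOverlay:
    by_ses: dict[str, float]     # fractions of route length by SES category
    by_class: dict[str, float]   # fractions by segregation class


def route_overlay(route: Route, units: Sequence[GeographicUnit],
                  classes: Mapping[int, str]) -> RouteOverlay:
    """Length fractions of the route by unit SES category and segregation
    class; each grouping sums to 1."""
    pieces = polyline_pieces(route.geometry, list(units))
    if not pieces:
        raise JoinError("route does not intersect the unit tessellation")
    unit_by_id = {u.unit_id: u for u in units}
    total = sum(length for length, _ in pieces)
    by_ses: dict[str, float] = {s: 0.0 for s in SES_LEVELS}
    by_class: dict[str, float] = {}
    for length, unit_id in pieces:
        u = unit_by_id[unit_id]
        by_ses[u.dominant_ses] += length / total
        cls = classes[unit_id]
        by_class[cls] = by_class.get(cls, 0.0) + length / total
    return RouteOverlay(by_ses=by_ses, by_class=by_class)
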