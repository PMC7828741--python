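"""Self-evaluation harness: oracle cross-checks and recovery studies.

Every function here re-runs the package end to end on freshly generated
inputs and measures how well a known planted quantity is recovered, or how
closely an implementation matches an independent oracle.  These are the
computations behind the repository's acceptance checks; they are ordinary
library code so they can be driven both from the test suite and from
``scripts/acceptance.py``.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np

from . import exposure as expo
from . import harmonize as harm
from . import synthetic_city as synth
from .core import ParticipantRecord, StreetNetwork
from .segregation import CompositionTable, theil_index


def _route_all(city, participants):
    return [expo.shortest_path_trajectory(
                city.network, p.origin_node, p.destination_node,
                p.participant_id, p.ses_of_origin)
            for p in participants]


def build_exposure_dataset(city, participants,
                           segment_len_m: float = 500.0) -> expo.ExposureDataset:
    pmap = expo.ses_percentile_map(city.units)
    assignment = expo.EdgeUnitAssignment(city.network, city.units)
    return expo.ExposureDataset.build(
        _route_all(city, participants), assignment, pmap,
        [p.origin_unit for p in participants], segment_len_m=segment_len_m)


# ---------------------------------------------------------------------------
# Oracle cross-checks
# ---------------------------------------------------------------------------

def theil_oracle_max_error(n_tables: int = 100, seed: int = 0) -> float:
    """Largest |H - oracle| over random composition tables, where the
    oracle is an explicit double loop over units and groups."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        counts = rng.integers(0, 500, size=(10, 3))
        counts[0] = [50, 60, 70]  # guarantee a multi-group metro
        import pandas as pd
        table = CompositionTable(pd.DataFrame({
            "unit_id": range(len(counts)),
            "pop_low": counts[:, 0], "pop_mid": counts[:, 1],
            "pop_high": counts[:, 2]}))
        H = theil_index(table).H
        # independent double-loop recomputation
        T = counts.sum()
        metro = counts.sum(axis=0) / T
        E = sum(-p * math.log(p) for p in metro if p > 0)
        H_oracle = 0.0
        for row in counts:
            t_i = row.sum()
            E_i = 0.0
            for c in row:
                if t_i > 0 and c > 0:
                    p = c / t_i
                    E_i -= p * math.log(p)
            H_oracle += t_i * (E - E_i) / (E * T)
        worst = max(worst, abs(H - H_oracle))
    return worst


def shortest_path_match_rate(n_graphs: int = 100, seed: int = 0) -> float:
    """Fraction of random small graphs (<= 12 nodes) on which the routed
    length equals the exhaustive simple-path-enumeration minimum."""
    rng = np.random.default_rng(seed)
    matches = 0
    done = 0
    while done < n_graphs:
        n = int(rng.integers(4, 13))
        g = nx.gnm_random_graph(n, int(rng.integers(n, 2 * n)),
                                seed=int(rng.integers(2**31)))
        for u, v in g.edges:
            g.edges[u, v]["length_m"] = float(rng.uniform(10, 500))
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp).copy()
        if g.number_of_nodes() < 2:
            continue
        for node in g.nodes:
            g.nodes[node]["x"] = g.nodes[node]["y"] = 0.0
        net = StreetNetwork(g)
        o, d = rng.choice(sorted(g.nodes), size=2, replace=False)
        routed = expo.shortest_path_trajectory(net, int(o), int(d))
        oracle = expo.brute_force_shortest_length(net, int(o), int(d))
        matches += abs(routed.total_length_m - oracle) <= 1e-9 * max(oracle, 1)
        done += 1
    return matches / n_graphs


# ---------------------------------------------------------------------------
# Exposure recovery
# ---------------------------------------------------------------------------

def planted_span_estimates(n_seeds: int = 20, n_participants: int = 500,
                           span: float = 40.0, seed: int = 0) -> list[float]:
    """Low-SES-origin maximum percentile differences measured on the
    planted-span city (true span = ``span``), one estimate per seed."""
    city = synth.planted_span_city(span)
    pmap = expo.ses_percentile_map(city.units)
    assignment = expo.EdgeUnitAssignment(city.network, city.units)
    out = []
    for s in range(n_seeds):
        parts = synth.generate_participants(city, n_participants,
                                            seed=seed + s)
        ds = expo.ExposureDataset.build(
            _route_all(city, parts), assignment, pmap,
            [p.origin_unit for p in parts])
        out.append(ds.max_difference("low").max_diff)
    return out


def scenario_attenuation_pairs(n_seeds: int = 20, n_participants: int = 500,
                               seed: int = 0) -> list[tuple[float, float]]:
    """(crossing, confined) low-origin |max diff| pairs on the same seed.

    Crossing routes span the SES gradient with home-origin journeys;
    confined routes sit in the high-SES area with on-route intercept
    journeys, which should attenuate the measured excursion."""
    pairs = []
    for s in range(n_seeds):
        vals = {}
        for scenario in ("crossing", "confined"):
            cfg = synth.CityConfig(grid_rows=6, grid_cols=16,
                                   gradient_strength=6.0, mixing_noise=12.0,
                                   route_scenario=scenario, seed=seed + s)
            city = synth.generate_city(cfg)
            parts = synth.generate_participants(city, n_participants,
                                                seed=seed + s)
            ds = build_exposure_dataset(city, parts)
            vals[scenario] = abs(ds.max_difference("low").max_diff)
        pairs.append((vals["crossing"], vals["confined"]))
    return pairs


# ---------------------------------------------------------------------------
# Permutation-test calibration
# ---------------------------------------------------------------------------

def permutation_rejection_rate(n_replicates: int = 500, B: int = 199,
                               seed: int = 0,
                               alpha: float = 0.05) -> tuple[float, int]:
    """Null rejection rate of the permutation test at level ``alpha``.

    One synthetic city's trajectory set is held fixed; each replicate
    randomly re-assigns the SES-of-origin labels (so labels are independent
    of trajectories by construction) and runs the test for each of the
    three groups.  Returns (rate, number of tests)."""
    city = synth.generate_city(synth.CityConfig(
        grid_rows=4, grid_cols=10, gradient_strength=2.0, mixing_noise=6.0,
        seed=9))
    parts = synth.generate_participants(city, 80, seed=9)
    ds = build_exposure_dataset(city, parts)
    rng = np.random.default_rng(seed)
    rejections = 0
    n_tests = 0
    for _ in range(n_replicates):
        labels = rng.permutation(ds.labels)
        shuffled = expo.ExposureDataset(ds.values, ds.origin_percentile,
                                        labels, ds.participant_ids)
        for group in ("low", "middle", "high"):
            p = shuffled.permutation_test(group, B=B,
                                          seed=int(rng.integers(2**31)),
                                          min_n=5)
            rejections += p <= alpha
            n_tests += 1
    return rejections / n_tests, n_tests


# ---------------------------------------------------------------------------
# Model recovery
# ---------------------------------------------------------------------------

def model_ci_coverage(n_replicates: int = 200, true_log_or: float = 0.7,
                      n_per_city: int = 800, sigma_city: float = 0.3,
                      seed: int = 0) -> float:
    """Fraction of replicates whose 95% Wald CI for the planted sex effect
    covers the truth, running the full survey-generation -> harmonization
    -> two-level-fit pipeline each time."""
    effects = synth.EffectSpec(
        intercept=0.0, sex_female=true_log_or, ses_middle=0.0, ses_high=0.0,
        edu_secondary=0.0, edu_college=0.0, edu_masters=0.0,
        city_sd=sigma_city)
    n = n_per_city * len(harm.CITIES)
    covered = 0
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        roster_rng = np.random.default_rng(rep_seed)
        roster = [ParticipantRecord(
            i, 0, 0, 0, 0,
            str(roster_rng.choice(["low", "middle", "high"],
                                  p=[0.2, 0.55, 0.25])),
            harm.CITIES[i % len(harm.CITIES)]) for i in range(n)]
        tables = synth.generate_survey(roster, effects, seed=rep_seed)
        hdf = harm.harmonize_surveys(tables)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = harm.fit_two_level_logistic(hdf)
        row = res.table.set_index("term").loc["sex[female]"]
        covered += row["ci_low"] < math.exp(true_log_or) < row["ci_high"]
    return covered / n_replicates
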