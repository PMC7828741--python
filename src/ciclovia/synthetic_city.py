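"""Seeded synthetic cities, routes, participants and raw surveys.

The study's survey and GIS data are not public, so every downstream stage
is exercised on synthetic cities that reproduce the statistical structure
the analysis assumes: a rectangular tessellation of 500-m square units
whose SES composition drifts west-to-east (a Dirichlet whose mean follows a
logistic gradient), a lattice street network on the unit corners, an
open-streets route that either *crosses* the gradient or stays *confined*
to the high-SES side, participants with population-weighted home locations,
and raw surveys in four city dialects whose binary PA outcome comes from a
logistic model with a city-level random intercept.

Scenario semantics follow the two origin designs used in the field: in the
``crossing`` scenario the measured journey starts at the home intersection
(home-origin design); in the ``confined`` scenario it starts at an
intersection on the route (on-route intercept design), while the home unit
still determines SES-of-origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from shapely.geometry import box

from .core import (GeographicUnit, ParticipantRecord, Route, SES_LEVELS,
                   StreetNetwork, ValidationError, point_in_unit,
                   route_from_nodes, ses_score_from_counts, substream)
from .harmonize import CITIES, DEFAULT_CODEBOOK

import networkx as nx
import pandas as pd


class GenerationError(ValidationError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CityConfig:
    grid_rows: int = 6
    grid_cols: int = 12
    unit_side_m: float = 500.0
    pop_per_unit_mean: float = 1000.0
    n_ses_groups: int = 3
    gradient_strength: float = 2.0   # spatial SES sorting (0 = none)
    mixing_noise: float = 8.0        # Dirichlet concentration (> 0)
    route_scenario: str = "crossing"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < 4:
            raise GenerationError("grid must contain at least 4 units")
        if self.grid_rows <= 0 or self.grid_cols <= 0 or self.unit_side_m <= 0:
            raise GenerationError("non-positive grid dimensions")
        if self.mixing_noise <= 0:
            raise GenerationError("mixing_noise must be > 0")
        if self.gradient_strength < 0:
            raise GenerationError("gradient_strength must be >= 0")
        if self.n_ses_groups != 3:
            raise GenerationError("exactly 3 SES groups are supported")
        if self.route_scenario not in ("crossing", "confined"):
            raise GenerationError(
                f"unknown route scenario {self.route_scenario!r}")


@dataclass
class SyntheticCity:
    config: CityConfig
    units: list[GeographicUnit]
    network: StreetNetwork
    route: Route

    def unit_at(self, row: int, col: int) -> GeographicUnit:
        return self.units[row * self.config.grid_cols + col]


def _node_id(config: CityConfig, row: int, col: int) -> int:
    return row * (config.grid_cols + 1) + col


def _unit_corner_nodes(config: CityConfig, unit_id: int) -> list[int]:
    r, c = divmod(unit_id, config.grid_cols)
    return [_node_id(config, r, c), _node_id(config, r, c + 1),
            _node_id(config, r + 1, c), _node_id(config, r + 1, c + 1)]


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

def composition_mean(config: CityConfig, col: int) -> np.ndarray:
    """Expected SES composition for a grid column: a softmax gradient with
    low-SES mass peaking at the west edge and high-SES at the east."""
    C = config.grid_cols
    x = 0.5 if C == 1 else col / (C - 1)
    g = config.gradient_strength
    scores = g * np.array([1.0 - 2.0 * x,
                           1.0 - 2.0 * abs(x - 0.5),
                           2.0 * x - 1.0])
    e = np.exp(scores - scores.max())
    return e / e.sum()


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Deterministic proportional integer split (largest-remainder rule,
    ties toward the lowest group index)."""
    target = weights / weights.sum() * total
    base = np.floor(target).astype(int)
    short = total - base.sum()
    order = np.lexsort((np.arange(len(weights)), -(target - base)))
    base[order[:short]] += 1
    return base


def generate_units(config: CityConfig) -> list[GeographicUnit]:
    """One square unit per grid cell with Dirichlet SES composition and
    Poisson population.

    The Dirichlet draw uses inverse-CDF (common-uniform) gamma coupling so
    that, under a fixed seed, compositions respond monotonically to
    ``gradient_strength``.
    """
    rng = substream(config.seed, "units")
    R, C, s = config.grid_rows, config.grid_cols, config.unit_side_m
    u = np.clip(rng.random((R * C, 3)), 1e-12, 1.0 - 1e-12)
    pops = substream(config.seed, "population").poisson(
        config.pop_per_unit_mean, size=R * C)
    units = []
    for r in range(R):
        for c in range(C):
            i = r * C + c
            alpha = config.mixing_noise * composition_mean(config, c)
            gam = stats.gamma.ppf(u[i], alpha)
            gam = np.where(gam > 0, gam, 1e-300)
            pi = gam / gam.sum()
            counts = _largest_remainder(int(pops[i]), pi)
            units.append(GeographicUnit(
                unit_id=i,
                polygon=box(c * s, r * s, (c + 1) * s, (r + 1) * s),
                counts=tuple(int(x) for x in counts),
                ses_score=ses_score_from_counts(counts),
            ))
    return units


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def generate_network(config: CityConfig) -> StreetNetwork:
    """Lattice street graph: a node at every unit corner, edges between
    4-neighbors, edge weight = Euclidean length."""
    g = nx.Graph()
    R, C, s = config.grid_rows, config.grid_cols, config.unit_side_m
    for r in range(R + 1):
        for c in range(C + 1):
            g.add_node(_node_id(config, r, c), x=c * s, y=r * s)
    for r in range(R + 1):
        for c in range(C + 1):
            if c < C:
                g.add_edge(_node_id(config, r, c), _node_id(config, r, c + 1),
                           length_m=s)
            if r < R:
                g.add_edge(_node_id(config, r, c), _node_id(config, r + 1, c),
                           length_m=s)
    return StreetNetwork(g)


# ---------------------------------------------------------------------------
# Routes
# ---------------------------------------------------------------------------

def generate_route(config: CityConfig, units: Sequence[GeographicUnit],
                   network: StreetNetwork) -> Route:
    """Open-streets route for the configured scenario.

    ``crossing``: a west-east path along a central grid line, spanning the
    entire SES gradient.  ``confined``: the longest contiguous west-east
    stretch whose flanking units are all dominantly high-SES (so the route
    length lies entirely, hence >= 75%, within high-SES units); raises when
    no such stretch of at least two units exists.
    """
    R, C = config.grid_rows, config.grid_cols
    rm = R // 2
    if config.route_scenario == "crossing":
        nodes = [_node_id(config, rm, c) for c in range(C + 1)]
        return route_from_nodes(network, nodes)

    adjacent_rows = [r for r in (rm - 1, rm) if 0 <= r < R]
    ok = [all(units[r * C + c].dominant_ses == "high" for r in adjacent_rows)
          for c in range(C)]
    best_run, run_start, cur_start = (0, 0), 0, None
    for c, flag in enumerate(ok + [False]):
        if flag and cur_start is None:
            cur_start = c
        elif not flag and cur_start is not None:
            if c - cur_start > best_run[0]:
                best_run = (c - cur_start, cur_start)
            cur_start = None
    length, start = best_run
    if length < 2:
        raise GenerationError(
            "confined scenario infeasible: no contiguous stretch of >= 2 "
            "columns with dominantly high-SES units flanking the route line")
    nodes = [_node_id(config, rm, c) for c in range(start, start + length + 1)]
    return route_from_nodes(network, nodes)


def generate_city(config: CityConfig) -> SyntheticCity:
    units = generate_units(config)
    network = generate_network(config)
    route = generate_route(config, units, network)
    return SyntheticCity(config, units, network, route)


# ---------------------------------------------------------------------------
# Planted-span city (three-block construction)
# ---------------------------------------------------------------------------

def planted_span_city(span_percentile: float = 40.0, grid_cols: int = 20,
                      grid_rows: int = 5, origin_cols: int = 5,
                      total_population: int = 50_000,
                      unit_side_m: float = 500.0) -> SyntheticCity:
    """City with a known SES-percentile span between the low-SES-origin
    baseline and the route's plateau.

    Three blocks with deterministic, within-block-identical compositions:

    * origin block (dominant low, population share ``f_B``) along the west
      end of the route;
    * plateau block (dominant high, share ``f_C``) along the rest of the
      route, a single tied percentile so far exposure bands are constant;
    * filler block (dominant middle, lowest SES score, share
      ``f_A = 1 - span/50``) away from the route.

    With blocks ranked filler < origin < plateau, the origin-block midpoint
    percentile is ``100*(f_A + f_B/2)`` and the plateau midpoint is
    ``100*(1 - f_C/2)``; their difference reduces to ``50*(1 - f_A)``, so
    any span in (0, 50) can be planted exactly.  The route runs along the
    first grid line (the side the smallest-node-id shortest-path tie-break
    favors), so trajectory bands join only first-row units.
    """
    if not 0.0 < span_percentile < 50.0:
        raise GenerationError("plantable spans lie strictly between 0 and 50")
    f_a = 1.0 - span_percentile / 50.0
    f_b = f_c = (1.0 - f_a) / 2.0
    R, C, s = grid_rows, grid_cols, unit_side_m
    if R < 2 or not 1 <= origin_cols < C:
        raise GenerationError("need >= 2 rows and 1 <= origin_cols < cols")

    comp = {"filler": np.array([0.45, 0.50, 0.05]),   # dominant middle, score 1.60
            "origin": np.array([0.45, 0.30, 0.25]),   # dominant low,    score 1.80
            "plateau": np.array([0.10, 0.20, 0.70])}  # dominant high,   score 2.60
    pop = {"filler": int(round(f_a * total_population / ((R - 1) * C))),
           "origin": int(round(f_b * total_population / origin_cols)),
           "plateau": int(round(f_c * total_population / (C - origin_cols)))}

    config = CityConfig(grid_rows=R, grid_cols=C, unit_side_m=s,
                        pop_per_unit_mean=total_population / (R * C),
                        route_scenario="crossing", seed=0)
    units = []
    for r in range(R):
        for c in range(C):
            if r > 0:
                block = "filler"
            elif c < origin_cols:
                block = "origin"
            else:
                block = "plateau"
            counts = _largest_remainder(pop[block], comp[block])
            units.append(GeographicUnit(
                unit_id=r * C + c,
                polygon=box(c * s, r * s, (c + 1) * s, (r + 1) * s),
                counts=tuple(int(x) for x in counts),
                ses_score=ses_score_from_counts(counts),
            ))
    network = generate_network(config)
    route = route_from_nodes(
        network, [_node_id(config, 0, c) for c in range(C + 1)])
    return SyntheticCity(config, units, network, route)


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------

def generate_participants(city: SyntheticCity, n: int, seed: int,
                          design: str | None = None) -> list[ParticipantRecord]:
    """Sample ``n`` participants.

    Home units are drawn proportional to unit population; SES-of-origin is
    the home unit's dominant SES.  Under the ``home`` design (default for
    crossing routes) the journey origin is a random corner intersection of
    the home unit; under the ``route`` design (default for confined routes,
    emulating on-route intercept surveys) it is a random route
    intersection.  Destinations are uniform over route nodes.  City
    dialects are assigned round-robin.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if design is None:
        design = ("route" if city.config.route_scenario == "confined"
                  else "home")
    if design not in ("home", "route"):
        raise ValidationError(f"unknown participant design {design!r}")
    rng = substream(seed, "participants")
    pops = np.array([u.population for u in city.units], dtype=float)
    if pops.sum() <= 0:
        raise GenerationError("city has no population")
    home_units = rng.choice(len(city.units), size=n, p=pops / pops.sum())
    route_nodes = np.asarray(city.route.nodes)
    destinations = rng.choice(route_nodes, size=n)
    participants = []
    for i in range(n):
        home = int(home_units[i])
        if design == "home":
            origin_node = int(rng.choice(
                _unit_corner_nodes(city.config, home)))
            origin_unit = home
        else:
            origin_node = int(rng.choice(route_nodes))
            x, y = city.network.coords(origin_node)
            origin_unit = point_in_unit(city.units, x, y)
        participants.append(ParticipantRecord(
            participant_id=i,
            origin_node=origin_node,
            origin_unit=origin_unit,
            home_unit=home,
            destination_node=int(destinations[i]),
            ses_of_origin=city.units[home].dominant_ses,
            city=CITIES[i % len(CITIES)],
        ))
    return participants


# ---------------------------------------------------------------------------
# Raw surveys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """True data-generating effects for the meets-PA-during-program
    outcome (log odds ratios; city intercepts ~ N(0, city_sd^2))."""

    intercept: float
    sex_female: float
    ses_middle: float
    ses_high: float
    edu_secondary: float
    edu_college: float
    edu_masters: float
    city_sd: float

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "EffectSpec":
        missing = [f.name for f in dc_fields(cls) if f.name not in d]
        if missing:
            raise GenerationError(f"missing effect coefficients: {missing}")
        return cls(**{f.name: float(d[f.name]) for f in dc_fields(cls)})


#: Defaults follow the published multivariable odds ratios (sex 0.90, SES
#: middle 0.94 / high 1.21, education 0.92 / 1.43 / 1.88) with a unit
#: city-level SD matching the wide between-city prevalence range.
DEFAULT_EFFECTS = EffectSpec(
    intercept=0.0, sex_female=np.log(0.90),
    ses_middle=np.log(0.94), ses_high=np.log(1.21),
    edu_secondary=np.log(0.92), edu_college=np.log(1.43),
    edu_masters=np.log(1.88), city_sd=1.0,
)

#: Per-city marginal distributions for the descriptive variables,
#: following the published per-city frequencies.
CITY_MARGINALS: dict = {
    "male_prob": {"bogota": 0.618, "mexico_city": 0.513,
                  "santiago_cali": 0.505, "santiago_chile": 0.354},
    "age_group_probs": {  # 18-29 / 30-49 / >=50
        "bogota": (0.367, 0.452, 0.181), "mexico_city": (0.356, 0.467, 0.177),
        "santiago_cali": (0.264, 0.450, 0.286),
        "santiago_chile": (0.304, 0.479, 0.217)},
    "education_probs": {  # primary / secondary / college / masters
        "bogota": (0.044, 0.288, 0.537, 0.131),
        "mexico_city": (0.011, 0.377, 0.504, 0.108),
        "santiago_cali": (0.038, 0.365, 0.538, 0.059),
        "santiago_chile": (0.003, 0.209, 0.788)},
    "single_prob": {"bogota": 0.575, "mexico_city": 0.636,
                    "santiago_cali": 0.486},
    "car_prob": {"bogota": 0.458, "mexico_city": 0.367,
                 "santiago_cali": 0.608},
    "health_probs": {  # Likert 1..5
        "bogota": (0.31, 0.59, 0.06, 0.03, 0.01),
        "santiago_cali": (0.20, 0.66, 0.09, 0.04, 0.01),
        "santiago_chile": (0.69, 0.26, 0.03, 0.01, 0.01)},
    "safety_probs": {  # Likert 1..5
        "bogota": (0.020, 0.017, 0.048, 0.400, 0.515),
        "santiago_cali": (0.200, 0.226, 0.243, 0.180, 0.151),
        "santiago_chile": (0.030, 0.025, 0.005, 0.440, 0.500)},
    "activity_probs": {  # cycling / rollerblading / walking / running / other
        "bogota": (0.604, 0.052, 0.222, 0.118, 0.004),
        "mexico_city": (0.879, 0.035, 0.032, 0.053, 0.001),
        "santiago_cali": (0.180, 0.018, 0.407, 0.143, 0.252),
        "santiago_chile": (0.686, 0.072, 0.040, 0.182, 0.020)},
    "frequency_probs": {  # >=4/month, 2-3/month, 1/month, >=1/year
        "bogota": (0.554, 0.258, 0.120, 0.068),
        "mexico_city": (0.301, 0.391, 0.132, 0.176),
        "santiago_cali": (0.641, 0.173, 0.091, 0.095),
        "santiago_chile": (0.277, 0.117, 0.147, 0.459)},
    "alone_prob": {"bogota": 0.566, "mexico_city": 0.657,
                   "santiago_cali": 0.658},
}

_AGE_BOUNDS = {"18-29": (18, 29), "30-49": (30, 49), ">=50": (50, 72)}


def _linear_predictor(effects: EffectSpec, female: bool, ses: str,
                      education: str, u_city: float) -> float:
    lp = effects.intercept + u_city
    if female:
        lp += effects.sex_female
    if ses == "middle":
        lp += effects.ses_middle
    elif ses == "high":
        lp += effects.ses_high
    if education == "secondary":
        lp += effects.edu_secondary
    elif education == "college":
        lp += effects.edu_college
    elif education == "masters_plus":
        lp += effects.edu_masters
    return lp


def generate_survey(participants: Sequence[ParticipantRecord],
                    effects: EffectSpec | Mapping[str, float] = DEFAULT_EFFECTS,
                    seed: int = 0,
                    codebook: Mapping | None = None) -> dict[str, pd.DataFrame]:
    """Raw city-dialect survey tables for a participant roster.

    Every emitted value is legal under the harmonization codebook; the
    binary meets-PA-during-program outcome is drawn from the logistic model
    in ``effects`` and encoded as minutes of program PA (>= 150 iff the
    outcome is positive), so harmonization genuinely recovers it.
    """
    if not isinstance(effects, EffectSpec):
        effects = EffectSpec.from_dict(effects)
    cb = codebook or DEFAULT_CODEBOOK
    rng = substream(seed, "survey")
    u_city = {city: rng.normal(0.0, effects.city_sd) for city in CITIES}
    m = CITY_MARGINALS

    def inv(mapping: Mapping[str, str]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rawv, harm in mapping.items():
            out.setdefault(harm, []).append(rawv)
        return out

    tables: dict[str, list[dict]] = {city: [] for city in CITIES}
    for p in participants:
        city = p.city
        avail = cb["available"]
        obs_date = cb["observation_date"][city]
        row: dict = {"participant_id": p.participant_id,
                     "fecha_encuesta": obs_date}

        female = rng.random() >= m["male_prob"][city]
        sex_codes = inv(cb["sex"][city])
        row["sexo"] = sex_codes["female" if female else "male"][0]

        age_grp_probs = m["age_group_probs"][city]
        grp = rng.choice(list(_AGE_BOUNDS), p=age_grp_probs)
        lo, hi = _AGE_BOUNDS[grp]
        age = int(rng.integers(lo, hi + 1))
        if cb["age_field"][city] == "edad":
            row["edad"] = age
        else:
            y0, m0, d0 = map(int, obs_date.split("-"))
            days_extra = int(rng.integers(0, 364))
            birth = (pd.Timestamp(y0, m0, d0)
                     - pd.DateOffset(years=age)
                     - pd.Timedelta(days=days_extra))
            row["fecha_nacimiento"] = birth.strftime("%Y-%m-%d")

        edu_levels = ["primary", "secondary", "college", "masters_plus"]
        edu_probs = m["education_probs"][city]
        education = rng.choice(edu_levels[:len(edu_probs)],
                               p=np.asarray(edu_probs) / np.sum(edu_probs))
        row["educacion"] = inv(cb["education"][city])[education][0]

        if city in avail["marital"]:
            single = rng.random() < m["single_prob"][city]
            codes = inv(cb["marital"][city])
            row["estado_civil"] = str(rng.choice(
                codes["single" if single else "partner"]))

        ses_codes = inv(cb["ses"][city])[p.ses_of_origin]
        row["nse"] = str(rng.choice(ses_codes))

        if city in avail["car"]:
            row["auto"] = "si" if rng.random() < m["car_prob"][city] else "no"
        if city in avail["health"]:
            row["salud"] = int(rng.choice(np.arange(1, 6),
                                          p=m["health_probs"][city]))
        if city in avail["bmi"]:
            height_m = rng.normal(1.58 if female else 1.70,
                                  0.065 if female else 0.07)
            bmi = rng.normal(24.5, 3.8)
            row["peso_kg"] = round(max(bmi, 15.0) * height_m ** 2, 1)
            unit = cb["height_unit"][city]
            row["talla"] = round(height_m * 100, 0) if unit == "cm" \
                else round(height_m, 2)
        if city in avail["ltpa"]:
            row["min_moderada_ocio"] = round(float(rng.gamma(1.5, 110)), 0)
            vig = rng.gamma(1.0, 40) if rng.random() < 0.5 else 0.0
            row["min_vigorosa_ocio"] = round(float(vig), 0)
        if city in avail["transport_pa"]:
            row["min_transporte"] = round(float(rng.gamma(1.2, 120)), 0)

        lp = _linear_predictor(effects, female, p.ses_of_origin, education,
                               u_city[city])
        meets = rng.random() < 1.0 / (1.0 + np.exp(-lp))
        if meets:
            row["minutos_programa"] = round(150.0 + float(rng.exponential(75)), 0)
        else:
            row["minutos_programa"] = round(float(rng.uniform(15, 149)), 0)

        act_levels = ["cycling", "rollerblading", "walking", "running", "other"]
        activity = rng.choice(act_levels, p=m["activity_probs"][city])
        row["actividad"] = inv(cb["activity"][city])[activity][0]

        freq_levels = [">=4_per_month", "2_3_per_month", "1_per_month",
                       ">=1_per_year"]
        freq = rng.choice(freq_levels, p=m["frequency_probs"][city])
        row["frecuencia"] = inv(cb["frequency"][city])[freq][0]

        if city in avail["companion"]:
            alone = rng.random() < m["alone_prob"][city]
            row["compania"] = "solo" if alone else "acompanado"
        if city in avail["safety"]:
            row["seguridad"] = int(rng.choice(np.arange(1, 6),
                                              p=m["safety_probs"][city]))
        tables[city].append(row)
    return {city: pd.DataFrame(rows) for city, rows in tables.items() if rows}
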