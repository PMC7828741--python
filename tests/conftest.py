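import numpy as np
import pytest
from shapely.geometry import box

import ciclovia as cv
from ciclovia import exposure as expo
from ciclovia.core import GeographicUnit, ses_score_from_counts


def route_trajectories(city, participants):
    return [expo.shortest_path_trajectory(
                city.network, p.origin_node, p.destination_node,
                p.participant_id, p.ses_of_origin)
            for p in participants]


def exposure_dataset(city, participants, segment_len_m=500.0):
    pmap = expo.ses_percentile_map(city.units)
    assignment = expo.EdgeUnitAssignment(city.network, city.units)
    trajs = route_trajectories(city, participants)
    return expo.ExposureDataset.build(
        trajs, assignment, pmap, [p.origin_unit for p in participants],
        segment_len_m=segment_len_m)


def make_units(compositions, side=500.0, cols=None):
    """Row of square units with the given (low, mid, high) counts."""
    cols = cols or len(compositions)
    units = []
    for i, counts in enumerate(compositions):
        r, c = divmod(i, cols)
        units.append(GeographicUnit(
            unit_id=i,
            polygon=box(c * side, r * side, (c + 1) * side, (r + 1) * side),
            counts=tuple(int(x) for x in counts),
            ses_score=ses_score_from_counts(counts),
        ))
    return units


@pytest.fixture(scope="session")
def planted_city():
    return cv.planted_span_city(40.0)


@pytest.fixture(scope="session")
def gradient_city():
    cfg = cv.CityConfig(grid_rows=6, grid_cols=16, gradient_strength=6.0,
                        mixing_noise=12.0, route_scenario="crossing", seed=5)
    return cv.generate_city(cfg)
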