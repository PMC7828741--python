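"""Evenness dimension of urban segregation.

For a metropolitan area tessellated into geographic units i = 1..n, with
t_i the unit population, T the metro population and pi_ri the within-unit
proportion of SES group r, the entropy score of unit i is

    E_i = sum_r pi_ri * log(1 / pi_ri)        (natural log, 0*log(1/0) = 0)

and the Theil (entropy) segregation index is the population-weighted average
shortfall of unit entropy relative to the metro entropy E,

    H = sum_i t_i * (E - E_i) / (E * T),

which lies in [0, 1]: 0 when every unit mirrors the metro composition
(no segregation) and 1 when no two SES groups share a unit.

Two distinct city-level summaries are produced and labelled separately:
the Theil index H, and the mean +/- SD across units of the *normalized*
local entropy e_i = E_i / log(r) (a 0-1 diversity score).  Both an
unweighted and a population-weighted mean/SD of e_i are emitted because
either convention is defensible for a per-city diversity summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GeographicUnit, SES_LEVELS, ValidationError

#: Quantile classes in ascending order of normalized local entropy.
ENTROPY_CLASSES: tuple[str, ...] = (
    "highly_segregated", "segregated", "integrated", "highly_integrated",
)


class DegenerateMetroError(ValidationError):
    """Metro-wide entropy is zero (a single SES group city): the Theil
    index H is undefined because the E in its denominator vanishes."""


def entropy_score(proportions: Sequence[float]) -> float:
    """Entropy score E_i of a composition vector, in nats.

    ``proportions`` must be non-negative and sum to 1 (within 1e-9).
    The 0*log(1/0) terms are 0 by the limit convention.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative proportion in composition vector")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions sum to {p.sum()!r}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class CompositionTable:
    """Per-unit SES composition: unit_id, t_i and counts per group."""

    frame: pd.DataFrame  # columns: unit_id, one column per SES group

    GROUP_COLS = [f"pop_{g}" for g in ("low", "mid", "high")]

    def __post_init__(self) -> None:
        missing = [c for c in ["unit_id", *self.GROUP_COLS]
                   if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"composition table missing columns {missing}")
        if (self.frame[self.GROUP_COLS] < 0).to_numpy().any():
            raise ValidationError("negative population count")

    @classmethod
    def from_units(cls, units: Iterable[GeographicUnit]) -> "CompositionTable":
        rows = [{"unit_id": u.unit_id,
                 "pop_low": u.counts[0],
                 "pop_mid": u.counts[1],
                 "pop_high": u.counts[2]} for u in units]
        return cls(pd.DataFrame(rows))

    @property
    def counts(self) -> np.ndarray:
        return self.frame[self.GROUP_COLS].to_numpy(dtype=float)

    @property
    def unit_pop(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.unit_pop.sum())


@dataclass
class EntropyResult:
    """Per-unit entropy scores plus the city-level summaries."""

    per_unit: pd.DataFrame  # unit_id, E_i, e_i, entropy_class
    E: float                # metropolitan entropy (nats)
    H: float                # Theil index, dimensionless in [0, 1]
    mean_e: float           # unweighted mean of e_i across units
    sd_e: float             # unweighted SD of e_i across units
    mean_e_weighted: float  # population-weighted mean of e_i
    sd_e_weighted: float    # population-weighted SD of e_i
    cutpoints: tuple[float, float, float]

    def to_files(self, csv_path: str, json_path: str) -> None:
        self.per_unit.to_csv(csv_path, index=False)
        with open(json_path, "w") as fh:
            json.dump({
                "E": self.E, "H": self.H,
                "mean_e": self.mean_e, "sd_e": self.sd_e,
                "mean_e_weighted": self.mean_e_weighted,
                "sd_e_weighted": self.sd_e_weighted,
                "cutpoints": list(self.cutpoints),
            }, fh, indent=2)


def classify_by_quantiles(e_values: Sequence[float]) -> tuple[list[str], tuple[float, float, float]]:
    """Quartile classification of normalized local entropies.

    Cut points are the empirical quartiles (linear interpolation); classes
    are assigned ascending: below Q1 -> highly_segregated, [Q1, Q2) ->
    segregated, [Q2, Q3) -> integrated, >= Q3 -> highly_integrated.
    """
    e = np.asarray(e_values, dtype=float)
    if e.size < 4:
        raise ValidationError("quantile classification needs >= 4 units")
    return _classify(e)


def _classify(e: np.ndarray) -> tuple[list[str], tuple[float, float, float]]:
    q1, q2, q3 = np.quantile(e, [0.25, 0.5, 0.75])
    if np.allclose(e, e[0]):
        warnings.warn("all local entropies identical: single-class output",
                      stacklevel=2)
    idx = np.searchsorted([q1, q2, q3], e, side="right")
    return [ENTROPY_CLASSES[i] for i in idx], (float(q1), float(q2), float(q3))


def theil_index(table: CompositionTable) -> EntropyResult:
    """Theil index H plus per-unit (normalized) entropy scores.

    Raises :class:`DegenerateMetroError` when the metro hosts a single SES
    group (E = 0), for which H is undefined.
    """
    counts = table.counts
    t = table.unit_pop
    T = table.total
    if T <= 0:
        raise ValidationError("metro population must be positive")
    r = counts.shape[1]

    metro_prop = counts.sum(axis=0) / T
    E = entropy_score(metro_prop)
    if E <= 0.0:
        raise DegenerateMetroError(
            "metropolitan entropy is 0 (single SES group present): the Theil "
            "index H = sum t_i (E - E_i) / (E T) is undefined")

    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(t[:, None] > 0, counts / np.where(t[:, None] > 0, t[:, None], 1), 0.0)
        logs = np.where(pi > 0, np.log(pi), 0.0)
    E_i = -(pi * logs).sum(axis=1)
    e_i = E_i / np.log(r)

    H = float((t * (E - E_i)).sum() / (E * T))

    classes, cutpoints = _classify(e_i)
    per_unit = pd.DataFrame({
        "unit_id": table.frame["unit_id"].to_numpy(),
        "E_i": E_i,
        "e_i": e_i,
        "entropy_class": classes,
    })

    w = t / T
    mean_w = float(np.dot(w, e_i))
    sd_w = float(np.sqrt(np.dot(w, (e_i - mean_w) ** 2)))
    return EntropyResult(
        per_unit=per_unit,
        E=float(E),
        H=H,
        mean_e=float(e_i.mean()),
        sd_e=float(e_i.std(ddof=1)) if e_i.size > 1 else 0.0,
        mean_e_weighted=mean_w,
        sd_e_weighted=sd_w,
        cutpoints=cutpoints,
    )
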