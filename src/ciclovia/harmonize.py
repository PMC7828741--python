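"""Survey harmonization and statistical analysis.

Four city programs (Bogota, Mexico City, Santiago de Cali, Santiago de
Chile) collected intercept surveys in city-specific dialects: DANE strata
1-6 in the Colombian cities, the Chilean E/D/C3/C2/ABC1 scheme, a 3-level
Mexican coding; birthdate vs. reported age; different category tokens for
education, marital status, activity and so on.  A codebook maps every legal
raw value to one harmonized value; variables a city never collected are
flagged unavailable and stay missing (never imputed).

Derived classifications:

* SES merged to low/middle/high (DANE 1-2 / 3-4 / 5-6; Chile E,D -> low,
  C3,C2 -> middle, ABC1 -> high; Mexico passthrough).
* Age in completed years at the observation date, grouped 18-29 / 30-49 /
  >=50.
* BMI = weight / height^2 with WHO cuts (<18.5 / 18.5-24.9 / 25.0-29.9 /
  >=30.0).
* Self-rated health 1 -> excellent, 2 -> good, 3-5 -> fair.
* WHO adult PA guideline: met iff moderate + 2 x vigorous >= 150 min/week
  (covers the >=150 moderate, >=75 vigorous, or equivalent-combination
  rule); program PA uses the same 150-min threshold on time spent being
  active at the event, treated as moderate intensity.
* Safety Likert 1-2 -> unsafe, 3 -> neither, 4-5 -> safe.

Downstream analytics: per-city and pooled descriptive frequencies with
complete-case denominators, Pearson chi-square tests, and a two-level
(participant within city) random-intercept logistic regression fit by
maximum likelihood with Gauss-Hermite quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import ValidationError


class CodebookError(ValidationError):
    pass


class FitError(RuntimeError):
    pass


CITIES: tuple[str, ...] = ("bogota", "mexico_city", "santiago_cali",
                           "santiago_chile")

_DANE = {str(k): v for k, v in
         {1: "low", 2: "low", 3: "middle", 4: "middle",
          5: "high", 6: "high"}.items()}

_MARITAL = {"soltero": "single", "viudo": "single", "divorciado": "single",
            "separado": "single", "casado": "partner",
            "union_libre": "partner"}

#: Default harmonization codebook.  Serializable to/from YAML; every legal
#: raw value maps to exactly one harmonized value, and per-variable
#: availability flags mark what each city's questionnaire actually asked.
DEFAULT_CODEBOOK: dict = {
    "observation_date": {
        "bogota": "2018-06-10", "mexico_city": "2017-05-21",
        "santiago_cali": "2019-03-17", "santiago_chile": "2016-11-20",
    },
    "ses": {
        "bogota": dict(_DANE),
        "santiago_cali": dict(_DANE),
        "mexico_city": {"bajo": "low", "medio": "middle", "alto": "high"},
        "santiago_chile": {"E": "low", "D": "low", "C3": "middle",
                           "C2": "middle", "ABC1": "high"},
    },
    "sex": {
        "bogota": {"hombre": "male", "mujer": "female"},
        "santiago_cali": {"hombre": "male", "mujer": "female"},
        "mexico_city": {"H": "male", "M": "female"},
        "santiago_chile": {"masculino": "male", "femenino": "female"},
    },
    "age_field": {
        "bogota": "edad", "mexico_city": "fecha_nacimiento",
        "santiago_cali": "fecha_nacimiento",
        "santiago_chile": "fecha_nacimiento",
    },
    "marital": {
        "bogota": dict(_MARITAL), "mexico_city": dict(_MARITAL),
        "santiago_cali": dict(_MARITAL),
    },
    "education": {
        "bogota": {"primaria": "primary", "bachillerato": "secondary",
                   "universitario": "college", "posgrado": "masters_plus"},
        "santiago_cali": {"primaria": "primary", "bachillerato": "secondary",
                          "universitario": "college",
                          "posgrado": "masters_plus"},
        "mexico_city": {"primaria": "primary", "preparatoria": "secondary",
                        "licenciatura": "college", "posgrado": "masters_plus"},
        "santiago_chile": {"basica": "primary", "media": "secondary",
                           "superior": "college"},
    },
    "car": {
        "bogota": {"si": "yes", "no": "no"},
        "mexico_city": {"si": "yes", "no": "no"},
        "santiago_cali": {"si": "yes", "no": "no"},
    },
    "activity": {
        "bogota": {"bicicleta": "cycling", "patines": "rollerblading",
                   "caminar": "walking", "trotar": "running", "otro": "other"},
        "mexico_city": {"bici": "cycling", "patines": "rollerblading",
                        "caminata": "walking", "correr": "running",
                        "otra": "other"},
        "santiago_cali": {"bicicleta": "cycling", "patines": "rollerblading",
                          "caminar": "walking", "trotar": "running",
                          "otro": "other"},
        "santiago_chile": {"bicicleta": "cycling", "patines": "rollerblading",
                           "caminata": "walking", "trote": "running",
                           "otra": "other"},
    },
    "frequency": {
        city: {"todos_los_domingos": ">=4_per_month",
               "2_3_veces_mes": "2_3_per_month",
               "1_vez_mes": "1_per_month",
               "ocasional": ">=1_per_year"}
        for city in CITIES
    },
    "companion": {
        "bogota": {"solo": "alone", "acompanado": "accompanied"},
        "mexico_city": {"solo": "alone", "acompanado": "accompanied"},
        "santiago_cali": {"solo": "alone", "acompanado": "accompanied"},
    },
    "height_unit": {"bogota": "cm", "santiago_cali": "cm", "mexico_city": "m"},
    # Variables each city's questionnaire actually included.
    "available": {
        "marital": ["bogota", "mexico_city", "santiago_cali"],
        "car": ["bogota", "mexico_city", "santiago_cali"],
        "health": ["bogota", "santiago_cali", "santiago_chile"],
        "bmi": ["bogota", "mexico_city", "santiago_cali"],
        "safety": ["bogota", "santiago_cali", "santiago_chile"],
        "companion": ["bogota", "mexico_city", "santiago_cali"],
        "ltpa": ["bogota", "mexico_city"],
        "transport_pa": ["bogota", "mexico_city"],
    },
}


# ---------------------------------------------------------------------------
# Elementary recodes
# ---------------------------------------------------------------------------

def harmonize_ses(raw_code: str, city: str,
                  codebook: Mapping | None = None) -> str:
    cb = codebook or DEFAULT_CODEBOOK
    try:
        city_map = cb["ses"][city]
    except KeyError:
        raise CodebookError(f"unknown city {city!r}") from None
    key = str(raw_code)
    if key not in city_map:
        raise CodebookError(f"unknown SES code {raw_code!r} for city {city!r}")
    return city_map[key]


def derive_age_group(observation_date: date, *, age: int | None = None,
                     birthdate: date | None = None) -> str:
    """Age group from completed (floor) years at the observation date."""
    if age is None:
        if birthdate is None:
            raise ValidationError("need either age or birthdate")
        if birthdate > observation_date:
            raise ValidationError(f"birthdate {birthdate} is in the future")
        age = observation_date.year - birthdate.year - (
            (observation_date.month, observation_date.day)
            < (birthdate.month, birthdate.day))
    if age < 18:
        raise ValidationError(f"age {age} below the adult study population")
    if age <= 29:
        return "18-29"
    if age <= 49:
        return "30-49"
    return ">=50"


def classify_bmi(weight_kg: float, height_m: float) -> str:
    if weight_kg <= 0 or height_m <= 0:
        raise ValidationError("weight and height must be positive")
    bmi = weight_kg / height_m ** 2
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def classify_health(five_point: int) -> str:
    if five_point not in (1, 2, 3, 4, 5):
        raise ValidationError(f"health rating {five_point!r} outside 1..5")
    return {1: "excellent", 2: "good"}.get(five_point, "fair")


def meets_pa(minutes_moderate_per_week: float,
             minutes_vigorous_per_week: float) -> str:
    """WHO guideline: moderate + 2 x vigorous >= 150 min/week."""
    if minutes_moderate_per_week < 0 or minutes_vigorous_per_week < 0:
        raise ValidationError("PA minutes must be non-negative")
    met = minutes_moderate_per_week + 2.0 * minutes_vigorous_per_week >= 150.0
    return "yes" if met else "no"


def meets_pa_program(program_pa_minutes: float) -> str:
    """PA guideline met during the event itself (minutes treated as
    moderate intensity, 150-min threshold)."""
    if program_pa_minutes < 0:
        raise ValidationError("program minutes must be non-negative")
    return "yes" if program_pa_minutes >= 150.0 else "no"


def classify_safety(likert_1_to_5: int) -> str:
    if likert_1_to_5 not in (1, 2, 3, 4, 5):
        raise ValidationError(f"safety rating {likert_1_to_5!r} outside 1..5")
    if likert_1_to_5 <= 2:
        return "unsafe"
    if likert_1_to_5 == 3:
        return "neither"
    return "safe"


def classify_time_cat(program_pa_minutes: float) -> str:
    if program_pa_minutes < 0:
        raise ValidationError("program minutes must be non-negative")
    if program_pa_minutes < 180:
        return "<3h"
    if program_pa_minutes <= 240:
        return "3-4h"
    return ">=4h"


# ---------------------------------------------------------------------------
# Row-level harmonization of a raw city table
# ---------------------------------------------------------------------------

HARMONIZED_COLUMNS = [
    "participant_id", "city", "sex", "age_group", "marital", "education",
    "ses3", "car", "health3", "bmi_cat", "meets_pa_program", "meets_ltpa",
    "meets_overall", "meets_transport", "activity", "time_cat", "freq_cat",
    "companion", "safety3",
]


def _map_raw(value, mapping: Mapping[str, str], city: str, var: str):
    if pd.isna(value):
        return pd.NA
    key = str(value)
    if key not in mapping:
        raise CodebookError(f"unknown {var} code {value!r} for city {city!r}")
    return mapping[key]


def harmonize_city_table(raw: pd.DataFrame, city: str,
                         codebook: Mapping | None = None) -> pd.DataFrame:
    """Harmonize one raw city survey table into the common schema.

    Unavailable variables come back as missing for every row; illegal raw
    codes raise :class:`CodebookError` naming the city and code.
    """
    cb = codebook or DEFAULT_CODEBOOK
    if city not in CITIES:
        raise CodebookError(f"unknown city {city!r}")
    avail = cb["available"]
    obs_date = date.fromisoformat(cb["observation_date"][city])
    out = pd.DataFrame(index=raw.index, columns=HARMONIZED_COLUMNS, dtype=object)
    out["participant_id"] = raw.get("participant_id", pd.Series(raw.index))
    out["city"] = city

    out["sex"] = raw["sexo"].map(lambda v: _map_raw(v, cb["sex"][city], city, "sex"))
    if cb["age_field"][city] == "edad":
        out["age_group"] = raw["edad"].map(
            lambda a: pd.NA if pd.isna(a)
            else derive_age_group(obs_date, age=int(a)))
    else:
        out["age_group"] = raw["fecha_nacimiento"].map(
            lambda b: pd.NA if pd.isna(b)
            else derive_age_group(obs_date, birthdate=date.fromisoformat(str(b))))
    if city in avail["marital"]:
        out["marital"] = raw["estado_civil"].map(
            lambda v: _map_raw(v, cb["marital"][city], city, "marital"))
    out["education"] = raw["educacion"].map(
        lambda v: _map_raw(v, cb["education"][city], city, "education"))
    out["ses3"] = raw["nse"].map(
        lambda v: pd.NA if pd.isna(v) else harmonize_ses(v, city, cb))
    if city in avail["car"]:
        out["car"] = raw["auto"].map(
            lambda v: _map_raw(v, cb["car"][city], city, "car"))
    if city in avail["health"]:
        out["health3"] = raw["salud"].map(
            lambda v: pd.NA if pd.isna(v) else classify_health(int(v)))
    if city in avail["bmi"]:
        unit = cb["height_unit"][city]
        div = 100.0 if unit == "cm" else 1.0
        out["bmi_cat"] = [
            pd.NA if (pd.isna(w) or pd.isna(h))
            else classify_bmi(float(w), float(h) / div)
            for w, h in zip(raw["peso_kg"], raw["talla"])]
    out["meets_pa_program"] = raw["minutos_programa"].map(
        lambda m: pd.NA if pd.isna(m) else meets_pa_program(float(m)))
    out["time_cat"] = raw["minutos_programa"].map(
        lambda m: pd.NA if pd.isna(m) else classify_time_cat(float(m)))
    if city in avail["ltpa"]:
        out["meets_ltpa"] = [
            pd.NA if (pd.isna(m) or pd.isna(v))
            else meets_pa(float(m), float(v))
            for m, v in zip(raw["min_moderada_ocio"], raw["min_vigorosa_ocio"])]
    if city in avail["transport_pa"]:
        out["meets_transport"] = raw["min_transporte"].map(
            lambda m: pd.NA if pd.isna(m) else meets_pa(float(m), 0.0))
    if city in avail["ltpa"] and city in avail["transport_pa"]:
        out["meets_overall"] = [
            pd.NA if (pd.isna(a) or pd.isna(b))
            else ("yes" if "yes" in (a, b) else "no")
            for a, b in zip(out["meets_ltpa"], out["meets_transport"])]
    out["activity"] = raw["actividad"].map(
        lambda v: _map_raw(v, cb["activity"][city], city, "activity"))
    out["freq_cat"] = raw["frecuencia"].map(
        lambda v: _map_raw(v, cb["frequency"][city], city, "frequency"))
    if city in avail["companion"]:
        out["companion"] = raw["compania"].map(
            lambda v: _map_raw(v, cb["companion"][city], city, "companion"))
    if city in avail["safety"]:
        out["safety3"] = raw["seguridad"].map(
            lambda v: pd.NA if pd.isna(v) else classify_safety(int(v)))
    return out


def harmonize_surveys(raw_tables: Mapping[str, pd.DataFrame],
                      codebook: Mapping | None = None) -> pd.DataFrame:
    frames = [harmonize_city_table(df, city, codebook)
              for city, df in sorted(raw_tables.items())]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Descriptive table and chi-square
# ---------------------------------------------------------------------------

DESCRIPTIVE_VARIABLES = [c for c in HARMONIZED_COLUMNS
                         if c not in ("participant_id", "city")]


def pearson_chi2(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Classic Pearson chi-square on a contingency table of counts.

    Returns (statistic, dof, p).  Warns when any expected count is < 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValidationError("negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValidationError("degenerate table: zero marginal")
    res = stats.chi2_contingency(obs, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("expected count below 5: chi-square approximation "
                      "may be poor", stacklevel=2)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pooled_percentages(counts_by_city: Mapping[str, Mapping[str, int]]) -> dict[str, float]:
    """Pooled column percentages from per-city category counts.

    ``counts_by_city[city][category]`` are counts over non-missing responses;
    the pooled denominator is the sum over cities that collected the
    variable (complete-case pooling).
    """
    totals: dict[str, int] = {}
    for city_counts in counts_by_city.values():
        for cat, n in city_counts.items():
            totals[cat] = totals.get(cat, 0) + int(n)
    denom = sum(totals.values())
    if denom == 0:
        raise ValidationError("no observations")
    return {cat: 100.0 * n / denom for cat, n in totals.items()}


def descriptive_table(harmonized: pd.DataFrame,
                      variables: Sequence[str] = DESCRIPTIVE_VARIABLES) -> pd.DataFrame:
    """Counts and column percentages per variable/category, by city and
    pooled, with a Pearson chi-square p-value (variable x city) per
    variable.  Denominators are per-variable complete cases."""
    records = []
    for var in variables:
        sub = harmonized[["city", var]].dropna()
        if sub.empty:
            continue
        ct = pd.crosstab(sub[var], sub["city"])
        pooled = ct.sum(axis=1)
        p_val = np.nan
        if ct.shape[0] >= 2 and ct.shape[1] >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, p_val = pearson_chi2(ct.to_numpy())
        for cat in ct.index:
            rec = {"variable": var, "category": cat,
                   "n_overall": int(pooled[cat]),
                   "pct_overall": 100.0 * pooled[cat] / pooled.sum(),
                   "chi2_p": p_val}
            for city in ct.columns:
                rec[f"n_{city}"] = int(ct.loc[cat, city])
                rec[f"pct_{city}"] = 100.0 * ct.loc[cat, city] / ct[city].sum()
            records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Two-level (random-intercept) logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """Odds ratios with Wald 95% CIs plus the city-level random-intercept
    variance from a two-level logistic fit."""

    table: pd.DataFrame         # term, coef, se, odds_ratio, ci_low, ci_high, p
    sigma_group: float          # random-intercept SD
    loglik: float
    n_obs: int
    n_groups: int
    dropped: tuple[str, ...] = ()

    @property
    def random_intercept_variance(self) -> float:
        return self.sigma_group ** 2


_SIGMA_FLOOR = 1e-4  # a fitted SD at the floor means "effectively zero"


def _gh_loglik_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                        group_idx: np.ndarray, n_groups: int,
                        z: np.ndarray, w: np.ndarray):
    """Marginal log-likelihood and gradient of the random-intercept
    logistic model via *adaptive* Gauss-Hermite quadrature.

    Nodes are re-centered and re-scaled at each group's posterior mode
    (found by Newton), which keeps the quadrature accurate even when large
    groups make the integrand extremely peaked.  The gradient uses Fisher's
    identity: the score equals the posterior expectation of the
    complete-data score.
    """
    beta, sigma = theta[:-1], max(float(theta[-1]), _SIGMA_FLOOR)
    eta = X @ beta
    # Newton iterations for the posterior modes u_hat_g.
    u_hat = np.zeros(n_groups)
    inv_var = 1.0 / sigma ** 2
    for _ in range(50):
        p = special.expit(eta + u_hat[group_idx])
        score = (np.bincount(group_idx, weights=y - p, minlength=n_groups)
                 - u_hat * inv_var)
        curv = (np.bincount(group_idx, weights=p * (1 - p),
                            minlength=n_groups) + inv_var)
        step = score / curv
        u_hat += step
        if np.max(np.abs(step)) < 1e-11:
            break
    p = special.expit(eta + u_hat[group_idx])
    curv = (np.bincount(group_idx, weights=p * (1 - p), minlength=n_groups)
            + inv_var)
    tau = 1.0 / np.sqrt(curv)

    U = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]  # (G, q)
    M = eta[:, None] + U[group_idx]                                # (n, q)
    ll = np.where(y[:, None] == 1, -np.logaddexp(0.0, -M),
                  -np.logaddexp(0.0, M))
    F = np.zeros((n_groups, len(z)))
    np.add.at(F, group_idx, ll)
    log_phi = (-0.5 * np.log(2 * np.pi) - np.log(sigma)
               - 0.5 * (U / sigma) ** 2)
    A = (F + log_phi + np.log(np.sqrt(2.0) * tau)[:, None]
         + np.log(w)[None, :] + z[None, :] ** 2)
    L = special.logsumexp(A, axis=1)                 # (G,)
    loglik = float(L.sum())
    Q = np.exp(A - L[:, None])                       # posterior node weights
    resid = y[:, None] - special.expit(M)
    w_obs = Q[group_idx]
    grad_beta = X.T @ (w_obs * resid).sum(axis=1)
    grad_sigma = float((Q * (U ** 2 / sigma ** 3 - 1.0 / sigma)).sum())
    return loglik, np.append(grad_beta, grad_sigma)


def fit_random_intercept_logit(X: np.ndarray, y: np.ndarray,
                               groups: np.ndarray,
                               n_quad: int = 21,
                               terms: Sequence[str] | None = None) -> ModelResult:
    """Maximum-likelihood random-intercept logistic regression.

    The group effects u_g ~ N(0, sigma^2) are integrated out with ``n_quad``
    Gauss-Hermite nodes; Wald standard errors come from the observed
    information (finite-difference Hessian of the analytic gradient).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    uniq, group_idx = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise FitError("need at least two groups for a two-level model")
    if y.min() == y.max():
        raise FitError("outcome does not vary")
    z, w = np.polynomial.hermite.hermgauss(n_quad)

    def negf(theta):
        ll, g = _gh_loglik_and_grad(theta, X, y, group_idx, len(uniq), z, w)
        return -ll, -g

    theta0 = np.zeros(X.shape[1] + 1)
    theta0[-1] = 0.5
    bounds = [(None, None)] * X.shape[1] + [(_SIGMA_FLOOR, None)]
    res = optimize.minimize(negf, theta0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12,
                                     "gtol": 1e-8})
    if not res.success and np.linalg.norm(res.jac[:-1]) > 1e-3:
        raise FitError(f"fit did not converge: {res.message}; "
                       f"|grad|={np.linalg.norm(res.jac):.2e}")
    theta = res.x

    # Observed information via central differences of the analytic gradient.
    p = theta.size
    H = np.zeros((p, p))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] = max(tm[j] - h[j], _SIGMA_FLOOR) if j == p - 1 else tm[j] - h[j]
        _, gp = negf(tp)
        _, gm = negf(tm)
        H[:, j] = (gp - gm) / (tp[j] - tm[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        raise FitError("singular information matrix (separation or "
                       "collinearity)") from None
    if not np.all(np.isfinite(se[:-1])) or np.any(se[:-1] > 50):
        raise FitError("unstable standard errors: possible separation")

    beta, se_b = theta[:-1], se[:-1]
    zcrit = stats.norm.ppf(0.975)
    names = list(terms) if terms is not None else [f"x{j}" for j in range(len(beta))]
    table = pd.DataFrame({
        "term": names,
        "coef": beta,
        "se": se_b,
        "odds_ratio": np.exp(beta),
        "ci_low": np.exp(beta - zcrit * se_b),
        "ci_high": np.exp(beta + zcrit * se_b),
        "p": 2 * stats.norm.sf(np.abs(beta) / np.where(se_b > 0, se_b, np.inf)),
    })
    return ModelResult(table=table, sigma_group=float(theta[-1]),
                       loglik=float(-res.fun), n_obs=len(y),
                       n_groups=len(uniq))


#: Covariate dummy coding for the PA model: reference levels are male sex,
#: low SES and primary education.
MODEL_TERMS = [
    ("sex", "female"),
    ("ses3", "middle"), ("ses3", "high"),
    ("education", "secondary"), ("education", "college"),
    ("education", "masters_plus"),
]


def fit_two_level_logistic(harmonized: pd.DataFrame,
                           outcome: str = "meets_pa_program",
                           group: str = "city",
                           n_quad: int = 21) -> ModelResult:
    """Table-4-style model: outcome ~ sex + SES + education with a
    city-level random intercept.  Constant covariate columns are dropped
    with a warning; rows missing any model variable are excluded."""
    cols = [outcome, group, "sex", "ses3", "education"]
    df = harmonized[cols].dropna()
    y = (df[outcome] == "yes").to_numpy(dtype=float)
    design = [np.ones(len(df))]
    names = ["intercept"]
    dropped = []
    for var, level in MODEL_TERMS:
        col = (df[var] == level).to_numpy(dtype=float)
        if col.min() == col.max():
            dropped.append(f"{var}[{level}]")
            continue
        design.append(col)
        names.append(f"{var}[{level}]")
    if dropped:
        warnings.warn(f"constant covariates dropped: {dropped}", stacklevel=2)
    X = np.column_stack(design)
    result = fit_random_intercept_logit(X, y, df[group].to_numpy(),
                                        n_quad=n_quad, terms=names)
    result.dropped = tuple(dropped)
    return result
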