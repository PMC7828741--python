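"""Codebook recodes, derived classifications, descriptive statistics,
chi-square, and the two-level logistic model."""

import warnings
from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ciclovia as cv
from ciclovia import harmonize as harm
from ciclovia.core import ParticipantRecord, ValidationError
from ciclovia.harmonize import (CodebookError, FitError, classify_bmi,
                                classify_health, classify_safety,
                                classify_time_cat, derive_age_group,
                                fit_random_intercept_logit, harmonize_ses,
                                meets_pa, meets_pa_program, pearson_chi2,
                                pooled_percentages)

OBS = date(2018, 6, 10)


class TestSESMerging:
    @pytest.mark.parametrize("raw,city,expected", [
        ("1", "bogota", "low"), ("2", "santiago_cali", "low"),
        ("3", "bogota", "middle"), ("4", "santiago_cali", "middle"),
        ("5", "bogota", "high"), ("6", "santiago_cali", "high"),
        ("E", "santiago_chile", "low"), ("D", "santiago_chile", "low"),
        ("C3", "santiago_chile", "middle"), ("C2", "santiago_chile", "middle"),
        ("ABC1", "santiago_chile", "high"),
        ("bajo", "mexico_city", "low"), ("alto", "mexico_city", "high"),
    ])
    def test_merge_rules(self, raw, city, expected):
        assert harmonize_ses(raw, city) == expected

    def test_unknown_code_names_city_and_code(self):
        with pytest.raises(CodebookError, match="7.*bogota|bogota.*7"):
            harmonize_ses("7", "bogota")

    def test_codebook_totality(self):
        """Every legal raw value maps for every city; illegal ones raise."""
        cb = harm.DEFAULT_CODEBOOK
        for var in ("ses", "sex", "marital", "education", "car", "activity",
                    "frequency", "companion"):
            for city, mapping in cb[var].items():
                for raw in mapping:
                    assert harm._map_raw(raw, mapping, city, var) in \
                        set(mapping.values())
                with pytest.raises(CodebookError):
                    harm._map_raw("___not_a_code___", mapping, city, var)


class TestDerivedClassifications:
    def test_age_boundaries(self):
        assert derive_age_group(OBS, birthdate=date(1988, 6, 10)) == "30-49"
        assert derive_age_group(OBS, age=50) == ">=50"
        assert derive_age_group(OBS, birthdate=date(1988, 6, 11)) == "18-29"
        assert derive_age_group(OBS, age=29) == "18-29"

    def test_age_validation(self):
        with pytest.raises(ValidationError):
            derive_age_group(OBS, age=17)
        with pytest.raises(ValidationError):
            derive_age_group(OBS, birthdate=date(2020, 1, 1))

    def test_bmi_categories(self):
        assert classify_bmi(24.9, 1.0) == "normal"
        assert classify_bmi(25.0, 1.0) == "overweight"
        assert classify_bmi(80.0, 1.60) == "obese"        # BMI 31.25
        assert classify_bmi(18.4, 1.0) == "underweight"
        with pytest.raises(ValidationError):
            classify_bmi(-1.0, 1.7)

    def test_health_grouping(self):
        assert classify_health(1) == "excellent"
        assert classify_health(2) == "good"
        assert classify_health(4) == "fair"
        with pytest.raises(ValidationError):
            classify_health(6)

    @pytest.mark.parametrize("mod,vig,expected", [
        (150, 0, "yes"), (0, 75, "yes"), (100, 25, "yes"), (100, 24, "no"),
    ])
    def test_who_guideline_combination(self, mod, vig, expected):
        assert meets_pa(mod, vig) == expected

    def test_pa_validation(self):
        with pytest.raises(ValidationError):
            meets_pa(-1, 0)

    @pytest.mark.parametrize("minutes,expected",
                             [(180, "yes"), (150, "yes"), (90, "no")])
    def test_program_threshold(self, minutes, expected):
        assert meets_pa_program(minutes) == expected

    def test_safety_split(self):
        assert classify_safety(5) == "safe"
        assert classify_safety(3) == "neither"
        assert classify_safety(1) == "unsafe"
        with pytest.raises(ValidationError):
            classify_safety(0)

    def test_time_categories(self):
        assert classify_time_cat(120) == "<3h"
        assert classify_time_cat(200) == "3-4h"
        assert classify_time_cat(300) == ">=4h"


class TestHarmonizeTables:
    def _roster(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [ParticipantRecord(i, 0, 0, 0, 0,
                                  str(rng.choice(["low", "middle", "high"])),
                                  harm.CITIES[i % 4]) for i in range(n)]

    def test_unavailable_variables_stay_missing(self):
        tables = cv.generate_survey(self._roster(80), seed=1)
        chile = harm.harmonize_city_table(tables["santiago_chile"],
                                          "santiago_chile")
        for col in ("marital", "car", "bmi_cat", "companion"):
            assert chile[col].isna().all()
        mex = harm.harmonize_city_table(tables["mexico_city"], "mexico_city")
        for col in ("health3", "safety3"):
            assert mex[col].isna().all()

    def test_percent_closure(self):
        tables = cv.generate_survey(self._roster(400), seed=2)
        table3 = harm.descriptive_table(harm.harmonize_surveys(tables))
        for (var, city), grp in table3.melt(
                id_vars=["variable", "category"],
                value_vars=[c for c in table3.columns
                            if c.startswith("pct_")],
                var_name="city", value_name="pct").groupby(
                ["variable", "city"]):
            total = grp["pct"].sum()
            if total > 0:  # city collected the variable
                assert total == pytest.approx(100.0, abs=0.01)

    def test_pooled_shares_from_counts(self):
        shares = pooled_percentages({"a": {"x": 30, "y": 10},
                                     "b": {"x": 10, "y": 50}})
        assert shares["x"] == pytest.approx(40.0)
        assert shares["y"] == pytest.approx(60.0)


class TestPearsonChi2:
    def test_exact_independence(self):
        stat, dof, p = pearson_chi2([[25, 25], [25, 25]])
        assert stat == pytest.approx(0.0)
        assert dof == 1
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        obs = np.array([[10, 20], [20, 10]])
        # textbook formula
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        hand = ((obs - exp) ** 2 / exp).sum()
        stat, dof, _ = pearson_chi2(obs)
        assert stat == pytest.approx(hand, abs=1e-9)

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            obs = rng.integers(1, 60, size=(rng.integers(2, 5),
                                            rng.integers(2, 5)))
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            hand = ((obs - exp) ** 2 / exp).sum()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, _, _ = pearson_chi2(obs)
            assert stat == pytest.approx(hand, abs=1e-9)

    def test_null_calibration(self):
        rng = np.random.default_rng(17)
        pr = np.array([0.2, 0.3, 0.5])
        pc = np.array([0.25, 0.25, 0.3, 0.2])
        rej = 0
        n_rep = 2000
        for _ in range(n_rep):
            table = rng.multinomial(400, np.outer(pr, pc).ravel()).reshape(3, 4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, p = pearson_chi2(table)
            rej += p <= 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.015)

    def test_degenerate_marginal_raises(self):
        with pytest.raises(ValidationError):
            pearson_chi2([[0, 0], [5, 5]])


class TestTwoLevelLogistic:
    def _simulate(self, n, beta, sigma, seed, n_groups=4):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.binomial(1, 0.5, n),
                             rng.binomial(1, 0.3, n)])
        groups = rng.integers(0, n_groups, n)
        u = rng.normal(0, sigma, n_groups)
        lp = X @ beta + u[groups]
        y = rng.binomial(1, 1 / (1 + np.exp(-lp)))
        return X, y, groups

    def test_limiting_case_matches_plain_logit(self):
        import statsmodels.api as sm
        X, y, groups = self._simulate(6000, [0.2, 0.7, -0.4], 0.0, seed=3)
        mine = fit_random_intercept_logit(X, y, groups)
        plain = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(np.exp(mine.table["coef"]),
                                   np.exp(plain.params), rtol=0.01)
        assert mine.sigma_group < 0.1

    def test_recovers_planted_effect_within_ci(self):
        X, y, groups = self._simulate(3200, [0.0, 0.7, 0.0], 0.3, seed=8)
        res = fit_random_intercept_logit(X, y, groups)
        row = res.table.iloc[1]
        assert row["ci_low"] < np.exp(0.7) < row["ci_high"]

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        n = 600
        hdf = pd.DataFrame({
            "meets_pa_program": rng.choice(["yes", "no"], n),
            "city": rng.choice(list(harm.CITIES), n),
            "sex": "male",                                  # constant
            "ses3": rng.choice(["low", "middle", "high"], n),
            "education": rng.choice(["primary", "secondary", "college"], n),
        })
        with pytest.warns(UserWarning, match="sex"):
            res = harm.fit_two_level_logistic(hdf)
        assert "sex[female]" in res.dropped
        assert "sex[female]" not in set(res.table["term"])

    def test_requires_varying_outcome_and_groups(self):
        X = np.ones((50, 1))
        with pytest.raises(FitError):
            fit_random_intercept_logit(X, np.ones(50), np.zeros(50))
        with pytest.raises(FitError):
            fit_random_intercept_logit(
                X, np.r_[np.ones(25), np.zeros(25)], np.zeros(50))
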