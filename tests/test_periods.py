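"""Period aggregation, coefficient arithmetic and the mixed-model machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ringphys.periods import (
    DEFAULT_PERIODS,
    CoefficientTable,
    PUBLISHED_COEFFICIENTS,
    PeriodDefinition,
    PeriodMixedModel,
    compact_letter_display,
    fit_increment_vs_discrimination,
    parse_estimate,
    percent_change_report,
    period_means_annual,
    period_means_segments,
    period_of,
    period_slopes,
    read_coefficient_csv,
    validate_periods,
)


class TestPeriodDefinitions:
    def test_default_periods_cover_the_pollution_chronology(self):
        labels = {p.label: (p.start_year, p.end_year) for p in DEFAULT_PERIODS}
        assert labels == {
            "pre": (1900, 1935), "pollution": (1971, 1989),
            "post1": (1998, 2005), "post2": (2006, 2011),
        }

    def test_overlapping_periods_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            validate_periods(
                [PeriodDefinition("a", 1900, 1950), PeriodDefinition("b", 1940, 1960)]
            )

    def test_period_of_gap_years_is_none(self):
        assert period_of(1950) is None
        assert period_of(1980) == "pollution"


class TestPeriodMeans:
    def test_annual_fully_inside_is_plain_mean(self):
        data = pd.DataFrame(
            {"tree_id": "t", "year": np.arange(1971, 1990),
             "value": np.arange(19.0)}
        )
        out = period_means_annual(data)
        row = out[out["period"] == "pollution"]
        assert row["value"].iloc[0] == pytest.approx(np.arange(19.0).mean())
        assert row["n"].iloc[0] == 19

    def test_segment_overlap_weight(self):
        # 1969-1973 overlaps the pollution period by 3 of its 5 years
        p = DEFAULT_PERIODS[1]
        assert p.overlap_years(1969, 1973) == 3

    def test_segment_weighted_mean_worked_example(self):
        data = pd.DataFrame(
            {"tree_id": ["t", "t"], "start_year": [1971, 1973],
             "end_year": [1972, 1977], "value": [18.0, 20.0]}
        )
        out = period_means_segments(data)
        row = out[out["period"] == "pollution"]
        # weights 2 and 5 -> (2*18 + 5*20)/7
        assert row["value"].iloc[0] == pytest.approx(19.43, abs=0.005)

    def test_zero_overlap_cell_absent(self):
        data = pd.DataFrame(
            {"tree_id": ["t"], "start_year": [1950], "end_year": [1954],
             "value": [18.0]}
        )
        assert len(period_means_segments(data)) == 0


class TestCoefficientTable:
    def test_decimal_comma_and_unicode_minus(self):
        assert parse_estimate("-1,876") == pytest.approx(-1.876)
        assert parse_estimate("−0,480") == pytest.approx(-0.48)
        assert parse_estimate("204,310") == pytest.approx(204.31)
        assert parse_estimate("3.702") == pytest.approx(3.702)

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "coef.csv"
        path.write_text('term,estimate\nintercept,"19,635"\nperiod[pollution],"-1,876"\n')
        table = read_coefficient_csv(path, "delta13C")
        assert table.predict("pollution") == pytest.approx(17.759)

    def test_prediction_assembles_all_applicable_terms(self):
        table = PUBLISHED_COEFFICIENTS["biomass_increment"]
        assert table.predict("pollution", "Plesne") == pytest.approx(
            9.945 + 1.141 + 3.702 - 1.966
        )
        assert table.predict("pre", "Certovo") == pytest.approx(9.945)

    def test_absent_term_raises_with_name(self):
        table = PUBLISHED_COEFFICIENTS["biomass_increment"]
        with pytest.raises(KeyError, match=r"period\[post2\]"):
            table.predict("post2")
        with pytest.raises(KeyError, match="catchment"):
            PUBLISHED_COEFFICIENTS["delta13C"].predict("pre", "Plesne")

    def test_identical_baseline_and_target_is_zero(self):
        table = PUBLISHED_COEFFICIENTS["iwue"]
        assert percent_change_report(table, "pollution", "pollution") == 0.0

    def test_predictions_invariant_to_reference_level(self):
        """Re-expressing the table around another reference period leaves
        every prediction unchanged (re-parameterization check)."""
        table = PUBLISHED_COEFFICIENTS["delta13C"]
        new_int = table.predict("pollution")
        rebased = CoefficientTable(
            response="delta13C",
            terms={
                "intercept": new_int,
                "period[pre]": table.predict("pre") - new_int,
                "period[post1]": table.predict("post1") - new_int,
                "period[post2]": table.predict("post2") - new_int,
            },
            reference_period="pollution",
        )
        for period in ("pre", "pollution", "post1", "post2"):
            assert rebased.predict(period) == pytest.approx(table.predict(period))


def _balanced_data(rng, n_trees=30, effects=None, tree_sd=1.0, resid_sd=1.0,
                   periods=("pre", "pollution", "post1", "post2")):
    effects = effects or {}
    rows = []
    for i in range(n_trees):
        b = rng.normal(0, tree_sd)
        for p in periods:
            rows.append(
                {"tree_id": f"t{i}", "period": p,
                 "value": 10.0 + effects.get(p, 0.0) + b + rng.normal(0, resid_sd)}
            )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_balanced_no_random_variance_reduces_to_group_means(self):
        rng = np.random.default_rng(20)
        data = _balanced_data(rng, 20, {"pollution": 2.0}, tree_sd=0.0,
                              periods=("pre", "pollution"))
        res = PeriodMixedModel(data).fit(structure="period")
        groups = data.groupby("period")["value"].mean()
        assert res.fe_params["intercept"] == pytest.approx(groups["pre"], abs=1e-6)
        assert res.fe_params["period[pollution]"] == pytest.approx(
            groups["pollution"] - groups["pre"], abs=1e-6
        )

    def test_pseudo_r2_with_known_variance_components(self):
        # fixed-predictor variance 1 (effect 2, two balanced periods),
        # random variance 2, residual 1 -> (0.25, 0.75)
        rng = np.random.default_rng(21)
        data = _balanced_data(rng, 400, {"pollution": 2.0},
                              tree_sd=np.sqrt(2), resid_sd=1.0,
                              periods=("pre", "pollution"))
        res = PeriodMixedModel(data).fit(structure="period")
        r2m, r2c = res.pseudo_r2()
        assert r2m == pytest.approx(0.25, abs=0.03)
        assert r2c == pytest.approx(0.75, abs=0.03)

    def test_pseudo_r2_degenerate_limits(self):
        table_resid = 1e-8
        rng = np.random.default_rng(22)
        # essentially pure fixed effects
        data = _balanced_data(rng, 10, {"pollution": 3.0}, tree_sd=0.0,
                              resid_sd=table_resid, periods=("pre", "pollution"))
        res = PeriodMixedModel(data).fit(structure="period")
        r2m, r2c = res.pseudo_r2()
        assert r2m == pytest.approx(1.0, abs=1e-3)
        assert r2c == pytest.approx(1.0, abs=1e-3)

    def test_zero_effects_prefer_intercept_only_by_aic(self):
        rng = np.random.default_rng(23)
        wins = 0
        reps = 30
        for _ in range(reps):
            data = _balanced_data(rng, 15, {}, tree_sd=1.0, resid_sd=1.0)
            res = PeriodMixedModel(data).fit()
            wins += res.structure == "intercept"
        assert wins > reps / 2

    def test_aic_ordering_invariant_to_rescaling(self):
        rng = np.random.default_rng(24)
        data = _balanced_data(rng, 15, {"pollution": 1.0})
        res1 = PeriodMixedModel(data).fit()
        data10 = data.assign(value=data["value"] * 10)
        res2 = PeriodMixedModel(data10).fit()
        shifts = [res2.aic_table[k] - res1.aic_table[k] for k in res1.aic_table]
        assert max(shifts) - min(shifts) < 0.2  # common additive constant


class TestTukey:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(25)
        data = _balanced_data(rng, 20, {}, periods=("pre", "pollution"))
        res = PeriodMixedModel(data).fit(structure="period")
        tab = res.tukey(n_mc=50_000)
        assert tab["p_adj"].iloc[0] > 0.1
        letters = tab.attrs["letters"]
        assert letters["pre"] == letters["pollution"]

    def test_large_separation_gets_distinct_letters(self):
        rng = np.random.default_rng(26)
        data = _balanced_data(rng, 20, {"pollution": 10.0}, resid_sd=1.0,
                              periods=("pre", "pollution"))
        res = PeriodMixedModel(data).fit(structure="period")
        tab = res.tukey(n_mc=50_000)
        letters = tab.attrs["letters"]
        assert tab["p_adj"].iloc[0] < 0.001
        assert set(letters["pre"]) & set(letters["pollution"]) == set()

    def test_letters_consistent_with_pvalue_matrix(self):
        rng = np.random.default_rng(27)
        data = _balanced_data(
            rng, 25, {"pollution": -1.5, "post1": -0.5, "post2": -0.4},
            tree_sd=0.6, resid_sd=0.6,
        )
        res = PeriodMixedModel(data).fit(structure="period")
        tab = res.tukey(n_mc=100_000)
        letters = tab.attrs["letters"]
        for _, row in tab.iterrows():
            shared = set(letters[row["period_a"]]) & set(letters[row["period_b"]])
            if row["p_adj"] < 0.05:
                assert not shared, f"significant pair shares letter: {row}"
            else:
                assert shared, f"non-significant pair separated: {row}"

    def test_letter_assignment_brute_force_oracle(self):
        labels = ["a", "b", "c", "d"]
        pairs = list(itertools.combinations(labels, 2))
        rng = np.random.default_rng(28)
        means = pd.Series(rng.normal(size=4), index=labels)
        for mask in range(2 ** len(pairs)):
            sig = [(mask >> k) & 1 == 1 for k in range(len(pairs))]
            letters = compact_letter_display(labels, pairs, sig, means)
            for (x, y), s in zip(pairs, sig):
                shared = set(letters[x]) & set(letters[y])
                if s:
                    assert not shared, f"pattern {sig}: significant pair {x},{y} shares {shared}"
                else:
                    assert shared, f"pattern {sig}: pair {x},{y} wrongly separated ({letters})"


class TestIncrementVsDiscrimination:
    def _simulate(self, rng, slope=-5.3, pollution_interaction=5.5, noise=3.0):
        rows = []
        for i in range(30):
            b = rng.normal(0, 4.0)
            for p in ("pre", "pollution", "post1"):
                delta = rng.normal(18.5, 1.0)
                s = slope + (pollution_interaction if p == "pollution" else 0.0)
                rows.append(
                    {"tree_id": f"t{i}", "period": p, "delta13C": delta,
                     "increment": 120.0 + s * delta + b + rng.normal(0, noise)}
                )
        return pd.DataFrame(rows)

    def test_recovers_sign_structure(self):
        rng = np.random.default_rng(30)
        res = fit_increment_vs_discrimination(self._simulate(rng))
        slopes = period_slopes(res)
        assert slopes["pre"] < -3.0
        assert abs(slopes["pollution"]) < 1.5
        assert slopes["post1"] < -3.0

    def test_null_interaction_type_one_error(self):
        rng = np.random.default_rng(31)
        reps, hits = 60, 0
        for _ in range(reps):
            data = self._simulate(rng, slope=0.0, pollution_interaction=0.0)
            res = fit_increment_vs_discrimination(data)
            term = "period[pollution]:delta13C"
            z = res.fe_params[term] / res.bse_fe[term]
            hits += abs(z) > 1.96
        assert hits / reps <= 0.12

    def test_single_period_reduces_to_simple_regression(self):
        rng = np.random.default_rng(32)
        data = self._simulate(rng)
        data = data[data["period"] == "pre"]
        res = fit_increment_vs_discrimination(data)
        assert list(res.fe_params.index) == ["intercept", "delta13C"]
        assert res.fe_params["delta13C"] < -3.0
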