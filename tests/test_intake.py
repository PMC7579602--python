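"""Nutrient-intake aggregation: unit conversions, profiles, panel assembly."""

import numpy as np
import pandas as pd
import pytest

from stoichdiet.intake import (
    CONTROL_COLUMNS,
    MEASURES,
    assemble_covariates,
    compute_intake_profile,
    covariate_columns,
    mean_concentration,
    merge_concentrations,
    period_aggregate,
)


def _conc_table(rows, db="db"):
    df = pd.DataFrame(rows, columns=["food_group", "n_gram_per_kg", "p_gram_per_kg",
                                     "protein_gram_per_kg", "kcal_per_kg"])
    df["database_id"] = db
    return df


class TestMeanConcentration:
    def test_two_databases_average(self):
        t1 = _conc_table([["meat", 20.0, 2.0, 120.0, 1500.0]], "a")
        t2 = _conc_table([["meat", 24.0, 4.0, 160.0, 2500.0]], "b")
        out = mean_concentration("meat", [t1, t2])
        assert out["n_gram_per_kg"] == 22.0
        assert out["p_gram_per_kg"] == 3.0

    def test_single_database_passthrough(self):
        t = _conc_table([["grain", 30.0, 1.0, 80.0, 900.0]])
        assert mean_concentration("grain", [t])["n_gram_per_kg"] == 30.0

    def test_absent_group_raises(self):
        t = _conc_table([["grain", 30.0, 1.0, 80.0, 900.0]])
        with pytest.raises(KeyError, match="meat"):
            mean_concentration("meat", [t])

    def test_matches_brute_force_over_random_tables(self):
        rng = np.random.default_rng(42)
        groups = ["g1", "g2", "g3"]
        tables = []
        for db in range(5):
            present = [g for g in groups if rng.random() < 0.8] or ["g1"]
            tables.append(
                _conc_table([[g, *rng.uniform(0.1, 50, 4)] for g in present], f"db{db}")
            )
        for g in groups:
            rows = [t[t.food_group == g] for t in tables if (t.food_group == g).any()]
            if not rows:
                continue
            # independent re-summation oracle
            for col in ("n_gram_per_kg", "p_gram_per_kg", "protein_gram_per_kg", "kcal_per_kg"):
                vals = [float(r[col].iloc[0]) for r in rows]
                expected = sum(vals) / len(vals)
                assert mean_concentration(g, tables)[col] == pytest.approx(expected, abs=1e-12)


class TestIntakeProfile:
    def test_single_group_exact(self):
        intake = pd.DataFrame(
            {
                "country": ["A"],
                "year": [2000],
                "food_group": ["meat"],
                "source_category": ["terrestrial-animal"],
                "intake_kg_per_capita_yr": [50.0],
            }
        )
        conc = merge_concentrations([_conc_table([["meat", 30.0, 3.0, 180.0, 2000.0]])])
        prof = compute_intake_profile(intake, conc)
        row = prof.loc[("A", 2000, "terrestrial-animal")]
        assert row["N_kg"] == pytest.approx(1.5)
        assert row["P_kg"] == pytest.approx(0.15)
        assert row["NP_ratio"] == pytest.approx(10.0)
        assert row["kcal"] == pytest.approx(100_000.0)
        assert row["total_kg"] == 50.0

    def test_zero_intake_gives_zero_profile_and_undefined_np(self):
        intake = pd.DataFrame(
            {
                "country": ["A"],
                "year": [2000],
                "food_group": ["meat"],
                "source_category": ["terrestrial-animal"],
                "intake_kg_per_capita_yr": [0.0],
            }
        )
        conc = merge_concentrations([_conc_table([["meat", 30.0, 3.0, 180.0, 2000.0]])])
        row = compute_intake_profile(intake, conc).iloc[0]
        assert row[["N_kg", "P_kg", "protein_kg", "kcal", "total_kg"]].eq(0).all()
        assert np.isnan(row["NP_ratio"])

    def test_matches_loop_oracle_on_random_table(self):
        rng = np.random.default_rng(7)
        rows, conc_rows = [], []
        for s, src in enumerate(["terrestrial-animal", "vegetable"]):
            for g in range(3):
                name = f"s{s}g{g}"
                conc_rows.append([name, *rng.uniform(0.1, 40, 4)])
                for country in ("A", "B"):
                    rows.append([country, 2001, name, src, rng.uniform(0, 200)])
        intake = pd.DataFrame(
            rows, columns=["country", "year", "food_group", "source_category",
                           "intake_kg_per_capita_yr"],
        )
        conc = merge_concentrations([_conc_table(conc_rows)])
        prof = compute_intake_profile(intake, conc)

        # brute-force per-row accumulation, independent of the implementation
        acc = {}
        for _, r in intake.iterrows():
            key = (r.country, r.year, r.source_category)
            c = conc.loc[r.food_group]
            d = acc.setdefault(key, dict.fromkeys(["N", "P", "prot", "kcal", "tot"], 0.0))
            d["N"] += r.intake_kg_per_capita_yr * c.n_gram_per_kg / 1000
            d["P"] += r.intake_kg_per_capita_yr * c.p_gram_per_kg / 1000
            d["prot"] += r.intake_kg_per_capita_yr * c.protein_gram_per_kg / 1000
            d["kcal"] += r.intake_kg_per_capita_yr * c.kcal_per_kg
            d["tot"] += r.intake_kg_per_capita_yr
        for key, d in acc.items():
            row = prof.loc[key]
            assert row["N_kg"] == pytest.approx(d["N"], abs=1e-12)
            assert row["P_kg"] == pytest.approx(d["P"], abs=1e-12)
            assert row["protein_kg"] == pytest.approx(d["prot"], abs=1e-12)
            assert row["kcal"] == pytest.approx(d["kcal"], abs=1e-9)
            assert row["total_kg"] == pytest.approx(d["tot"], abs=1e-12)
            assert row["NP_ratio"] == pytest.approx(d["N"] / d["P"], rel=1e-9)

    def test_missing_concentration_lists_groups(self):
        intake = pd.DataFrame(
            {
                "country": ["A"],
                "year": [2000],
                "food_group": ["mystery"],
                "source_category": ["vegetable"],
                "intake_kg_per_capita_yr": [1.0],
            }
        )
        conc = merge_concentrations([_conc_table([["meat", 30.0, 3.0, 180.0, 2000.0]])])
        with pytest.raises(KeyError, match="mystery"):
            compute_intake_profile(intake, conc)

    def test_negative_intake_rejected(self, small_intake_tables):
        intake, conc = small_intake_tables
        bad = intake.copy()
        bad.loc[0, "intake_kg_per_capita_yr"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            compute_intake_profile(bad, merge_concentrations([conc]))

    def test_duplicate_keys_rejected(self, small_intake_tables):
        intake, conc = small_intake_tables
        dup = pd.concat([intake, intake.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            compute_intake_profile(dup, merge_concentrations([conc]))

    def test_additivity_over_disjoint_tables(self, small_intake_tables):
        """Profile of a union of disjoint intake tables = sum of profiles."""
        intake, conc = small_intake_tables
        extra = intake.copy()
        extra["food_group"] = extra["food_group"] + "_x"
        conc2 = conc.copy()
        conc2["food_group"] = conc2["food_group"] + "_x"
        cmerged = merge_concentrations([pd.concat([conc, conc2], ignore_index=True)])
        p_union = compute_intake_profile(pd.concat([intake, extra], ignore_index=True), cmerged)
        p_a = compute_intake_profile(intake, cmerged)
        p_b = compute_intake_profile(extra, cmerged)
        summed = p_a.add(p_b, fill_value=0.0)
        cols = ["N_kg", "P_kg", "protein_kg", "kcal", "total_kg"]
        pd.testing.assert_frame_equal(p_union[cols], summed[cols], check_like=True)

    def test_scale_equivariance(self, small_intake_tables):
        """Doubling intakes doubles mass/energy components, leaves N:P fixed."""
        intake, conc = small_intake_tables
        cmerged = merge_concentrations([conc])
        p1 = compute_intake_profile(intake, cmerged)
        doubled = intake.assign(intake_kg_per_capita_yr=2 * intake.intake_kg_per_capita_yr)
        p2 = compute_intake_profile(doubled, cmerged)
        for col in ("N_kg", "P_kg", "protein_kg", "kcal", "total_kg"):
            assert np.allclose(p2[col], 2 * p1[col])
        assert np.allclose(p2["NP_ratio"], p1["NP_ratio"], equal_nan=True)

    def test_np_consistency_invariant(self, default_config):
        """N = NP_ratio * P on every emitted row of a full synthetic table."""
        from stoichdiet import synthetic

        food = synthetic.generate_food_panel(default_config)
        conc = merge_concentrations(food.concentrations)
        prof = compute_intake_profile(food.intake, conc)
        defined = prof.dropna(subset=["NP_ratio"])
        assert np.allclose(defined["NP_ratio"] * defined["P_kg"], defined["N_kg"], rtol=1e-9)


class TestPeriodAggregate:
    @staticmethod
    def _series(values_by_country_year):
        idx = pd.MultiIndex.from_tuples(list(values_by_country_year), names=["country", "year"])
        return pd.DataFrame({"v": list(values_by_country_year.values())}, index=idx)

    def test_constant_series(self):
        vals = {("A", y): 7.0 for y in range(1960, 2011)}
        df = self._series(vals)
        assert period_aggregate(df, (1960, 2010), "mean")["v"].iloc[0] == 7.0
        assert period_aggregate(df, (1960, 2010), "change")["v"].iloc[0] == 0.0

    def test_decade_change(self):
        vals = {("A", y): 10.0 for y in range(1960, 1970)}
        vals.update({("A", y): 17.0 for y in range(1970, 2001)})
        vals.update({("A", y): 25.0 for y in range(2001, 2011)})
        df = self._series(vals)
        assert period_aggregate(df, (1960, 2010), "change")["v"].iloc[0] == pytest.approx(15.0)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(3)
        vals = {(c, y): rng.normal() for c in "ABC" for y in range(1960, 2011)}
        df = self._series(vals)
        out = period_aggregate(df, (1965, 2005), "mean")
        for c in "ABC":
            expected = np.mean([v for (cc, y), v in vals.items() if cc == c and 1965 <= y <= 2005])
            assert out.loc[c, "v"] == pytest.approx(expected, abs=1e-12)

    def test_country_without_decade_data_dropped(self, caplog):
        vals = {("A", y): 1.0 for y in range(1960, 2011)}
        vals.update({("B", y): 1.0 for y in range(1980, 2011)})  # no 1960s data
        df = self._series(vals)
        out = period_aggregate(df, (1960, 2010), "change")
        assert list(out.index) == ["A"]

    def test_empty_period_rejected(self):
        df = self._series({("A", 2000): 1.0})
        with pytest.raises(ValueError):
            period_aggregate(df, (2010, 2000), "mean")


class TestAssemble:
    def test_exactly_33_canonical_columns(self, default_panel):
        assert len(default_panel.columns) == 33
        assert default_panel.columns == covariate_columns()
        assert not default_panel.data.isna().any().any()

    def test_ratio_column_single_country(self):
        prof_idx = pd.MultiIndex.from_tuples(
            [("A", 2000, s) for s in
             ("terrestrial-animal", "vegetable", "aquatic-animal", "alcoholic")],
            names=["country", "year", "source_category"],
        )
        prof = pd.DataFrame(
            {
                "N_kg": [2.0, 1.0, 0.5, 0.1],
                "P_kg": [0.2, 0.25, 0.05, 0.02],
                "NP_ratio": [10.0, 4.0, 10.0, 5.0],
                "protein_kg": [12.0, 6.0, 3.0, 0.5],
                "kcal": [9e5, 8e5, 1e5, 1e5],
                "total_kg": [60.0, 150.0, 12.0, 20.0],
            },
            index=prof_idx,
        )
        socio = pd.DataFrame(
            {"country": ["A"], "year": [2000], "gdp_pc": [2e4], "hdi": [0.8],
             "median_age": [35.0], "life_expectancy": [78.0]}
        )
        panel = assemble_covariates(prof, socio, (2000, 2000), "mean")
        assert panel.data.loc["A", "N_ta_veg"] == pytest.approx(2.0)
        assert panel.data.loc["A", "NP_ta_veg"] == pytest.approx(10.0 / 4.0)
        assert panel.data.loc["A", "gdp_pc"] == 2e4

    def test_change_mode_constant_inputs_zero(self, default_config):
        """Time-constant profiles give zero change for nutritional columns."""
        from stoichdiet import synthetic

        food = synthetic.generate_food_panel(default_config)
        conc = merge_concentrations(food.concentrations)
        prof = compute_intake_profile(food.intake, conc)
        # freeze every country-source profile at its 1960 value for all years
        first = prof.xs(1960, level="year")
        years = sorted(food.intake.year.unique())
        frames = []
        for y in years:
            f = first.copy()
            f["year"] = y
            frames.append(f.set_index("year", append=True))
        frozen = pd.concat(frames).reorder_levels(["country", "year", "source_category"])
        panel = assemble_covariates(frozen, food.socio, (1960, 2010), "change")
        nutritional = [c for c in panel.columns if c not in CONTROL_COLUMNS]
        assert np.allclose(panel.data[nutritional], 0.0, atol=1e-12)

    def test_zero_vegetable_denominator_drops_country(self, caplog):
        prof_idx = pd.MultiIndex.from_tuples(
            [(c, 2000, s) for c in ("A", "B") for s in
             ("terrestrial-animal", "vegetable", "aquatic-animal", "alcoholic")],
            names=["country", "year", "source_category"],
        )
        base = dict(N_kg=1.0, P_kg=0.1, NP_ratio=10.0, protein_kg=5.0, kcal=1e5, total_kg=50.0)
        prof = pd.DataFrame([base] * 8, index=prof_idx)
        prof.loc[("B", 2000, "vegetable"), :] = 0.0  # zero veg intake for B
        socio = pd.DataFrame(
            {"country": ["A", "B"], "year": [2000, 2000], "gdp_pc": [2e4, 1e4],
             "hdi": [0.8, 0.6], "median_age": [35.0, 25.0], "life_expectancy": [78.0, 65.0]}
        )
        panel = assemble_covariates(prof, socio, (2000, 2000), "mean")
        assert panel.countries == ["A"]
        assert "B" in panel.dropped_countries

    def test_no_shared_countries_raises(self, small_intake_tables):
        intake, conc = small_intake_tables
        prof = compute_intake_profile(intake, merge_concentrations([conc]))
        socio = pd.DataFrame(
            {"country": ["Z"], "year": [2000], "gdp_pc": [1.0], "hdi": [0.5],
             "median_age": [30.0], "life_expectancy": [70.0]}
        )
        with pytest.raises(ValueError, match="shared"):
            assemble_covariates(prof, socio, (2000, 2000), "mean")
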