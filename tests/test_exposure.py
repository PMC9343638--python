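"""Groundwater-consuming population and the three exposure estimators."""

import numpy as np
import pandas as pd
import pytest

import fluoromap as fm
from fluoromap.grids import GridSpec, Raster


def make_raster(arr, cell=1.0):
    arr = np.asarray(arr, dtype=float)
    grid = GridSpec(nrows=arr.shape[0], ncols=arr.shape[1],
                    y0=arr.shape[0] * cell, cell_size=cell)
    return Raster(arr, grid)


def usage_frame(entries):
    return pd.DataFrame(
        [{"country_id": cid, "rural_fraction": r, "urban_fraction": u}
         for cid, r, u in entries]
    )


@pytest.fixture()
def two_country():
    rural = make_raster([[100.0, 200.0], [50.0, 0.0]])
    urban = make_raster([[0.0, 1000.0], [0.0, 300.0]])
    country = make_raster([[0, 1], [0, 1]])
    return rural, urban, country


class TestGroundwaterPopulation:
    def test_full_usage_equals_total_population(self, two_country):
        rural, urban, country = two_country
        usage = usage_frame([(0, 1.0, 1.0), (1, 1.0, 1.0)])
        out = fm.groundwater_population(rural, urban, usage, country)
        np.testing.assert_allclose(out.data, rural.data + urban.data)

    def test_zero_usage_gives_zero_everywhere(self, two_country):
        rural, urban, country = two_country
        usage = usage_frame([(0, 0.0, 0.0), (1, 0.0, 0.0)])
        out = fm.groundwater_population(rural, urban, usage, country)
        assert out.data.sum() == 0.0

    def test_rural_only_half_usage(self):
        rural = make_raster([[200.0]])
        urban = make_raster([[0.0]])
        country = make_raster([[0]])
        out = fm.groundwater_population(rural, urban, usage_frame([(0, 0.5, 0.0)]), country)
        assert out.data[0, 0] == 100.0

    def test_missing_country_listed_in_error(self, two_country):
        rural, urban, country = two_country
        with pytest.raises(ValueError, match=r"\[1\]"):
            fm.groundwater_population(rural, urban, usage_frame([(0, 0.5, 0.5)]), country)

    def test_cellwise_oracle_two_countries(self, two_country):
        rural, urban, country = two_country
        usage = usage_frame([(0, 0.4, 0.2), (1, 0.9, 0.1)])
        out = fm.groundwater_population(rural, urban, usage, country)
        frac = {0: (0.4, 0.2), 1: (0.9, 0.1)}
        for r in range(2):
            for c in range(2):
                rf, uf = frac[int(country.data[r, c])]
                assert out.data[r, c] == pytest.approx(
                    rural.data[r, c] * rf + urban.data[r, c] * uf
                )

    def test_usage_outside_unit_interval_rejected(self, two_country):
        rural, urban, country = two_country
        with pytest.raises(ValueError, match="usage fractions"):
            fm.groundwater_population(
                rural, urban, usage_frame([(0, 1.2, 0.0), (1, 0.5, 0.5)]), country
            )


class TestEstimators:
    def test_worked_cell_high(self):
        pop = make_raster([[100.0]])
        hazard = make_raster([[0.47]])
        assert fm.exposed_high(pop, hazard).total == pytest.approx(47.0)

    def test_high_limits(self):
        pop = make_raster([[100.0, 50.0]])
        assert fm.exposed_high(pop, make_raster([[0.0, 0.0]])).total == 0.0
        assert fm.exposed_high(pop, make_raster([[1.0, 1.0]])).total == 150.0

    def test_low_cutoff_behaviour(self):
        pop = make_raster([[100.0]])
        assert fm.exposed_low(pop, make_raster([[0.47]])).total == 0.0
        assert fm.exposed_low(pop, make_raster([[0.6]])).total == 100.0
        # strict comparison at the boundary
        assert fm.exposed_low(pop, make_raster([[0.5]])).total == 0.0

    def test_low_matches_masked_sum_oracle(self, rng):
        probs = rng.uniform(size=(10, 10))
        pop = rng.uniform(0, 500, size=(10, 10))
        got = fm.exposed_low(make_raster(pop), make_raster(probs), 0.5).total
        assert got == pytest.approx(pop[probs > 0.5].sum())

    def test_hybrid_weighting_and_exclusion(self):
        pop = make_raster([[100.0]])
        assert fm.exposed_hybrid(pop, make_raster([[0.47]])).total == pytest.approx(47.0)
        assert fm.exposed_hybrid(pop, make_raster([[0.2]])).total == 0.0

    def test_hybrid_never_exceeds_high(self, rng):
        for _ in range(200):
            probs = make_raster(rng.uniform(size=(6, 6)))
            pop = make_raster(rng.uniform(0, 100, size=(6, 6)))
            assert fm.exposed_hybrid(pop, probs).total <= fm.exposed_high(pop, probs).total

    def test_estimators_monotone_in_probability_and_population(self, rng):
        probs = rng.uniform(size=(5, 5))
        pop = rng.uniform(0, 100, size=(5, 5))
        bumped_p = np.clip(probs + 0.1, 0, 1)
        for fn in (fm.exposed_high, fm.exposed_low, fm.exposed_hybrid):
            base = fn(make_raster(pop), make_raster(probs)).total
            assert fn(make_raster(pop), make_raster(bumped_p)).total >= base
            assert fn(make_raster(pop * 2), make_raster(probs)).total >= base

    def test_doubling_population_doubles_every_estimate(self, rng):
        probs = make_raster(rng.uniform(size=(5, 5)))
        pop = rng.uniform(0, 100, size=(5, 5))
        for fn in (fm.exposed_high, fm.exposed_low, fm.exposed_hybrid):
            a = fn(make_raster(pop), probs).total
            b = fn(make_raster(2 * pop), probs).total
            assert b == pytest.approx(2 * a)

    def test_truth_surface_calibration_exact(self, small_truth, small_scenario):
        # with the hazard equal to the true surface, the high estimate is
        # exactly the expected number of exposed consumers
        rural, urban, country, usage = fm.gen_population_and_usage(small_scenario)
        consuming = fm.groundwater_population(rural, urban, usage, country)
        est = fm.exposed_high(consuming, small_truth)
        assert est.total == pytest.approx(
            float((consuming.data * small_truth.data).sum()), rel=1e-12
        )

    def test_nodata_cells_reported_uncovered(self):
        probs = np.array([[0.8, -9999.0]])
        pop = make_raster([[10.0, 20.0]])
        est = fm.exposed_high(pop, make_raster(probs))
        assert est.total == pytest.approx(8.0)
        assert est.uncovered_population == 20.0

    def test_misaligned_rasters_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            fm.exposed_high(make_raster(np.ones((2, 2))), make_raster(np.ones((3, 3))))


class TestAggregation:
    def test_single_country_table_equals_totals(self):
        pop = make_raster([[10.0, 40.0]])
        hazard = make_raster([[0.6, 0.3]])
        country = make_raster([[0, 0]])
        table, continents = fm.aggregate_exposure(pop, hazard, country, {0: "A"})
        assert len(table) == 1
        assert table.loc[0, "exposed_high"] == pytest.approx(10 * 0.6 + 40 * 0.3)
        assert table.loc[0, "exposed_low"] == pytest.approx(10.0)
        assert table.loc[0, "exposed_hybrid"] == pytest.approx(10 * 0.6 + 40 * 0.3)
        assert continents.loc[0, "continent"] == "A"

    def test_permuting_country_ids_permutes_table_same_totals(self, rng):
        probs = rng.uniform(size=(4, 4))
        pop = rng.uniform(0, 100, size=(4, 4))
        ids = rng.integers(0, 3, size=(4, 4))
        cont = {0: "A", 1: "A", 2: "B"}
        t1, _ = fm.aggregate_exposure(make_raster(pop), make_raster(probs), make_raster(ids), cont)
        perm = {0: 2, 1: 0, 2: 1}
        ids2 = np.vectorize(perm.get)(ids)
        cont2 = {perm[k]: v for k, v in cont.items()}
        t2, _ = fm.aggregate_exposure(make_raster(pop), make_raster(probs), make_raster(ids2), cont2)
        assert t1["exposed_hybrid"].sum() == pytest.approx(t2["exposed_hybrid"].sum())
        m1 = t1.set_index("country_id")["exposed_hybrid"]
        m2 = t2.set_index("country_id")["exposed_hybrid"]
        for old, new in perm.items():
            assert m1[old] == pytest.approx(m2[new])

    def test_four_country_ranks_match_zonal_oracle(self, small_scenario, small_truth):
        rural, urban, country, usage = fm.gen_population_and_usage(small_scenario)
        consuming = fm.groundwater_population(rural, urban, usage, country)
        continents = dict(zip(usage["country_id"], usage["continent"]))
        table, _ = fm.aggregate_exposure(consuming, small_truth, country, continents)
        p = small_truth.data
        for _, row in table.iterrows():
            sel = (country.data == row["country_id"]) & (p > 0.25)
            oracle = (consuming.data * p)[sel].sum()
            assert row["exposed_hybrid"] == pytest.approx(oracle)
        assert list(table["exposed_hybrid"]) == sorted(table["exposed_hybrid"], reverse=True)
        assert table["rank"].tolist() == list(range(1, len(table) + 1))
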