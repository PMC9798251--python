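import datetime as dt

import numpy as np
import pandas as pd
import pytest

import ccm
from ccm.indices import (
    accumulation_curve,
    accumulation_speed,
    dbh_selectivity,
    density_difference,
    fraction_by_day,
    miss_rate,
    pooled_plot_density,
)

from conftest import record

D = dt.date


class TestCcmIndex:
    def test_forced_arithmetic(self, toy_occupancy):
        hr = {(i, j) for i in range(4) for j in range(3)}  # 12 cells incl. presences
        idx = ccm.ccm_index(toy_occupancy, hr)
        assert idx["A"] == pytest.approx(2 / 12)
        assert idx["B"] == pytest.approx(1 / 12)

    def test_bounds(self, toy_occupancy):
        hr_all = toy_occupancy.presence_cells("A")
        idx = ccm.ccm_index(toy_occupancy, hr_all)
        assert idx["A"] == 1.0
        assert idx["C"] == 0.0  # C's cell outside hr

    def test_hand_intersection(self, grid50):
        recs = [record(D(2020, 1, 1), "S", 25 + 50 * k, 25) for k in range(5)]
        occ = ccm.rasterize_records(recs, grid50)
        hr = {(0, 0), (1, 0)} | {(90 + k, 90) for k in range(38)}  # 2 of 5 inside, |hr|=40
        assert ccm.ccm_index(occ, hr)["S"] == pytest.approx(0.05)

    def test_empty_hr_rejected(self, toy_occupancy):
        with pytest.raises(ValueError, match="empty"):
            ccm.ccm_index(toy_occupancy, set())

    def test_nondecreasing_in_time(self, scenario):
        """Computed on growing record prefixes with a fixed home range,
        the index can only grow."""
        occ, hr = scenario.occupancy, scenario.hr_cells
        recs = sorted(scenario.records, key=lambda r: r.date)
        cut = recs[len(recs) // 3].date
        early = ccm.rasterize_records([r for r in recs if r.date <= cut], occ.grid)
        full_idx = ccm.ccm_index(occ, hr)
        early_idx = ccm.ccm_index(early, hr).reindex(full_idx.index).fillna(0.0)
        assert (early_idx <= full_idx + 1e-12).all()


class TestPlotIndices:
    def test_unit_area_density(self):
        inv = ccm.PlotInventory(
            plots=pd.DataFrame(dict(plot_id=list("abcd"), x=[0, 1, 2, 3], y=[0, 0, 0, 0])),
            stems=pd.DataFrame(
                dict(plot_id=["a"] * 4 + ["b"] * 3, species=["S"] * 7,
                     dbh_cm=[30.0] * 7, lifeform=["tree"] * 7)
            ),
        )
        assert ccm.plot_density(inv, None).per_ha["S"] == pytest.approx(7.0)
        assert pooled_plot_density(inv, None) == pytest.approx(7.0)

    def test_presence_fraction(self, toy_inventory):
        pres = ccm.plot_presence(toy_inventory, None)
        assert pres["A"] == pytest.approx(3 / 4)
        assert pres["B"] == pytest.approx(2 / 4)

    def test_minima_interact_with_presence(self, toy_inventory):
        """A 19 cm tree and a 4 cm liana drop below the minima, removing
        their plots from the species' presence count."""
        pres = ccm.plot_presence(toy_inventory, ccm.DEFAULT_SIZE_MINIMA)
        assert pres["A"] == pytest.approx(2 / 4)  # p2's 19 cm tree fails
        # C's stems (12 cm tree, 4 cm liana) all fail: species drops out
        assert "C" not in pres.index

    def test_presence_zero_iff_density_zero(self, scenario):
        tbl = scenario.table
        assert ((tbl.plot_presence == 0) == (tbl.plot_density_km2 == 0)).all()

    def test_density_additivity_over_species(self, toy_inventory):
        dens = ccm.plot_density(toy_inventory, None)
        assert dens.per_ha.sum() == pytest.approx(pooled_plot_density(toy_inventory, None))

    def test_zero_plots_rejected(self):
        inv = ccm.PlotInventory(
            plots=pd.DataFrame(columns=["plot_id", "x", "y"]), stems=pd.DataFrame()
        )
        with pytest.raises(ValueError):
            ccm.plot_density(inv)

    def test_consumption_rank_deterministic_ties(self, toy_occupancy):
        ranks = ccm.consumption_rank(toy_occupancy)
        assert ranks["A"] == 1  # 2 cells
        assert ranks["B"] == 2 and ranks["C"] == 3  # 1 cell each, lexical tie-break


class TestAccumulation:
    def test_single_day_single_step(self, grid50):
        recs = [record(D(2020, 1, 1), "A", 50 * k, 0) for k in range(5)]
        curve = accumulation_curve(ccm.rasterize_records(recs, grid50))
        assert list(curve.index) == [1]
        assert curve.iloc[0] == 5
        assert accumulation_speed(curve) == 1

    def test_monotone(self, scenario):
        curve = accumulation_curve(scenario.occupancy)
        assert (curve.diff().dropna() >= 0).all()
        assert curve.iloc[-1] == scenario.occupancy.total_presences()

    def test_linear_curve_crosses_at_90(self, grid50):
        recs = [record(D(2020, 1, 1) + dt.timedelta(days=k), "A", 50 * k, 0) for k in range(100)]
        curve = accumulation_curve(ccm.rasterize_records(recs, grid50))
        assert accumulation_speed(curve, threshold=0.9) == 90

    def test_two_phase_hand_curve(self):
        curve = pd.Series([50.0, 80.0, 85.0, 90.0, 95.0, 100.0], index=[1, 2, 3, 4, 5, 6])
        assert accumulation_speed(curve, 0.9) == 4
        assert fraction_by_day(curve, 2) == pytest.approx(0.8)

    def test_saturation_slows_with_duration(self, scenario):
        """Under stationary preferences the fraction accumulated in a
        fixed early window shrinks as the horizon grows (concavity)."""
        curve = accumulation_curve(scenario.occupancy)
        total_days = int(curve.index[-1])
        f_half = fraction_by_day(curve, total_days // 2)
        assert f_half > 0.5  # concave: first half contributes more than half


class TestMissRate:
    def make(self, detected_cells, ccm_cells, grid50):
        """Plots detect species S in ``detected_cells`` (100 m agg cells);
        the consumer shows S in ``ccm_cells`` and visits everything."""
        agg = ccm.GridSpec(cell_size=100.0)
        plots = pd.DataFrame(
            [dict(plot_id=f"p{k}", x=100 * i + 25, y=100 * j + 25)
             for k, (i, j) in enumerate(detected_cells)]
        )
        stems = pd.DataFrame(
            [dict(plot_id=f"p{k}", species="S", dbh_cm=30.0, lifeform="tree")
             for k in range(len(detected_cells))]
        )
        inv = ccm.PlotInventory(plots=plots, stems=stems)
        recs = [record(D(2020, 1, 1), "S", 100 * i + 10, 100 * j + 10) for i, j in ccm_cells]
        # filler species makes every detected agg cell 'visited'
        recs += [record(D(2020, 1, 1), "F", 100 * i + 60, 100 * j + 60) for i, j in detected_cells]
        occ = ccm.rasterize_records(recs, grid50)
        return miss_rate(occ, inv, agg)

    def test_no_misses(self, grid50):
        cells = [(0, 0), (1, 0), (2, 0)]
        assert self.make(cells, cells, grid50)["S"] == 0.0

    def test_all_missed(self, grid50):
        assert self.make([(0, 0), (1, 0), (2, 0), (3, 0)], [], grid50)["S"] == 1.0

    def test_hand_tally_third(self, grid50):
        detected = [(i, 0) for i in range(6)]
        present = [(i, 0) for i in range(4)]
        assert self.make(detected, present, grid50)["S"] == pytest.approx(1 / 3)

    def test_undetected_species_is_nan(self, grid50, toy_inventory):
        recs = [record(D(2020, 1, 1), "Z", 10, 10)]
        occ = ccm.rasterize_records(recs, grid50)
        rates = miss_rate(occ, toy_inventory, ccm.GridSpec(cell_size=500.0))
        assert np.isnan(rates["Z"])


class TestResponses:
    def test_density_difference_symmetric_toy(self):
        tbl = pd.DataFrame(
            dict(ccm_index=[0.1, 0.2, 0.3, 0.4, 0.5],
                 plot_density_km2=[50.0, 40.0, 30.0, 20.0, 10.0]),
            index=list("abcde"),
        )
        # frozen from hand z-score arithmetic on the logs
        expected = [-2.532514, -1.090696, 0.0, 1.090696, 2.532514]
        assert density_difference(tbl).values == pytest.approx(expected, abs=1e-5)

    def test_identical_distributions_give_zero(self):
        tbl = pd.DataFrame(
            dict(ccm_index=[0.1, 0.2, 0.4], plot_density_km2=[100.0, 200.0, 400.0]),
            index=list("abc"),
        )
        assert density_difference(tbl).abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_too_few_species_rejected(self):
        tbl = pd.DataFrame(dict(ccm_index=[0.1, 0.2], plot_density_km2=[1.0, 2.0]))
        with pytest.raises(ValueError, match=">= 3"):
            density_difference(tbl)

    def test_dbh_identical_samples(self):
        d, t, p = dbh_selectivity([20.0, 25, 30, 35], [20.0, 25, 30, 35])
        assert d == 0.0 and t == pytest.approx(0.0)

    def test_dbh_shift_detected(self):
        rng = np.random.default_rng(0)
        plot = rng.lognormal(3.3, 0.4, 5000)
        d, t, p = dbh_selectivity(plot + 1.0, plot)
        assert d == pytest.approx(1.0)
        assert t > 0 and p < 0.05

    def test_dbh_welch_hand_values(self):
        # frozen from the Welch formula evaluated by hand
        fed = [22.0, 25, 30, 28, 24, 27]
        plot = [20.0, 23, 21, 26, 22, 24]
        d, t, p = dbh_selectivity(fed, plot)
        assert d == pytest.approx(3.333333, abs=1e-5)
        assert t == pytest.approx(2.258767, abs=1e-5)
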