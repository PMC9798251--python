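import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import ccm
from ccm.distribution import (
    fit_linear,
    fit_zip,
    nagelkerke_r2,
)
from ccm.dispersion import CountGrid
from ccm.homerange import KernelAssignment

import pandas as pd


def zip_sample(rng, n, lam, pi, x=None, beta=None):
    mu = lam if x is None else np.exp(beta[0] + beta[1] * x)
    return rng.poisson(mu, n) * (rng.random(n) > pi)


class TestFitZip:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        y = zip_sample(rng, 4000, lam=2.0, pi=0.3)
        fit = fit_zip(y)
        assert fit.pi == pytest.approx(0.3, rel=0.1)
        assert fit.lambda_intercept == pytest.approx(2.0, rel=0.05)
        assert fit.converged

    def test_no_inflation_detected(self):
        rng = np.random.default_rng(7)
        y = rng.poisson(2.0, 4000)
        fit = fit_zip(y)
        assert fit.pi <= 0.05
        assert fit.lambda_intercept == pytest.approx(y.mean(), rel=0.05)

    def test_mle_dominates_true_parameters(self):
        """The fitted likelihood is at least the likelihood of the
        generating parameters on the same sample."""
        from scipy.stats import poisson

        rng = np.random.default_rng(3)
        lam, pi = 2.0, 0.3
        y = zip_sample(rng, 2000, lam=lam, pi=pi)
        fit = fit_zip(y)
        p0 = pi + (1 - pi) * np.exp(-lam)
        ll_true = np.sum(
            np.where(y == 0, np.log(p0), np.log(1 - pi) + poisson.logpmf(y, lam))
        )
        assert fit.loglik >= ll_true - 1e-6

    def test_zip_collapses_to_poisson_glm(self):
        """On Poisson data the ZIP count part matches a plain Poisson
        regression (independent route through statsmodels GLM)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 3000)
        y = rng.poisson(np.exp(0.4 + 0.7 * x))
        fit = fit_zip(y, x)
        glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        assert fit.beta == pytest.approx(np.asarray(glm.params), abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_zip(np.zeros(20))
        with pytest.raises(ValueError, match="integer"):
            fit_zip(np.full(20, 1.5))
        with pytest.raises(ValueError, match=">= 10"):
            fit_zip(np.ones(5))


class TestNagelkerke:
    def test_null_model_scores_zero(self):
        assert nagelkerke_r2(-50.0, -50.0, 100) == 0.0

    def test_perfect_binary_model_scores_one(self):
        assert nagelkerke_r2(0.0, -69.3, 100) == pytest.approx(1.0, abs=1e-6)

    def test_hand_arithmetic(self):
        # frozen from direct evaluation of the formula:
        # (1 - e^(2(-100+80)/100)) / (1 - e^(-200/100))
        assert nagelkerke_r2(-80.0, -100.0, 100) == pytest.approx(0.3812807, abs=1e-6)

    @given(st.floats(0.1, 40.0), st.floats(0.1, 40.0))
    def test_monotone_in_full_loglik(self, g1, g2):
        ll_null = -100.0
        lo, hi = sorted([g1, g2])
        assert nagelkerke_r2(ll_null + hi, ll_null, 50) >= nagelkerke_r2(
            ll_null + lo, ll_null, 50
        )

    def test_worse_than_null_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-101.0, -100.0, 50)


class TestFitLinear:
    def test_exact_fit(self):
        x = np.arange(10.0)
        out = fit_linear(3.0 * x + 1.0, x)
        assert out["r2"] == pytest.approx(1.0)
        assert out["coefficients"] == pytest.approx([1.0, 3.0])

    def test_textbook_five_points(self):
        # frozen from the normal equations solved by hand
        out = fit_linear([1.0, 3, 2, 5, 4], [0.0, 1, 2, 3, 4])
        assert out["coefficients"] == pytest.approx([1.4, 0.8])
        assert out["r2"] == pytest.approx(0.64)

    def test_orthogonal_predictor(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 200)
        out = fit_linear(y, x)
        assert abs(out["coefficients"][1]) < 0.2
        assert out["r2"] < 0.05

    def test_rank_deficient_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_linear(x, np.column_stack([x, 2 * x]))


def grids_from_arrays(y_by_species, x_by_species, cell_size=1000.0):
    cells = [(k, 0) for k in range(len(next(iter(y_by_species.values()))))]
    mk = lambda vals, src: CountGrid(
        grid=ccm.GridSpec(cell_size=cell_size),
        counts={sp: {c: v for c, v in zip(cells, arr) if v} for sp, arr in vals.items()},
        source=src, cells=set(cells),
    )
    return mk(y_by_species, "ccm"), mk(x_by_species, "plot"), cells


def flat_inventory_for(cells, cell_size=1000.0):
    plots = pd.DataFrame(
        [dict(plot_id=f"p{k}", x=cell_size * i + 25, y=cell_size * j + 25)
         for k, (i, j) in enumerate(cells)]
    )
    inv = ccm.PlotInventory(plots=plots, stems=pd.DataFrame(
        columns=["plot_id", "species", "dbh_cm", "lifeform"]))
    n = len(cells)
    ka = KernelAssignment(
        percents={f"p{k}": 20.0 + 75.0 * k / max(n - 1, 1) for k in range(n)}
    )
    return inv, ka


class TestDistributionAgreement:
    def test_perfect_agreement_all_significant(self):
        rng = np.random.default_rng(0)
        x = {f"s{k}": rng.lognormal(1, 0.8, 40).round(2) for k in range(5)}
        y = {sp: np.round(v).astype(float) for sp, v in x.items()}
        cg_ccm, cg_plot, cells = grids_from_arrays(y, x)
        inv, ka = flat_inventory_for(cells)
        tbl, summary = ccm.distribution_agreement(cg_ccm, cg_plot, inv, ka)
        assert summary.model == "linear"
        assert summary.n_significant == summary.n_species_fit == 5
        assert summary.mean_r2 > 0.9
        assert summary.chance_baseline_pct == 5.0

    def test_zip_model_selected_at_fine_scale(self):
        rng = np.random.default_rng(1)
        x = {f"s{k}": rng.lognormal(0, 1, 60).round(1) for k in range(3)}
        y = {sp: rng.poisson(0.3 + 0.5 * v).astype(float) for sp, v in x.items()}
        cg_ccm, cg_plot, cells = grids_from_arrays(y, x, cell_size=500.0)
        inv, ka = flat_inventory_for(cells, cell_size=500.0)
        tbl, summary = ccm.distribution_agreement(cg_ccm, cg_plot, inv, ka)
        assert summary.model == "zip"
        assert (tbl.model == "zip").all()

    def test_scenario_beats_chance(self, scenario):
        """Against a real (synthetic) landscape the share of species with
        significant plot-abundance slopes clearly exceeds the 5% false-
        positive baseline."""
        agg = ccm.GridSpec(cell_size=500.0)
        cg_ccm = ccm.aggregate_ccm_counts(scenario.occupancy, agg)
        cg_plot = ccm.aggregate_plot_counts(
            scenario.inventory, agg, scenario.config.forager.size_minima
        )
        tbl, summary = ccm.distribution_agreement(
            cg_ccm, cg_plot, scenario.inventory, scenario.plot_ka
        )
        assert summary.model == "zip"
        # more significant species than the 5% chance baseline can explain
        upper = stats.binom.ppf(0.95, summary.n_species_fit, 0.05)
        assert summary.n_significant > upper


class TestPresenceAgreement:
    def test_identical_presence_flags_separation(self):
        rng = np.random.default_rng(2)
        x = {f"s{k}": (rng.random(40) < 0.5).astype(float) for k in range(4)}
        cg_ccm, cg_plot, cells = grids_from_arrays(x, x)
        inv, ka = flat_inventory_for(cells)
        tbl, pooled = ccm.presence_agreement(cg_ccm, cg_plot, inv, ka)
        assert (tbl.flag != "").all()
        assert pooled["n_species_pooled"] == 0

    def test_peripheral_underdetection_gives_negative_kernel_slope(self):
        """When detection probability falls with percent kernel, the
        pooled kernel coefficient comes out negative."""
        rng = np.random.default_rng(3)
        n = 200
        y_by, x_by = {}, {}
        pct = np.linspace(20, 95, n)
        for k in range(8):
            x = (rng.random(n) < 0.6).astype(float)
            # detection falls toward the periphery; a floor rate where the
            # plots saw nothing prevents complete separation on x
            p_detect = (0.15 + 0.55 * x) * (1.2 - 0.01 * pct)
            y = (rng.random(n) < p_detect).astype(float)
            y_by[f"s{k}"], x_by[f"s{k}"] = y, x
        cells = [(k, 0) for k in range(n)]
        mk = lambda vals, src: CountGrid(
            grid=ccm.GridSpec(cell_size=1000.0),
            counts={sp: {c: v for c, v in zip(cells, arr) if v} for sp, arr in vals.items()},
            source=src, cells=set(cells),
        )
        plots = pd.DataFrame(
            [dict(plot_id=f"p{k}", x=1000 * k + 25, y=25) for k in range(n)]
        )
        inv = ccm.PlotInventory(plots=plots, stems=pd.DataFrame(
            columns=["plot_id", "species", "dbh_cm", "lifeform"]))
        ka = KernelAssignment(percents={f"p{k}": pct[k] for k in range(n)})
        tbl, pooled = ccm.presence_agreement(mk(y_by, "ccm"), mk(x_by, "plot"), inv, ka)
        assert pooled["n_species_pooled"] >= 4
        assert pooled["b2"] < 0
        assert pooled["b1"] > 0  # plot presence is genuinely informative here

    def test_uninformative_plot_presence_ci_covers_zero(self):
        rng = np.random.default_rng(4)
        n = 150
        y_by, x_by = {}, {}
        for k in range(10):
            y_by[f"s{k}"] = (rng.random(n) < 0.4).astype(float)
            x_by[f"s{k}"] = (rng.random(n) < 0.5).astype(float)
        cg_ccm, cg_plot, cells = grids_from_arrays(y_by, x_by)
        inv, ka = flat_inventory_for(cells)
        tbl, pooled = ccm.presence_agreement(cg_ccm, cg_plot, inv, ka)
        lo, hi = pooled["ci95_b1"]
        assert lo < 0 < hi
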