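"""Per-species spatial distribution agreement between the two methods.

At coarse aggregation scales each species becomes a small regression
dataset: one row per aggregation cell, response = consumer-derived
abundance in the cell, test predictor = plot-derived mean abundance,
control = mean percent kernel of the cell's plots (space-use intensity,
since the consumer samples its core range harder than the periphery).

At 500 m the cell counts are sparse and zero-heavy, so a zero-inflated
Poisson (ZIP) is used: P(y=0) = pi + (1-pi) e^-lambda and
P(y=k) = (1-pi) e^-lambda lambda^k / k! with log lambda = X beta and an
intercept-only logit for pi.  At 1000/1500 m ordinary linear models
suffice.  Goodness of fit is Nagelkerke's pseudo-R² for the count
models and classical r² for the linear ones.  Presence/absence
agreement is modelled per species with a fixed-effects logistic
regression and the slopes pooled by inverse variance — a declared
simplification of a crossed-random-effects binomial mixed model, noted
in every summary this module emits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from statsmodels.discrete.count_model import ZeroInflatedPoisson

from .dispersion import CountGrid
from .homerange import KernelAssignment
from .indices import PlotInventory

__all__ = [
    "ZipFit",
    "fit_zip",
    "nagelkerke_r2",
    "fit_linear",
    "distribution_agreement",
    "presence_agreement",
    "DistributionSummary",
]

POOLING_NOTE = (
    "per-species fixed-effects fits pooled by inverse variance; "
    "no crossed random effects for cell and species"
)


@dataclass
class ZipFit:
    """A fitted zero-inflated Poisson model.

    ``beta`` are the count-part coefficients (log link, intercept
    first), ``gamma`` the zero-part logit intercept; ``pi`` is the
    implied structural-zero probability.
    """

    beta: np.ndarray
    gamma: float
    pi: float
    loglik: float
    loglik_null: float
    converged: bool
    n: int
    p_values: np.ndarray = field(default=None)
    #: likelihood-ratio p for the first (test) predictor; Wald p-values in
    #: ``p_values`` are mildly anti-conservative in small zero-heavy samples
    p_slope: float = float("nan")

    @property
    def lambda_intercept(self) -> float:
        """exp(beta0): the Poisson mean of an intercept-only count part."""
        return float(np.exp(self.beta[0]))


def _zip_start_params(y: np.ndarray, k_exog: int) -> np.ndarray:
    """Moment-based starts: pi0 from excess zeros, lambda0 from the mean."""
    mean = max(y.mean(), 1e-3)
    p0_obs = np.mean(y == 0)
    p0_pois = np.exp(-mean)
    pi0 = np.clip((p0_obs - p0_pois) / max(1 - p0_pois, 1e-6), 0.02, 0.9)
    lam0 = max(mean / (1 - pi0), 1e-3)
    start = np.zeros(1 + k_exog)
    start[0] = np.log(pi0 / (1 - pi0))
    start[1] = np.log(lam0)
    return start


def fit_zip(y, X=None) -> ZipFit:
    """Maximum-likelihood ZIP fit of counts on optional predictors.

    ``X`` (n x p, without constant) enters the count part with a log
    link; the zero-inflation part is an intercept-only logit.  Needs
    >= 10 cells and non-negative integer counts; an all-zero response
    is non-identifiable and rejected.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 10:
        raise ValueError("ZIP fit needs >= 10 observations")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("ZIP response must be non-negative integers")
    if np.all(y == 0):
        raise ValueError("all-zero response: ZIP parameters not identifiable")
    exog = np.ones((len(y), 1)) if X is None else sm.add_constant(np.asarray(X, dtype=float))
    start = _zip_start_params(y, exog.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ZeroInflatedPoisson(y, exog, exog_infl=np.ones((len(y), 1)), inflation="logit")
        res = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
        null_model = ZeroInflatedPoisson(
            y, np.ones((len(y), 1)), exog_infl=np.ones((len(y), 1)), inflation="logit"
        )
        null_res = null_model.fit(
            start_params=_zip_start_params(y, 1), method="bfgs", maxiter=500, disp=0
        )
    p_slope = float("nan")
    if X is not None and exog.shape[1] >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reduced = ZeroInflatedPoisson(
                y, np.delete(exog, 1, axis=1), exog_infl=np.ones((len(y), 1)),
                inflation="logit",
            ).fit(
                start_params=_zip_start_params(y, exog.shape[1] - 1),
                method="bfgs", maxiter=500, disp=0,
            )
        lr = max(2.0 * (res.llf - reduced.llf), 0.0)
        p_slope = float(chi2_dist.sf(lr, 1))
    gamma = float(res.params[0])  # inflation logit intercept comes first
    beta = np.asarray(res.params[1:], dtype=float)
    return ZipFit(
        beta=beta,
        gamma=gamma,
        pi=float(expit(gamma)),
        loglik=float(res.llf),
        loglik_null=float(null_res.llf),
        converged=bool(res.mle_retvals.get("converged", False)),
        n=len(y),
        p_values=np.asarray(res.pvalues[1:], dtype=float),
        p_slope=p_slope,
    )


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's normalized likelihood-ratio pseudo-R² in [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_full < loglik_null - 1e-8:
        raise ValueError("full-model loglik below null loglik")
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom <= 0:
        raise ValueError("null log-likelihood of 0 leaves Nagelkerke R² undefined")
    cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    return float(np.clip(cs / denom, 0.0, 1.0))


def fit_linear(y, X) -> dict:
    """OLS of y on X (constant added); rank-deficient X is rejected.

    Returns coefficients, r², and the p-value of the first (test)
    predictor's slope.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > #predictors + 1")
    exog = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        bad = [
            j for j in range(1, exog.shape[1])
            if np.linalg.matrix_rank(np.delete(exog, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; redundant column index(es): {bad}")
    res = sm.OLS(y, exog).fit()
    return dict(
        coefficients=np.asarray(res.params),
        r2=float(res.rsquared),
        p_slope=float(res.pvalues[1]),
        loglik=float(res.llf),
        n=len(y),
    )


@dataclass
class DistributionSummary:
    """Across-species summary of one model set (one cell size, one group)."""

    cell_size: float
    model: str
    n_species_fit: int
    n_species_total: int
    mean_r2: float
    sd_r2: float
    range_r2: tuple[float, float]
    n_significant: int
    pct_significant_of_fit: float
    pct_significant_of_total: float
    chance_baseline_pct: float = 5.0
    note: str = POOLING_NOTE


def _cell_mean_percent_kernel(
    inv: PlotInventory, plot_ka: KernelAssignment, agg_grid
) -> dict[tuple[int, int], float]:
    """Mean percent kernel of the plots inside each aggregation cell."""
    pi, pj = agg_grid.index(inv.plots.x.values, inv.plots.y.values)
    acc: dict[tuple[int, int], list[float]] = {}
    for p, i, j in zip(inv.plots.plot_id, pi, pj):
        if p in plot_ka.percents:
            acc.setdefault((int(i), int(j)), []).append(plot_ka.percents[p])
    return {cell: float(np.mean(v)) for cell, v in acc.items()}


def distribution_agreement(
    ccm_counts: CountGrid,
    plot_counts: CountGrid,
    inv: PlotInventory,
    plot_ka: KernelAssignment,
    min_cells: int = 10,
    alpha: float = 0.05,
    zip_threshold_m: float = 750.0,
) -> tuple[pd.DataFrame, DistributionSummary]:
    """Fit one distribution model per species and summarize across species.

    The datapoints are aggregation cells carrying plot data; response is
    the CCM count, predictors are the plot mean abundance and the cell's
    mean plot percent-kernel.  Cells finer than ``zip_threshold_m`` get
    a ZIP model, coarser ones a linear model.  Species with fewer than
    ``min_cells`` usable cells, or degenerate responses, are listed as
    skipped.  The summary reports the share of species whose
    plot-abundance slope has p < alpha, next to the 5% chance baseline,
    with both the fitted-species and full-species denominators.
    """
    agg = plot_counts.grid
    cell_size = agg.cell_size
    use_zip = cell_size <= zip_threshold_m
    cells = sorted(plot_counts.cells)
    pct_by_cell = _cell_mean_percent_kernel(inv, plot_ka, agg)
    pct_vec = np.array([pct_by_cell.get(c, 100.0) for c in cells])

    species = sorted(set(ccm_counts.species_list) | set(plot_counts.species_list))
    rows = []
    for sp in species:
        y = ccm_counts.vector(sp, cells)
        x_plot = plot_counts.vector(sp, cells)
        row = dict(species=sp, cell_size=cell_size, n_cells=len(cells),
                   model="zip" if use_zip else "linear", r2=np.nan,
                   p_slope=np.nan, slope=np.nan, flag="")
        if len(cells) < min_cells:
            row["flag"] = "too-few-cells"
            rows.append(row)
            continue
        X = np.column_stack([x_plot, pct_vec])
        if np.ptp(x_plot) == 0:
            row["flag"] = "constant-predictor"
            rows.append(row)
            continue
        try:
            if use_zip:
                fit = fit_zip(y, X)
                row.update(
                    slope=float(fit.beta[1]),
                    p_slope=float(fit.p_slope),
                    r2=nagelkerke_r2(fit.loglik, fit.loglik_null, fit.n),
                    flag="" if fit.converged else "not-converged",
                )
            else:
                fit = fit_linear(y, X)
                row.update(slope=float(fit["coefficients"][1]),
                           p_slope=fit["p_slope"], r2=fit["r2"])
        except (ValueError, np.linalg.LinAlgError) as exc:
            row["flag"] = f"skipped: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows).set_index("species")

    fitted = table[table.r2.notna()]
    n_sig = int((fitted.p_slope < alpha).sum())
    summary = DistributionSummary(
        cell_size=cell_size,
        model="zip" if use_zip else "linear",
        n_species_fit=len(fitted),
        n_species_total=len(species),
        mean_r2=float(fitted.r2.mean()) if len(fitted) else float("nan"),
        sd_r2=float(fitted.r2.std(ddof=1)) if len(fitted) > 1 else float("nan"),
        range_r2=(
            (float(fitted.r2.min()), float(fitted.r2.max())) if len(fitted) else (np.nan, np.nan)
        ),
        n_significant=n_sig,
        pct_significant_of_fit=100.0 * n_sig / len(fitted) if len(fitted) else float("nan"),
        pct_significant_of_total=100.0 * n_sig / len(species) if species else float("nan"),
        chance_baseline_pct=100.0 * alpha,
    )
    return table, summary


def presence_agreement(
    ccm_counts: CountGrid,
    plot_counts: CountGrid,
    inv: PlotInventory,
    plot_ka: KernelAssignment,
    min_cells: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Per-species logistic agreement on presence/absence per cell.

    logit P(CCM presence) = b0 + b1 * plot_presence + b2 * percent_kernel,
    fitted per species; species with complete separation (or only one
    outcome class) are flagged and excluded from the pooled
    inverse-variance means of b1 and b2.
    """
    agg = plot_counts.grid
    cells = sorted(plot_counts.cells)
    pct_by_cell = _cell_mean_percent_kernel(inv, plot_ka, agg)
    pct_vec = np.array([pct_by_cell.get(c, 100.0) for c in cells])

    rows = []
    for sp in sorted(set(ccm_counts.species_list) | set(plot_counts.species_list)):
        y = (ccm_counts.vector(sp, cells) > 0).astype(float)
        x_pres = (plot_counts.vector(sp, cells) > 0).astype(float)
        row = dict(species=sp, n_cells=len(cells), b1=np.nan, b2=np.nan,
                   se_b1=np.nan, se_b2=np.nan, flag="")
        if len(cells) < min_cells or y.min() == y.max():
            row["flag"] = "too-few-cells" if len(cells) < min_cells else "one-outcome-class"
            rows.append(row)
            continue
        X = sm.add_constant(np.column_stack([x_pres, pct_vec]), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = np.asarray(res.params)
            ses = np.asarray(res.bse)
            if (
                not res.mle_retvals.get("converged", False)
                or np.any(np.abs(params) > 15)
                or np.any(~np.isfinite(ses))
            ):
                row["flag"] = "separation"
            else:
                row.update(b1=float(params[1]), b2=float(params[2]),
                           se_b1=float(ses[1]), se_b2=float(ses[2]))
        except Exception as exc:  # perfect separation raises in statsmodels
            row["flag"] = f"separation: {type(exc).__name__}"
        rows.append(row)
    table = pd.DataFrame(rows).set_index("species")

    ok = table[(table.flag == "") & table.se_b1.gt(0) & table.se_b2.gt(0)]
    pooled: dict = {"n_species_pooled": int(len(ok)), "note": POOLING_NOTE}
    for coef in ("b1", "b2"):
        if len(ok):
            w = 1.0 / ok[f"se_{coef}"] ** 2
            est = float(np.sum(w * ok[coef]) / np.sum(w))
            se = float(np.sqrt(1.0 / np.sum(w)))
            pooled[coef] = est
            pooled[f"se_{coef}"] = se
            pooled[f"ci95_{coef}"] = (est - 1.96 * se, est + 1.96 * se)
        else:
            pooled[coef] = float("nan")
            pooled[f"se_{coef}"] = float("nan")
            pooled[f"ci95_{coef}"] = (float("nan"), float("nan"))
    return table, pooled
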