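# ccm — consumer-centric resource sampling

`ccm` estimates the density, dispersion, and spatial distribution of food
resources in a landscape from the feeding locations of the consumer itself,
and quantifies how well those consumer-derived estimates agree with
conventional investigator-placed vegetation plots.

Field studies of foraging animals routinely collect GPS locations of every
tree or liana a followed group feeds on. The consumer-centric method (CCM)
treats that byproduct as a botanical survey: feeding locations are
rasterized into 50 × 50 m *observational cells* (a size that absorbs
typical handheld-GPS error of 15–20 m), and per-species presence across
those cells, within the group's kernel home range, becomes a density index.
The package is aimed at behavioral ecologists who want to know whether
months of follow data can substitute for — or complement — plot surveys,
and at methodologists who want a seeded simulation harness for that
question.

## The three indices

For species *s*, group home range estimated as a kernel utilization
distribution (UD) with p% isopleths:

- **CCM Index** = |presence cells of *s* ∩ cells in the 95% isopleth| /
  |cells in the 95% isopleth|, in [0, 1];
- **Plot Density** = qualifying stems of *s* / total plot area
  (individuals/km² and /ha), from 50 × 50 m vegetation plots;
- **Plot Presence** = fraction of plots containing ≥ 1 qualifying stem of
  *s*, in [0, 1].

"Qualifying" applies the consumer's size minima (DBH ≥ 20 cm for trees,
≥ 5 cm for lianas). Agreement between methods is Pearson's *r* on
log-transformed indices, swept over isopleth level (20–95% in 1% steps) and
dietary inclusion (top-k most consumed species), with a moving
percent-kernel window for core-versus-periphery comparisons and a day-by-day
series for temporal stability. Dispersion is compared through Morisita's
index Id = n·Σxᵢ(xᵢ−1)/(N(N−1)) on 500/1000/1500 m quadrat counts; spatial
distribution through per-species zero-inflated Poisson (500 m) or linear
(1000/1500 m) models of consumer cell counts on plot-mean abundance with a
percent-kernel covariate, summarized by Nagelkerke/classical R² and the
share of species with a significant plot-abundance slope.

A fully seeded synthetic ecosystem (Poisson and Thomas-cluster stem maps,
lognormal DBH, a home-range-constrained selective forager, stratified plot
surveys) provides ground truth for every stage.

## Worked example

Run the default synthetic study — 25 species with log-spaced densities of
15–400 stems/km² on an 8 × 8 km landscape, a neutral (non-selective)
forager observed for 600 days with ~9.5 feeding locations/day — and compare
what the consumer "surveyed" against the truth:

```python
import ccm

res = ccm.recovery_experiment(seed=1)
print(res.table[["ccm_index", "plot_density_ha",
                 "plot_presence", "consumption_rank"]].head(6).round(4))
m = res.metrics
print(f"records: {m['n_records']}, home-range cells: {m['n_hr_cells']}")
print(f"r(log CCM Index, log true density)    = {m['r_ccm_log_density']:.3f}")
print(f"r(log Plot Density, log true density) = {m['r_plot_log_density']:.3f}")
print(f"agreement stabilizes on day {m['stability_day']} of {res.config.n_days}")
```

```
         ccm_index  plot_density_ha  plot_presence  consumption_rank
species
sp00        0.1760           3.4000         0.5917                 1
sp01        0.1410           2.3667         0.4000                 3
sp02        0.1666           2.2667         0.4417                 2
sp03        0.0697           0.6667         0.1583                 7
sp04        0.1175           2.4000         0.4667                 4
sp05        0.1091           2.0667         0.3500                 5

records: 5851, home-range cells: 3914
r(log CCM Index, log true density)    = 0.943
r(log Plot Density, log true density) = 0.860
agreement stabilizes on day 60 of 600
```

The most consumed species (`sp00`, true density 400/km²) tops both the CCM
Index and the plot estimates; across all 25 species the consumer-derived
index tracks true log density with r = 0.94 — here slightly better than the
120 in-range plots manage — and the cross-method correlation settles within
the first two months of simulated observation.

The same machinery runs on real files through the CLI:

```sh
ccm simulate --seed 7 --out data/          # or bring your own CSV/GPX
ccm indices --feeding data/feeding.csv --tracklog data/tracklog.csv \
            --plots data/plots.csv --kernel 95
ccm run --simulate --seed 7 --out runout/  # full pipeline + manifest
```

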