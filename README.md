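# nichetrack

Seasonal environmental-niche overlap and niche-tracking analysis for
animal movement data.

Migratory animals can keep their *geographic* range or their
*environmental* niche — the conditions they live in — constant across
seasons, but rarely both.  `nichetrack` quantifies the second option: for
GPS-tracked individuals and populations it measures how much the
environmental conditions occupied in one season overlap those occupied in
the next, whether that overlap is greater than chance given what was
available ("niche tracking"), and whether the variation in overlap and
tracking sits between or within individuals, populations and years.  It is
aimed at movement ecologists studying migratory strategies at the
individual-to-population scale, and ships a synthetic
movement-and-environment generator so the entire pipeline can be exercised
and validated against known ground truth without any proprietary tracking
data.

## The method

For each analysis unit (individual × annual cycle, or flyway × annual
cycle) and season, occurrence points are annotated with temperature,
precipitation and NDVI — either from daily layers at each fix's own date
("weather") or from long-term monthly means ("climate") — and smoothed
into a density *z*<sub>occ</sub> on a grid spanning environmental space.  A
background sample (10 000 points uniform over the flyway's 300-km-buffered
100% minimum convex polygon) yields an availability density
*z*<sub>bkg</sub> on the same grid, and the corrected occupancy is
*z* ∝ *z*<sub>occ</sub>/*z*<sub>bkg</sub>.  Overlap between two seasons'
occupancies is Schoener's

> *D* = 1 − ½ Σ |*z*₁ − *z*₂|,  *D* ∈ [0, 1],

and a permutation similarity test (200 randomizations redrawing one
season's environments from the background, 100 per direction) flags niche
tracking when observed *D* exceeds the 95th percentile of the simulated
values.  Bayesian random-intercept models then partition the variance of
overlap (Gaussian) and tracking (binary, probit) into between-unit
*V*<sub>B</sub>, year and residual *V*<sub>W</sub> components, summarized
as repeatability *R* = *V*<sub>B</sub>/(*V*<sub>B</sub> + *V*<sub>W</sub>).
See [`docs/methods.md`](docs/methods.md) for assumptions, priors and
numerical choices.

## Worked example

Simulate two flyways of three weather-seeking individuals (bias κ = 6)
tracked hourly for two years, and run the full pipeline:

```python
from nichetrack import RunConfig, SimulationConfig, MCMCConfig, run_all, summarize

cfg = RunConfig(
    simulation=SimulationConfig(n_individuals=3, years=2, fix_interval_min=60,
                                extent_km=400, cell_km=10, kappa=6.0),
    n_background=3000, n_perm=100, grid_R_3d=15, variable_sets=("all",),
    mcmc=MCMCConfig(iterations=6000, thin=10, burn_in=1000), seed=42,
)
out = run_all(cfg, "runs/demo")       # ~3.5 min on one CPU
tables = summarize(out)
print(tables["summary"]); print(tables["welch"]); print(tables["repeatability"])
```

Output (abridged):

```
     level    mode variable_set  n_pairs   mean_D  tracking_pct
individual climate          all       48 0.000317          0.00
individual weather          all       48 0.064855         12.50
population climate          all       16 0.000078          0.00
population weather          all       16 0.065958          6.25

                         contrast         t        df        p
   individual: climate vs weather -5.547036 47.008130 0.000001
   population: climate vs weather -3.280143 15.000140 0.005061

                      model parameter     mean     q2_5    q97_5
individual_climate_gaussian         R 0.073468 0.000125 0.393202
population_climate_gaussian         R 0.890470 0.063283 0.999495
```

Reading it: these simulated birds chase daily conditions, so seasonal
overlap is an order of magnitude higher on the weather scale than on the
climate scale (mean *D* 0.065 vs 0.0003; Welch *t* < 0, *p* < 0.01), and
overlap is far more repeatable between populations (*R* ≈ 0.89) than
between individuals (*R* ≈ 0.07) — variation at the individual level is
mostly within-individual.  The same tables are written as CSVs in the run
directory, next to every intermediate (tracks, seasonal points, background
polygons and annotations, per-pair overlap and tracking results, posterior
draws), all reproducible bit-for-bit from the config and seed.

The same stages are available from the shell:

```sh
nichetrack run-all --seed 42 -o runs/demo
nichetrack simulate -c config.yaml -o runs/sim      # or stage by stage
```

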