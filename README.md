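# playvis

Visibility-graph analysis of school playgrounds, trajectory-based usage
heatmaps, and negative-binomial mixed models linking the two.

Playground observation studies record where children of different ages
and genders spend their breaktimes. A recurring question is how much of
that spatial behaviour is shaped by the *visibility structure* of the
ground — whether a spot is visually central (seen from almost
everywhere) or deep (hidden behind sheds, hedges and walls). `playvis`
implements an analysis pipeline for this question, for researchers in
environmental psychology, space syntax and children's physical-activity
research:

1. **Geometry** — a playground layout (boundary, eye-level obstruction
   polygons, named zones) is tessellated into 45 × 45 cm cells, the
   footprint of a stationary child.
2. **Visibility** — cells become nodes of a visibility graph; two cells
   are joined when the straight line between their centroids misses all
   obstruction interiors. The **Visual Mean Depth** (VMD) of a cell is
   the mean number of graph edges ("visual steps") on shortest paths to
   every other cell: VMD = 1 means everything is directly visible;
   higher values mean visually deeper, more hidden locations.
3. **Heatmaps** — each observed child contributes one 10-second
   movement polyline. A 70 cm buffer around the polyline represents the
   space a moving child occupies, and the per-cell usage count is the
   number of *distinct* buffered trajectories overlapping the cell, per
   gender × year-group stratum.
4. **Regression** — usage counts are modelled with NB2 negative-binomial
   mixed models (variance μ + μ²/θ) in a nested sequence:
   M0 (intercept), M1 (+ VMD), M2 (+ random intercept per playground
   zone), M3 (+ group-specific VMD slopes):

   log μ = β₀ + γ_g + β_g·VMD + u_zone,  u_zone ~ N(0, σ²)

   The zone random intercept absorbs baseline differences between
   functional areas (a football pitch attracts children regardless of
   its visibility), so β_g isolates the visual-depth association. The
   zone effect is integrated out by adaptive Gauss–Hermite quadrature;
   each group's slope is reported as an incidence rate ratio
   IRR = exp(β_g) and a percent change 100·(IRR − 1) per 1-unit VMD
   increase, with a Wald p-value at the slope level. A ball-game
   exclusion filter re-runs the analysis without institutionally
   allocated ball play.
5. **Synthetic data** — no per-child observation records are public, so
   a generator produces playground layouts (integrated or separated
   ball-field templates, and random layouts), NB2 cell counts from the
   generating model, and synthetic 10-second trajectories, making every
   stage testable end to end against known ground truth.

Descriptive helpers (cross-tabulations, Pearson chi-square, Cramér's V,
Haberman adjusted standardized residuals) cover the non-spatial side of
such studies.

## Worked example

Simulate an "integrated ball fields" playground (ball courts placed in
the middle of the main ground), run the full pipeline, and fit the
model sequence:

```python
import numpy as np
import playvis as pv

cfg = pv.GeneratorConfig(template="integrated-fields", n_trajectories_per_group=360)
scene = pv.simulate_scene(cfg, seed=1)           # layout -> lattice -> VMD
v = scene.vmd.values
print(f"lattice: {scene.lattice.nrows} x {scene.lattice.ncols} cells "
      f"({scene.lattice.n_walkable} walkable)")
print(f"VMD: min {np.nanmin(v):.2f}, mean {np.nanmean(v):.2f}, max {np.nanmax(v):.2f}")

_, truth = pv.generate_cell_counts(scene.layout, scene.lattice, scene.vmd, cfg, seed=1)
records = pv.generate_trajectories(scene.layout, scene.lattice, truth, cfg, seed=1)
result = pv.rasterize_counts(records, scene.lattice, radius=0.70, vmd=scene.vmd)

diag = pv.check_overdispersion(result.counts)
print(f"Poisson dispersion ratio: {diag.pearson_ratio:.2f} (overdispersed: {diag.overdispersed})")

fits = pv.fit_sequence(result.counts)            # M0 -> M3
print(pv.compare_models(list(fits.values()))[["loglik", "aic", "lrt", "lrt_p", "selected"]].round(2))
for e in pv.group_effects(fits["M3"]):
    print(f"{e.group:13s} slope {e.slope:+.3f}  IRR {e.irr:.2f}  "
          f"change {e.pct_change:+.0f}%  p {e.p:.2g}")
```

Output:

```
lattice: 67 x 105 cells (6459 walkable)
VMD: min 1.10, mean 1.28, max 2.06
Poisson dispersion ratio: 2.42 (overdispersed: True)
         loglik        aic      lrt  lrt_p  selected
model
M0    -54776.33  109556.66      NaN    NaN     False
M1    -54622.20  109250.39   308.27    0.0     False
M2    -50818.76  101645.51  7606.88    0.0     False
M3    -50344.75  100709.50   948.02    0.0      True
female:Y3/4   slope +0.506  IRR 1.66  change +66%  p 1.7e-28
female:Y5/6   slope +0.630  IRR 1.88  change +88%  p 1.3e-43
male:Y3/4     slope -0.109  IRR 0.90  change -10%  p 0.023
male:Y5/6     slope -1.047  IRR 0.35  change -65%  p 1.5e-80
```

Reading the output: counts are overdispersed relative to Poisson
(ratio 2.42), so the NB2 family is warranted; the interaction model M3
wins every likelihood-ratio test and has the lowest AIC. In this
integrated layout boys' expected cell usage falls steeply with visual
depth (−65% per VMD unit for the older boys: they concentrate in the
central, highly visible ball fields), while girls' usage *rises* with
depth — not because girls seek hidden corners, but because ball games
crowd them out of the visually central courts. Excluding ball-game
trajectories (`pv.filter_ball_games(records)`) and refitting reverses
the boys' association, which is exactly the contrast the exclusion
analysis is designed to expose.

A thin CLI wraps the generator:

```bash
playvis simulate-layout --template separated-fields --seed 1 --out layout.geojson
playvis simulate-counts --template integrated-fields --seed 1 --out counts.csv
playvis simulate-trajectories --template integrated-fields --seed 1 --out trajs.csv
```

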