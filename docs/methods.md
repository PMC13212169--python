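# Methods

This note documents the models, conventions and numerical choices
behind `playvis`, and what its synthetic-data tests do and do not show
about real observational data.

## Lattice and geometry conventions

The analysis unit is a square cell of 0.45 m (default), the approximate
footprint of a stationary primary-school child; all coordinates are
planar metres in a local frame (inputs must be pre-projected). The
lattice origin sits at the minimum corner of the boundary's axis-aligned
bounding box (configurable), which makes runs reproducible for a given
layout. Cell membership is decided by the cell centroid with a
closed-boundary convention: a cell is *walkable* when its centroid lies
inside the boundary (edge included) and strictly outside every
obstruction interior; a centroid exactly on a zone edge belongs to the
zone; overlapping zones are resolved by declaration order with a
warning. The centroid rule avoids the ambiguity of partially covered
cells; alternatives (area-majority membership) shift the walkable set by
at most the boundary ring of cells.

Obstruction polygons are expected to be pre-filtered to objects tall
enough to block a child's sight line (eye level 1.2 m, carried as
metadata only) — the filter belongs to map preparation, not to this
package.

## Visibility graph and VMD

Line of sight is centroid-to-centroid: two walkable cells are connected
when the open segment between their centroids does not pass through any
obstruction interior. Grazing contact with an obstruction edge or vertex
(contact of measure zero, epsilon 10⁻⁹ m) does not block, matching
common grid-VGA practice; the boundary itself never blocks — space
outside it simply has no cells. The graph builder is vectorised (proper
segment-edge crossing tests with bounding-box pruning; near-degenerate
contacts fall back to the exact predicate) and is tested to agree
exactly with the per-pair shapely predicate and with an independent
all-pairs BFS oracle.

Visual Mean Depth of a cell is the mean unweighted shortest-path edge
count to every other cell of its connected component ("visual steps");
cells in singleton components get a missing value, and everything
outside the largest component is excluded from the regression population
with the excluded fraction reported. Distances are computed by boolean
wavefront expansion (iterated adjacency products), which is exact and
fast for the small graph diameters of open layouts; a 10,000-cell layout
completes in minutes on one CPU.

## Heatmap semantics

Each 10-second trajectory polyline is buffered at 0.70 m with round caps
and joins (32 segments per quarter arc); a single-point record (a
stationary child) yields a disc. A trajectory *touches* a cell when the
buffer–cell intersection has positive area (threshold 10⁻⁶ m² to
suppress numerical slivers) and increments the cell's count **at most
once** — counts are trajectory-level, not pass-level, which is the
natural reading of "how many distinct children's movements reached this
cell". Implementation note: touch detection uses a distance-within-radius
query with the exact buffer-area rule applied in the thin tangency ring,
which is equivalent to, and tested against, the brute-force
buffer-area rule. Counts are pooled over sessions; per-session layers
are available. Buffers may legitimately spill onto non-walkable cells;
the spill-over tally is reported.

## Descriptive statistics

Pearson chi-square without continuity correction (tables are large),
Cramér's V = √(χ²/(n·min(r−1, c−1))), and Haberman adjusted standardized
residuals (O−E)/√(E(1−rowshare)(1−colshare)), which are approximately
standard normal under independence; |r| > 1.96 flags over-/
under-represented cells. For play-type association the effect-size n is
the number of play observations, not all observations — the only n under
which the published χ² and V values of the two-school campaign are
mutually consistent. The published summary tables used for these
consistency checks are embedded as module constants
(`REFERENCE_SUMMARIES`); the raw per-child records behind them are not
public.

## The NB2 mixed-model sequence

Counts per (cell, group) are modelled as NB2: Var(y) = μ + μ²/θ (the
parameterisation is a package choice; sources rarely state it). The
nested sequence is M0 (intercept), M1 (+VMD), M2 (+zone random
intercept), M3 (+group offsets and group-specific VMD slopes):

log μ = β₀ + γ_g + β_g·VMD + u_zone,  u_zone ~ N(0, σ²)

Choices that matter:

* **VMD enters raw** (unstandardised) so "per 1-unit increase in VMD"
  is directly interpretable as one visual step.
* **Group-specific slopes are parameterised directly** (one β_g per
  group rather than reference + interaction contrasts) — mathematically
  equivalent, and each slope's Wald SE, p, IRR = exp(β_g) and percent
  change read off the fit without delta-rule combinations.
* **No exposure offset**: cells have equal area.
* **Zero inflation** is diagnosed (observed vs Poisson-implied zero
  share) but no ZI component is fitted; the NB2 family is selected after
  the overdispersion check (Pearson χ²/df of a Poisson fit with the M1
  mean structure; ratio > 1.5 is flagged as overdispersed, a zero-share
  excess > 2 points as possible zero inflation).

### Estimation

The marginal likelihood factorises over zones; each zone's scalar
random-intercept integral is evaluated by **adaptive Gauss–Hermite
quadrature** (default 15 nodes; 1 node = Laplace): nodes are centred on
the conditional mode (found by a damped scalar Newton iteration, warm
started across evaluations) and scaled by the conditional curvature.
Estimates with 7 vs 25 nodes agree to < 10⁻³ on recovery-test data.
Optimisation is L-BFGS-B on (β, log θ, log σ) with analytic gradients;
the gradient holds the quadrature adaptation fixed, which is exact up to
the quadrature error itself since the true integral does not depend on
the adaptation point. Convergence requires a relative objective change
below ~10⁻¹¹; line-search stalls with a near-zero gradient are accepted
as converged, otherwise one restart is attempted and failure is flagged
on the fit (never silent). log σ is bounded below at ln 10⁻⁴ and a
boundary estimate (σ² ≈ 0) is reported. Standard errors come from the
finite-difference Hessian of the analytic gradient; a non-positive
definite Hessian falls back to a pseudo-inverse with a warning.
Numerical safety: linear predictors are clipped at ±50 before
exponentiation, and for θ > 10⁶ the Γ-ratio in the likelihood switches
to the exact integer-count sum Σ_{j<y} log(θ+j), so the Poisson limit is
accurate to 10⁻⁶. The implementation is validated against numeric
integration of the integrand, the statsmodels NB2 MLE in the σ = 0
limit, and R's glmmTMB on a shared fixture (agreement to ~10⁻³ in
coefficients and ~10⁻² in log-likelihood).

### Model comparison

Likelihood-ratio tests compare adjacent models (2·ΔlogLik, df =
Δparameters, with parameters counting θ and σ). The M1→M2 step tests
σ² = 0 on the boundary of its space and uses the 50:50 χ²₀:χ²₁ mixture
p-value. AIC = −2logLik + 2k, BIC with log n; the selected model is the
lowest-AIC model among those reachable from M0 by consecutive
significant LRT steps. Deviance is reported as −2 logLik (differences
along the sequence are the LRT statistics; an NB saturated-model
deviance adds nothing for nested comparison). Predicted-count curves are
evaluated at u = 0 with delta-rule bands on the log scale (exponentiated,
so bands are positive and widen away from the VMD mean); they agree with
1,000-draw parametric-bootstrap bands to ~15%.

## Synthetic data generator

The generator emulates the observational structure of a two-school
breaktime campaign: playgrounds of ~1,400–1,600 m², a 45 cm grid, a
70 cm buffer, four gender × year strata, and ~1,450 ten-second
trajectories per site at default settings.

**Templates.** `integrated-fields` places designated ball zones
(football, basketball, hockey, tennis) centrally inside a 47 × 30 m
ground; `separated-fields` puts football/basketball in a back strip
behind a blocking structure reachable through one narrow corridor, with
kingball the only ball zone in the main ground. Both templates' wall and
hedge sets were calibrated once so their VMD profiles match published
two-school values (integrated: range 1.10–2.06, mean 1.28; separated:
range 1.62–3.38, mean 2.18 — the separated school is visually deeper,
as in reality). `convex` is a bare rectangle (VMD ≡ 1); `random-obstacles`
mixes compact blocks with thin wall-like blockers, which is what gives
real grounds their depth variation.

**Direct counts.** For each modelled cell and group,
μ = exp(β₀ + γ_g + β_g·VMD + u_zone) with one N(0, σ²) draw per zone,
and y ~ NB2(μ, θ) via the gamma–Poisson mixture. Defaults: β₀ = 1.3,
slopes (−0.3, +0.4, −0.6, −0.2) spanning the ±50% percent-change
magnitudes reported for real playgrounds, σ = 0.5, θ = 1.5. This is the
clean path for parameter-recovery tests.

**Trajectories.** Free-play trajectories are *tethered* random walks: a
child plays around an anchor spot (tether radius 1.2 m, step 0.5 m,
turning sd 1.0 rad, path length ~Γ with mean 8 m per 10 s — kinematic
constants are package choices; no source states them). Anchors are drawn
with probability proportional to the group's intensity divided by the
local reach-kernel mass (the number of cells a trajectory anchored there
can touch); without this correction, trajectory touch counts simply
mirror how geometrically open each location is — an exposure gradient of
roughly −0.6 per VMD unit that swamps any preference signal. Ball-game
trajectories (per-group share; boys' shares high, reflecting the strong
male skew of ball games) start uniformly inside designated ball zones
and stay there, emulating institutional allocation rather than free
choice. `ball_game_contrast_config()` constructs the exclusion-contrast
scenario: boys' free-play slopes positive (+1.0 / +0.55, the printed
+179%/+70% magnitudes) with ball shares 0.75/0.70, so the slope fitted
on all data is negative and flips sign when ball games are filtered out.

**What the trajectory path does not emulate:** social interaction,
supervision, rota scheduling, realistic path tortuosity, or
behaviourally heterogeneous dwell times. Rasterisation is a smoothing,
noisy measurement of the intensity surface by design, so statistical
recovery tests use the direct-count path and the trajectory path is
held to sign-level and correlation-level checks only.

## Test problem sizes and frozen tolerances

* Parameter recovery: random-obstacles layout of ~3,900 cells, 6 zone
  labels, seeds 1–100; |mean slope bias| < 0.05 per group, mean σ and θ
  within 20%, pooled 95% Wald coverage within [90%, 98%].
* LRT behaviour: ~1,300-cell layout, 50 replicates per scenario; M3 vs
  M2 at α = 10⁻³ rejects in ≥ 95% under default group effects and ≤ 2%
  when all group parameters are equal.
* Pipeline closure: full-scale separated-fields scene computed once;
  zone intercepts drawn once per scene (a school's zone baselines are
  fixed attributes — replicates resample observation sampling, as a
  repeated campaign would), 1,600 trajectories per group so the check
  tests closure of the method rather than single-campaign power;
  all four slope signs recovered in ≥ 48 of 50 replicates.
* Heatmap-vs-intensity fidelity: per-group Spearman thresholds (≥ 0.25
  per group, ≥ 0.35 mean) were frozen from a seeded pilot of the exact
  test scenario; at study-scale count density (mean ~6 per cell-group)
  per-cell sampling noise caps the attainable correlation near 0.3–0.5,
  dominated by the smallest-slope group.

## Known limitations

* Spatial autocorrelation between neighbouring cells is ignored, as is
  standard for this analysis; buffered trajectories induce correlated
  counts in adjacent cells, so cell-level SEs are optimistic on the
  trajectory path (the recovery tests quantify coverage on the direct
  path only).
* 2-D visibility at a single eye level; no terrain, no variable child
  heights, no restricted-radius visibility variants.
* The visibility builder's vectorised path resolves near-degenerate
  sight lines (through obstruction vertices) by an exact fallback;
  pathological polygons that enter and exit interiors exclusively
  through vertices at multiple disjoint points are not expected in
  practice and are not handled beyond that fallback.
* ML estimation of σ with ~6 zones carries the usual downward
  finite-group bias (≈ −10% here); REML-type corrections are not
  implemented.
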