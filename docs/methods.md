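# Methods

This note documents the statistical model behind `pikathresh`, the defaults
it ships with and why, and what the synthetic-data generator does and does
not emulate.

## The analysis chain

A survey consists of plots (1 ha) of two grassland types — alpine meadow
(AM) and alpine steppe (AS) — each holding a few quadrats, with per-plot
effective pika burrow-entrance density (holes/ha) as the disturbance
gradient. The two types are analysed independently throughout: they differ
in climate, species pools and quadrat sizes, so pooling would confound
every downstream contrast.

1. **Indicators.** Quadrat metrics are aggregated to plots: arithmetic mean
   for continuous metrics (Shannon H, cover, height, biomass, edible
   share), pooled species count for richness. Shannon uses natural
   logarithms (nats); H = 0 for monocultures and H = ln S for uniform
   communities.
2. **Health index.** The seven indicators are min-max standardized to
   [0, 1]; burrow density is reversed (more burrows → lower health) — the
   only orientation under which the composite is a *health* index. Weights
   come from a PCA of the indicator correlation matrix: components are
   retained by the Kaiser rule (eigenvalue > 1, at least one), and
   indicator i receives wᵢ ∝ Σₖ varexpₖ·|loadingᵢₖ|, normalized to sum to
   one — the common composite-index convention. KMO (anti-image formula)
   and Bartlett's sphericity test report whether the correlations justify
   PCA weighting. Zero-variance indicators are dropped with a warning.
3. **Disturbance levels.** Ward hierarchical clustering of the 1-D GHI
   scores, cut at k = 4, labeled I–IV by decreasing mean GHI. Clustering
   operates on the composite scores, not the raw matrix, because the levels
   are meant to partition overall condition. Ties in cluster means break by
   the smallest member plot id, making labels deterministic.
4. **Thresholds.** Each diversity metric (Shannon, richness) is regressed
   on burrow density by loess — local polynomial of degree 2, tricube
   weights, span 0.75, no robustness iterations (the classical defaults;
   all configurable). The fitted curve is evaluated on a 512-point uniform
   grid; the threshold candidate is the grid argmax, ties broken toward the
   lower density (the protective choice). A peak on the grid boundary is
   flagged: it indicates a monotone (already-degraded) response with no
   interior optimum. The adopted threshold is the minimum candidate; if the
   candidates' relative spread (max − min)/max is below 0.005 the decision
   is labeled "negligible-difference" rather than "conservative". The
   denominator choice (max) is documented because either convention
   classifies near-coincident candidates identically.
5. **Change rates.** 100·(v − b)/b per metric and type, with b = mean over
   level-I plots and v = mean over plots above the 90th within-type
   percentile of burrow density. The comparison stratum is a design choice
   (the "highest density state" is not otherwise defined); the percentile
   is configurable.
6. **Spatial screen.** Plot coordinates → haversine distances (sphere,
   R = 6371 km) → dbMEM: truncation at the longest minimum-spanning-tree
   edge, beyond-threshold distances replaced by 4× the threshold (the
   classical principal-coordinates-of-neighbour-matrices construction),
   Gower double-centering of −d²/2, eigendecomposition, positive-eigenvalue
   axes retained broad-scale first. The Mantel screen correlates a
   diversity distance matrix with one predictor matrix at a time (spatial =
   Euclidean distance in retained MEM coordinates by default; burrow
   density, temperature, precipitation, TOC, pH as scalar Euclidean
   matrices), one-sided p from seeded row/column permutations, significance
   binned at p < 0.05 / p < 0.01 with *no* multiple-testing correction —
   deliberately mirroring common practice in such screens, and a caveat for
   interpretation. Wilcoxon rank-sum comparisons use exact enumeration for
   m + n ≤ 16 without ties, otherwise a tie- and continuity-corrected
   normal approximation.

## Synthetic-data generator

The generator targets the *statistical structure* of such a survey, not its
biology: no pika population dynamics, burrowing mechanics or soil
processes.

- **Design**: 30 AM + 26 AS plots, 3 quadrats each, rejection-sampled
  coordinates in a per-type 40×40 km box with a 1 km geodesic spacing floor
  (bounded at 10,000 attempts per point). Burrow densities are independent
  uniform draws over [0, 1200] holes/ha — the gradient is treated as an
  observed covariate with even expected coverage, since no sampling design
  along it is assumed.
- **Response curves**: each metric's expectation along the gradient is a
  Gaussian hump, baseline + amplitude·exp(−(d − peak)²/2·width²) — the
  minimal parameterization of a rise-then-fall response — except community
  height, which declines logistically (heights fall monotonically with
  disturbance). Default diversity peaks sit at 680/683 holes/ha (AM) and
  217/307 (AS): the meadow tolerates roughly three times the burrow density
  before its diversity turns down. Biomass peaks mid-gradient, cover and
  edible share peak at low-to-moderate disturbance, with levels chosen once
  at field-plausible magnitudes (meadow biomass ~120–210 g/m², steppe
  ~45–73 g/m²; meadow cover ~0.55–0.85, steppe ~0.25–0.40).
- **Communities**: quadrat richness is Poisson around its response mean;
  species are drawn from a fixed pool split between edible and inedible
  members so the edible-abundance share tracks its response curve;
  abundances are multinomial (120 individuals/quadrat) over symmetric
  Dirichlet weights whose concentration is solved from
  E[−Σ p ln p] = ψ(Sα+1) − ψ(α+1) to hit the target Shannon value —
  evenness is therefore tunable semi-independently of richness. Continuous
  metrics add Gaussian noise truncated at physical bounds (cover ∈ [0, 1],
  others ≥ 0).
- **Covariates**: per-type climatology (meadow ≈ 660 mm precipitation,
  TOC ≈ 4.7; steppe ≈ 155 mm, TOC ≈ 1.3) plus a mild north–south trend and
  plot-level noise, so spatial predictors carry weak but nonzero signal.
- **Seeding**: one master seed; every (plot, quadrat, metric) stream is
  keyed by a CRC-32 hash of its identifier, so identical seeds give
  byte-identical datasets and enlarging one type never reshuffles the other.

**What passing tests do and do not show.** The generator's responses are
smooth, unimodal and additive-noise; real vegetation data carry
zero-inflation, spatially autocorrelated residuals, observer effects and
quadrat-area bias (1 m² meadow vs 0.25 m² steppe quadrats are compared
without areal correction — the per-type analysis sidesteps, but does not
resolve, this). Recovery of configured peaks here therefore demonstrates
correctness of the estimation chain, not field-level accuracy of any
particular threshold.

## Numerical choices and degenerate inputs

- Loess windows use the ceil(span·n) nearest points; a window with fewer
  than degree + 1 positively weighted points raises an error naming the
  window. Grid argmax (512 points) is used instead of analytic
  optimization: loess surfaces are only piecewise smooth, and the grid
  makes the estimate deterministic at a resolution (~2 holes/ha on the
  default gradient) far below the estimator's sampling noise.
- Peak-recovery accuracy at survey size: with 56 plots, a 300-holes/ha peak
  of width 120 and 5–20% noise, the mean absolute peak error over 50 seeds
  is about 4–7% of the true peak at the default span. At the steppe's
  n = 26 the estimate is noticeably noisier — visible in the examples —
  which is a property of the design, not the estimator.
- Permutation p-values use the add-one convention (1 + #extreme)/(1 + B),
  so p ≥ 1/(B+1) and the test is exact-level; the exhaustive Mantel mode
  enumerates all n! relabelings instead.
- KMO requires an invertible correlation matrix; near-singularity (condition
  number > 1e12) raises an error naming the most collinear column pair.
- Hierarchical classification refuses k greater than the number of distinct
  scores; an explicitly bare quadrat contributes H = 0 and edible share 0.

## Known limitations

- No rarefaction or coverage-standardized richness; no factor rotation or
  alternative index families; no partial Mantel or variation partitioning;
  no confidence intervals on peak locations in the core path; thresholds
  are point estimates whose uncertainty at n ≈ 26–30 plots is substantial.
- Geodesic distances use a spherical Earth; ellipsoid corrections are
  negligible at the ≤ 50 km extents involved.
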