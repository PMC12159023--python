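# pikathresh

Disturbance-threshold analysis for alpine grasslands under plateau pika
(*Ochotona curzoniae*) burrowing.

Plateau pikas are both ecosystem engineers and, at high density, a driver of
grassland degradation on the Qinghai-Tibet Plateau. Management therefore
needs the burrow density at which each grassland type starts to degrade —
and that threshold differs between the wetter, more diverse **alpine meadow
(AM)** and the arid, sparser **alpine steppe (AS)**. `pikathresh` is a
library for ecologists working with plot/quadrat vegetation surveys along a
burrow-density gradient. It provides:

- **Community metrics** per quadrat and plot: Shannon-Wiener diversity
  H = −Σ pᵢ ln pᵢ (nats), species richness, aboveground biomass, community
  height, vegetation cover, edible-forage proportion, effective
  burrow-entrance density (holes/ha).
- **Grassland health index (GHI)** = Σᵢ vᵢwᵢ over min-max standardized
  indicators vᵢ (burrow density reversed) with PCA-derived weights wᵢ,
  plus KMO and Bartlett sampling-adequacy statistics, and Ward clustering of
  the scores into disturbance levels I (none) – IV (heavy).
- **Thresholds**: loess (local polynomial, tricube weights) response curves
  of each diversity metric against burrow density; the threshold is the
  fitted peak, and when metrics disagree the *minimum* candidate is adopted
  (conservative rule), unless they differ by under 0.5% (negligible
  difference).
- **Spatial/nonparametric statistics**: haversine distances, distance-based
  Moran's eigenvector maps (dbMEM), Moran's I, seeded permutation Mantel
  tests (with an exhaustive mode), Wilcoxon rank-sum with exact enumeration.
- **A seeded synthetic-survey generator** reproducing the two-type study
  design (30 AM + 26 AS plots of 1 ha, 3 quadrats each, ≥ 1 km apart) with
  hump-shaped ("rise then fall") metric responses, so the full pipeline is
  testable end-to-end without field data.

## Worked example

```python
from pikathresh import GeneratorConfig, generate_survey, build_plot_indicators, \
    diversity_thresholds, adopt_threshold

dataset = generate_survey(GeneratorConfig(seed=1))
indicators = build_plot_indicators(dataset.quadrats, dataset.plots)
for gtype in ("AM", "AS"):
    dec = diversity_thresholds(indicators, gtype)
    print(gtype, {m: round(v) for m, v in dec.candidates.items()},
          "->", round(dec.adopted), dec.principle)
print(adopt_threshold({"SW": 217.0, "SR": 307.0}).adopted)
```

prints

```
AM {'SW': 699, 'SR': 708} -> 699 conservative
AS {'SW': 73, 'SR': 77} -> 73 conservative
217.0
```

The first two lines are loess peak estimates of the Shannon (SW) and
richness (SR) responses on one synthetic survey: the steppe's diversity
peaks far earlier along the burrow gradient than the meadow's, so its
adopted management threshold is much lower. The last line applies the
adoption rule to a published steppe candidate pair — the minimum, 217
holes/ha, is adopted because it safeguards both diversity dimensions.

The same analysis runs end-to-end in one call (or via the `pikathresh` CLI):

```python
from pikathresh import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(seed=1, out_dir="out"))
```

which writes `plot_indicators.csv`, `ghi_scores.csv`, `thresholds.csv`,
`change_rates.csv`, `mantel_results.csv` and a `report.json`. See
`examples/` for one short script per capability.

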