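# pauniq — protected-area uniqueness from gridded species occurrences

`pauniq` is a Python library and CLI for quantifying the conservation
value ("uniqueness") of protected areas (PAs) — national parks and
biosphere reserves — from coarse, gridded species-occurrence data of the
kind EU member states report for the species listed in the Annexes of the
Birds and Habitats Directives. It is aimed at conservation biogeographers
who want a reproducible, multi-metric evaluation of a PA network rather
than a single prioritization score.

## The model

Occurrence data come as 10 km × 10 km grid cells per species, far coarser
than PA boundaries. Species are therefore assigned to PAs
probabilistically: if a PA covers fractions `c_1 … c_n` of the `n`
occupied cells of species *i*, the chain-rule probability that the
species occurs inside PA *j* is

    p_ij = 1 − ∏_k (1 − c_k)

From the resulting PA × species probability matrix the package computes,
per PA:

- **Richness_RS** = Σ_i p_ij — expected number of reported species;
- **Richness_SAR_%Surplus** — the residual from the best-fitting
  species–area relationship (SAR), expressed as a percentage of the
  fitted richness. Candidate SARs are the Arrhenius power model
  `S = b·A^c`, Gleason's semi-log model `S = y + z·ln A`, and a
  zero-intercept linear null `S = m·A`, compared by AIC;
- **Richness_Rarity_weighted** = Σ_i p_ij·w_i, with conservation weight
  `w_i = 1/(cells occupied by i across the whole land grid)`;
- **Rarity_Mean** = rarity-weighted richness / Richness_RS ∈ [0, 1];
- **Dissimilarity_Total / _Balanced / _Gradient** — per-PA mean of
  pairwise Bray–Curtis dissimilarities on the probability vectors,
  additively partitioned (Baselga 2013) into balanced (turnover-like)
  and gradient (nestedness-like) components, plus the SD of the pairwise
  totals.

A sensitivity layer probes how national reporting deficits distort these
metrics: a frequency-preserving null model (species redistributed
uniformly over land cells, occupied-cell counts conserved) with paired
Wilcoxon signed-rank tests per nation, unpaired rank-sum tests of each
nation against the rest of the region, leave-nations-out cross-validation
(per-PA SD across runs), and Pearson correlations between metrics with a
spatially corrected (Dutilleul-type) t-test.

A seeded synthetic-landscape generator (`pauniq.synthetic_data`) emulates
the statistical structure of such data — contiguous rectangular nations,
log-uniform PA sizes, a right-skewed species frequency spectrum, optional
spatial aggregation and per-nation under-reporting — so the whole
pipeline is testable without any external download.

## Worked example

```python
from pauniq import (
    ConservationWeights, build_matrix, metric_table,
    run_null_model_analysis, generate_dataset, preset_scenario,
)

# synthetic landscape: 12 nations, 10 PAs each, 350 species,
# with 50% of nation N03's occurrence records deleted
ds, truth = generate_dataset(preset_scenario("biased", seed=7))

P = build_matrix(ds.coverage, ds.occurrences)
weights = ConservationWeights.from_occurrences(ds.occurrences)
table, sel = metric_table(P, weights, ds.areas)
print(sel.selected, sel.best.params)
print(table.head(4).round(3))

report = run_null_model_analysis(ds, metrics=["richness_rs"],
                                 n_sims=200, seed=11)
print(report.table[["nation", "observed_median", "null_median",
                    "p_vs_null", "p_vs_rest"]].round(4))
```

prints (abridged):

```
gleason_exponential {'y': -77.7112, 'z': 19.3802}
        richness_rs  richness_sar_pct_surplus  richness_rarity_weighted  rarity_mean  dissimilarity_total
PA0001       51.518                     8.735                     1.495        0.029                0.467
PA0002       54.818                    17.531                     1.479        0.027                0.468
PA0003       33.426                    -1.658                     0.181        0.005                0.444
PA0004       34.357                     3.245                     0.238        0.007                0.443

nation  observed_median  null_median  p_vs_null  p_vs_rest
   N00          30.3248      30.0451     0.1309     0.8234
   ...
   N03          15.9192      25.1024     0.0020     0.0012
   ...
```

Each PA row reads as: PA0001 is expected to hold ~51.5 reported species,
8.7% more than a PA of its area typically holds, and its composition
differs from an average other PA by a Bray–Curtis distance of 0.47. In
the sensitivity table the under-reporting nation N03 stands out exactly
as intended: its PAs hold significantly fewer species than the null model
predicts for their footprints (p = 0.002) and than the rest of the region
(p = 0.0012), while the other nations stay unflagged.

The same pipeline is available from a shell:

```bash
pauniq simulate --preset biased --seed 7 --out-dir run/
pauniq metrics --grid run/grid.csv --occurrences run/occurrences.csv \
       --pas run/pas.csv --out-dir run/
pauniq sensitivity --grid run/grid.csv --occurrences run/occurrences.csv \
       --pas run/pas.csv --n-sims 200 --seed 11 --out-dir run/
```

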