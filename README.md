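# icemoor

Analyses for Arctic marine microbiome time series collected by moored
autonomous samplers — the setting where a community is observed weekly to
fortnightly over several annual cycles at sites contrasting in Atlantic
water (AW) influence and sea-ice cover, such as the marginal ice zone (MIZ)
and the densely ice-covered East Greenland Current (core-EGC) at ~79° N.

The package implements the bespoke computational stages such a study
needs, each exercisable end-to-end on synthetic data with planted ground
truth:

- **Occupancy partitioning.** ASVs are classified by detection frequency
  *f* over the sample series: resident (*f* > 0.90), intermittent
  (0.25 ≤ *f* ≤ 0.90), transient (*f* < 0.25). Per-sample summed relative
  abundances of the three fractions are correlated (Pearson) against
  environmental covariates; Bray-Curtis dissimilarities and two-site
  shared/unique ASV proportions round out the community-level view.
- **Oscillation co-occurrence networks.** Each ASV's series is gridded
  weekly, and per annual cycle the mean-removed DFT yields an oscillation
  signal (harmonics 1..K as amplitude/phase). Pairwise Pearson
  correlations of signal vectors are Benjamini–Hochberg adjusted; edges
  with r > 0, r ≥ t, p_adj < α are retained. The cutoff t is selected by
  robustness analysis: the largest grid value at which the network's giant
  component is biconnected, i.e. survives any single node removal. Degree,
  betweenness and closeness centralities summarise the result.
- **Environmental signatures.** ASVs whose relative abundance correlates
  with ≥1 covariate at |r| > 0.4, p < 0.05 are clustered by their full
  correlation profiles (agglomerative, average linkage); clusters are
  summarised by prominent genera (members ≥ 1% maximum relative abundance,
  maximum per genus).
- **Long-read LCA classification.** ORF-level protein hits (BLAST/DIAMOND
  tabular + query coverage) pass a two-stage filter — identity ≥ 50%,
  query cover ≥ 60%, bitscore within 5% of the ORF's best, then identity
  > 65% and e-value < 1e-10 — before a lowest-common-ancestor walk over
  GTDB-style lineages per ORF, then per read. Gene counts are normalised
  by the mean depth of 16 universal single-copy ribosomal proteins to give
  copies per genome equivalent.
- **Genome quantification.** TAD80, the 80% truncated average sequencing
  depth (sort per-position depths, drop the top and bottom 10% of
  positions, average the rest), with relative abundance = TAD80 / marker
  mean depth and detection at ≥ 1× truncated coverage.

## Worked example

```python
import pandas as pd
from icemoor import (
    synthetic, occupancy_table, classify_occupancy, detection_frequency,
    group_abundance_series, fraction_env_correlation,
)

env = synthetic.generate_env_series(
    n_years=2, site="MIZ", sampling_interval_days=7, seed=7
)
matrix, truth = synthetic.generate_community(
    env, n_resident=40, n_intermittent=120, n_transient=140,
    depth_per_sample=50_000, noise=1.5, seed=8,
)
table = occupancy_table(matrix)
print(table["group"].value_counts().to_string())
records = classify_occupancy(detection_frequency(matrix))
series = group_abundance_series(matrix, records)
for g in ("resident", "intermittent", "transient"):
    r, p = fraction_env_correlation(series[g], env["aw_fraction"])
    print(f"{g:>12} fraction vs AW: r = {r:+.2f}, p = {p:.3g}")
print(f"planted labels recovered: "
      f"{100 * (table['group'] == pd.Series(truth.asv_labels)).mean():.1f}%")
```

prints

```
group
transient       140
intermittent    120
resident         40
    resident fraction vs AW: r = -0.94, p = 2.79e-50
intermittent fraction vs AW: r = +0.95, p = 1.43e-53
   transient fraction vs AW: r = -0.33, p = 0.000516
planted labels recovered: 100.0%
```

The occupancy classifier recovers every planted group label, and the
fraction–environment correlations show the planted sign structure: the
intermittent fraction rises with AW influx while the resident and
transient fractions recede — the compositional signature of advected
populations overprinting a stable resident community.

A `icemoor` console script exposes the same stages on TSV files
(`simulate`, `occupancy`, `network`, `signatures`, `lca`, `magabund`);
see `icemoor --help`.

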