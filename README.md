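# fosnet

Network-level analysis of regional immediate-early-gene activation counts:
from per-animal count tables to thresholded interregional functional
networks, centrality metrics, clustering-matched small-world null
comparisons, and community structure — plus a synthetic-cohort generator
with planted correlation structure so the whole pipeline is testable
without any external data.

## Pipeline

1. **Counts** (`fosnet.counts`) — read/validate per-animal, per-region count
   CSVs (`animal_id, group, <region columns>`), normalize to a control
   group's per-region mean, compute the behavioral generalization index
   `B / (A + B)`.
2. **Connectivity** (`fosnet.connectivity`) — per-group region×region
   Pearson correlation matrices (zeroed diagonal), r-value extraction
   overall and per region collection (Amyg/HPC/PFC/Other), Kruskal–Wallis +
   Mann–Whitney group comparisons.
3. **Network construction** (`fosnet.networks`) — one pooled cutoff
   (mean + 1 sample SD of all groups' off-diagonal r values), weighted
   undirected graphs keeping edges with r strictly above it; isolated nodes
   retained; negative correlations never retained.
4. **Metrics** (`fosnet.metrics`) — degree; unnormalized fractional
   betweenness on unweighted geodesics; nodal/global efficiency on weighted
   shortest paths with edge length `1/r` (disconnected pairs contribute 0);
   average local clustering; descending average-rank node rankings.
5. **Small-world null** (`fosnet.smallworld`) — ring-lattice rewired
   (Watts–Strogatz) ensembles, density-matched via even `k` from the mean
   degree, rewiring probability tuned by Monte-Carlo bisection to the memory
   network's clustering coefficient; percentile interval of the
   per-replicate efficiency differences (null − memory).
6. **Communities** (`fosnet.communities`) — deterministic leading-eigenvector
   bisection of the weighted modularity matrix, no refinement step,
   singleton communities for isolated nodes.
7. **Stats** (`fosnet.stats`) — native Kruskal–Wallis (tie-corrected),
   Mann–Whitney U (exact for combined n ≤ 20 without ties, tie-corrected
   normal approximation with continuity correction otherwise), percentile
   mean-difference intervals (type-7 quantiles). Cross-checked against scipy
   in the test suite.
8. **Synthetic cohorts** (`fosnet.synthetic`) — latent Gaussian copula with
   lognormal margins (per-region mean and CV) and a planted PSD latent
   correlation matrix per group; the `paperlike` preset emulates
   3 groups × 8 animals × 12 regions with a near-independent control, a
   globally correlated mild-memory group, and an amygdala-block-only
   strong-memory group.

## CLI

```bash
# generate a synthetic cohort (3 groups x 8 animals x 12 regions)
fosnet simulate --preset paperlike --n 8 --seed 1 --out counts.csv

# run the full analysis
fosnet analyze --counts counts.csv --control NS --reps 1000 --seed 1 --out results_dir
```

`fosnet analyze` writes per-group correlation matrices and r-value lists
(CSV), edge lists (CSV) and GraphML networks, metric tables with ranks
(CSV), null-comparison replicate efficiencies (CSV), community assignments
(CSV), and a machine-readable `report.json`. Runs are deterministic given
the inputs and `--seed`, and an existing non-empty output directory is
refused unless `--force` is passed.

## Conventions worth knowing

- Thresholding uses signed r (the pooled mean+SD cutoff is applied to raw
  correlations), so negative edges can never survive.
- Betweenness and efficiency deliberately use different path definitions
  (edge count vs `1/r` length).
- Null networks carry unit edge weights; the memory network keeps its `1/r`
  distances in the comparison.
- Collection r-value comparisons default to "incident" pair membership (at
  least one endpoint in the collection); `--collection-rule within`
  restricts to pairs inside the collection.
- The null ensemble's rewiring probability is floored at 0.02 so the
  percentile interval never degenerates to a point mass.
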