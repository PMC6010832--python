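# lekgraph

Genetic network analysis for lek-breeding populations. From multilocus
microsatellite genotypes and lek coordinates, `lekgraph`:

1. quality-controls samples (amplification-failure filtering, duplicate
   genotype removal, probability of identity, allele-ladder checks);
2. clusters leks into nodes by great-circle distance (complete-linkage
   hierarchical clustering, configurable cut, minimum node size);
3. fits a **conditional genetic covariance network**: genotypes are encoded
   as per-allele contribution vectors, squared distances between node mean
   vectors are Gower-centered into a covariance matrix, and an edge is
   retained only when its partial correlation survives an edge-exclusion
   deviance test against the chi-square(1) critical value;
4. derives the minimum spanning tree, conditional genetic distances, and
   six node centrality indices (degree, strength, betweenness, closeness,
   clustering coefficient, eigenvector);
5. tests network structure (regular / random / small-world / scale-free)
   against an Erdos-Renyi ensemble matched on nodes, edges, and edge-weight
   distribution, with permutation p-values and bootstrap uncertainty;
6. ranks nodes into hubs, spokes, and **keystone nodes** (high centrality
   despite low lek attendance or peripheral range position).

A stepping-stone Wright-Fisher simulator (with optional planted hub demes)
generates fully synthetic input bundles, so the entire pipeline is testable
without any field data.

## CLI

All stages run behind one command. Each subcommand accepts `--config`
(YAML), `--seed`, and `--out`; exit codes are 0 (ok), 1 (user error),
2 (internal error).

```sh
lekgraph run --seed 1 --out out/                # simulate + full pipeline
lekgraph simulate --seed 1 --out out/          # just write a fixture bundle
lekgraph qc --config my.yaml --out out/        # stages are individually
lekgraph cluster --config my.yaml --out out/   # re-runnable from the
lekgraph graph --config my.yaml --out out/     # previous stage's outputs
lekgraph analyze --config my.yaml --out out/
lekgraph prioritize --config my.yaml --out out/
```

A config file overrides the defaults in `lekgraph.pipeline.DEFAULT_CONFIG`,
e.g.:

```yaml
inputs:
  genotypes: data/genotypes.csv
  lek_counts: data/lek_counts.csv
clustering: {cut_km: 15.0, min_node_size: 4}
graph: {alpha: 0.05, tolerance: 1.0e-4}
analysis: {null_B: 1000, bootstrap_B: 1000, bootstrap_fraction: 0.75}
```

The effective config, a run manifest (seeds, per-stage counts), and every
intermediate table are written to the output directory: node table, edge
list, GraphML network, covariance and partial-correlation matrices, MST
edges, conditional genetic distances, centrality table with ranks,
null-model comparison JSON, bootstrap summaries, Spearman correlation
matrices, prioritization report, and a Markdown summary.

## Genotype CSV dialect

One row per sample: `sample_id, lek_id, lat, lon, source`, then two integer
columns per locus named `<locus>_1` / `<locus>_2` (allele lengths in base
pairs). Missing genotypes are `0` or empty in both columns; a half-missing
call is coerced to missing with a warning. Coordinates are WGS84 decimal
degrees. `lekgraph.io.split_concatenated_calls` converts GENEPOP-style
concatenated columns (`"150152"`) into this dialect.

Lek counts: `lek_id, year, high_male_count` (or `count`), at most one row
per lek and year.

## Notes on conventions

- Characteristic path length is computed on unweighted hops; betweenness
  and closeness treat edge weight as a distance; strength and eigenvector
  centrality treat it as connection mass. Closeness is
  1 / (summed weighted shortest-path distance), larger = more central.
- The clustering coefficient is unweighted and undefined (NA) below
  degree 2; network means exclude NA nodes.
- Eigenvector centrality is scaled so its maximum is 1 on the network.
- The deviance sample size `n_eff` in edge pruning defaults to the number
  of genotyped individuals when fitting from data (`build_popgraph`), and
  to the node count when calling `fit_conditional_graph` directly; both
  are overridable and logged.
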