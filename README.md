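# ncycnet

Co-occurrence network analysis of nitrogen-cycle functional-gene abundances
measured by high-throughput qPCR (HT-qPCR) in soil.

Soil microbes drive the nitrogen cycle through sequential enzymatic steps —
nitrification (*amoA*, *hao*, *nxrB*), denitrification (*napA*/*narG*,
*nirK*/*nirS*, *nosZ*), N fixation (*nifH*), DNRA (*nrfA*) and anammox
(*hzo*).  HT-qPCR arrays quantify dozens of these gene targets in hundreds
of samples at once, and correlation networks built from those abundances
reveal which functions co-occur, how tightly the functional community is
organised across seasons, and which genes occupy central ("keystone")
positions.  `ncycnet` implements that analysis as a reusable, tested
pipeline, aimed at soil microbial ecologists working with functional-gene
panels across a temporal or spatial design.

## The method

For each grouping cell (location × timepoint):

1. **Correlation.** Spearman's ρ between every assay pair over
   pairwise-complete samples (ties mid-ranked; non-detects masked, never
   zero-filled).  Two-sided p-values from the t approximation
   t = ρ√((n−2)/(1−ρ²)) on n−2 df.
2. **FDR control.** Benjamini–Hochberg adjustment over the cell's
   upper-triangle tests.
3. **Thresholding.** An undirected edge for every pair with |ρ| > 0.75 and
   BH-adjusted p < 0.01 (both strict; defaults configurable).  Networks are
   simplified: no self-loops, no isolated nodes.
4. **Consensus.** Per-timepoint intersection across locations (nodes and
   edges present in *both* parents), then a global consensus across all
   timepoints — the seasonally stable co-occurrence backbone.
5. **Statistics.** Density m/C(n,2), global transitivity
   C = 3·triangles/triples, average path length L over mutually reachable
   pairs, Girvan–Newman modules, and per-node betweenness, closeness and
   normalized degree.
6. **Null comparison.** Erdős–Rényi G(n, m) ensembles matched on nodes and
   edges; response ratio RR = C_obs/C_random and LRR = ln(RR); a network is
   "random-like" when C_obs sits inside the central 95% of the null
   distribution.
7. **Keystones.** Within the nitrification and denitrification pathways of
   each network, an assay topping at least two of {betweenness, closeness,
   normalized degree} (ties inclusive).

Because every inference step is rank-based, the networks are identical on
raw copies g⁻¹ and on log₁₀ copies g⁻¹ — the pipeline asserts this.

A synthetic-data generator with known ground truth (Gaussian copula with
block correlation structure and a seasonal block schedule) supports
calibration and recovery testing end to end.

## Worked example

```python
import ncycnet as nn

config = nn.PipelineConfig(
    synth=nn.SynthConfig(seed=1), seed=1, null_reps=1000, outdir="out"
)
result = nn.run_pipeline(config)
cols = ["network_id", "n_nodes", "n_edges", "density_2dp", "c_obs_2dp",
        "c_random_mean_2dp", "l_obs_2dp", "l_random_mean_2dp", "rr_2dp", "lrr_2dp"]
print(result.stats_table[cols].to_string(index=False))
print("consensus edges:", [tuple(sorted(e)) for e in result.consensus.edges])
```

prints

```
     network_id  n_nodes  n_edges density_2dp c_obs_2dp c_random_mean_2dp l_obs_2dp l_random_mean_2dp rr_2dp lrr_2dp
intersection_t1       15       28        0.27      0.97              0.25      1.10              2.02   3.84    1.35
intersection_t2        9       16        0.44      1.00              0.41      1.00              1.64   2.44    0.89
intersection_t3        8       12        0.43      1.00              0.38      1.00              1.68   2.64    0.97
intersection_t4        7        8        0.38      0.92              0.30      1.11              1.78   3.09    1.13
intersection_t5        6        6        0.40      1.00              0.29      1.00              1.75   3.47    1.25
intersection_t6        4        2        0.33      0.00              0.00      1.00              1.26
consensus edges: [('Arch_amoA', 'Beta_amoA')]
```

Reading the table: the per-timepoint intersection networks shrink from 15
nodes in the first (dense, dry-season-like) timepoint to 4 nodes in the
last, mirroring the generator's seasonal block schedule.  Observed
clustering C_obs far exceeds the size-matched random expectation
C_random_mean (RR between 2.4 and 3.8) in the first five timepoints — the
small-world signature of genuinely block-structured co-occurrence — while
the sparsest final network (two disconnected dyads, so C_obs = 0) cannot be
distinguished from random.  The global consensus keeps only the single
planted co-occurrence that survived thresholding in all twelve per-cell
networks.  A run also writes `stats.csv`, `keystones.csv`,
`betweenness_timeline.csv`, GraphML/TSV exports of every network, and a
`manifest.json`; reruns with the same seed are byte-identical.

The same pipeline runs from the command line:

```bash
ncyc simulate --seed 1 --out data/
ncyc run --config config.yaml --out results/
ncyc null --nodes 9 --edges 16 --reps 1000 --seed 1
```

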