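# pathprop

Network-propagation pathway enrichment analysis for gene expression data.

## The problem

Pathway enrichment methods such as preranked GSEA assume that the genes of a
perturbed pathway move coherently — all up or all down. Real disease
pathways often show *mixed* expression patterns, and classical enrichment
statistics let the two directions cancel. Genes also do not act in
isolation: perturbation spreads through protein–protein interactions, so a
pathway can be impacted even when several of its members show weak or
missing scores.

`pathprop` addresses both issues. Signed gene scores (e.g. log2 fold
changes) are converted to absolute values and diffused over a
protein–protein interaction (PPI) network by random walk with restart
(RWR):

```
p_k = α p0 + (1 − α) W p_{k−1},      W = D^{−1/2} A D^{−1/2}
```

where `p0` holds the absolute gene scores, `A` is the network adjacency
matrix, `D` its diagonal degree matrix and `α` the restart probability
(default 0.2). The fixed point `α (I − (1−α)W)^{−1} p0` amplifies signals
shared by connected genes.

Propagated scores are then tested per pathway with a three-stage cascade:

1. **Kolmogorov–Smirnov** — distribution of pathway scores vs the
   background of all other scored genes;
2. **Mann–Whitney U** — rank-based validation, run only on K–S survivors;
3. **permutation test** — the observed mean pathway score against means of
   10 000 random gene sets of the same size (add-one empirical p-value).

Benjamini–Hochberg correction is applied after each stage; a pathway is
significant when both its K–S and Mann–Whitney adjusted p-values are ≤ 0.05,
and the permutation stage refines the ranking of significant pathways.

The package also implements the standard comparators over a shared
preranked enrichment core (weighted Kolmogorov–Smirnov running-sum
statistic, gene-label permutation null): signed **GSEA**, absolute-value
**ABS GSEA**, and **NGSEA** neighbor averaging
(`NS_i = |x_i| + mean of neighbor |x_j|`), plus a synthetic benchmark
generator that plants a connected mixed-sign signal module so the whole
pipeline can be evaluated without external data.

## Worked example

```python
from pathprop import RunConfig, SynthConfig, generate, rank_of_pathway, run_method

data = generate(SynthConfig(seed=42))          # 500 genes, 1 planted module
cfg = RunConfig(method="netprop", n_perm=10_000, seed=42, min_size=1)
table, manifest = run_method(cfg, data.scores, data.network, data.collection)
print(table.head())
```

prints (see `examples/run_enrichment.py`):

```
  pathway  effective_size direction       ks_fdr       mw_fdr  perm_fdr  significant  rank
SIGNAL_01              35        up 2.161125e-51 2.839149e-23    0.0001         True     1
DECOY_027              40        up 6.292034e-01          NaN       NaN        False     2
DECOY_029              20        up 6.292034e-01          NaN       NaN        False     3
```

The planted module — large |score| but mixed signs, invisible to signed
enrichment by design — is recovered at rank 1 with all three cascade stages
populated; random decoy pathways never leave stage 1 (`NaN` marks stages
that were not reached). `direction` classifies the pathway as up- or
down-regulated from the mean signed score of its members.

`examples/compare_methods.py` benchmarks all four methods on eight
synthetic datasets at moderate signal strength and prints the per-dataset
rank of the true pathway together with paired Wilcoxon signed-rank tests —
propagation and absolute-value methods rank the mixed-sign module first
throughout, while signed GSEA trails (mean rank difference −3.6,
p = 0.0078).

A thin command-line interface mirrors the library:

```sh
pathprop synth --n-genes 500 --seed 7 --out data/
pathprop run --rnk data/scores.rnk --network data/network.edgelist \
    --gmt data/pathways.gmt --method netprop --alpha 0.2 --seed 7 --out run/
pathprop compare --runs run_netprop --runs run_gsea \
    --targets targets.tsv --out cmp/
```

Inputs are plain text: two-column `.rnk` score lists, tab-delimited edge
lists (SIF-style lines are accepted), and GMT pathway collections; pathway
size filtering retains sets with 15–500 members by default.

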