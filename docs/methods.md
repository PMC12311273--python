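# Methods

## Model

`pathprop` scores pathways on the premise that disease-relevant
perturbation is (a) directionally mixed within a pathway and (b) locally
coherent on the protein–protein interaction (PPI) network. Signed gene
scores are therefore reduced to magnitudes before any network computation,
and magnitudes are smoothed by random walk with restart (RWR):

    p_k = α p0 + (1 − α) W p_{k−1}

with `W = D^{−1/2} A D^{−1/2}` the symmetric normalization of the adjacency
matrix. Because the spectral radius of `W` is at most 1, the map is a
contraction for α ∈ (0, 1] with a unique fixed point
`α (I − (1−α) W)^{−1} p0`; the iterative solver converges geometrically with
ratio ≤ (1 − α) and the closed-form solve of the same linear system serves
as an independent oracle in the test suite.

Assumptions worth stating explicitly: the network is undirected with
non-negative weights; edge semantics are uniform (no signs or directions);
and the input scores are comparable in magnitude across genes (log2 fold
changes or moderated statistics qualify, raw counts do not).

### Handling of degenerate structure

* Degree-zero nodes get zero rows/columns in `W` rather than an error —
  intersecting real score lists with real networks routinely produces
  isolated nodes, and the fixed point remains well defined
  (`p[i] = α p0[i]`).
* `W` is computed entrywise as `a_ij / sqrt(d_i d_j)` with a single square
  root; this keeps rational entries exact (a k-regular graph yields exactly
  `A/k`), which matters only for reproducibility guarantees, not accuracy.
* Network genes missing from the score list are zero-filled rather than
  dropped, keeping the diffusion operator intact; score genes missing from
  the network are dropped and counted. Both counts are logged and recorded
  in the run manifest.
* Self-loops are preserved if a file explicitly lists them, with a warning;
  duplicate edges keep the maximum weight (deterministic and
  order-independent).
* Input scores are not renormalized before propagation: all downstream
  tests are rank-based, hence invariant to overall scale, and keeping the
  raw magnitudes simplifies interpretation. An L1-normalization switch
  (`PropagationConfig.normalize_input`) exists for cross-dataset
  comparability.

## The statistical cascade

Per pathway, on the propagated scores over the network universe:

1. **Kolmogorov–Smirnov**, pathway members vs all non-members;
2. **Mann–Whitney U** (tie-corrected), only for pathways whose K–S
   Benjamini–Hochberg-adjusted p is ≤ the threshold;
3. **permutation test**: observed statistic = mean propagated score of the
   pathway's effective members; null = the same statistic for `n_perm`
   uniformly drawn gene sets of identical size (without replacement within
   a draw, members included in the sampling universe); empirical
   p = (1 + #{null ≥ observed}) / (1 + n_perm).

BH correction is applied after each stage *within the set of pathways
tested at that stage* (a `bh_scope="global"` switch corrects over all
stage-1 pathways instead). Significance requires both the K–S and
Mann–Whitney adjusted values at or below the threshold; the permutation
stage does not gate the significance call and is used to refine the
ranking of significant pathways. Final ordering: significant pathways by
(perm FDR, MW FDR, KS FDR, KS p, name), the rest by (KS FDR, KS p, name) —
the pathway name is always the last key so output is deterministic.

Design choices that were genuinely open:

* **Sidedness.** Propagating absolute values makes enrichment
  one-directional — a perturbed pathway can only have *larger* propagated
  scores — so both rank tests default to the one-sided "greater"
  alternative (`alternative="two-sided"` restores symmetric behavior).
* **Permutation statistic.** The mean is the simplest size-comparable
  location statistic; a `statistic="median"` option is provided.
* **Add-one estimator.** Matches the rank-of-observed-in-null reading of an
  empirical p-value and can never return 0.
* **Per-pathway seeding.** Each pathway's generator seed is derived by
  SHA-256 from (master seed, pathway name), so results are independent of
  pathway iteration order and stable across runs.
* **Direction call.** A pathway is labeled up/down by the sign of the mean
  *raw* (signed) score of its members, mean exactly 0 resolving to "up".

Defaults: α = 0.2, tol = 1e−6 (L1), max_iter = 1000, threshold = 0.05,
n_perm = 10 000, pathway size filter 15–500 (inclusive, applied to full
member sets before network intersection; effective sizes — members present
in the scored universe — are tracked separately, with a floor of 2 for
testability).

## Preranked comparator core

Signed GSEA, absolute-value GSEA and NGSEA neighbor averaging
(`NS_i = |x_i| + (1/n_i) Σ_j |x_j|`; an isolated gene keeps `|x_i|`, the
continuous limit of a vanishing neighbor term) run through one shared
preranked engine so that method comparisons are not confounded by
implementation differences:

* descending score sort with ascending-name tie-break;
* running sum: +`|s|^w / NR` at member hits (`NR` = sum over members),
  −`1/(N−m)` at misses; ES = signed maximum deviation, computed only at
  its candidate extrema (immediately after a hit / immediately before the
  next hit), which makes the gene-label permutation null vectorizable;
* weight exponent default 1 (the classic choice);
* nominal p from the same-sign null tail with an add-one estimator; NES by
  same-sign null-mean normalization; FDR q by the standard pooled
  normalized-ES procedure, clipped to [0, 1];
* result ordering by (nominal p, FDR q, |NES| descending, name).

Numerical details: the hit increment normalizer is the cumulative sum's own
last element, so a pathway occupying the top m ranks scores ES = +1
*exactly*; when the maximal positive and negative deviations tie, the
positive one wins, with a 1e−12 epsilon so the choice cannot flip on
sub-ulp noise; all-zero hit weights (possible at w > 0 with zero scores)
fall back to rank-only increments. Enrichment scores were cross-checked
against an independent brute-force walk and against GSEApy on identical
inputs.

The Benjamini–Hochberg step-up is implemented directly (sort, scale by
n/rank, reverse cumulative minimum, cap at 1) and cross-checked against
statsmodels in the test suite.

## Synthetic benchmark generator

The generator emulates the benchmark regime in which each dataset has one
known associated pathway: background genes draw signed Normal(0, σ²)
scores; the planted module's members receive magnitude `|N(0, σ²)| + δ`
with i.i.d. random signs, so the module is invisible to directional
statistics by construction while its magnitude profile and network
coherence remain; when `signal_connected` is set the module is grown
breadth-first from a random seed node (sorted neighbor order, retried from
multiple seeds, erroring with a hint if the graph is too sparse). Decoys
are uniform random gene sets. Defaults — 500 genes, Erdős–Rényi edge
probability 0.02 (mean degree ≈ 10), 50 pathways of 15–40 members, one
signal module, δ = 3σ — are sized so a full four-method run over 20
replicate datasets completes in well under a minute.

What the generator does *not* emulate: heavy-tailed score distributions,
correlated noise between network neighbors, pathway–pathway overlap, hub
bias of disease genes, or measurement missingness. Passing tests therefore
demonstrate correctness of the machinery and the qualitative behavior of
the methods under idealized conditions, not performance on real expression
data. One consequence is worth spelling out: with Gaussian background, a
δ = 3σ module occupies the global score extremes, and *every* method —
including signed GSEA, whose one-tailed running sum still accumulates half
the module at the top of the list — recovers it at rank ~1. The methods
separate in the moderate-signal regime (δ ≈ 0.75–1σ), where signed GSEA's
median rank degrades to 3–9 while the propagation and absolute-value
methods stay at 1; `examples/compare_methods.py` demonstrates this regime.

The edge-list writer emits only nodes with at least one edge; a fully
isolated node survives the in-memory round trip via the .rnk universe but
not via the edge-list file. This is inherent to the two-column format and
only affects file-based runs on graphs with isolated nodes.

## Evaluation protocol

A method's performance on a dataset is the 1-based rank of the known
associated pathway in its significance-sorted output; rank vectors of two
methods are compared with the two-sided Wilcoxon signed-rank test on paired
ranks (all-tied pairs short-circuit to p = 1; a single dataset reports win
counts with p marked not applicable). Wilcoxon p-values were cross-checked
against R's `wilcox.test(paired = TRUE)`.

## Problem sizes used in checks

The automated checks run at desk scale by choice: propagation solver
agreement on 25 random graphs up to 200 nodes; null calibration on 20
replicate pure-null datasets of 200 decoy pathways each (4 000 tests);
permutation exactness against exhaustive enumeration of all C(12,3)
subsets; enrichment-score bounds on 1 000 random pathway/ranking pairs; and
planted-signal recovery over 20 replicate datasets of 500 genes and 50
pathways.

## Known limitations

* No gene-level leading-edge extraction, pathway cross-talk correction, or
  signed/directed network support.
* The FDR q of the preranked core follows the standard pooled-NES recipe
  without the extra monotonicity enforcement some implementations add;
  q-values of marginal pathways can be slightly non-monotone in |NES|.
* Identifier matching is case-sensitive by default (a fold-case switch
  exists on the readers); no identifier-namespace conversion is attempted.
* With very small universes the one-sided Kolmogorov–Smirnov p-values are
  discrete and conservative; calibration was verified at universe sizes of
  a few hundred genes.
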