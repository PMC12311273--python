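"""Comparator enrichment methods sharing one preranked core.

Three transforms feed a common preranked enrichment engine:

* ``gsea`` — signed scores unchanged (classic preranked GSEA);
* ``abs_gsea`` — absolute values before ranking, so coordinated but
  mixed-direction perturbation is not cancelled;
* ``ngsea`` — each gene's absolute score plus the average absolute score of
  its immediate network neighbors, NS_i = |x_i| + (1/n_i) sum_j |x_j|
  (an isolated gene keeps NS_i = |x_i|).

The preranked core is implemented here rather than delegated so that all
methods share identical permutation machinery and tie handling: genes are
sorted by descending score (name-ascending tie-break); walking down the
list, the running sum gains |score|^weight / NR at member hits (NR the sum
over members) and loses 1/(N-m) at misses; the enrichment score ES is the
signed maximum deviation from zero.  The null is a gene-label permutation
(random member sets of the same size scored by the same walk), nominal p
comes from the same-sign null tail with an add-one estimator, and FDR q
follows the standard normalized-ES pooling procedure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .enrichment import child_seed, _CHUNK_BUDGET
from .genesets import PathwayCollection, effective_pathway_sizes
from .graph_io import PPINetwork
from .propagation import GeneScoreVector, intersect_with_network, to_absolute

logger = logging.getLogger(__name__)

__all__ = ["ngsea_transform", "abs_transform", "prerank_enrichment",
           "run_baseline", "BASELINE_METHODS"]

BASELINE_METHODS = ("gsea", "abs_gsea", "ngsea")
DEFAULT_PRERANK_PERM = 1000

BASELINE_COLUMNS = ["pathway", "effective_size", "es", "nes", "nominal_p",
                    "fdr_q", "rank"]


def abs_transform(scores: GeneScoreVector) -> GeneScoreVector:
    """Absolute-value transform (alias of :func:`pathprop.to_absolute`)."""
    return to_absolute(scores)


def ngsea_transform(scores: GeneScoreVector, net: PPINetwork) -> GeneScoreVector:
    """Neighbor-smoothed absolute scores NS_i = |x_i| + mean_j |x_j|.

    The neighbor average is unweighted (each of the n_i immediate neighbors
    contributes equally); a degree-zero gene keeps its own absolute score,
    the continuous limit of a vanishing neighbor term.  Scores must already
    be aligned to the network node order.
    """
    if scores.genes != list(net.nodes):
        raise ValueError("scores must be aligned to the network; "
                         "run intersect_with_network first")
    absx = np.abs(scores.scores)
    binary = sp.csr_array((np.ones_like(net.adjacency.data),
                           net.adjacency.indices, net.adjacency.indptr),
                          shape=net.adjacency.shape)
    counts = np.asarray(binary.sum(axis=1)).ravel()
    sums = binary @ absx
    with np.errstate(invalid="ignore"):
        neighbor_mean = np.where(counts > 0, sums / np.where(counts > 0, counts, 1),
                                 0.0)
    return GeneScoreVector(
        genes=list(scores.genes),
        scores=absx + neighbor_mean,
        provenance="ngsea",
    )


def _rank_genes(scores: GeneScoreVector) -> tuple[list[str], np.ndarray]:
    """Descending score order with ascending-name tie-break."""
    names = np.asarray(scores.genes, dtype=object)
    order = np.lexsort((names, -scores.scores))
    return [str(g) for g in names[order]], scores.scores[order]


def _es_from_positions(
    pos_sorted: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """Enrichment score(s) from sorted 0-based hit positions.

    ``pos_sorted``/``weights`` are (batch, m); the running sum only attains
    extrema immediately after a hit (candidate maxima) or immediately before
    the next hit (candidate minima), so the full walk never needs to be
    materialized.
    """
    batch, m = pos_sorted.shape
    miss_step = 1.0 / (n - m)
    cw = np.cumsum(weights, axis=1)
    # normalizing by the cumulative sum's own last element keeps the final
    # increment landing on exactly 1 (so the top-m pathway scores ES = +1)
    tw = cw[:, -1]
    hit_cum = cw / np.where(tw > 0, tw, 1.0)[:, None]
    # degenerate all-zero weights: fall back to equal increments (rank-only)
    flat = (tw <= 0)
    if np.any(flat):
        hit_cum[flat] = (np.arange(1, m + 1, dtype=float) / m)[None, :]
    k = np.arange(1, m + 1, dtype=float)[None, :]
    after_hit = hit_cum - (pos_sorted + 1.0 - k) * miss_step
    before_hit = np.concatenate(
        [np.zeros((batch, 1)), hit_cum[:, :-1]], axis=1
    ) - (pos_sorted - (k - 1.0)) * miss_step
    max_dev = np.maximum(after_hit.max(axis=1), 0.0)
    min_dev = np.minimum(before_hit.min(axis=1), 0.0)
    # positive deviation wins exact ties; the epsilon keeps the choice stable
    # against sub-ulp noise between mathematically tied extremes
    return np.where(max_dev + min_dev >= -1e-12, max_dev, min_dev)


def enrichment_score(
    ranked_scores: np.ndarray, hit_positions: np.ndarray, weight: float = 1.0
) -> float:
    """ES of one pathway given its hit positions in a ranked score list."""
    n = ranked_scores.size
    m = hit_positions.size
    if not 0 < m < n:
        raise ValueError("pathway must hit a strict nonempty subset of ranks")
    pos = np.sort(np.asarray(hit_positions, dtype=np.int64))[None, :]
    w_all = np.abs(ranked_scores) ** weight
    w = w_all[pos]
    return float(_es_from_positions(pos, w, n)[0])


def _null_es(
    w_all: np.ndarray, m: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Gene-label-permutation null: ES of random size-m member sets."""
    n = w_all.size
    chunk = max(1, min(n_perm, _CHUNK_BUDGET // n))
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        take = min(chunk, n_perm - done)
        keys = rng.random((take, n))
        pos = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
        w = w_all[pos]
        out[done:done + take] = _es_from_positions(pos, w, n)
        done += take
    return out


def prerank_enrichment(
    scores: GeneScoreVector,
    col: PathwayCollection,
    n_perm: int = DEFAULT_PRERANK_PERM,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked enrichment over a collection: ES, NES, nominal p and FDR q.

    Pathways with effective size 0, or covering the whole ranked list, are
    skipped.  Output rows are ordered by the final significance ranking
    (nominal p, then FDR q, then descending |NES|, then name).
    """
    ranked_genes, ranked_scores = _rank_genes(scores)
    n = len(ranked_genes)
    pos_of = {g: i for i, g in enumerate(ranked_genes)}
    w_all = np.abs(ranked_scores) ** weight

    records = []
    null_nes_pool: list[np.ndarray] = []
    for p in col.pathways:
        hits = np.array(sorted(pos_of[g] for g in p.members if g in pos_of),
                        dtype=np.int64)
        m = hits.size
        if m == 0 or m >= n:
            logger.info("skipping pathway %s (effective size %d of %d)",
                        p.name, m, n)
            continue
        es = enrichment_score(ranked_scores, hits, weight)
        rng = np.random.default_rng(child_seed(seed, p.name))
        null = _null_es(w_all, m, n_perm, rng)
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.nan
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.nan
        if es >= 0:
            nes = es / mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else 0.0
            tail = np.count_nonzero(pos_null >= es)
            p_nom = (1.0 + tail) / (1.0 + pos_null.size)
            null_nes = np.concatenate([
                pos_null / mean_pos if np.isfinite(mean_pos) and mean_pos > 0
                else np.empty(0),
                -np.abs(neg_null) / mean_neg if np.isfinite(mean_neg) and mean_neg > 0
                else np.empty(0),
            ])
        else:
            nes = es / mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else 0.0
            tail = np.count_nonzero(neg_null <= es)
            p_nom = (1.0 + tail) / (1.0 + neg_null.size)
            null_nes = np.concatenate([
                pos_null / mean_pos if np.isfinite(mean_pos) and mean_pos > 0
                else np.empty(0),
                -np.abs(neg_null) / mean_neg if np.isfinite(mean_neg) and mean_neg > 0
                else np.empty(0),
            ])
        records.append({"pathway": p.name, "effective_size": int(m),
                        "es": es, "nes": float(nes),
                        "nominal_p": float(p_nom)})
        null_nes_pool.append(null_nes)

    if not records:
        return pd.DataFrame(columns=BASELINE_COLUMNS)

    df = pd.DataFrame(records)
    all_null_nes = np.concatenate(null_nes_pool)
    obs_nes = df["nes"].to_numpy()
    q = np.empty(len(df))
    pos_null_nes = all_null_nes[all_null_nes >= 0]
    neg_null_nes = all_null_nes[all_null_nes < 0]
    pos_obs = obs_nes[obs_nes >= 0]
    neg_obs = obs_nes[obs_nes < 0]
    for i, nes in enumerate(obs_nes):
        if nes >= 0:
            null_frac = (np.count_nonzero(pos_null_nes >= nes) /
                         max(pos_null_nes.size, 1))
            obs_frac = np.count_nonzero(pos_obs >= nes) / max(pos_obs.size, 1)
        else:
            null_frac = (np.count_nonzero(neg_null_nes <= nes) /
                         max(neg_null_nes.size, 1))
            obs_frac = np.count_nonzero(neg_obs <= nes) / max(neg_obs.size, 1)
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    df["fdr_q"] = q
    df = df.sort_values(
        by=["nominal_p", "fdr_q", "nes", "pathway"],
        ascending=[True, True, False, True],
        key=lambda s: s.abs() if s.name == "nes" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[BASELINE_COLUMNS]


def run_baseline(
    method: str,
    scores: GeneScoreVector,
    net: PPINetwork | None,
    col: PathwayCollection,
    n_perm: int = DEFAULT_PRERANK_PERM,
    seed: int = 0,
    weight: float = 1.0,
    restrict_to_network: bool = False,
) -> pd.DataFrame:
    """Run one comparator method end to end on raw signed scores.

    ``gsea`` and ``abs_gsea`` use the full score list unless
    ``restrict_to_network`` intersects them with the network universe (the
    secondary, input-standardized comparison); ``ngsea`` always requires and
    intersects with the network.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline method {method!r}")
    if scores.provenance != "raw":
        raise ValueError("baselines start from raw signed scores")
    if method == "ngsea":
        if net is None:
            raise ValueError("ngsea requires a network")
        aligned = intersect_with_network(scores, net)
        transformed = ngsea_transform(aligned, net)
    else:
        work = scores
        if restrict_to_network:
            if net is None:
                raise ValueError("restrict_to_network requires a network")
            work = intersect_with_network(scores, net)
        transformed = abs_transform(work) if method == "abs_gsea" else work
    return prerank_enrichment(transformed, col, n_perm=n_perm, weight=weight,
                              seed=seed)
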