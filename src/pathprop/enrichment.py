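"""Three-stage statistical cascade for propagated pathway scores.

Stage 1 compares the distribution of propagated scores inside each pathway
against the background of all other scored genes with a two-sample
Kolmogorov-Smirnov test; stage 2 validates Kolmogorov-Smirnov survivors
with a Mann-Whitney U rank test; stage 3 computes an empirical permutation
p-value for the surviving pathways by comparing the observed pathway mean
against means of randomly sampled gene sets of the same size.  A
Benjamini-Hochberg correction is applied after each stage, within the set
of pathways tested at that stage.  A pathway is called significant when both
its Kolmogorov-Smirnov and Mann-Whitney adjusted p-values fall at or below
the threshold; the permutation stage refines the ranking of significant
pathways but does not gate the call.

Because propagation runs on absolute scores, enrichment is one-directional
(larger propagated score = more perturbed neighborhood), so both rank tests
default to the one-sided "pathway greater" alternative; a flag restores
two-sided behavior.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import PathwayCollection, effective_pathway_sizes
from .propagation import GeneScoreVector

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "PermutationNull", "ks_pathway_test",
           "mw_pathway_test", "permutation_test", "bh_adjust", "run_cascade",
           "results_to_frame", "child_seed"]

DEFAULT_THRESHOLD = 0.05
DEFAULT_N_PERM = 10_000
# cap on random-key matrix entries per chunk when vectorizing subset draws
_CHUNK_BUDGET = 20_000_000

RESULT_COLUMNS = ["pathway", "effective_size", "direction", "ks_p", "ks_fdr",
                  "mw_p", "mw_fdr", "perm_p", "perm_fdr", "significant",
                  "rank"]


@dataclass
class PermutationNull:
    """Null distribution of pathway-mean statistics for one pathway size."""

    pathway_size: int
    n_perm: int
    statistics: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)
        if self.statistics.shape != (self.n_perm,):
            raise ValueError("null must hold exactly n_perm statistics")


@dataclass
class EnrichmentResult:
    """Per-pathway cascade record; absent stages are None."""

    pathway: str
    effective_size: int
    ks_p: float
    ks_fdr: float
    mw_p: float | None = None
    mw_fdr: float | None = None
    perm_p: float | None = None
    perm_fdr: float | None = None
    significant: bool = False
    rank: int = 0
    direction: str = "up"


def child_seed(master_seed: int, name: str) -> int:
    """Stable per-pathway seed below 2^31, independent of iteration order."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _split_scores(
    scores: GeneScoreVector, members: frozenset[str] | set[str]
) -> tuple[np.ndarray, np.ndarray]:
    mask = np.fromiter((g in members for g in scores.genes), bool, len(scores))
    return scores.scores[mask], scores.scores[~mask]


def ks_pathway_test(
    scores: GeneScoreVector,
    pathway_members: frozenset[str] | set[str],
    alternative: str = "greater",
) -> float:
    """Two-sample Kolmogorov-Smirnov p-value, pathway vs background scores.

    ``alternative="greater"`` tests whether pathway scores are stochastically
    greater than background (scipy's "less" on the pathway CDF).
    """
    inside, outside = _split_scores(scores, pathway_members)
    if inside.size < 2 or outside.size < 2:
        raise ValueError("need at least 2 scores in pathway and background")
    scipy_alt = {"greater": "less", "less": "greater",
                 "two-sided": "two-sided"}[alternative]
    return float(stats.ks_2samp(inside, outside, alternative=scipy_alt).pvalue)


def mw_pathway_test(
    scores: GeneScoreVector,
    pathway_members: frozenset[str] | set[str],
    alternative: str = "greater",
) -> float:
    """Mann-Whitney U p-value (tie-corrected), pathway ranks vs background."""
    inside, outside = _split_scores(scores, pathway_members)
    if inside.size < 2 or outside.size < 2:
        raise ValueError("need at least 2 scores in pathway and background")
    if np.ptp(np.concatenate([inside, outside])) == 0.0:
        return 1.0  # every value tied: no rank information
    return float(stats.mannwhitneyu(inside, outside,
                                    alternative=alternative).pvalue)


def _sample_subset_means(
    values: np.ndarray, m: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of ``n_perm`` size-``m`` subsets drawn without replacement.

    Vectorized via random-key argpartition, chunked to bound memory.
    """
    n = values.size
    chunk = max(1, min(n_perm, _CHUNK_BUDGET // n))
    out = np.empty(n_perm, dtype=float)
    done = 0
    while done < n_perm:
        take = min(chunk, n_perm - done)
        keys = rng.random((take, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        out[done:done + take] = values[idx].mean(axis=1)
        done += take
    return out


def permutation_test(
    scores: GeneScoreVector,
    pathway_members: frozenset[str] | set[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    statistic: str = "mean",
) -> tuple[float, float, PermutationNull]:
    """Empirical p-value of the observed pathway score summary.

    The observed statistic is the mean (configurably median) propagated score
    over the pathway's effective members; the null is the same statistic for
    ``n_perm`` gene sets of identical size sampled uniformly without
    replacement from the full scored universe.  The add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_perm)`` keeps p strictly positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    inside, _ = _split_scores(scores, pathway_members)
    m = inside.size
    if m < 1:
        raise ValueError("pathway has no scored members")
    if m > len(scores):
        raise ValueError("pathway effective size exceeds the scored universe")
    stat_fn = {"mean": np.mean, "median": np.median}[statistic]
    observed = float(stat_fn(inside))
    rng = np.random.default_rng(seed)
    if statistic == "mean":
        null = _sample_subset_means(scores.scores, m, n_perm, rng)
    else:
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = stat_fn(rng.choice(scores.scores, m, replace=False))
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)
    return observed, float(p), PermutationNull(m, n_perm, null, seed)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Sorted p-values are scaled by n/rank and made monotone by a reverse
    cumulative minimum, then capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def classify_direction(
    raw_scores: GeneScoreVector, pathway_members: frozenset[str] | set[str]
) -> str:
    """Up/down call from the mean signed score of effective members.

    Mean >= 0 is "up" (ties resolve up by convention).
    """
    mask = np.fromiter((g in pathway_members for g in raw_scores.genes), bool,
                       len(raw_scores))
    if not mask.any():
        raise ValueError("pathway has no members in the raw score universe")
    return "up" if float(raw_scores.scores[mask].mean()) >= 0.0 else "down"


def run_cascade(
    scores: GeneScoreVector,
    col: PathwayCollection,
    threshold: float = DEFAULT_THRESHOLD,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    raw_scores: GeneScoreVector | None = None,
    alternative: str = "greater",
    perm_statistic: str = "mean",
    min_effective_size: int = 2,
    bh_scope: str = "stage",
) -> list[EnrichmentResult]:
    """Run the full Kolmogorov-Smirnov / Mann-Whitney / permutation cascade.

    Parameters
    ----------
    scores
        Propagated gene scores (provenance must be ``propagated``).
    col
        Size-filtered pathway collection.
    threshold
        Adjusted-p cutoff gating each later stage and the significance call.
    raw_scores
        Optional signed scores used for the up/down direction call; when
        omitted every pathway is labeled "up".
    bh_scope
        ``stage`` adjusts within the subset tested at each stage (default);
        ``global`` adjusts stages 2 and 3 over all stage-1 pathways.

    Returns the per-pathway records in final rank order: significant pathways
    first, ordered by (perm_fdr, mw_fdr, ks_fdr, ks_p, name); the rest by
    (ks_fdr, ks_p, name).
    """
    if scores.provenance != "propagated":
        raise ValueError("cascade requires propagated scores")
    if bh_scope not in ("stage", "global"):
        raise ValueError("bh_scope must be 'stage' or 'global'")
    n_genes = len(scores)
    sizes = effective_pathway_sizes(col, scores.genes, floor=min_effective_size)
    testable = [p for p in col.pathways
                if sizes[p.name] >= min_effective_size
                and n_genes - sizes[p.name] >= 2]
    skipped = [p.name for p in col.pathways if p not in testable]
    if skipped:
        logger.info("skipping %d untestable pathways", len(skipped))
    if not testable:
        return []

    results: dict[str, EnrichmentResult] = {}
    ks_ps = [ks_pathway_test(scores, p.members, alternative) for p in testable]
    ks_fdrs = bh_adjust(ks_ps)
    for p, kp, kf in zip(testable, ks_ps, ks_fdrs):
        direction = (classify_direction(raw_scores, p.members)
                     if raw_scores is not None else "up")
        results[p.name] = EnrichmentResult(
            pathway=p.name, effective_size=sizes[p.name],
            ks_p=float(kp), ks_fdr=float(kf), direction=direction,
        )

    n_stage1 = len(testable)

    def _adjust(pvals: list[float]) -> np.ndarray:
        if bh_scope == "stage":
            return bh_adjust(pvals)
        # correct as if all stage-1 pathways had been tested
        padded = bh_adjust(list(pvals) + [1.0] * (n_stage1 - len(pvals)))
        return padded[: len(pvals)]

    stage2 = [p for p in testable if results[p.name].ks_fdr <= threshold]
    if stage2:
        mw_ps = [mw_pathway_test(scores, p.members, alternative) for p in stage2]
        mw_fdrs = _adjust(mw_ps)
        for p, mp, mf in zip(stage2, mw_ps, mw_fdrs):
            results[p.name].mw_p = float(mp)
            results[p.name].mw_fdr = float(mf)

    stage3 = [p for p in stage2 if results[p.name].mw_fdr <= threshold]
    if stage3:
        perm_ps = []
        for p in stage3:
            _, pp, _ = permutation_test(
                scores, p.members, n_perm=n_perm,
                seed=child_seed(seed, p.name), statistic=perm_statistic,
            )
            perm_ps.append(pp)
        perm_fdrs = _adjust(perm_ps)
        for p, pp, pf in zip(stage3, perm_ps, perm_fdrs):
            results[p.name].perm_p = float(pp)
            results[p.name].perm_fdr = float(pf)

    for r in results.values():
        r.significant = (
            r.ks_fdr <= threshold
            and r.mw_fdr is not None
            and r.mw_fdr <= threshold
        )

    def _sig_key(r: EnrichmentResult):
        return (r.perm_fdr if r.perm_fdr is not None else np.inf,
                r.mw_fdr if r.mw_fdr is not None else np.inf,
                r.ks_fdr, r.ks_p, r.pathway)

    def _rest_key(r: EnrichmentResult):
        return (r.ks_fdr, r.ks_p, r.pathway)

    sig = sorted((r for r in results.values() if r.significant), key=_sig_key)
    rest = sorted((r for r in results.values() if not r.significant),
                  key=_rest_key)
    ordered = sig + rest
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate cascade results; absent stages become NA."""
    rows = []
    for r in results:
        rows.append({
            "pathway": r.pathway,
            "effective_size": r.effective_size,
            "direction": r.direction,
            "ks_p": r.ks_p,
            "ks_fdr": r.ks_fdr,
            "mw_p": r.mw_p if r.mw_p is not None else np.nan,
            "mw_fdr": r.mw_fdr if r.mw_fdr is not None else np.nan,
            "perm_p": r.perm_p if r.perm_p is not None else np.nan,
            "perm_fdr": r.perm_fdr if r.perm_fdr is not None else np.nan,
            "significant": r.significant,
            "rank": r.rank,
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
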