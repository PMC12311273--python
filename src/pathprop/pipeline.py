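"""End-to-end orchestration and the rank-of-true-pathway evaluation protocol.

The propagation method ("netprop") runs: read scores -> intersect with the
network -> absolute values -> random walk with restart -> statistical
cascade.  Comparator methods (gsea / abs_gsea / ngsea) run their transform
followed by the shared preranked enrichment core.  Evaluation follows the
benchmark protocol: each dataset has one known associated pathway and a
method is scored by the 1-based position ("rank") of that pathway in its
significance-sorted output; rank distributions of method pairs are compared
with the two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .baselines import BASELINE_METHODS, run_baseline
from .enrichment import (DEFAULT_N_PERM, DEFAULT_THRESHOLD, classify_direction,
                         results_to_frame, run_cascade)
from .genesets import (DEFAULT_MAX_SIZE, DEFAULT_MIN_SIZE, PathwayCollection,
                       filter_by_size, read_gmt, read_rnk)
from .graph_io import PPINetwork, normalize_symmetric, read_edge_list
from .propagation import (GeneScoreVector, PropagationConfig,
                          intersect_with_network, propagate_iterative,
                          to_absolute)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "run_method", "rank_of_pathway",
           "classify_direction", "compare_methods", "METHODS"]

METHODS = ("netprop",) + BASELINE_METHODS


@dataclass
class RunConfig:
    """Full configuration of one enrichment run.

    ``netprop`` and ``ngsea`` require a network; ``gsea``/``abs_gsea`` use
    the full score list unless ``restrict_to_network`` is set.
    """

    method: str = "netprop"
    alpha: float = 0.2
    tol: float = 1e-6
    max_iter: int = 1000
    n_perm: int = DEFAULT_N_PERM
    threshold: float = DEFAULT_THRESHOLD
    weight: float = 1.0
    min_size: int = DEFAULT_MIN_SIZE
    max_size: int = DEFAULT_MAX_SIZE
    restrict_to_network: bool = False
    seed: int = 0
    rnk: str | None = None
    network: str | None = None
    gmt: str | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    def needs_network(self) -> bool:
        return self.method in ("netprop", "ngsea") or self.restrict_to_network


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run_method(
    cfg: RunConfig,
    scores: GeneScoreVector,
    net: PPINetwork | None,
    col: PathwayCollection,
) -> tuple[pd.DataFrame, dict]:
    """Run one method on in-memory inputs; returns (results table, manifest)."""
    if cfg.needs_network() and net is None:
        raise ValueError(f"method {cfg.method!r} requires a network")
    if scores.provenance != "raw":
        raise ValueError("run_method expects raw signed scores")
    col = filter_by_size(col, cfg.min_size, cfg.max_size)
    manifest: dict = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "versions": _library_versions(),
        "n_genes_input": len(scores),
        "n_pathways_tested": len(col),
        "pathway_filter": col.filter_state,
    }
    if cfg.method == "netprop":
        aligned_raw = intersect_with_network(scores, net)
        p0 = to_absolute(aligned_raw)
        prop_cfg = PropagationConfig(alpha=cfg.alpha, tol=cfg.tol,
                                     max_iter=cfg.max_iter)
        propagated = propagate_iterative(p0, normalize_symmetric(net), prop_cfg)
        manifest["propagation"] = {k: propagated.meta[k]
                                   for k in ("n_iter", "residual", "converged")}
        manifest["intersection"] = aligned_raw.meta
        results = run_cascade(
            propagated, col, threshold=cfg.threshold, n_perm=cfg.n_perm,
            seed=cfg.seed, raw_scores=aligned_raw,
        )
        table = results_to_frame(results)
    else:
        table = run_baseline(
            cfg.method, scores, net, col, n_perm=cfg.n_perm, seed=cfg.seed,
            weight=cfg.weight, restrict_to_network=cfg.restrict_to_network,
        )
    return table, manifest


def run(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Run from files named in the config; optionally write outputs.

    Writes ``results.tsv`` and ``manifest.json`` to ``cfg.outdir`` when set.
    """
    if cfg.rnk is None or cfg.gmt is None:
        raise ValueError("config must name rnk and gmt input files")
    scores = read_rnk(cfg.rnk)
    net = None
    if cfg.network is not None:
        net = read_edge_list(cfg.network)
    elif cfg.needs_network():
        raise ValueError(f"method {cfg.method!r} requires --network")
    col = read_gmt(cfg.gmt)
    table, manifest = run_method(cfg, scores, net, col)
    manifest["input_checksums"] = {
        "rnk": _sha256(cfg.rnk),
        "gmt": _sha256(cfg.gmt),
        "network": _sha256(cfg.network) if cfg.network else None,
    }
    if cfg.outdir:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "results.tsv", sep="\t", index=False,
                     na_rep="NA", float_format="%.6g")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return table, manifest


def _library_versions() -> dict[str, str]:
    import networkx
    import scipy
    import statsmodels

    return {
        "pathprop": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "statsmodels": statsmodels.__version__,
    }


def rank_of_pathway(
    results: pd.DataFrame,
    target: str,
    collection: PathwayCollection | None = None,
    filtered: PathwayCollection | None = None,
) -> int:
    """1-based position of the target pathway in the method's final ordering.

    When the target is missing from the results, the optional collections
    let the error distinguish "filtered by size" (present pre-filter,
    absent post-filter) from "absent from the GMT".
    """
    hit = results.loc[results["pathway"] == target, "rank"]
    if len(hit) == 1:
        return int(hit.iloc[0])
    if collection is not None and target not in collection:
        raise KeyError(f"pathway {target!r} is absent from the collection")
    if filtered is not None and collection is not None and target in collection \
            and target not in filtered:
        raise KeyError(f"pathway {target!r} was removed by the size filter")
    raise KeyError(f"pathway {target!r} not present in the results table")


def compare_methods(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise comparison of per-dataset target-pathway ranks across methods.

    ``rank_table`` has one row per dataset and one column per method.  For
    each method pair the two-sided Wilcoxon signed-rank test is applied to
    the paired ranks, alongside the mean rank difference (A - B; negative
    favors A) and win counts.  With a single dataset, or when every pair is
    tied, the test is not applicable and p is NaN (or 1.0 for all-ties).
    """
    methods = list(rank_table.columns)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    if rank_table.isna().any().any():
        raise ValueError("every method needs a rank for every dataset")
    rows = []
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            ra = rank_table[a].to_numpy(dtype=float)
            rb = rank_table[b].to_numpy(dtype=float)
            diff = ra - rb
            n = diff.size
            if n < 2:
                p = np.nan
            elif np.all(diff == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(ra, rb, zero_method="wilcox",
                                         alternative="two-sided").pvalue)
            rows.append({
                "method_a": a,
                "method_b": b,
                "n_datasets": n,
                "mean_rank_diff": float(diff.mean()),
                "wins_a": int(np.sum(diff < 0)),
                "wins_b": int(np.sum(diff > 0)),
                "ties": int(np.sum(diff == 0)),
                "wilcoxon_p": p,
            })
    return pd.DataFrame(rows)
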