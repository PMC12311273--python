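"""Readers and writers for .rnk score lists and GMT pathway collections.

The .rnk format is a two-column tab-delimited list of (gene, signed score);
GMT lines are ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Pathway
collections carry an optional size-filter record; the conventional filter
retains pathways with between 15 and 500 members inclusive, applied on the
database side (before any network intersection).  Effective sizes — member
counts within a scored universe — are tracked separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .graph_io import ParseError
from .propagation import GeneScoreVector

logger = logging.getLogger(__name__)

__all__ = ["Pathway", "PathwayCollection", "read_rnk", "write_rnk",
           "read_gmt", "write_gmt", "filter_by_size",
           "effective_pathway_sizes"]

DEFAULT_MIN_SIZE = 15
DEFAULT_MAX_SIZE = 500


class Pathway(NamedTuple):
    name: str
    description: str
    members: frozenset[str]


@dataclass
class PathwayCollection:
    """Ordered collection of named gene sets with GMT semantics."""

    pathways: list[Pathway]
    filter_state: dict | None = None
    _index: dict[str, Pathway] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {p.name: p for p in self.pathways}
        if len(self._index) != len(self.pathways):
            raise ValueError("pathway names must be unique")
        for p in self.pathways:
            if not p.members:
                raise ValueError(f"pathway {p.name!r} has no members")

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> Pathway:
        return self._index[name]

    def names(self) -> list[str]:
        return [p.name for p in self.pathways]


def read_rnk(path, fold_case: bool = False) -> GeneScoreVector:
    """Read a two-column preranked score list.

    Duplicate genes keep the entry with the largest absolute score (with a
    warning).  ``#`` comment lines are skipped; a non-numeric score is a
    parse error naming the line.  Identifiers are whitespace-trimmed and
    matched case-sensitively unless ``fold_case`` uppercases them.
    """
    order: list[str] = []
    best: dict[str, float] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            cols = [c.strip() for c in cols if c.strip()]
            if len(cols) < 2:
                raise ParseError(f"line {lineno}: expected 2 columns (gene, score)")
            gene = cols[0].upper() if fold_case else cols[0]
            try:
                score = float(cols[1])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-numeric score {cols[1]!r}"
                ) from None
            if gene in best:
                n_dup += 1
                if abs(score) > abs(best[gene]):
                    best[gene] = score
            else:
                order.append(gene)
                best[gene] = score
    if not order:
        raise ParseError(f"no score rows parsed from {path}")
    if n_dup:
        logger.warning("%d duplicate gene entries collapsed (kept largest |score|)",
                       n_dup)
    return GeneScoreVector(
        genes=order,
        scores=np.array([best[g] for g in order], dtype=float),
        provenance="raw",
    )


def write_rnk(scores: GeneScoreVector, path) -> None:
    with open(path, "w") as fh:
        for g, s in zip(scores.genes, scores.scores):
            fh.write(f"{g}\t{s:.10g}\n")


def read_gmt(path, fold_case: bool = False) -> PathwayCollection:
    """Read a GMT pathway collection; member lists are deduplicated per set."""
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = [c.strip() for c in line.split("\t")]
            cols = [c for c in cols if c]
            if len(cols) < 3:
                raise ParseError(
                    f"line {lineno}: GMT line needs name, description and "
                    f"at least one member"
                )
            name, desc = cols[0], cols[1]
            members = cols[2:]
            if fold_case:
                members = [m.upper() for m in members]
            pathways.append(Pathway(name, desc, frozenset(members)))
    if not pathways:
        logger.warning("empty GMT file %s", path)
    return PathwayCollection(pathways=pathways)


def write_gmt(col: PathwayCollection, path) -> None:
    """Write a collection in GMT format (members sorted for determinism)."""
    with open(path, "w") as fh:
        for p in col.pathways:
            fh.write("\t".join([p.name, p.description, *sorted(p.members)]) + "\n")


def filter_by_size(
    col: PathwayCollection,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> PathwayCollection:
    """Retain pathways with min_size <= |members| <= max_size (inclusive)."""
    if not (1 <= min_size <= max_size):
        raise ValueError("require 1 <= min_size <= max_size")
    kept = [p for p in col.pathways if min_size <= len(p.members) <= max_size]
    state = {
        "min_size": min_size,
        "max_size": max_size,
        "n_before": len(col.pathways),
        "n_after": len(kept),
    }
    return PathwayCollection(pathways=kept, filter_state=state)


def effective_pathway_sizes(
    col: PathwayCollection,
    scored_genes: Iterable[str],
    floor: int = 2,
) -> dict[str, int]:
    """Per-pathway count of members present in the scored universe.

    Pathways whose effective size falls below ``floor`` cannot be tested and
    are logged; the full mapping is returned so callers decide the exclusion.
    """
    universe = set(scored_genes)
    sizes = {p.name: len(p.members & universe) for p in col.pathways}
    too_small = [n for n, s in sizes.items() if s < floor]
    if too_small:
        logger.info("%d pathways below effective-size floor %d: %s",
                    len(too_small), floor, ", ".join(sorted(too_small)[:10]))
    return sizes
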