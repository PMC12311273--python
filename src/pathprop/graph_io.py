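"""Protein-protein interaction network I/O and diffusion-matrix construction.

Networks are undirected graphs over gene identifiers with strictly positive
edge weights, stored as a symmetric sparse adjacency matrix ``A``.  The
diffusion operator used by random-walk-with-restart propagation is the
symmetric normalization

    W = D^{-1/2} A D^{-1/2}

where ``D`` is the diagonal matrix of weighted degrees (row sums of ``A``).
Isolated nodes are kept and receive zero rows/columns in ``W``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["PPINetwork", "NormalizedMatrix", "ParseError", "read_edge_list",
           "normalize_symmetric"]


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


@dataclass
class PPINetwork:
    """Undirected weighted network over gene identifiers.

    Parameters
    ----------
    nodes : list of str
        Gene identifiers in first-appearance order.
    adjacency : scipy.sparse.csr_array
        Symmetric non-negative adjacency matrix aligned to ``nodes``.
    """

    nodes: list[str]
    adjacency: sp.csr_array
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node identifiers in network")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        a = sp.triu(self.adjacency)
        return int(a.nnz)

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degree of each node (row sums of the adjacency)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    @classmethod
    def from_edges(
        cls,
        nodes: list[str],
        edges: list[tuple[str, str, float]],
    ) -> "PPINetwork":
        """Build a network from an explicit node list and weighted edge list.

        Duplicate undirected edges keep the maximum weight; self-loops are
        preserved but warned about.
        """
        index = {g: i for i, g in enumerate(nodes)}
        dedup: dict[tuple[int, int], float] = {}
        for a, b, w in edges:
            if w <= 0:
                raise ValueError(f"non-positive edge weight {w} on edge {a}-{b}")
            i, j = index[a], index[b]
            if i == j:
                logger.warning("self-loop on node %s preserved", a)
            key = (min(i, j), max(i, j))
            if key not in dedup or w > dedup[key]:
                dedup[key] = w
        n = len(nodes)
        if dedup:
            rows, cols, vals = [], [], []
            for (i, j), w in dedup.items():
                rows.append(i)
                cols.append(j)
                vals.append(w)
                if i != j:
                    rows.append(j)
                    cols.append(i)
                    vals.append(w)
            adj = sp.csr_array(
                sp.coo_array((vals, (rows, cols)), shape=(n, n), dtype=float)
            )
        else:
            adj = sp.csr_array((n, n), dtype=float)
        return cls(nodes=nodes, adjacency=adj)


def _parse_weight(token: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"line {lineno}: non-numeric weight {token!r}"
        ) from None


def read_edge_list(path, weighted: bool = False) -> PPINetwork:
    """Read an undirected network from a plain-text edge list.

    Accepted layouts per data line (tab- or whitespace-delimited):
    ``nodeA nodeB``, ``nodeA nodeB weight``, and the SIF dialect
    ``nodeA relation nodeB`` (detected when there are exactly three columns
    and the third is non-numeric; the middle column is ignored).

    Lines starting with ``#`` and blank lines are skipped.  Duplicate
    undirected edges keep the maximum weight; node order is order of first
    appearance.
    """
    nodes: list[str] = []
    seen: set[str] = set()
    edges: list[tuple[str, str, float]] = []

    def note(g: str) -> None:
        if g not in seen:
            seen.add(g)
            nodes.append(g)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            cols = [c.strip() for c in cols if c.strip()]
            if len(cols) < 2:
                raise ParseError(f"line {lineno}: expected at least 2 columns")
            a, b = cols[0], cols[1]
            w = 1.0
            if len(cols) >= 3:
                third = cols[2]
                is_numeric = True
                try:
                    float(third)
                except ValueError:
                    is_numeric = False
                if len(cols) == 3 and not is_numeric:
                    # SIF dialect: nodeA relation nodeB
                    a, b = cols[0], cols[2]
                elif weighted:
                    w = _parse_weight(third, lineno)
            note(a)
            note(b)
            edges.append((a, b, w))
    return PPINetwork.from_edges(nodes, edges)


@dataclass
class NormalizedMatrix:
    """Symmetrically normalized diffusion matrix W = D^{-1/2} A D^{-1/2}.

    ``W`` is symmetric with spectral radius at most 1; rows and columns of
    degree-zero nodes are identically zero.
    """

    W: sp.csr_array
    node_order: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.W.shape

    def toarray(self) -> np.ndarray:
        return self.W.toarray()


def normalize_symmetric(net: PPINetwork) -> NormalizedMatrix:
    """Compute the symmetric normalization W = D^{-1/2} A D^{-1/2}.

    For degree-zero nodes the D^{-1/2} entry is defined as 0, so isolated
    nodes get all-zero rows and columns rather than raising.
    """
    if net.n_nodes < 1:
        raise ValueError("network must contain at least one node")
    deg = net.degrees
    coo = net.adjacency.tocoo()
    # computing a_ij / sqrt(d_i d_j) with a single square root keeps
    # rational entries (e.g. k-regular graphs -> exactly A/k)
    vals = coo.data / np.sqrt(deg[coo.row] * deg[coo.col])
    W = sp.csr_array(sp.coo_array((vals, (coo.row, coo.col)),
                                  shape=coo.shape))
    return NormalizedMatrix(W=W, node_order=list(net.nodes))
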