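"""Internal mini-batching of residue graphs into block-diagonal arrays.

Each graph is pre-digested once into directed edge arrays sorted by
destination node (the CSR row order used by every aggregation step); a batch
is then a cheap concatenation with node offsets.  Self-loop-augmented edges
are kept separately for the attention layer, whose softmax normalizes over
each node's in-neighborhood including the node itself, so every softmax
segment is non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .graphs import ProteinGraph

_DTYPE = np.float32


@dataclass
class _DigestedGraph:
    x: np.ndarray            # (n, 6) float32
    n: int
    # neighbor edges (both directions, no self-loops), sorted by dst
    nb_src: np.ndarray       # (e,) int64
    nb_counts: np.ndarray    # (n,) in-degree per node
    nb_mean_val: np.ndarray  # (e,) 1/deg[dst], for mean aggregation
    # self-loop-augmented edges, sorted by dst
    sl_src: np.ndarray
    sl_dst_local: np.ndarray
    sl_counts: np.ndarray    # (n,) = in-degree + 1
    sl_dist: np.ndarray      # (e+n,) Cα distance, 0 for self-loops


def digest_graph(graph: ProteinGraph) -> _DigestedGraph:
    n = graph.n_nodes
    und = graph.edges
    # directed both ways
    src = np.concatenate([und[:, 0], und[:, 1]])
    dst = np.concatenate([und[:, 1], und[:, 0]])
    dist = np.concatenate([graph.edge_attr, graph.edge_attr]).astype(_DTYPE)
    order = np.argsort(dst, kind="stable")
    src, dst, dist = src[order], dst[order], dist[order]
    counts = np.bincount(dst, minlength=n)
    inv_deg = np.zeros(n, dtype=_DTYPE)
    nz = counts > 0
    inv_deg[nz] = 1.0 / counts[nz]
    mean_val = inv_deg[dst]

    # add self-loops, re-sort by dst (stable: self-loop goes after neighbors)
    sl_src = np.concatenate([src, np.arange(n, dtype=np.int64)])
    sl_dst = np.concatenate([dst, np.arange(n, dtype=np.int64)])
    sl_dist = np.concatenate([dist, np.zeros(n, dtype=_DTYPE)])
    order = np.argsort(sl_dst, kind="stable")
    sl_src, sl_dst, sl_dist = sl_src[order], sl_dst[order], sl_dist[order]
    return _DigestedGraph(
        x=graph.node_features.astype(_DTYPE),
        n=n,
        nb_src=src,
        nb_counts=counts,
        nb_mean_val=mean_val,
        sl_src=sl_src,
        sl_dst_local=sl_dst,
        sl_counts=counts + 1,
        sl_dist=sl_dist,
    )


class GraphBatch:
    """Block-diagonal union of digested graphs plus the sparse operators
    every layer needs (mean-normalized adjacency, plain adjacency, and the
    CSR skeleton the attention layer fills with per-edge coefficients)."""

    def __init__(self, digested: Sequence[_DigestedGraph]):
        ns = np.array([g.n for g in digested], dtype=np.int64)
        self.n_graphs = len(digested)
        self.node_ptr = np.concatenate([[0], np.cumsum(ns)])
        self.n_nodes = int(self.node_ptr[-1])
        offsets = self.node_ptr[:-1]

        self.x = np.concatenate([g.x for g in digested]) if digested else np.empty((0, 6), _DTYPE)
        # node -> graph index
        self.node_graph = np.repeat(np.arange(self.n_graphs), ns)

        nb_src = np.concatenate([g.nb_src + off for g, off in zip(digested, offsets)])
        nb_counts = np.concatenate([g.nb_counts for g in digested])
        nb_mean_val = np.concatenate([g.nb_mean_val for g in digested])
        nb_indptr = np.concatenate([[0], np.cumsum(nb_counts)]).astype(np.int64)
        shape = (self.n_nodes, self.n_nodes)
        # rows = destination, cols = source
        self.A_mean = sp.csr_matrix((nb_mean_val, nb_src, nb_indptr), shape=shape)
        self.A_sum = sp.csr_matrix(
            (np.ones(nb_src.shape[0], dtype=_DTYPE), nb_src, nb_indptr), shape=shape
        )

        self.sl_src = np.concatenate([g.sl_src + off for g, off in zip(digested, offsets)])
        self.sl_dst = np.concatenate(
            [g.sl_dst_local + off for g, off in zip(digested, offsets)]
        )
        sl_counts = np.concatenate([g.sl_counts for g in digested])
        self.sl_indptr = np.concatenate([[0], np.cumsum(sl_counts)]).astype(np.int64)
        self.sl_dist = np.concatenate([g.sl_dist for g in digested])

    def attention_csr(self, alpha: np.ndarray) -> sp.csr_matrix:
        """CSR with per-edge attention coefficients (rows = destination)."""
        return sp.csr_matrix(
            (alpha, self.sl_src, self.sl_indptr),
            shape=(self.n_nodes, self.n_nodes),
        )

    def segment_softmax(self, e: np.ndarray) -> np.ndarray:
        """Softmax of per-edge scores over each destination's in-edges.

        Every segment is non-empty (self-loops), so reduceat is safe.
        """
        starts = self.sl_indptr[:-1]
        seg_max = np.maximum.reduceat(e, starts)
        z = np.exp(e - seg_max[self.sl_dst])
        seg_sum = np.add.reduceat(z, starts)
        return z / seg_sum[self.sl_dst]

    def graph_sum(self, y: np.ndarray, node_graph: np.ndarray) -> np.ndarray:
        """Sum node rows into per-graph rows (global add pooling).

        ``node_graph`` must be non-decreasing and cover every graph at least
        once (guaranteed: pooling keeps ceil(ratio * n) >= 1 nodes per graph).
        """
        starts = np.searchsorted(node_graph, np.arange(self.n_graphs))
        return np.add.reduceat(y, starts, axis=0)
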