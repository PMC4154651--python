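"""Directed weighted network container used across the pipeline.

The functional networks inferred here are directed (activation order gives
the arrow), weighted (weights accumulate Gaussian-decayed activation delays
over bursts), and carry no self-links.  Node identifiers are opaque strings
sorted lexicographically for reproducible output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class DirectedWeightedNetwork:
    """A directed graph with a dense nonnegative weight matrix.

    Parameters
    ----------
    nodes
        Node identifiers, in the order matching the rows/columns of ``w``.
    w
        Square matrix; ``w[i, j]`` is the weight of the link i -> j.
        The diagonal must be zero and all entries nonnegative.
    """

    nodes: list[str]
    w: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.nodes)
        if self.w.shape != (n, n):
            raise ValueError(f"weight matrix shape {self.w.shape} != ({n}, {n})")
        if np.any(self.w < 0):
            raise ValueError("link weights must be nonnegative")
        if np.any(np.diagonal(self.w) != 0):
            raise ValueError("self-links are not allowed (diagonal must be zero)")

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Number of nonzero directed links."""
        return int(np.count_nonzero(self.w))

    @property
    def total_weight(self) -> float:
        """Total strength S of the network (sum of all link weights)."""
        return float(self.w.sum())

    def out_degree(self) -> np.ndarray:
        return (self.w > 0).sum(axis=1)

    def in_degree(self) -> np.ndarray:
        return (self.w > 0).sum(axis=0)

    def out_strength(self) -> np.ndarray:
        return self.w.sum(axis=1)

    def in_strength(self) -> np.ndarray:
        return self.w.sum(axis=0)

    def total_strength(self) -> np.ndarray:
        """Per-node total strength s_in + s_out, the rich-club ranking variable."""
        return self.in_strength() + self.out_strength()

    # -- conversion -------------------------------------------------------

    def index_of(self, node: str) -> int:
        return self.nodes.index(node)

    def subnetwork(self, keep: "np.ndarray | list[int]") -> "DirectedWeightedNetwork":
        """Restrict to the node indices in ``keep`` (order preserved)."""
        keep = np.asarray(keep, dtype=int)
        return DirectedWeightedNetwork(
            [self.nodes[i] for i in keep], self.w[np.ix_(keep, keep)]
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        src, dst = np.nonzero(self.w)
        g.add_weighted_edges_from(
            (self.nodes[i], self.nodes[j], float(self.w[i, j]))
            for i, j in zip(src, dst)
        )
        return g

    @classmethod
    def from_edges(
        cls,
        edges: "list[tuple[str, str, float]]",
        nodes: "list[str] | None" = None,
    ) -> "DirectedWeightedNetwork":
        """Build from (src, dst, weight) triples; repeated pairs accumulate."""
        if nodes is None:
            nodes = sorted({u for u, _, _ in edges} | {v for _, v, _ in edges})
        idx = {v: i for i, v in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for u, v, wt in edges:
            if u == v:
                raise ValueError(f"self-link {u}->{v} not allowed")
            w[idx[u], idx[v]] += wt
        return cls(list(nodes), w)
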