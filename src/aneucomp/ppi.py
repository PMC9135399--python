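"""Protein-protein interaction counting and degree-preserving null model.

The enrichment of physical interactions between two differentially abundant
protein sets is assessed by replacing, in each randomization, every protein
of the aneuploid set with a distinct network protein of similar degree
(logarithmic degree bins, widened on exhaustion) and recounting edges to a
fixed partner set.  The empirical p-value uses the (1 + k)/(N + 1)
pseudocount convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


class InteractionNetwork:
    """Undirected simple PPI graph with a logarithmic degree-bin index."""

    def __init__(self, edges, bin_base: float = 2.0):
        g = nx.Graph()
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r} not allowed")
            g.add_edge(u, v)
        self.graph = g
        self.bin_base = bin_base
        self._degree = dict(g.degree())
        self._bins: dict[int, list[str]] = {}
        for node, deg in self._degree.items():
            self._bins.setdefault(self._bin_of(deg), []).append(node)
        for nodes in self._bins.values():
            nodes.sort()

    def _bin_of(self, degree: int) -> int:
        return int(np.floor(np.log(degree) / np.log(self.bin_base))) if degree > 0 else 0

    @classmethod
    def from_edge_list(cls, path) -> "InteractionNetwork":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: edge list needs two columns")
        return cls(df.iloc[:, :2].itertuples(index=False, name=None))

    def to_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\n")
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{u}\t{v}\n")

    def __contains__(self, node) -> bool:
        return node in self.graph

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node) -> int:
        return self._degree[node]

    def degree_bin(self, node, widen: int = 0) -> list[str]:
        """Nodes in the same log-degree bin, optionally widened by +-widen bins."""
        b = self._bin_of(self._degree[node])
        out: list[str] = []
        for k in range(b - widen, b + widen + 1):
            out.extend(self._bins.get(k, ()))
        return out


def count_cross_interactions(set_a: set, set_b: set, net: InteractionNetwork) -> int:
    """Number of network edges with one endpoint in A and the other in B.

    Each qualifying edge is counted once, including edges internal to the
    intersection; proteins absent from the network contribute nothing.
    """
    a = {p for p in set_a if p in net}
    b = {p for p in set_b if p in net}
    count = 0
    for u, v in net.graph.edges:
        if (u in a and v in b) or (u in b and v in a):
            count += 1
    return count


def degree_preserving_test(
    set_a: set,
    set_b: set,
    net: InteractionNetwork,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    max_widen: int = 10,
    pseudocount: bool = True,
) -> tuple[int, np.ndarray, float]:
    """Degree-preserving randomization test for cross-set interaction excess.

    Each iteration replaces every protein of ``set_a`` by a distinct network
    protein drawn uniformly from its degree bin (the protein's own identity
    excluded; the bin is widened to adjacent bins when exhausted), then
    recounts interactions with the fixed ``set_b``.  The p-value counts how
    often a randomized count is at least the observed one:
    ``p = (1 + #{null >= obs}) / (n_iter + 1)``.

    Returns (observed count, null counts, p).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_in = sorted(p for p in set_a if p in net)
    dropped = set(set_a) - set(a_in)
    if dropped:
        warnings.warn(f"{len(dropped)} set-A proteins absent from network dropped")
    if not a_in:
        raise ValueError("no set-A protein present in the network")
    observed = count_cross_interactions(set(a_in), set_b, net)

    # Precompute adjacency into B once; cross-count for a replacement set is
    # edges-to-B summed per member minus internal double counts, but since
    # replacements form an arbitrary set we recount exactly via edge scan on
    # the (small) candidate adjacency.
    b_set = {p for p in set_b if p in net}
    null = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        replacement = _sample_degree_matched(a_in, net, rng, max_widen)
        null[it] = _cross_count_fast(replacement, b_set, net)
    k = int((null >= observed).sum())
    p = (1 + k) / (n_iter + 1) if pseudocount else k / n_iter
    return observed, null, float(p)


def _sample_degree_matched(
    proteins: list, net: InteractionNetwork, rng: np.random.Generator, max_widen: int
) -> set:
    chosen: set = set()
    for prot in proteins:
        pick = None
        for widen in range(max_widen + 1):
            pool = [q for q in net.degree_bin(prot, widen) if q != prot and q not in chosen]
            if pool:
                pick = pool[int(rng.integers(len(pool)))]
                break
        if pick is None:
            raise RuntimeError(f"degree bin exhausted for {prot!r} even after widening")
        chosen.add(pick)
    return chosen


def _cross_count_fast(set_a: set, set_b: set, net: InteractionNetwork) -> int:
    count = 0
    adj = net.graph.adj
    for u in set_a:
        for v in adj[u]:
            if v not in set_b:
                continue
            # an edge is seen from both sides only when v is also in A and
            # u is also in B; tie-break on ordering to count it once
            if v in set_a and u in set_b and not (u <= v):
                continue
            count += 1
    return count
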