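"""Partial-correlation (graphical Gaussian) biomarker networks.

Variables are connected when they remain correlated after conditioning on
every subset of the other adjacent variables: the PC-algorithm skeleton
search with a regression-based conditional-independence test.  X and Y are
judged independent given S when the t-test p-value on X's coefficient in the
OLS regression of Y on {X} union S exceeds the alpha threshold (0.001 by
default, matching the published analysis).  Edge directions are deliberately
not inferred.  Networks from several datasets are merged into a consensus of
solid (always present) and dashed (sometimes present) edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PartialCorrelationNetwork", "ConsensusNetwork",
           "regression_ci_test", "pc_skeleton", "consensus"]

Edge = FrozenSet[str]


def _edge(a: str, b: str) -> Edge:
    return frozenset((a, b))


@dataclass
class PartialCorrelationNetwork:
    nodes: List[str]
    edges: Set[Edge]
    alpha: float
    separating_sets: Dict[Edge, Tuple[str, ...]] = field(default_factory=dict)

    def has_edge(self, a: str, b: str) -> bool:
        return _edge(a, b) in self.edges

    def neighbors(self, a: str) -> List[str]:
        return sorted(n for n in self.nodes
                      if n != a and _edge(a, n) in self.edges)

    def to_graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def edge_list(self) -> List[Tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.edges)


def regression_ci_test(data: pd.DataFrame, x: str, y: str,
                       conditioning: Sequence[str]) -> float:
    """p-value for X independent of Y given S, via the t test on X's
    coefficient in the OLS regression of Y on {X} union S."""
    cols = [x, *conditioning]
    X = data[cols].to_numpy(dtype=float)
    yv = data[y].to_numpy(dtype=float)
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ beta
    dof = n - p - 1
    if dof <= 0:
        raise ValueError("too few rows for the conditioning-set size")
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(A.T @ A)
    se = np.sqrt(s2 * XtX_inv[1, 1])  # index 1 = x's coefficient
    if se == 0:
        return 0.0
    t = beta[1] / se
    return float(2.0 * sps.t.sf(abs(t), dof))


def pc_skeleton(data: pd.DataFrame, alpha: float = 0.001,
                stable: bool = False) -> PartialCorrelationNetwork:
    """PC-algorithm skeleton over the data columns.

    Starts from the complete graph; for conditioning-set sizes k = 0, 1, ...
    each remaining edge (X, Y) is tested against every size-k subset of X's
    (and Y's) other neighbors, and removed as soon as one test accepts
    independence (p > alpha).  Nodes, pairs and subsets are processed in
    lexicographic order so the result is deterministic; with ``stable=True``
    all removals at a given k are collected before the adjacency is updated.
    """
    nodes = sorted(data.columns)
    arr = data[nodes].dropna()
    n = arr.shape[0]
    if n < len(nodes) + 3:
        raise ValueError("need at least (variables + 3) complete rows")
    for c in nodes:
        if arr[c].std() == 0:
            raise ValueError(f"constant column: {c}")

    edges: Set[Edge] = {_edge(a, b) for a, b in combinations(nodes, 2)}
    sepsets: Dict[Edge, Tuple[str, ...]] = {}

    def adj(node: str, current: Set[Edge]) -> List[str]:
        return sorted(m for m in nodes
                      if m != node and _edge(node, m) in current)

    k = 0
    while True:
        any_big_enough = False
        removals: Set[Edge] = set()
        snapshot = set(edges)
        for a, b in combinations(nodes, 2):
            e = _edge(a, b)
            if e not in edges or (stable and e in removals):
                continue
            removed = False
            for x, y in ((a, b), (b, a)):
                cand = [m for m in adj(x, snapshot if stable else edges)
                        if m != y]
                if len(cand) < k:
                    continue
                any_big_enough = True
                for S in combinations(cand, k):
                    p = regression_ci_test(arr, x, y, S)
                    if p > alpha:
                        sepsets[e] = tuple(S)
                        removed = True
                        break
                if removed:
                    break
            if removed:
                if stable:
                    removals.add(e)
                else:
                    edges.discard(e)
        if stable:
            edges -= removals
        if not any_big_enough:
            break
        k += 1
    return PartialCorrelationNetwork(nodes=nodes, edges=edges, alpha=alpha,
                                     separating_sets=sepsets)


@dataclass
class ConsensusNetwork:
    """Merge of per-dataset networks.

    An edge is solid when present in every network whose node set contains
    both endpoints, dashed when present in some but not all, and a node is
    unplaceable when it has no edge at all in any network containing it.
    """

    solid: Set[Edge]
    dashed: Set[Edge]
    unplaceable: List[str]
    nodes: List[str]

    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b, "solid") for a, b in
                sorted(tuple(sorted(e)) for e in self.solid)]
        rows += [(a, b, "dashed") for a, b in
                 sorted(tuple(sorted(e)) for e in self.dashed)]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "status"])


def consensus(networks: Sequence[PartialCorrelationNetwork],
              ) -> ConsensusNetwork:
    if not networks:
        raise ValueError("empty network list")
    all_nodes = sorted({n for net in networks for n in net.nodes})
    solid: Set[Edge] = set()
    dashed: Set[Edge] = set()
    for a, b in combinations(all_nodes, 2):
        applicable = [net for net in networks
                      if a in net.nodes and b in net.nodes]
        if not applicable:
            continue
        present = sum(net.has_edge(a, b) for net in applicable)
        if present == len(applicable):
            solid.add(_edge(a, b))
        elif present > 0:
            dashed.add(_edge(a, b))
    placed = {n for e in solid | dashed for n in e}
    unplaceable = [n for n in all_nodes if n not in placed]
    return ConsensusNetwork(solid=solid, dashed=dashed,
                            unplaceable=unplaceable, nodes=all_nodes)
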