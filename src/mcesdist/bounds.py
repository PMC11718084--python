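"""Provably-correct lower bounds on the weighted MCES distance.

Two bounds are provided.  The *degree bound* greedily pairs nodes by sorted
weighted degree and sums absolute differences; it costs O(n log n).  The
*atom-type matching bound* solves, per element, a minimum-weight perfect
matching between the nodes of that element in the two graphs, with pair
costs obtained by exactly matching the local (one-hop) edge neighborhoods;
it costs O(n^3) and dominates the degree bound.  Both are halved at the end
because every edge is counted at both endpoints, and both are pseudometrics,
which the thresholded pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .molgraph import MolecularGraph, from_quarter


@dataclass(frozen=True)
class BoundValue:
    """A lower bound on the weighted MCES distance, in quarter units."""

    value_q: int
    kind: str  # "degree" | "atomtype_matching"

    @property
    def value(self) -> float:
        return from_quarter(self.value_q)


def degree_bound(g1: MolecularGraph, g2: MolecularGraph) -> BoundValue:
    """Weighted-degree lower bound.

    Sorts both node sets by weighted degree (descending), pairs them
    positionally summing absolute differences, adds the degrees of leftover
    nodes of the larger graph, and halves the total.  The result never
    exceeds the exact weighted MCES distance.
    """
    d1 = sorted((g1.weighted_degree_q(n) for n in g1.nodes()), reverse=True)
    d2 = sorted((g2.weighted_degree_q(n) for n in g2.nodes()), reverse=True)
    if len(d1) < len(d2):
        d1, d2 = d2, d1
    total = sum(abs(a - b) for a, b in zip(d1, d2)) + sum(d1[len(d2):])
    # every incident edge was counted at both endpoints
    assert total % 2 == 0
    return BoundValue(total // 2, "degree")


def neighborhood_cost_q(g1: MolecularGraph, u, g2: MolecularGraph, v) -> int:
    """Exact cost of matching the incident-edge neighborhoods of u and v.

    Minimum over injective pairings of u's and v's incident edges — an edge
    may pair only when the opposite endpoints share an atom type — of the
    summed absolute weight differences, plus the weights of all unpaired
    incident edges.  Solved as a small assignment problem (degrees are
    bounded by valence), so the value is exact.
    """
    if g1.atom_type(u) != g2.atom_type(v):
        raise ValidationError(
            f"atom types differ: {g1.atom_type(u)} vs {g2.atom_type(v)}")
    e1 = [(g1.atom_type(w), g1.bond_weight_q(u, w)) for w in g1.neighbors(u)]
    e2 = [(g2.atom_type(w), g2.bond_weight_q(v, w)) for w in g2.neighbors(v)]
    return _edge_set_match_q(e1, e2)


def _edge_set_match_q(e1: list[tuple[str, int]],
                      e2: list[tuple[str, int]]) -> int:
    """Min-cost matching of two incident-edge multisets (type, qweight)."""
    n1, n2 = len(e1), len(e2)
    if n1 == 0 or n2 == 0:
        return sum(w for _, w in e1) + sum(w for _, w in e2)
    size = n1 + n2
    big = sum(w for _, w in e1) + sum(w for _, w in e2) + 1
    cost = np.full((size, size), big, dtype=np.int64)
    for i, (t1, w1) in enumerate(e1):
        for j, (t2, w2) in enumerate(e2):
            if t1 == t2:
                cost[i, j] = abs(w1 - w2)
        cost[i, n2 + i] = w1  # leave e1[i] unmatched
    for j, (_, w2) in enumerate(e2):
        cost[n1 + j, j] = w2  # leave e2[j] unmatched
    cost[n1:, n2:] = 0  # dummy-dummy
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


def neighborhood_cost(g1: MolecularGraph, u, g2: MolecularGraph, v) -> float:
    return from_quarter(neighborhood_cost_q(g1, u, g2, v))


def atomtype_matching_bound(g1: MolecularGraph,
                            g2: MolecularGraph) -> BoundValue:
    """Per-element bipartite matching lower bound (the stronger bound).

    For every element present in either graph, a bipartite graph is built
    between the nodes of that element; unequal sides are padded, a real node
    facing a padding node costing its weighted degree.  Real pairs cost
    their exact neighborhood matching cost.  The minimum-weight perfect
    matching values are summed over elements and halved.
    """
    total = 0
    elements = g1.elements() | g2.elements()
    for elem in sorted(elements):
        u_nodes = [n for n in g1.nodes() if g1.atom_type(n) == elem]
        v_nodes = [n for n in g2.nodes() if g2.atom_type(n) == elem]
        size = max(len(u_nodes), len(v_nodes))
        cost = np.zeros((size, size), dtype=np.int64)
        for i, u in enumerate(u_nodes):
            du = g1.weighted_degree_q(u)
            for j in range(size):
                if j < len(v_nodes):
                    cost[i, j] = neighborhood_cost_q(g1, u, g2, v_nodes[j])
                else:
                    cost[i, j] = du  # padding column
        for i in range(len(u_nodes), size):
            for j, v in enumerate(v_nodes):
                cost[i, j] = g2.weighted_degree_q(v)  # padding row
        if size:
            rows, cols = linear_sum_assignment(cost)
            total += int(cost[rows, cols].sum())
    assert total % 2 == 0
    return BoundValue(total // 2, "atomtype_matching")
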