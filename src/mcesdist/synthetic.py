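"""Synthetic molecular graphs, controlled perturbations and an exact
brute-force MCES oracle.

The generator stands in for subsampled biomolecular structures when testing
at desk scale: node counts, a valence-like degree cap of 4, a mostly-carbon
element distribution and aromatic weights restricted to ring edges keep the
graphs qualitatively molecule-like without attempting real chemistry.  The
oracle enumerates type-consistent injective node mappings with
branch-and-bound and is completely independent of the ILP machinery, which
makes it the anchor for every correctness test in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import OracleSizeError, ValidationError
from .molgraph import MolecularGraph, from_edge_list, from_quarter, to_quarter

#: element frequencies loosely matching small biomolecules (heavy atoms)
DEFAULT_ELEMENT_WEIGHTS = {"C": 0.72, "N": 0.10, "O": 0.13, "S": 0.03,
                           "Cl": 0.02}

ORACLE_EDGE_CAP = 7


def random_molecular_graph(n_nodes: int, seed: int,
                           element_weights: dict[str, float] | None = None,
                           max_degree: int = 4,
                           connected: bool = True,
                           extra_edge_factor: float = 0.25,
                           aromatic_cycles_only: bool = True,
                           p_double: float = 0.15) -> MolecularGraph:
    """Generate a random molecule-like graph, deterministic in ``seed``.

    A random tree is grown first (guaranteeing connectivity when requested),
    then extra edges — roughly ``extra_edge_factor * n_nodes`` of them,
    creating rings — are added subject to the degree cap.  Bond weights are
    single with probability ``1 - p_double`` and double otherwise; whole
    rings from the cycle basis are switched to aromatic (1.5) with
    probability one half each, so aromatic weights appear only on ring edges
    unless ``aromatic_cycles_only`` is lifted.
    """
    if n_nodes < 1:
        raise ValidationError("n_nodes must be >= 1")
    if max_degree < 1 or (connected and n_nodes > 1 and max_degree < 2):
        raise ValidationError("degree cap too small for a connected graph")
    rng = np.random.default_rng(seed)
    weights = element_weights or DEFAULT_ELEMENT_WEIGHTS
    symbols = list(weights)
    probs = np.array([weights[s] for s in symbols], dtype=float)
    probs = probs / probs.sum()
    elements = [symbols[i] for i in rng.choice(len(symbols), size=n_nodes,
                                               p=probs)]

    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    deg = [0] * n_nodes
    if connected and n_nodes > 1:
        for v in range(1, n_nodes):
            candidates = [u for u in range(v) if deg[u] < max_degree]
            if not candidates:
                raise ValidationError("degree constraints made growth infeasible")
            u = int(rng.choice(candidates))
            g.add_edge(u, v)
            deg[u] += 1
            deg[v] += 1
    n_extra = rng.binomial(max(n_nodes, 1), min(extra_edge_factor, 1.0))
    for _ in range(n_extra * 3):  # rejection attempts
        if n_extra == 0:
            break
        u, v = rng.integers(0, n_nodes, size=2)
        u, v = int(u), int(v)
        if u == v or g.has_edge(u, v):
            continue
        if deg[u] >= max_degree or deg[v] >= max_degree:
            continue
        g.add_edge(u, v)
        deg[u] += 1
        deg[v] += 1
        n_extra -= 1

    # weights: singles/doubles everywhere, aromatics only on whole rings
    for u, v in g.edges():
        w = 2.0 if rng.random() < p_double else 1.0
        g.edges[u, v]["qweight"] = to_quarter(w)
    cycles = nx.cycle_basis(g)
    if aromatic_cycles_only:
        for cyc in cycles:
            if rng.random() < 0.5:
                for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                    g.edges[a, b]["qweight"] = to_quarter(1.5)
    else:
        for u, v in g.edges():
            if rng.random() < 0.2:
                g.edges[u, v]["qweight"] = to_quarter(1.5)
    for i in range(n_nodes):
        g.nodes[i]["element"] = elements[i]
    return MolecularGraph(g, id=f"synth-{seed}-{n_nodes}")


@dataclass
class PerturbationRecord:
    """Edits applied to a graph and their total weight cost.

    The cost sums deleted weights, inserted weights and absolute weight
    changes, so it upper-bounds the exact MCES distance between the source
    and the perturbed graph.
    """

    source_id: str | None
    operations: list[tuple] = field(default_factory=list)
    truncated: bool = False

    @property
    def cost_q(self) -> int:
        return sum(op[-1] for op in self.operations)

    @property
    def cost(self) -> float:
        return from_quarter(self.cost_q)


_WEIGHT_CHOICES_Q = (4, 6, 8)  # 1.0, 1.5, 2.0 in quarter units


def perturb(g: MolecularGraph, seed: int,
            k_ops: int) -> tuple[MolecularGraph, PerturbationRecord]:
    """Apply ``k_ops`` random edits (edge deletion / weight change /
    insertion) and record their total weight cost.

    If the graph runs out of legal edits the record is flagged
    ``truncated`` and fewer operations are returned.
    """
    if k_ops < 0:
        raise ValidationError("k_ops must be >= 0")
    rng = np.random.default_rng(seed)
    h = g.graph.copy()
    record = PerturbationRecord(source_id=g.id)
    nodes = list(h.nodes())
    for _ in range(k_ops):
        ops = []
        if h.number_of_edges() > 0:
            ops.extend(["delete", "reweight"])
        if len(nodes) >= 2 and h.number_of_edges() < (
                len(nodes) * (len(nodes) - 1)) // 2:
            ops.append("insert")
        if not ops:
            record.truncated = True
            break
        op = ops[int(rng.integers(len(ops)))]
        if op == "delete":
            edges = sorted(h.edges())
            u, v = edges[int(rng.integers(len(edges)))]
            cost = h.edges[u, v]["qweight"]
            h.remove_edge(u, v)
            record.operations.append(("delete", (u, v), cost))
        elif op == "reweight":
            edges = sorted(h.edges())
            u, v = edges[int(rng.integers(len(edges)))]
            old = h.edges[u, v]["qweight"]
            new = old
            while new == old:
                new = _WEIGHT_CHOICES_Q[int(rng.integers(3))]
            h.edges[u, v]["qweight"] = new
            record.operations.append(("reweight", (u, v), abs(new - old)))
        else:  # insert
            for _ in range(100):
                u, v = (int(x) for x in rng.integers(0, len(nodes), size=2))
                u, v = nodes[u], nodes[v]
                if u != v and not h.has_edge(u, v):
                    w = _WEIGHT_CHOICES_Q[int(rng.integers(3))]
                    h.add_edge(u, v, qweight=w)
                    record.operations.append(("insert", (u, v), w))
                    break
            else:
                record.truncated = True
                break
    return MolecularGraph(h, id=(g.id or "g") + "-perturbed"), record


def brute_force_mces(g1: MolecularGraph, g2: MolecularGraph,
                     edge_cap: int = ORACLE_EDGE_CAP,
                     return_mapping: bool = False):
    """Exact weighted MCES distance by exhaustive node-mapping enumeration.

    Enumerates every injective, type-consistent partial mapping from the
    nodes of the first graph into the second with branch-and-bound on the
    achievable common-edge weight.  Returns the distance as a float (and the
    optimal mapping when requested).  Refuses pairs whose smaller edge count
    exceeds ``edge_cap``.
    """
    if min(g1.n_edges, g2.n_edges) > edge_cap:
        raise OracleSizeError(
            f"oracle cap {edge_cap} edges exceeded "
            f"({g1.n_edges} and {g2.n_edges})")
    b1q = g1.total_bond_weight_q()
    b2q = g2.total_bond_weight_q()

    # BFS-ish node order so edges close early; high degree first helps pruning
    order = sorted(g1.nodes(), key=lambda n: -g1.weighted_degree_q(n))
    n1 = len(order)
    # suffix potential: twice the weight of g1 edges touching remaining nodes
    suffix = [0] * (n1 + 1)
    seen: set = set()
    for idx in range(n1 - 1, -1, -1):
        u = order[idx]
        add = 0
        for w in g1.neighbors(u):
            if (u, w) not in seen and (w, u) not in seen:
                add += g1.bond_weight_q(u, w)
                seen.add((u, w))
        suffix[idx] = suffix[idx + 1] + add

    nodes2 = list(g2.nodes())
    by_type: dict[str, list] = {}
    for v in nodes2:
        by_type.setdefault(g2.atom_type(v), []).append(v)

    best = {"savings": 0, "mapping": {}}
    mapping: dict = {}
    used: set = set()

    def rec(idx: int, savings: int) -> None:
        if savings + 2 * suffix[idx] <= best["savings"]:
            return
        if idx == n1:
            if savings > best["savings"]:
                best["savings"] = savings
                best["mapping"] = dict(mapping)
            return
        u = order[idx]
        for v in by_type.get(g1.atom_type(u), ()):  # try mapping first
            if v in used:
                continue
            gain = 0
            for w in g1.neighbors(u):
                mw = mapping.get(w)
                if mw is not None and g2.graph.has_edge(v, mw):
                    gain += 2 * min(g1.bond_weight_q(u, w),
                                    g2.bond_weight_q(v, mw))
            mapping[u] = v
            used.add(v)
            rec(idx + 1, savings + gain)
            del mapping[u]
            used.remove(v)
        rec(idx + 1, savings)  # leave u unmapped

    rec(0, 0)
    dist_q = b1q + b2q - best["savings"]
    dist = from_quarter(dist_q)
    if return_mapping:
        return dist, best["mapping"]
    return dist


def brute_force_mces_q(g1: MolecularGraph, g2: MolecularGraph,
                       edge_cap: int = ORACLE_EDGE_CAP) -> int:
    return to_quarter(brute_force_mces(g1, g2, edge_cap=edge_cap))


def toy_library() -> dict[str, MolecularGraph]:
    """Canonical tiny fixtures with frozen edge lists."""
    c = "C"
    lib = {
        "methane-carbon": from_edge_list([c], [], id="methane-carbon"),
        "ethane": from_edge_list([c, c], [(0, 1, 1.0)], id="ethane"),
        "propane": from_edge_list([c, c, c],
                                  [(0, 1, 1.0), (1, 2, 1.0)], id="propane"),
        "carbon-triangle": from_edge_list(
            [c, c, c], [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)],
            id="carbon-triangle"),
        "benzene": from_edge_list(
            [c] * 6, [(i, (i + 1) % 6, 1.5) for i in range(6)], id="benzene"),
        "cyclohexane": from_edge_list(
            [c] * 6, [(i, (i + 1) % 6, 1.0) for i in range(6)],
            id="cyclohexane"),
        "ethanol": from_edge_list([c, c, "O"],
                                  [(0, 1, 1.0), (1, 2, 1.0)], id="ethanol"),
    }
    return lib


def toy(name: str) -> MolecularGraph:
    lib = toy_library()
    if name not in lib:
        raise ValidationError(
            f"unknown fixture {name!r}; known: {', '.join(sorted(lib))}")
    return lib[name]
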