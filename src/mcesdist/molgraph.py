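"""Labeled, edge-weighted molecular graphs.

A molecule is modelled as a simple graph over its heavy atoms: nodes carry an
element symbol, edges carry a bond weight of 1.0 (single), 1.5 (aromatic) or
2.0 (double).  Hydrogens are never represented.  All distances defined on
these graphs are multiples of 0.25, so weights are stored internally as
integer *quarter units* (the float weight times 4); every comparison in the
package is therefore exact integer arithmetic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

from .errors import InputError, ValidationError

#: canonical bond weights; triple bonds (3.0) are accepted as an extension
ALLOWED_WEIGHTS = (1.0, 1.5, 2.0)
TRIPLE_WEIGHT = 3.0


def to_quarter(value: float) -> int:
    """Convert a weight/distance to exact quarter units (int)."""
    q = round(value * 4)
    if abs(q - value * 4) > 1e-9:
        raise ValidationError(f"value {value!r} is not a multiple of 0.25")
    return q


def from_quarter(q: int) -> float:
    return q / 4.0


class MolecularGraph:
    """A node-labeled, edge-weighted simple graph of heavy atoms.

    Parameters
    ----------
    graph:
        ``networkx.Graph`` whose nodes carry an ``element`` attribute and
        whose edges carry a ``qweight`` attribute (bond weight in quarter
        units).  The constructor validates simplicity and the weight set.
    id:
        Optional structure identifier.
    empty_input:
        Set when the graph came from an input with no heavy atoms (e.g. the
        SMILES of molecular hydrogen); callers may warn on it.
    """

    __slots__ = ("_g", "id", "empty_input")

    def __init__(self, graph: nx.Graph, id: str | None = None,
                 empty_input: bool = False):
        for u, v in graph.edges():
            if u == v:
                raise ValidationError(f"self-loop at node {u!r}")
        for n, data in graph.nodes(data=True):
            if "element" not in data or not data["element"]:
                raise ValidationError(f"node {n!r} has no element symbol")
        for u, v, data in graph.edges(data=True):
            if "qweight" not in data:
                raise ValidationError(f"edge {(u, v)!r} has no weight")
        self._g = graph
        self.id = id
        self.empty_input = empty_input

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes(self) -> Iterator:
        return iter(self._g.nodes())

    def edges(self) -> Iterator[tuple]:
        return iter(self._g.edges())

    def neighbors(self, node) -> Iterator:
        return iter(self._g[node])

    def atom_type(self, node) -> str:
        try:
            return self._g.nodes[node]["element"]
        except KeyError:
            raise ValidationError(f"unknown node {node!r}") from None

    def bond_weight_q(self, u, v) -> int:
        try:
            return self._g.edges[u, v]["qweight"]
        except KeyError:
            raise ValidationError(f"unknown edge {(u, v)!r}") from None

    def bond_weight(self, u, v) -> float:
        return from_quarter(self.bond_weight_q(u, v))

    def elements(self) -> set[str]:
        return {d["element"] for _, d in self._g.nodes(data=True)}

    # -- weighted-degree queries -----------------------------------------
    def weighted_degree_q(self, node) -> int:
        if node not in self._g:
            raise ValidationError(f"unknown node {node!r}")
        return sum(d["qweight"] for _, _, d in self._g.edges(node, data=True))

    def weighted_degree(self, node) -> float:
        """Sum of incident bond weights (hydrogens excluded by model)."""
        return from_quarter(self.weighted_degree_q(node))

    def total_bond_weight_q(self) -> int:
        return sum(d["qweight"] for _, _, d in self._g.edges(data=True))

    def total_bond_weight(self) -> float:
        """Sum of all bond weights of the graph."""
        return from_quarter(self.total_bond_weight_q())

    # -- transforms ------------------------------------------------------
    def relabeled(self, mapping: Mapping) -> "MolecularGraph":
        """Isomorphic copy with node ids renamed by ``mapping``."""
        return MolecularGraph(nx.relabel_nodes(self._g, dict(mapping), copy=True),
                              id=self.id)

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(self._g.copy(), id=self.id,
                              empty_input=self.empty_input)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" id={self.id!r}" if self.id else ""
        return (f"<MolecularGraph{tag} nodes={self.n_nodes} "
                f"edges={self.n_edges}>")


# -- construction ---------------------------------------------------------

_BOND_WEIGHTS = {"SINGLE": 1.0, "AROMATIC": 1.5, "DOUBLE": 2.0,
                 "TRIPLE": TRIPLE_WEIGHT}


def from_smiles(smiles: str, id: str | None = None,
                reject_triple: bool = False) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom molecular graph.

    Aromaticity is taken from RDKit's perception model after sanitization
    (kekulized input is re-perceived), so aromatic rings always yield weight
    1.5.  Triple bonds are weighted 3.0 by default; pass ``reject_triple``
    to refuse them instead.  Disconnected (multi-fragment) SMILES produce a
    single disconnected graph.

    Raises
    ------
    InputError
        If the string cannot be parsed or contains an unsupported bond.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise InputError(f"cannot parse SMILES: {smiles!r}")
    g = nx.Graph()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:  # explicit hydrogens
            continue
        g.add_node(atom.GetIdx(), element=atom.GetSymbol())
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if u not in g or v not in g:
            continue  # bond to an explicit hydrogen
        name = bond.GetBondType().name
        if name not in _BOND_WEIGHTS:
            raise InputError(
                f"unsupported bond type {name} in SMILES {smiles!r}")
        if name == "TRIPLE" and reject_triple:
            raise InputError(f"triple bond rejected in SMILES {smiles!r}")
        g.add_edge(u, v, qweight=to_quarter(_BOND_WEIGHTS[name]))
    return MolecularGraph(g, id=id, empty_input=g.number_of_nodes() == 0)


def from_edge_list(atom_types: Sequence[str],
                   weighted_edges: Iterable[tuple[int, int, float]],
                   id: str | None = None,
                   allow_triple: bool = True) -> MolecularGraph:
    """Build a graph from element symbols and ``(u, v, weight)`` triples.

    Node ids are the 0-based positions in ``atom_types``.  Used for test
    fixtures and the JSON edge-list interchange format.
    """
    g = nx.Graph()
    allowed = set(ALLOWED_WEIGHTS) | ({TRIPLE_WEIGHT} if allow_triple else set())
    for i, sym in enumerate(atom_types):
        g.add_node(i, element=str(sym))
    n = len(atom_types)
    for u, v, w in weighted_edges:
        if not (0 <= u < n and 0 <= v < n):
            raise ValidationError(f"edge ({u}, {v}) out of range for {n} atoms")
        if u == v:
            raise ValidationError(f"self-loop at node {u}")
        if g.has_edge(u, v):
            raise ValidationError(f"duplicate edge ({u}, {v})")
        if float(w) not in allowed:
            raise ValidationError(
                f"bond weight {w!r} not in allowed set {sorted(allowed)}")
        g.add_edge(u, v, qweight=to_quarter(float(w)))
    return MolecularGraph(g, id=id)


# -- file interfaces ------------------------------------------------------

def read_smiles_file(path: str | Path,
                     reject_triple: bool = False) -> list[MolecularGraph]:
    """Read a SMILES list file: one record per line, optional id column.

    Lines starting with ``#`` and blank lines are skipped.  The first
    whitespace-separated token is the SMILES, the second (if present) the id;
    records without an id get ``line<N>``.
    """
    graphs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            gid = parts[1] if len(parts) > 1 else f"line{lineno}"
            try:
                graphs.append(from_smiles(smiles, id=gid,
                                          reject_triple=reject_triple))
            except InputError as exc:
                raise InputError(f"{path}, line {lineno}: {exc}") from exc
    return graphs


def graph_to_json(g: MolecularGraph) -> dict:
    """Serialize to the edge-list JSON dialect (0-based node indices)."""
    order = list(g.nodes())
    index = {n: i for i, n in enumerate(order)}
    return {
        "id": g.id,
        "atoms": [g.atom_type(n) for n in order],
        "bonds": [[index[u], index[v], g.bond_weight(u, v)]
                  for u, v in g.edges()],
    }


def graph_from_json(data: dict) -> MolecularGraph:
    return from_edge_list(data["atoms"],
                          [(int(u), int(v), float(w)) for u, v, w in data["bonds"]],
                          id=data.get("id"))


def read_edge_list_file(path: str | Path) -> list[MolecularGraph]:
    """Read one graph (JSON object) or several (JSON array) from a file."""
    with open(path) as fh:
        data = json.load(fh)
    items = data if isinstance(data, list) else [data]
    return [graph_from_json(item) for item in items]
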