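"""Exact weighted-MCES computation via integer linear programming.

The model has binary variables y_ik (node i of graph 1 maps to node k of
graph 2; only type-equal pairs exist), c_(ij,kl) (edge ij of graph 1 maps to
edge kl of graph 2; only pairs that are endpoint-type compatible in at least
one orientation exist) and n_e (edge e of either graph stays unmapped).  The
objective sums |b(ij) - b(kl)| over mapped edge pairs and b(e) over unmapped
edges, all in exact quarter units, so the optimal objective is the weighted
MCES distance.  Neighborhood-sum constraints tie edge mapping to node
mapping; one-to-one constraints make the node map injective; partition
constraints force each edge to be mapped or unmapped.  An optional threshold
constraint caps the objective at T, which both speeds up solving and yields
the clamped semantics the myopic distance needs.

Solving is delegated to HiGHS through :func:`scipy.optimize.milp`
(single-threaded, deterministic).  When stopped early the solver's dual
bound is still a valid lower bound on the distance, which the caller
combines with the matching bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .bounds import atomtype_matching_bound
from .errors import SolverEnvironmentError
from .molgraph import MolecularGraph, from_quarter

AVAILABLE_BACKENDS = ("highs",)


@dataclass
class SolverConfig:
    """Solver backend selection and limits.

    ``backend`` must name an available MILP backend ("highs").  A
    ``time_limit`` in seconds turns the solve into an anytime computation:
    the returned status is ``time_limit`` and only the proven lower bound is
    trusted.
    """

    backend: str = "highs"
    time_limit: float | None = None

    def check(self) -> None:
        if self.backend not in AVAILABLE_BACKENDS:
            raise SolverEnvironmentError(
                f"solver backend {self.backend!r} unavailable; "
                f"available: {', '.join(AVAILABLE_BACKENDS)}")


@dataclass
class ILPModel:
    """The assembled model, with named variable index maps for inspection."""

    g1: MolecularGraph
    g2: MolecularGraph
    y_index: dict[tuple, int]           # (i, k) -> column
    c_index: dict[tuple, int]           # ((i,j), (k,l)) -> column
    n_index: dict[tuple, int]           # ("g1"|"g2", (u,v)) -> column
    objective_q: np.ndarray             # quarter-unit coefficients
    rows: list[tuple[str, dict[int, int], str, int]] = field(
        default_factory=list)           # (family, coeffs, sense, rhs)
    threshold_q: int | None = None

    @property
    def n_cols(self) -> int:
        return len(self.y_index) + len(self.c_index) + len(self.n_index)

    def to_lp(self) -> str:
        """Render the model in LP text format for debugging."""
        names = [""] * self.n_cols
        for (i, k), col in self.y_index.items():
            names[col] = f"y_{i}_{k}"
        for ((i, j), (k, l)), col in self.c_index.items():
            names[col] = f"c_{i}_{j}__{k}_{l}"
        for (side, (u, v)), col in self.n_index.items():
            names[col] = f"n_{side}_{u}_{v}"
        lines = ["Minimize", " obj: " + " + ".join(
            f"{self.objective_q[c]} {names[c]}"
            for c in range(self.n_cols) if self.objective_q[c]), "Subject To"]
        for idx, (family, coeffs, sense, rhs) in enumerate(self.rows):
            terms = " + ".join(f"{v} {names[c]}" for c, v in coeffs.items())
            op = {"le": "<=", "eq": "="}[sense]
            lines.append(f" {family}_{idx}: {terms} {op} {rhs}")
        lines.append("Binary")
        lines.append(" " + " ".join(names))
        lines.append("End")
        return "\n".join(lines)


@dataclass
class MCESSolution:
    """Outcome of an exact solve.

    ``objective_q`` is meaningful only when ``status == "optimal"``.
    ``best_lower_bound_q`` is always a valid lower bound on the true
    weighted distance (clamped from below by the matching bound).
    """

    status: str                               # optimal | infeasible | time_limit
    objective_q: int | None
    best_lower_bound_q: int
    node_mapping: dict
    edge_mapping: dict
    unmatched_edges: list[tuple[str, tuple]]

    @property
    def objective(self) -> float | None:
        return None if self.objective_q is None else from_quarter(self.objective_q)

    @property
    def best_lower_bound(self) -> float:
        return from_quarter(self.best_lower_bound_q)


def _edge_key(u, v):
    return (u, v) if repr(u) <= repr(v) else (v, u)


def build_model(g1: MolecularGraph, g2: MolecularGraph,
                threshold: float | int | None = None) -> ILPModel:
    """Assemble objective and constraints; no solving happens here.

    ``threshold`` (same scale as distances) adds the objective-cap
    constraint; pass None to solve unthresholded.
    """
    y_index: dict[tuple, int] = {}
    c_index: dict[tuple, int] = {}
    n_index: dict[tuple, int] = {}
    col = 0
    v1, v2 = list(g1.nodes()), list(g2.nodes())
    e1 = [_edge_key(u, v) for u, v in g1.edges()]
    e2 = [_edge_key(u, v) for u, v in g2.edges()]

    for i in v1:
        for k in v2:
            if g1.atom_type(i) == g2.atom_type(k):
                y_index[(i, k)] = col
                col += 1
    for ij in e1:
        i, j = ij
        ti, tj = g1.atom_type(i), g1.atom_type(j)
        for kl in e2:
            k, l = kl
            tk, tl = g2.atom_type(k), g2.atom_type(l)
            if (ti == tk and tj == tl) or (ti == tl and tj == tk):
                c_index[(ij, kl)] = col
                col += 1
    for ij in e1:
        n_index[("g1", ij)] = col
        col += 1
    for kl in e2:
        n_index[("g2", kl)] = col
        col += 1

    obj = np.zeros(col, dtype=np.int64)
    for (ij, kl), c in c_index.items():
        obj[c] = abs(g1.bond_weight_q(*ij) - g2.bond_weight_q(*kl))
    for (side, e), c in n_index.items():
        obj[c] = g1.bond_weight_q(*e) if side == "g1" else g2.bond_weight_q(*e)

    rows: list[tuple[str, dict[int, int], str, int]] = []
    # (2)/(3): the node map is injective in both directions
    for i in v1:
        coeffs = {y_index[(i, k)]: 1 for k in v2 if (i, k) in y_index}
        if coeffs:
            rows.append(("eq2", coeffs, "le", 1))
    for k in v2:
        coeffs = {y_index[(i, k)]: 1 for i in v1 if (i, k) in y_index}
        if coeffs:
            rows.append(("eq3", coeffs, "le", 1))
    # (4): edges of g2 mapped around node i require i to map to an endpoint
    for i in v1:
        nbrs = [_edge_key(i, j) for j in g1.neighbors(i)]
        for kl in e2:
            k, l = kl
            coeffs: dict[int, int] = {}
            for ij in nbrs:
                c = c_index.get((ij, kl))
                if c is not None:
                    coeffs[c] = 1
            if not coeffs:
                continue
            for yk in ((i, k), (i, l)):
                if yk in y_index:
                    coeffs[y_index[yk]] = -1
            rows.append(("eq4", coeffs, "le", 0))
    # (5): symmetric condition on nodes of g2
    for k in v2:
        nbrs = [_edge_key(k, l) for l in g2.neighbors(k)]
        for ij in e1:
            i, j = ij
            coeffs = {}
            for kl in nbrs:
                c = c_index.get((ij, kl))
                if c is not None:
                    coeffs[c] = 1
            if not coeffs:
                continue
            for yk in ((i, k), (j, k)):
                if yk in y_index:
                    coeffs[y_index[yk]] = -1
            rows.append(("eq5", coeffs, "le", 0))
    # (6)/(7): every edge is mapped exactly once or marked unmapped
    for ij in e1:
        coeffs = {c: 1 for (ij2, kl), c in c_index.items() if ij2 == ij}
        coeffs[n_index[("g1", ij)]] = 1
        rows.append(("eq6", coeffs, "eq", 1))
    for kl in e2:
        coeffs = {c: 1 for (ij, kl2), c in c_index.items() if kl2 == kl}
        coeffs[n_index[("g2", kl)]] = 1
        rows.append(("eq7", coeffs, "eq", 1))

    threshold_q = None
    if threshold is not None:
        threshold_q = round(float(threshold) * 4)
        coeffs = {c: int(obj[c]) for c in range(col) if obj[c]}
        if coeffs:
            rows.append(("eq8", coeffs, "le", threshold_q))

    return ILPModel(g1, g2, y_index, c_index, n_index, obj, rows, threshold_q)


def _solve_milp(model: ILPModel, config: SolverConfig):
    n = model.n_cols
    data, ri, ci, lo, hi = [], [], [], [], []
    for r, (_, coeffs, sense, rhs) in enumerate(model.rows):
        for c, v in coeffs.items():
            ri.append(r)
            ci.append(c)
            data.append(v)
        lo.append(rhs if sense == "eq" else -np.inf)
        hi.append(rhs)
    a = sparse.csr_matrix((data, (ri, ci)), shape=(len(model.rows), n))
    constraints = [LinearConstraint(a, np.array(lo), np.array(hi))]
    options = {"presolve": True}
    if config.time_limit is not None:
        options["time_limit"] = float(config.time_limit)
    return milp(c=model.objective_q.astype(float), constraints=constraints,
                integrality=np.ones(n), bounds=Bounds(0, 1), options=options)


def solve_exact(g1: MolecularGraph, g2: MolecularGraph,
                threshold: float | int | None = None,
                time_limit: float | None = None,
                solver_config: SolverConfig | None = None) -> MCESSolution:
    """Solve the weighted-MCES ILP for a pair of molecular graphs.

    Returns status ``optimal`` with the minimum weighted distance (subject
    to the threshold cap if one is given), ``infeasible`` when a threshold
    is set and the true distance exceeds it, or ``time_limit`` when an
    anytime solve was stopped; in the last case only ``best_lower_bound``
    is valid.
    """
    config = solver_config or SolverConfig()
    if time_limit is not None:
        config = SolverConfig(backend=config.backend, time_limit=time_limit)
    config.check()

    match_q = atomtype_matching_bound(g1, g2).value_q
    model = build_model(g1, g2, threshold)

    if model.n_cols == 0:  # two graphs with no atoms at all
        return MCESSolution("optimal", 0, 0, {}, {}, [])

    res = _solve_milp(model, config)
    if res.status == 0:
        obj_q = int(round(res.fun))
        node_mapping, edge_mapping, unmatched = _extract(model, res.x)
        return MCESSolution("optimal", obj_q, max(obj_q, match_q),
                            node_mapping, edge_mapping, unmatched)
    if res.status == 2:  # infeasible: only possible under the threshold cap
        if model.threshold_q is None:
            raise RuntimeError("unthresholded model reported infeasible")
        return MCESSolution("infeasible", None,
                            max(model.threshold_q, match_q), {}, {}, [])
    if res.status == 1:  # stopped at the time limit
        dual = getattr(res, "mip_dual_bound", None)
        lb = int(math.floor(dual + 1e-9)) if dual is not None else 0
        return MCESSolution("time_limit", None, max(lb, match_q), {}, {}, [])
    raise RuntimeError(f"unexpected solver status {res.status}: {res.message}")


def _extract(model: ILPModel, x: np.ndarray):
    node_mapping = {i: k for (i, k), c in model.y_index.items() if x[c] > 0.5}
    edge_mapping = {ij: kl for (ij, kl), c in model.c_index.items()
                    if x[c] > 0.5}
    unmatched = [(side, e) for (side, e), c in model.n_index.items()
                 if x[c] > 0.5]
    return node_mapping, edge_mapping, unmatched


def verify_solution(g1: MolecularGraph, g2: MolecularGraph,
                    sol: MCESSolution) -> str:
    """Independently recheck a reported optimal solution.

    Returns ``"ok"`` or a message naming the first violated constraint
    family.  Works directly from the mappings, not from solver state.
    """
    if sol.status != "optimal":
        return "not an optimal solution"
    # injectivity, both directions (Eqs. 2-3)
    if len(set(sol.node_mapping.values())) != len(sol.node_mapping):
        return "violation: node map not injective (Eq. 3)"
    for i, k in sol.node_mapping.items():
        if g1.atom_type(i) != g2.atom_type(k):
            return "violation: node map not type-preserving (Eq. 2)"
    # endpoint consistency of mapped edges (Eqs. 4-5)
    for (i, j), (k, l) in sol.edge_mapping.items():
        mi, mj = sol.node_mapping.get(i), sol.node_mapping.get(j)
        if {mi, mj} != {k, l}:
            return "violation: edge map inconsistent with node map (Eqs. 4-5)"
    # each edge mapped xor unmatched (Eqs. 6-7)
    unmatched1 = {e for side, e in sol.unmatched_edges if side == "g1"}
    unmatched2 = {e for side, e in sol.unmatched_edges if side == "g2"}
    e1 = {_edge_key(u, v) for u, v in g1.edges()}
    e2 = {_edge_key(u, v) for u, v in g2.edges()}
    mapped1 = set(sol.edge_mapping.keys())
    mapped2 = set(sol.edge_mapping.values())
    if len(mapped2) != len(mapped1):
        return "violation: two edges mapped to one (Eq. 7)"
    if mapped1 | unmatched1 != e1 or mapped1 & unmatched1:
        return "violation: edge not mapped xor unmatched (Eq. 6)"
    if mapped2 | unmatched2 != e2 or mapped2 & unmatched2:
        return "violation: edge not mapped xor unmatched (Eq. 7)"
    # objective recomputation
    obj = sum(abs(g1.bond_weight_q(*ij) - g2.bond_weight_q(*kl))
              for ij, kl in sol.edge_mapping.items())
    obj += sum(g1.bond_weight_q(*e) for e in unmatched1)
    obj += sum(g2.bond_weight_q(*e) for e in unmatched2)
    if obj != sol.objective_q:
        return (f"violation: objective mismatch "
                f"(recomputed {obj}, reported {sol.objective_q})")
    return "ok"
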