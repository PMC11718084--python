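"""Exact ILP: model structure, worked values, threshold semantics,
solution verification."""

import numpy as np
import pytest

from mcesdist import (MCESSolution, SolverConfig, SolverEnvironmentError,
                      build_model, from_edge_list, brute_force_mces,
                      random_molecular_graph, solve_exact, verify_solution)


def test_model_variable_counts(toys):
    m = build_model(toys["ethane"], toys["methane-carbon"])
    # both ethane carbons are type-compatible with the single methane carbon
    assert (len(m.y_index), len(m.c_index), len(m.n_index)) == (2, 0, 1)
    m = build_model(toys["ethane"], toys["ethane"])
    assert (len(m.y_index), len(m.c_index), len(m.n_index)) == (4, 1, 2)


def test_disjoint_element_sets_forced_objective():
    g1 = from_edge_list(["N", "N"], [(0, 1, 1.0)])
    g2 = from_edge_list(["O", "O"], [(0, 1, 2.0)])
    m = build_model(g1, g2)
    assert len(m.y_index) == 0 and len(m.c_index) == 0
    sol = solve_exact(g1, g2)
    assert sol.status == "optimal"
    assert sol.objective == g1.total_bond_weight() + g2.total_bond_weight()


@pytest.mark.parametrize("a,b,expected", [
    ("benzene", "benzene", 0.0),
    ("benzene", "cyclohexane", 3.0),       # six ring edges each |1.5-1.0|
    ("carbon-triangle", "propane", 1.0),   # 3 + 2 - 2*2
    ("ethanol", "ethane", 1.0),            # drop the C-O edge
])
def test_worked_exact_distances(toys, a, b, expected):
    assert brute_force_mces(toys[a], toys[b]) == expected  # oracle first
    sol = solve_exact(toys[a], toys[b], threshold=10)
    assert sol.status == "optimal" and sol.objective == expected
    assert verify_solution(toys[a], toys[b], sol) == "ok"


def test_threshold_infeasible_and_consistency(toys):
    # benzene-methane distance is 9 > 5, so the capped model is infeasible
    sol = solve_exact(toys["benzene"], toys["methane-carbon"], threshold=5)
    assert sol.status == "infeasible"
    assert sol.best_lower_bound >= 5.0
    # re-solving without the cap gives the same value when below the cap
    with_t = solve_exact(toys["benzene"], toys["cyclohexane"], threshold=10)
    without = solve_exact(toys["benzene"], toys["cyclohexane"])
    assert with_t.objective == without.objective == 3.0


def test_value_symmetry_on_random_pairs():
    rng = np.random.default_rng(23)
    for _ in range(10):
        g1 = random_molecular_graph(int(rng.integers(4, 9)),
                                    seed=int(rng.integers(2**31)))
        g2 = random_molecular_graph(int(rng.integers(4, 9)),
                                    seed=int(rng.integers(2**31)))
        assert solve_exact(g1, g2).objective == solve_exact(g2, g1).objective


def test_unweighted_specialization():
    """With unit weights the objective is |E1| + |E2| - 2|Ec|."""
    rng = np.random.default_rng(29)
    for _ in range(8):
        g1 = random_molecular_graph(int(rng.integers(4, 8)),
                                    seed=int(rng.integers(2**31)),
                                    p_double=0.0, aromatic_cycles_only=False)
        g2 = random_molecular_graph(int(rng.integers(4, 8)),
                                    seed=int(rng.integers(2**31)),
                                    p_double=0.0, aromatic_cycles_only=False)
        # force all-single weights
        for g in (g1, g2):
            for u, v in g.edges():
                g.graph.edges[u, v]["qweight"] = 4
        sol = solve_exact(g1, g2)
        n_common = len(sol.edge_mapping)
        assert sol.objective == g1.n_edges + g2.n_edges - 2 * n_common


def test_verify_solution_catches_violations(toys):
    eth = toys["ethane"]
    good = solve_exact(eth, eth)
    assert verify_solution(eth, eth, good) == "ok"
    # non-injective node map
    bad = MCESSolution("optimal", 0, 0, {0: 0, 1: 0}, {}, [])
    assert "Eq. 3" in verify_solution(eth, eth, bad) or \
        "injective" in verify_solution(eth, eth, bad)
    # one edge mapped while also flagged unmatched
    e = tuple(eth.edges())[0]
    key = (e[0], e[1]) if repr(e[0]) <= repr(e[1]) else (e[1], e[0])
    bad2 = MCESSolution("optimal", 0, 0, {0: 0, 1: 1},
                        {key: key}, [("g1", key)])
    assert "Eq. 6" in verify_solution(eth, eth, bad2)


def test_unknown_backend_raises():
    with pytest.raises(SolverEnvironmentError, match="highs"):
        SolverConfig(backend="cplex").check()


def test_lp_export_mentions_all_variable_families(toys):
    m = build_model(toys["ethanol"], toys["ethane"], threshold=10)
    text = m.to_lp()
    assert "Minimize" in text and "Binary" in text
    assert "y_" in text and "n_" in text and "eq8" in text
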