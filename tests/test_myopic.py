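"""Myopic distance semantics, metric properties, closure."""

import numpy as np
import pytest

from mcesdist import (DistanceTable, PairRecord, ValidationError,
                      atomtype_matching_bound, metric_closure,
                      myopic_distance, pairwise_distances,
                      random_molecular_graph)


@pytest.mark.parametrize("a,b,T,value,provenance", [
    ("benzene", "benzene", 10, 0.0, "exact"),
    ("benzene", "cyclohexane", 10, 3.0, "exact"),
    ("benzene", "cyclohexane", 2, 3.0, "bound"),    # bound 3 >= 2, no ILP
    ("benzene", "methane-carbon", 5, 9.0, "bound"),
])
def test_worked_myopic_distances(toys, a, b, T, value, provenance):
    res = myopic_distance(toys[a], toys[b], T=T)
    assert (res.value, res.provenance) == (value, provenance)
    assert res.threshold == T


def test_bounds_only_reports_matching_bound(toys):
    from mcesdist import MyopicConfig
    res = myopic_distance(toys["benzene"], toys["cyclohexane"], T=10,
                          config=MyopicConfig(bounds_only=True))
    assert res.provenance == "bound" and res.value == 3.0


def test_threshold_must_be_positive(toys):
    with pytest.raises(ValidationError):
        myopic_distance(toys["ethane"], toys["ethane"], T=0)


def test_empty_vs_empty_graphs():
    from mcesdist import from_edge_list
    e = from_edge_list([], [])
    res = myopic_distance(e, e, T=10)
    assert res.value == 0.0 and res.provenance == "exact"


def test_provenance_dichotomy_and_bound_consistency():
    rng = np.random.default_rng(37)
    graphs = [random_molecular_graph(int(rng.integers(4, 16)),
                                     seed=int(rng.integers(2**31)))
              for _ in range(30)]
    for i in range(0, 30, 2):
        g1, g2 = graphs[i], graphs[i + 1]
        res = myopic_distance(g1, g2, T=10)
        if res.provenance == "exact":
            assert res.value < 10
            assert res.value_q % 2 == 0  # half-unit grid when exact
        elif res.provenance == "clamped":
            assert res.value == 10.0
        else:
            assert res.value >= 10
            assert res.value == atomtype_matching_bound(g1, g2).value


def test_exact_at_lower_threshold_agrees_with_higher():
    """Provenance=exact at T1 implies the same value at any T2 >= T1."""
    rng = np.random.default_rng(41)
    seen_exact = 0
    for _ in range(15):
        g1 = random_molecular_graph(int(rng.integers(4, 9)),
                                    seed=int(rng.integers(2**31)))
        g2 = random_molecular_graph(int(rng.integers(4, 9)),
                                    seed=int(rng.integers(2**31)))
        r10 = myopic_distance(g1, g2, T=10)
        if r10.provenance == "exact":
            r25 = myopic_distance(g1, g2, T=25)
            assert r25.value == r10.value and r25.provenance == "exact"
            seen_exact += 1
    assert seen_exact > 0


def test_isomorphic_relabeled_copy_has_distance_zero():
    g = random_molecular_graph(10, seed=99)
    perm = {n: f"x{(7 * i + 3) % 10}" for i, n in enumerate(g.nodes())}
    h = g.relabeled(perm)
    res = myopic_distance(g, h, T=10)
    assert res.value == 0.0 and res.provenance == "exact"


def test_metric_closure_identity_on_myopic_table():
    graphs = [random_molecular_graph(n, seed=n) for n in (5, 8, 11, 14)]
    table = pairwise_distances(graphs, T=6)
    closed = metric_closure(table)
    for key, rec in table.records.items():
        assert closed.records[key].value_q == rec.value_q


def test_metric_closure_shortens_violating_entry():
    table = DistanceTable(ids=["a", "b", "c"], threshold_q=40)
    table.add(PairRecord("a", "b", 4, "exact"))
    table.add(PairRecord("b", "c", 4, "exact"))
    table.add(PairRecord("a", "c", 20, "exact"))
    closed = metric_closure(table)
    assert closed.get("a", "c").value_q == 8
    assert closed.get("a", "b").value_q == 4  # no entry increases


def test_metric_closure_rejects_incomplete_table():
    table = DistanceTable(ids=["a", "b", "c"], threshold_q=40)
    table.add(PairRecord("a", "b", 4, "exact"))
    with pytest.raises(ValidationError, match="missing"):
        metric_closure(table)
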