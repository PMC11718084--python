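"""Batch tables, nearest-neighbor statistics, I/O and the CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

from mcesdist import (ValidationError, coverage_profile,
                      nearest_neighbor_distances, pairwise_distances,
                      random_molecular_graph, read_table, toy_library,
                      write_square_matrix, write_table)
from mcesdist.cli import main as cli_main


@pytest.fixture(scope="module")
def toy_table():
    toys = toy_library()
    structs = [toys["benzene"], toys["cyclohexane"], toys["methane-carbon"]]
    return structs, pairwise_distances(structs, T=10)


def test_three_structure_fixture_values(toy_table):
    _, table = toy_table
    assert len(table.records) == 3
    assert table.get("benzene", "cyclohexane").value == 3.0
    assert table.get("benzene", "methane-carbon").value == 9.0
    assert table.get("cyclohexane", "methane-carbon").value == 6.0


def test_empty_and_duplicate_inputs():
    assert pairwise_distances([], T=10).records == {}
    toys = toy_library()
    g1, g2 = toys["ethane"].copy(), toys["ethane"].copy()
    g2.id = g1.id = "dup"
    with pytest.raises(ValidationError, match="dup"):
        pairwise_distances([g1, g2], T=10)


def test_nearest_neighbor_minima(toy_table):
    _, table = toy_table
    nn = nearest_neighbor_distances(table)
    by_id = dict(zip(nn["id"], nn["min_distance"]))
    assert by_id == {"benzene": 3.0, "cyclohexane": 3.0,
                     "methane-carbon": 6.0}
    assert not nn.set_index("id").loc["benzene", "censored"]
    with pytest.warns(UserWarning):
        empty = nearest_neighbor_distances(table, query_ids=["nope"])
    assert empty.empty


def test_coverage_profile_kth_minimum():
    toys = toy_library()
    prof = coverage_profile([toys["cyclohexane"]],
                            [toys["benzene"], toys["methane-carbon"]], T=10)
    assert prof["distance"].tolist() == [3.0]
    prof2 = coverage_profile([toys["cyclohexane"]],
                             [toys["benzene"], toys["methane-carbon"]],
                             T=10, k=2)
    assert prof2["distance"].tolist() == [6.0]
    # structure present in the background has distance zero
    prof3 = coverage_profile([toys["benzene"]], [toys["benzene"]], T=10)
    assert prof3["distance"].tolist() == [0.0]
    with pytest.raises(ValidationError):
        coverage_profile([toys["benzene"]], [], T=10)


def test_table_round_trip(tmp_path, toy_table):
    _, table = toy_table
    p = tmp_path / "table.csv"
    write_table(table, p)
    back = read_table(p)
    assert back.ids == table.ids and back.threshold_q == table.threshold_q
    assert back.records == table.records

    empty = pairwise_distances([], T=10)
    write_table(empty, tmp_path / "empty.csv")
    assert read_table(tmp_path / "empty.csv").records == {}


def test_read_table_rejects_mismatched_threshold(tmp_path, toy_table):
    _, table = toy_table
    p = tmp_path / "bad.csv"
    write_table(table, p)
    text = p.read_text().replace("exact,10.0", "exact,12.0", 1)
    p.write_text(text)
    from mcesdist import InputError
    with pytest.raises(InputError, match="line"):
        read_table(p)


def test_square_matrix_export(tmp_path, toy_table):
    import pandas as pd
    _, table = toy_table
    p = tmp_path / "square.csv"
    write_square_matrix(table, p)
    df = pd.read_csv(p, index_col=0)
    assert (df.values.diagonal() == 0).all()
    assert df.loc["benzene", "cyclohexane"] == 3.0
    assert np.allclose(df.values, df.values.T)


def test_censoring_consistency_and_truncation_shape():
    """Pairwise values above T only ever come from bounds; at desk scale
    most random pairs are censored at T (the hump of the histogram)."""
    rng = np.random.default_rng(53)
    graphs = [random_molecular_graph(int(rng.integers(6, 26)),
                                     seed=int(rng.integers(2**31)))
              for _ in range(26)]
    table = pairwise_distances(graphs, T=10)
    n_bound = sum(r.provenance == "bound" for r in table.records.values())
    n_exact = sum(r.provenance == "exact" for r in table.records.values())
    for rec in table.records.values():
        if rec.value_q > 40:
            assert rec.provenance == "bound"
        if rec.value_q < 40:
            assert rec.provenance == "exact"
    assert n_bound > n_exact


def test_resume_skips_existing_pairs(toy_table):
    structs, table = toy_table
    partial = pairwise_distances(structs[:2], T=10)
    resumed = pairwise_distances(structs, T=10, resume_from=partial)
    assert resumed.records == table.records
    with pytest.raises(ValidationError, match="threshold"):
        pairwise_distances(structs, T=5, resume_from=partial)


# -- CLI ------------------------------------------------------------------

def test_cli_pair_and_exit_codes():
    runner = CliRunner()
    ok = runner.invoke(cli_main, ["pair", "--smiles", "c1ccccc1",
                                  "--smiles", "C1CCCCC1", "-T", "10"])
    assert ok.exit_code == 0 and "exact\t3.0" in ok.output
    bad = runner.invoke(cli_main, ["pair", "--smiles", "xyz[",
                                   "--smiles", "CC"])
    assert bad.exit_code == 2


def test_cli_batch(tmp_path):
    p = tmp_path / "pairs.csv"
    p.write_text("id1,id2,smiles1,smiles2\n"
                 "bz,ch,c1ccccc1,C1CCCCC1\n"
                 "et,eo,CC,CCO\n")
    runner = CliRunner()
    res = runner.invoke(cli_main, ["batch", str(p)])
    assert res.exit_code == 0
    assert "bz,ch,3.0,exact" in res.output
    assert "et,eo,1.0,exact" in res.output


def test_cli_matrix_and_coverage(tmp_path):
    smi = tmp_path / "structs.smi"
    smi.write_text("c1ccccc1 benzene\nC1CCCCC1 cyclohexane\nC methane\n")
    out = tmp_path / "table.csv"
    runner = CliRunner()
    res = runner.invoke(cli_main, ["matrix", str(smi), "-o", str(out),
                                   "--square", str(tmp_path / "sq.csv")])
    assert res.exit_code == 0, res.output
    table = read_table(out)
    assert table.get("benzene", "cyclohexane").value == 3.0

    res2 = runner.invoke(cli_main, ["coverage", str(smi), str(smi)])
    assert res2.exit_code == 0
    assert "benzene,0.0" in res2.output
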