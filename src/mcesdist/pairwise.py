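"""Batch pairwise myopic distances, coverage statistics and table I/O.

A :class:`DistanceTable` stores the lower triangle of the pairwise myopic
distance matrix in long form (one record per unordered pair, self distances
implicitly 0), all sharing a single threshold.  Tables are written as
commented CSV so partial runs can be resumed, and can be exported as a
square matrix for embedding tools that accept precomputed distances.
"""

from __future__ import annotations

import multiprocessing as mp
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .errors import InputError, ValidationError
from .molgraph import MolecularGraph, from_quarter
from .myopic import MyopicConfig, myopic_distance

_FORMAT_TAG = "mcesdist-table v1"


@dataclass(frozen=True)
class PairRecord:
    id1: str
    id2: str
    value_q: int
    provenance: str

    @property
    def value(self) -> float:
        return from_quarter(self.value_q)


@dataclass
class DistanceTable:
    """Long-form pairwise distance records over an ordered id list."""

    ids: list[str]
    threshold_q: int
    records: dict[tuple[str, str], PairRecord] = field(default_factory=dict)

    def _key(self, id1: str, id2: str) -> tuple[str, str]:
        if id1 == id2:
            raise ValidationError("self-pairs are implicit (distance 0)")
        return (id1, id2) if id1 < id2 else (id2, id1)

    def add(self, rec: PairRecord) -> None:
        key = self._key(rec.id1, rec.id2)
        self.records[key] = rec if (rec.id1, rec.id2) == key else PairRecord(
            key[0], key[1], rec.value_q, rec.provenance)

    def get(self, id1: str, id2: str) -> PairRecord:
        return self.records[self._key(id1, id2)]

    def has(self, id1: str, id2: str) -> bool:
        return self._key(id1, id2) in self.records

    @property
    def threshold(self) -> float:
        return from_quarter(self.threshold_q)

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        for a in range(len(self.ids)):
            for b in range(a + 1, len(self.ids)):
                if not self.has(self.ids[a], self.ids[b]):
                    out.append((self.ids[a], self.ids[b]))
        return out

    @property
    def complete(self) -> bool:
        return not self.missing_pairs()

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(r.id1, r.id2, r.value, r.provenance)
                for r in sorted(self.records.values(),
                                key=lambda r: (r.id1, r.id2))]
        return pd.DataFrame(rows, columns=["id1", "id2", "distance",
                                           "provenance"])


def _compute_pair(args):
    idx, g1, g2, t, config = args
    res = myopic_distance(g1, g2, T=from_quarter(t), config=config)
    return idx, res.value_q, res.provenance


def pairwise_distances(structures: list[MolecularGraph],
                       T: float = 10.0,
                       workers: int = 1,
                       resume_from: DistanceTable | None = None,
                       config: MyopicConfig | None = None,
                       checkpoint: str | Path | None = None) -> DistanceTable:
    """Myopic distances over all unordered pairs of ``structures``.

    Results are deterministic regardless of ``workers`` and of visit order;
    pairs already present in ``resume_from`` are reused, so an interrupted
    run can be completed from its checkpoint file.  When ``checkpoint`` is
    given the table is flushed to disk after every computed pair.
    """
    ids = [g.id or f"s{i}" for i, g in enumerate(structures)]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValidationError(f"duplicate structure ids: {dupes}")
    t_q = round(float(T) * 4)
    table = DistanceTable(ids=ids, threshold_q=t_q)
    by_id = dict(zip(ids, structures))

    if resume_from is not None:
        if resume_from.threshold_q != t_q:
            raise ValidationError(
                f"resume table threshold {resume_from.threshold} != {T}")
        for rec in resume_from.records.values():
            if rec.id1 in by_id and rec.id2 in by_id:
                table.add(rec)

    # deterministic shard order: pair index in id-sorted enumeration
    todo = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if not table.has(ids[a], ids[b]):
                todo.append((a, b))

    jobs = [((a, b), by_id[ids[a]], by_id[ids[b]], t_q, config)
            for a, b in todo]
    if workers > 1 and len(jobs) > 1:
        ctx = mp.get_context("fork")
        with ctx.Pool(workers) as pool:
            results = pool.map(_compute_pair, jobs,
                               chunksize=max(1, len(jobs) // (workers * 4)))
    else:
        results = [_compute_pair(job) for job in jobs]

    for (a, b), value_q, provenance in sorted(results):
        table.add(PairRecord(*table._key(ids[a], ids[b]), value_q, provenance))
        if checkpoint is not None:
            write_table(table, checkpoint)
    if checkpoint is not None:
        write_table(table, checkpoint)
    return table


def nearest_neighbor_distances(table: DistanceTable,
                               query_ids: list[str] | None = None
                               ) -> pd.DataFrame:
    """Per-structure minimum distance to any other structure in the table.

    Values at or above the threshold are censored: they mean "at least this
    dissimilar" and produce the characteristic hump at T in nearest-neighbor
    histograms.  Returns a DataFrame with columns id, min_distance,
    censored.
    """
    queries = list(query_ids) if query_ids is not None else list(table.ids)
    known = [q for q in queries if q in set(table.ids)]
    if query_ids is not None and not known:
        import warnings
        warnings.warn("no query id present in the table; empty result")
        return pd.DataFrame(columns=["id", "min_distance", "censored"])
    missing = table.missing_pairs()
    relevant = [p for p in missing if p[0] in set(known) or p[1] in set(known)]
    if relevant:
        raise ValidationError(f"table incomplete for queries: {relevant[:5]}")
    rows = []
    for q in known:
        vals = [table.get(q, other).value_q for other in table.ids
                if other != q]
        if not vals:
            continue
        best = min(vals)
        rows.append((q, from_quarter(best), best >= table.threshold_q))
    return pd.DataFrame(rows, columns=["id", "min_distance", "censored"])


def coverage_profile(dataset: list[MolecularGraph],
                     background: list[MolecularGraph],
                     T: float = 10.0,
                     k: int = 1,
                     workers: int = 1,
                     config: MyopicConfig | None = None) -> pd.DataFrame:
    """k-th nearest background distance for every dataset structure.

    Measures how well ``background`` (e.g. a training set plus reference
    structures) covers the region of chemical space occupied by
    ``dataset``: large or censored values flag structures the background
    does not represent.  Returns a DataFrame with columns id, distance,
    censored (distance >= T).
    """
    if not background:
        raise ValidationError("background must not be empty")
    if k < 1 or k > len(background):
        raise ValidationError(f"k={k} out of range for background size "
                              f"{len(background)}")
    t_q = round(float(T) * 4)
    jobs = []
    for i, g in enumerate(dataset):
        for j, h in enumerate(background):
            jobs.append(((i, j), g, h, t_q, config))
    if workers > 1 and len(jobs) > 1:
        ctx = mp.get_context("fork")
        with ctx.Pool(workers) as pool:
            results = pool.map(_compute_pair, jobs)
    else:
        results = [_compute_pair(job) for job in jobs]
    values: dict[int, list[int]] = {}
    for (i, _j), value_q, _prov in results:
        values.setdefault(i, []).append(value_q)
    rows = []
    for i, g in enumerate(dataset):
        kth = sorted(values[i])[k - 1]
        rows.append((g.id or f"s{i}", from_quarter(kth), kth >= t_q))
    return pd.DataFrame(rows, columns=["id", "distance", "censored"])


# -- table I/O ------------------------------------------------------------

def write_table(table: DistanceTable, path: str | Path) -> None:
    """Write a (possibly partial) table as commented CSV; lossless."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        fh.write(f"# {_FORMAT_TAG}\n")
        fh.write(f"# version: {_pkg_version}\n")
        fh.write(f"# threshold: {from_quarter(table.threshold_q)}\n")
        fh.write("# ids: " + " ".join(table.ids) + "\n")
        fh.write("id1,id2,distance,provenance,threshold\n")
        for rec in sorted(table.records.values(), key=lambda r: (r.id1, r.id2)):
            fh.write(f"{rec.id1},{rec.id2},{rec.value},{rec.provenance},"
                     f"{from_quarter(table.threshold_q)}\n")
    tmp.replace(path)


def read_table(path: str | Path) -> DistanceTable:
    """Read a table written by :func:`write_table`; partial tables are fine."""
    path = Path(path)
    ids: list[str] | None = None
    threshold: float | None = None
    records = []
    with open(path) as fh:
        lines = fh.readlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("threshold:"):
                threshold = float(body.split(":", 1)[1])
            elif body.startswith("ids:"):
                ids = body.split(":", 1)[1].split()
            continue
        if not header_seen:
            if line != "id1,id2,distance,provenance,threshold":
                raise InputError(f"{path}, line {lineno}: bad column header")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 5:
            raise InputError(f"{path}, line {lineno}: expected 5 fields")
        id1, id2, dist, prov, row_t = parts
        try:
            value = float(dist)
            row_threshold = float(row_t)
        except ValueError:
            raise InputError(f"{path}, line {lineno}: non-numeric value")
        if prov not in ("exact", "clamped", "bound"):
            raise InputError(f"{path}, line {lineno}: bad provenance {prov!r}")
        records.append((lineno, id1, id2, value, prov, row_threshold))
    if ids is None or threshold is None:
        raise InputError(f"{path}: missing ids/threshold header")
    t_q = round(threshold * 4)
    table = DistanceTable(ids=ids, threshold_q=t_q)
    for lineno, id1, id2, value, prov, row_threshold in records:
        if round(row_threshold * 4) != t_q:
            raise InputError(
                f"{path}, line {lineno}: threshold {row_threshold} does not "
                f"match table threshold {threshold}")
        table.add(PairRecord(id1, id2, round(value * 4), prov))
    return table


def write_square_matrix(table: DistanceTable, path: str | Path) -> None:
    """Symmetric square-matrix CSV export with zero diagonal.

    The hand-off format for embedding tools (UMAP/t-SNE in precomputed-
    distance mode); requires a complete table.
    """
    missing = table.missing_pairs()
    if missing:
        raise ValidationError(f"table incomplete: {missing[:5]}")
    n = len(table.ids)
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            v = table.get(table.ids[a], table.ids[b]).value
            mat[a, b] = mat[b, a] = v
    pd.DataFrame(mat, index=table.ids, columns=table.ids).to_csv(path)
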