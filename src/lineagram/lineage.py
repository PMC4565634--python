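"""Lineage query database built from per-interval correspondence tables.

After tracking, each interval ``t -> t+1`` is reduced to a *pair table*
``P^t`` holding one ``(source, sink)`` row per retained edge plus one
row per Dump (death) and per birth pseudo-source attachment.  Chaining
full outer joins of ``P^1, P^2, ..., P^{T-1}`` — joining the last column
of the accumulating database against the first column of the next table
— yields the lineage database: one row per complete evolution thread
across all ``T`` time-stamps.

Markers inside database cells:

* ``DUMP`` — the cluster died entering this column; the marker
  propagates through all later columns, so death can never be confused
  with a later birth.
* the empty string — padding before a birth; a thread born at time ``b``
  has empty cells in columns ``1..b-1``.

Birth pseudo-identifiers (``C0``, ``C-1``, ...) are consumed during the
join and replaced by fresh thread origins ``NewC<k>``, numbered globally
in birth order starting after the number of initial communities (a run
starting from 13 communities labels its first newborn ``NewC14``).

Rows arising from the outer-join cross product are deliberately *not*
deduplicated: duplicate-looking rows carry branch multiplicity, which
:func:`extract_threads` turns into a branch tree per origin.  Branches
created by a split never re-collapse into one line, even when they later
share a cluster label ("no-collapse" rule); this keeps every drawable
line a function of its own history.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from lineagram.tracking import DUMP, BipartiteMap

#: cell marker for a dead thread segment (written verbatim to lineage files)
DEAD_MARK = "DUMP"
#: cell marker for pre-birth padding (an empty cell in lineage files)
EMPTY_MARK = ""


class LineageError(ValueError):
    """Raised on contract violations while building the query database."""


@dataclass(frozen=True)
class PairTable:
    """``(source, sink)`` rows of one interval's pruned tracking map.

    ``rows`` lists retained edges and Dump attachments sorted by
    (source, target); ``births`` lists ``(pseudo_label, newborn_label)``
    pairs in birth order (``C0`` first).
    """

    t: int
    rows: tuple
    births: tuple = ()


@dataclass(frozen=True)
class QueryRow:
    origin: str
    cells: tuple


@dataclass
class QueryDatabase:
    """The joined lineage table: one row per evolution thread.

    ``n_times`` is the number of time columns currently covered,
    ``n_initial`` the number of distinct origins at the first
    time-stamp, and ``next_newc`` the next global newborn number.
    """

    n_times: int
    rows: list
    n_initial: int
    next_newc: int

    @property
    def origins(self) -> list:
        """Distinct thread origins in first-appearance order."""
        seen: dict = {}
        for row in self.rows:
            seen.setdefault(row.origin, None)
        return list(seen)

    def as_table(self) -> list:
        return [row.cells for row in self.rows]


@dataclass
class Branch:
    """One drawable line of a thread tree.

    ``labels[time]`` is the cluster label while the branch is alive;
    ``start`` its first time-stamp; ``parent`` the branch it forked from
    (``None`` for the main branch); ``died_at`` the time-stamp at which
    the branch's community entered the Dump sink, if it did.
    """

    origin: str
    branch_id: int
    start: int
    labels: dict
    parent: Optional[int] = None
    died_at: Optional[int] = None

    @property
    def end(self) -> int:
        """Last time-stamp at which the branch carries a label."""
        return max(self.labels)


@dataclass
class ThreadTree:
    """All branches of one origin, branch 0 being the main line."""

    origin: str
    branches: list

    def branch(self, branch_id: int) -> Branch:
        return self.branches[branch_id]


def make_pair_table(bmap: BipartiteMap) -> PairTable:
    """Reduce a pruned map with pseudo-clusters to its pair table."""
    if bmap.retained is None:
        raise LineageError("pair table requires a pruned map")
    rows = sorted(
        [(e.source, e.target) for e in bmap.retained]
        + [(src, DUMP) for src in bmap.dump_attachments]
    )
    return PairTable(t=bmap.t, rows=tuple(rows), births=tuple(bmap.birth_attachments))


def _initial_database(p: PairTable) -> QueryDatabase:
    sources = {s for s, _ in p.rows}
    n_initial = len(sources)
    rows = [
        QueryRow(origin=s, cells=(s, DEAD_MARK if tg == DUMP else tg))
        for s, tg in p.rows
    ]
    next_newc = n_initial + 1
    for _pseudo, lab in p.births:
        rows.append(QueryRow(origin=f"NewC{next_newc}", cells=(EMPTY_MARK, lab)))
        next_newc += 1
    db = QueryDatabase(n_times=2, rows=rows, n_initial=n_initial, next_newc=next_newc)
    _sort_rows(db)
    return db


def _sort_rows(db: QueryDatabase) -> None:
    db.rows.sort(key=lambda r: (r.cells, r.origin))


def outer_join_step(db: QueryDatabase, p: PairTable) -> QueryDatabase:
    """Full outer join of the database's last column against ``p``'s sources.

    Every matching (db row, pair row) combination produces one output
    row; dead threads extend with the ``DUMP`` marker; birth rows open
    new threads padded with empty cells.
    """
    if p.t != db.n_times:
        raise LineageError(
            f"pair table for interval {p.t}->{p.t + 1} cannot extend a "
            f"database covering {db.n_times} time-stamps"
        )
    succ = defaultdict(list)
    for s, tg in p.rows:
        succ[s].append(tg)
    rows = []
    for row in db.rows:
        last = row.cells[-1]
        if last == DEAD_MARK:
            rows.append(QueryRow(row.origin, row.cells + (DEAD_MARK,)))
            continue
        targets = succ.get(last)
        if not targets:
            # a live cluster with no pair-table row: treat as unmatched
            # outer-join side and close the thread
            rows.append(QueryRow(row.origin, row.cells + (DEAD_MARK,)))
            continue
        for tg in targets:
            cell = DEAD_MARK if tg == DUMP else tg
            rows.append(QueryRow(row.origin, row.cells + (cell,)))
    next_newc = db.next_newc
    for _pseudo, lab in p.births:
        rows.append(
            QueryRow(f"NewC{next_newc}", (EMPTY_MARK,) * db.n_times + (lab,))
        )
        next_newc += 1
    out = QueryDatabase(
        n_times=db.n_times + 1,
        rows=rows,
        n_initial=db.n_initial,
        next_newc=next_newc,
    )
    _sort_rows(out)
    return out


def build_query_database(pair_tables: Sequence) -> QueryDatabase:
    """Left-fold :func:`outer_join_step` over the pair tables in time order."""
    tables = list(pair_tables)
    if not tables:
        raise LineageError("no pair tables to join")
    if [p.t for p in tables] != list(range(tables[0].t, tables[0].t + len(tables))):
        raise LineageError("pair tables are not consecutive in time")
    db = _initial_database(tables[0])
    for p in tables[1:]:
        db = outer_join_step(db, p)
    return db


def pair_tables_from_rows(rows: Iterable) -> list:
    """Recover per-interval pair tables from lineage-table rows.

    The inverse of the join, up to deduplication: every adjacent
    non-padded cell pair becomes a pair-table row; ``DUMP`` cells become
    Dump attachments and cells following pre-birth padding become birth
    attachments (pseudo-labels reassigned ``C0, C-1, ...`` in label
    order, since member counts are not recorded in the table).
    """
    rows = [tuple(r) for r in rows]
    if not rows:
        raise LineageError("no lineage rows")
    n_times = len(rows[0])
    tables = []
    for j in range(n_times - 1):
        pair_rows = set()
        newborn = set()
        for cells in rows:
            a, b = cells[j], cells[j + 1]
            if a == DEAD_MARK or b == EMPTY_MARK:
                continue
            if a == EMPTY_MARK:
                newborn.add(b)
                continue
            pair_rows.add((a, DUMP if b == DEAD_MARK else b))
        births = tuple(
            (f"C{-i}", lab) for i, lab in enumerate(sorted(newborn))
        )
        tables.append(PairTable(t=j + 1, rows=tuple(sorted(pair_rows)), births=births))
    return tables


def database_from_rows(rows: Iterable) -> QueryDatabase:
    """Replay printed lineage rows through the join machinery."""
    return build_query_database(pair_tables_from_rows(rows))


def extract_threads(db: QueryDatabase) -> list:
    """Group database rows into per-origin branch trees.

    Within one origin, rows sharing a cell prefix follow one branch; at
    a split the child with the smallest cluster label inherits the
    parent branch and every other child opens a new branch.  Branches
    never re-collapse, even when they later share labels.
    """
    by_origin: dict = defaultdict(list)
    for row in db.rows:
        by_origin[row.origin].append(row.cells)
    trees = []
    for origin in db.origins:
        cells_list = by_origin[origin]
        start = next(
            j + 1 for j, c in enumerate(cells_list[0]) if c != EMPTY_MARK
        )
        first_labels = {cells[start - 1] for cells in cells_list}
        if len(first_labels) != 1:
            raise LineageError(
                f"origin {origin!r} rows disagree at their first column"
            )
        root = Branch(origin, 0, start, {start: first_labels.pop()})
        branches = [root]
        active = [(root, list(range(len(cells_list))))]
        for time in range(start + 1, db.n_times + 1):
            nxt = []
            for branch, idxs in active:
                col = {cells_list[i][time - 1] for i in idxs}
                if DEAD_MARK in col:
                    if col != {DEAD_MARK}:
                        raise LineageError(
                            f"origin {origin!r}: dead and live rows share a "
                            f"branch at time {time}"
                        )
                    branch.died_at = time
                    continue
                labels = sorted(col)
                keep = labels[0]
                branch.labels[time] = keep
                nxt.append(
                    (branch, [i for i in idxs if cells_list[i][time - 1] == keep])
                )
                for lab in labels[1:]:
                    child = Branch(
                        origin, len(branches), time, {time: lab}, parent=branch.branch_id
                    )
                    branches.append(child)
                    nxt.append(
                        (child, [i for i in idxs if cells_list[i][time - 1] == lab])
                    )
            active = nxt
        trees.append(ThreadTree(origin, branches))
    return trees
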