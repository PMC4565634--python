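"""Reading and writing membership tables, edge lists and lineage output.

On-disk layouts (all delimiter-separated text, tab by default):

* membership table — one row per (node, time, cluster) with an optional
  header; column order configurable.  A node absent from a snapshot
  simply has no row at that time.
* edge snapshot — one file per time-stamp, ``src dst [count]`` per line.
* lineage table — one row per evolution thread: an ``origin`` column
  followed by ``T1..TT``; dead segments carry the ``DUMP`` marker and
  pre-birth segments are empty cells.
* event log — one row per classified event, ordered by (time, type,
  labels).

The ``NewC`` origin prefix is reserved for newborn threads; cluster
labels themselves should not use it.
"""

from __future__ import annotations

import io as _stdio
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from lineagram.lineage import EMPTY_MARK, QueryDatabase, QueryRow
from lineagram.partition import (
    DynamicPartition,
    EdgeSeries,
    MembershipError,
    SnapshotPartition,
)

__all__ = [
    "read_memberships",
    "write_memberships",
    "read_edge_snapshots",
    "write_edge_snapshot",
    "read_lineage_table",
    "write_lineage_table",
    "write_events",
    "read_events",
    "DynamicPartition",
    "SnapshotPartition",
    "EdgeSeries",
]

_MEMBERSHIP_COLUMNS = ("node", "time", "cluster")


def _is_int(text: str) -> bool:
    try:
        int(text)
    except (TypeError, ValueError):
        return False
    return True


def read_memberships(
    path,
    delimiter: str = "\t",
    columns: Sequence = _MEMBERSHIP_COLUMNS,
    header: Optional[bool] = None,
) -> DynamicPartition:
    """Parse a membership table into a :class:`DynamicPartition`.

    ``columns`` names the on-disk column order using the keys ``node``,
    ``time`` and ``cluster``.  ``header=None`` auto-detects a header row
    by checking whether the time field of the first row is an integer.
    Duplicate (node, time) rows with conflicting labels are a hard
    error; rows are otherwise order-insensitive.
    """
    if sorted(columns) != sorted(_MEMBERSHIP_COLUMNS):
        raise MembershipError(f"columns must be a permutation of {_MEMBERSHIP_COLUMNS}")
    try:
        df = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise MembershipError(f"membership file {path} is empty") from None
    if df.shape[1] < 3:
        raise MembershipError(
            f"membership file {path} has {df.shape[1]} columns, need 3"
        )
    df = df.iloc[:, :3]
    df.columns = list(columns)
    if header is None:
        header = not _is_int(df["time"].iloc[0])
    if header:
        df = df.iloc[1:]
    if df.empty:
        raise MembershipError(f"membership file {path} has no data rows")
    if not df["time"].map(_is_int).all():
        bad = df.loc[~df["time"].map(_is_int), "time"].iloc[0]
        raise MembershipError(f"time value {bad!r} is not an integer")
    df["time"] = df["time"].astype(int)

    labels = df.groupby(["node", "time"])["cluster"].nunique()
    conflicts = labels[labels > 1]
    if not conflicts.empty:
        node, time = conflicts.index[0]
        raise MembershipError(
            f"node {node!r} has conflicting cluster labels at time {time}"
        )
    df = df.drop_duplicates()
    times = sorted(df["time"].unique())
    if times != list(range(1, len(times) + 1)):
        raise MembershipError(
            f"time-stamps {times} are not consecutive integers starting at 1; "
            f"re-index the time column"
        )
    snapshots = []
    for t in times:
        sub = df[df["time"] == t]
        clusters = {
            str(lab): frozenset(grp["node"])
            for lab, grp in sub.groupby("cluster")
        }
        snapshots.append(SnapshotPartition(int(t), clusters))
    return DynamicPartition(tuple(snapshots))


def write_memberships(dp: DynamicPartition, path, delimiter: str = "\t") -> None:
    """Write a membership table (with header) in (node, time, cluster) order."""
    records = [
        (node, snap.time_index, label)
        for snap in dp.snapshots
        for label, members in sorted(snap.clusters.items())
        for node in sorted(members, key=str)
    ]
    df = pd.DataFrame(records, columns=list(_MEMBERSHIP_COLUMNS))
    df.to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def read_edge_snapshots(
    paths: Sequence,
    dp: Optional[DynamicPartition] = None,
    delimiter: Optional[str] = None,
) -> EdgeSeries:
    """Read one edge file per snapshot into an :class:`EdgeSeries`.

    Files have 2 or 3 whitespace- or delimiter-separated columns
    (source, target, optional positive multiplicity; default 1).
    Repeated lines accumulate.  Endpoints absent from the matching
    snapshot of ``dp`` are recorded as warnings, not errors.
    """
    series = EdgeSeries()
    for i, path in enumerate(paths, start=1):
        counts: Counter = Counter()
        loops: Counter = Counter()
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            mult = 1
            if len(parts) == 3:
                if not _is_int(parts[2]) or int(parts[2]) < 1:
                    raise ValueError(
                        f"{path}:{lineno}: multiplicity {parts[2]!r} is not a "
                        f"positive integer"
                    )
                mult = int(parts[2])
            u, v = parts[0], parts[1]
            counts[(u, v)] += mult
            if u == v:
                loops[(u, v)] += mult
        series.per_time[i] = counts
        if loops:
            series.self_loops[i] = loops
        if dp is not None and i <= dp.T:
            known = dp[i].nodes
            missing = sorted(
                {n for e in counts for n in e if n not in known}, key=str
            )
            if missing:
                series.unknown_nodes[i] = missing
    return series


def write_edge_snapshot(counts, path, delimiter: str = "\t") -> None:
    """Write one snapshot's edge multiset as ``src dst count`` lines."""
    lines = [
        f"{u}{delimiter}{v}{delimiter}{m}"
        for (u, v), m in sorted(counts.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_lineage_table(
    db: QueryDatabase, path, delimiter: str = "\t", include_origin: bool = True
) -> None:
    """Write the lineage database as a ``T``-column thread table.

    Columns are labelled ``T1..TT`` (preceded by ``origin`` unless
    disabled); dead segments are marked ``DUMP`` and pre-birth segments
    left empty.  Re-reading with :func:`read_lineage_table` reproduces
    the database exactly.
    """
    if not db.rows:
        raise ValueError("refusing to write an empty lineage database")
    time_cols = [f"T{j}" for j in range(1, db.n_times + 1)]
    buf = _stdio.StringIO()
    if include_origin:
        buf.write(delimiter.join(["origin"] + time_cols) + "\n")
        for row in db.rows:
            buf.write(delimiter.join((row.origin,) + row.cells) + "\n")
    else:
        buf.write(delimiter.join(time_cols) + "\n")
        for row in db.rows:
            buf.write(delimiter.join(row.cells) + "\n")
    Path(path).write_text(buf.getvalue())


def read_lineage_table(path, delimiter: str = "\t") -> QueryDatabase:
    """Read a lineage table written by :func:`write_lineage_table`."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"lineage file {path} is empty")
    header = lines[0].split(delimiter)
    has_origin = header and header[0] == "origin"
    n_times = len(header) - (1 if has_origin else 0)
    rows = []
    for line in lines[1:]:
        parts = line.split(delimiter)
        if has_origin:
            origin, cells = parts[0], tuple(parts[1:])
        else:
            cells = tuple(parts)
            origin = next((c for c in cells if c != EMPTY_MARK), EMPTY_MARK)
        if len(cells) != n_times:
            raise ValueError(f"lineage row {line!r} has {len(cells)} cells, "
                             f"expected {n_times}")
        rows.append(QueryRow(origin, cells))
    newc = [
        int(r.origin[4:])
        for r in rows
        if r.origin.startswith("NewC") and r.origin[4:].isdigit()
    ]
    n_initial = len({r.origin for r in rows}) - len(set(newc))
    next_newc = max(newc) + 1 if newc else n_initial + 1
    return QueryDatabase(
        n_times=n_times, rows=rows, n_initial=n_initial, next_newc=next_newc
    )


_EVENT_COLUMNS = ("time", "type", "sources", "targets", "sizes", "unseen_frac")


def write_events(events: Iterable, path, delimiter: str = "\t") -> None:
    """Write classified events, one row per record.

    Rows are ordered by (time, type, sources, targets); participant
    labels are ``;``-joined and sizes serialized as
    ``time:label:count`` triples.
    """
    rows = []
    for e in sorted(events, key=lambda e: (e.time, e.type, e.sources, e.targets)):
        sizes = ";".join(
            f"{t}:{lab}:{n}" for (t, lab), n in sorted(e.sizes.items())
        )
        unseen = "" if e.unseen_frac is None else f"{e.unseen_frac:.6g}"
        rows.append(
            (e.time, e.type, ";".join(e.sources), ";".join(e.targets), sizes, unseen)
        )
    df = pd.DataFrame(rows, columns=list(_EVENT_COLUMNS))
    df.to_csv(path, sep=delimiter, index=False, lineterminator="\n")


def read_events(path, delimiter: str = "\t"):
    """Read an event log back into :class:`~lineagram.tracking.EventRecord`."""
    from lineagram.tracking import EventRecord

    df = pd.read_csv(path, sep=delimiter, dtype=str).fillna("")
    events = []
    for _, row in df.iterrows():
        sizes = {}
        if row["sizes"]:
            for item in row["sizes"].split(";"):
                t, lab, n = item.split(":")
                sizes[(int(t), lab)] = int(n)
        events.append(
            EventRecord(
                type=row["type"],
                time=int(row["time"]),
                sources=tuple(s for s in row["sources"].split(";") if s),
                targets=tuple(s for s in row["targets"].split(";") if s),
                sizes=sizes,
                unseen_frac=float(row["unseen_frac"]) if row["unseen_frac"] else None,
            )
        )
    return events
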