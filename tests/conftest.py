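"""Shared fixtures: the printed 15-row lineage table and small partitions."""

from __future__ import annotations

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lineagram.lineage import build_query_database, extract_threads, pair_tables_from_rows
from lineagram.partition import SnapshotPartition

# 15-thread lineage of 7 communities over 5 time-stamps, containing one
# cross-track merge chain (C5+C6 -> C8 at T2, merged lineage -> C1 at T4)
# and repeated splits; used throughout as the worked layout example.
TABLE1_ROWS = [
    ("C1", "C7", "C3", "C1", "C3"),
    ("C2", "C1", "C5", "C7", "C5"),
    ("C2", "C2", "C5", "C7", "C5"),
    ("C3", "C4", "C2", "C2", "C1"),
    ("C3", "C4", "C2", "C3", "C1"),
    ("C3", "C3", "C8", "C6", "C2"),
    ("C3", "C3", "C1", "C9", "C7"),
    ("C3", "C3", "C1", "C9", "C8"),
    ("C4", "C6", "C9", "C4", "C6"),
    ("C4", "C6", "C9", "C10", "C4"),
    ("C4", "C6", "C9", "C10", "C11"),
    ("C5", "C8", "C6", "C1", "C3"),
    ("C6", "C8", "C6", "C1", "C3"),
    ("C7", "C5", "C4", "C5", "C9"),
    ("C7", "C5", "C7", "C8", "C10"),
]

#: survivor policy hosting the T2-merged lineage on C6's track
TABLE1_MERGE_POLICY = {(2, "C8"): "C6"}


@pytest.fixture(scope="session")
def table1_rows():
    return list(TABLE1_ROWS)


@pytest.fixture(scope="session")
def table1_db(table1_rows):
    return build_query_database(pair_tables_from_rows(table1_rows))


@pytest.fixture(scope="session")
def table1_threads(table1_db):
    return extract_threads(table1_db)


@pytest.fixture
def two_snapshots():
    s1 = SnapshotPartition(1, {"A": frozenset({1, 2, 3, 4}), "B": frozenset({5, 6})})
    s2 = SnapshotPartition(2, {"X": frozenset({1, 2, 3}), "Y": frozenset({4, 5, 6})})
    return s1, s2
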