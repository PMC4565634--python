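"""Core containers for per-snapshot community memberships and edge lists.

A *snapshot* is the state of the evolving network at one time-stamp: a
partition of the nodes observed at that time into labelled clusters.
Time-stamps are 1-based consecutive integers ``1..T``.  Cluster labels
are opaque strings and are only meaningful within one snapshot: the same
label may denote unrelated node sets at different times.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class MembershipError(ValueError):
    """Raised when a membership table violates the partition contract."""


@dataclass(frozen=True)
class SnapshotPartition:
    """The clusters observed at one time-stamp.

    Parameters
    ----------
    time_index:
        1-based time-stamp of the snapshot.
    clusters:
        Mapping from cluster label to the frozen set of member node ids.
        Clusters must be pairwise disjoint and non-empty.
    """

    time_index: int
    clusters: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        seen: dict = {}
        for label, members in self.clusters.items():
            if not members:
                raise MembershipError(
                    f"cluster {label!r} at time {self.time_index} is empty"
                )
            for node in members:
                if node in seen:
                    raise MembershipError(
                        f"node {node!r} belongs to clusters {seen[node]!r} and "
                        f"{label!r} at time {self.time_index}"
                    )
                seen[node] = label
        object.__setattr__(self, "clusters", dict(self.clusters))

    @property
    def n(self) -> int:
        """Number of clusters in the snapshot."""
        return len(self.clusters)

    @property
    def nodes(self) -> frozenset:
        return frozenset().union(*self.clusters.values()) if self.clusters else frozenset()

    def sizes(self) -> dict:
        """Cluster label -> member count."""
        return {label: len(members) for label, members in self.clusters.items()}

    def label_of(self) -> dict:
        """Node id -> cluster label."""
        return {
            node: label for label, members in self.clusters.items() for node in members
        }


@dataclass(frozen=True)
class DynamicPartition:
    """An ordered sequence of snapshot partitions of an evolving network.

    Snapshots carry consecutive time indices ``1..T``.  Nodes may appear
    and disappear between snapshots; a node absent from a snapshot simply
    has no membership at that time.
    """

    snapshots: tuple

    def __post_init__(self) -> None:
        snaps = tuple(sorted(self.snapshots, key=lambda s: s.time_index))
        if not snaps:
            raise MembershipError("dynamic partition has no snapshots")
        times = [s.time_index for s in snaps]
        if times != list(range(1, len(snaps) + 1)):
            raise MembershipError(
                f"snapshot time indices {times} are not consecutive integers "
                f"starting at 1; re-index the input time-stamps"
            )
        object.__setattr__(self, "snapshots", snaps)

    @property
    def T(self) -> int:
        """Total number of time-stamps."""
        return len(self.snapshots)

    @property
    def node_universe(self) -> frozenset:
        return frozenset().union(*(s.nodes for s in self.snapshots))

    def __getitem__(self, time_index: int) -> SnapshotPartition:
        """Snapshot at 1-based ``time_index``."""
        if not 1 <= time_index <= self.T:
            raise IndexError(f"time index {time_index} outside 1..{self.T}")
        return self.snapshots[time_index - 1]

    def sizes(self) -> dict:
        """(time, cluster label) -> member count, over all snapshots."""
        out = {}
        for snap in self.snapshots:
            for label, members in snap.clusters.items():
                out[(snap.time_index, label)] = len(members)
        return out


@dataclass
class EdgeSeries:
    """Per-snapshot edge multisets (source, target) -> multiplicity.

    ``per_time[t]`` holds the (undirected, as-read) edge counts for
    snapshot ``t``.  Self-loops are retained but listed in
    ``self_loops``; endpoints missing from the matching partition are
    collected in ``unknown_nodes`` as warnings rather than errors.
    """

    per_time: dict = field(default_factory=dict)
    self_loops: dict = field(default_factory=dict)
    unknown_nodes: dict = field(default_factory=dict)

    def counts(self, time_index: int) -> Counter:
        return self.per_time.get(time_index, Counter())


def partition_from_tables(tables: Iterable) -> DynamicPartition:
    """Build a :class:`DynamicPartition` from (time, {label: node iterable}) pairs."""
    snaps = [
        SnapshotPartition(t, {lab: frozenset(members) for lab, members in clusters.items()})
        for t, clusters in tables
    ]
    return DynamicPartition(tuple(snaps))
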