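"""Unit and property tests for the bipartite tracking core."""

from __future__ import annotations

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineagram.partition import DynamicPartition, SnapshotPartition
from lineagram.tracking import (
    EventRecord,
    TrackingError,
    UserThresholdConfig,
    apply_user_threshold,
    attach_pseudo_clusters,
    build_bipartite_map,
    classify_events,
    compute_threshold,
    jaccard_weight,
    prune_map,
    track_all,
)


def finish(bmap, s_t, s_t1):
    return attach_pseudo_clusters(prune_map(compute_threshold(bmap)), s_t, s_t1)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y", "z"}, {"x", "y", "z"}, Fraction(1)),
            ({"x", "y"}, {"u", "v"}, Fraction(0)),
            ({1, 2, 3}, {2, 3, 4}, Fraction(1, 2)),
            ({1}, set(), Fraction(0)),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard_weight(a, b) == expected

    def test_both_empty_rejected(self):
        with pytest.raises(TrackingError):
            jaccard_weight(set(), set())

    @given(
        st.sets(st.integers(0, 30)),
        st.sets(st.integers(0, 30)),
    )
    def test_symmetric_and_bounded(self, a, b):
        if not a and not b:
            return
        w = jaccard_weight(a, b)
        assert w == jaccard_weight(b, a)
        assert 0 <= w <= 1
        assert (w == 1) == (a == b)


class TestBipartiteMap:
    def test_positive_pairs_only(self, two_snapshots):
        s1, s2 = two_snapshots
        bmap = build_bipartite_map(s1, s2)
        weights = {(e.source, e.target): e.weight for e in bmap.edges}
        assert weights == {
            ("A", "X"): Fraction(3, 4),
            ("A", "Y"): Fraction(1, 6),
            ("B", "Y"): Fraction(2, 3),
        }

    def test_identity_partition_all_ones(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1, 2}), "B": frozenset({3})})
        s2 = SnapshotPartition(2, {"A": frozenset({1, 2}), "B": frozenset({3})})
        bmap = compute_threshold(build_bipartite_map(s1, s2))
        assert all(e.weight == 1 for e in bmap.edges)
        assert bmap.theta == 1

    def test_disjoint_snapshots_have_no_edges(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1, 2})})
        s2 = SnapshotPartition(2, {"Z": frozenset({8, 9})})
        bmap = compute_threshold(build_bipartite_map(s1, s2))
        assert bmap.edges == [] and bmap.theta is None

    def test_non_consecutive_rejected(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1})})
        s3 = SnapshotPartition(3, {"A": frozenset({1})})
        with pytest.raises(TrackingError):
            build_bipartite_map(s1, s3)


class TestThreshold:
    def test_min_of_max_worked_example(self, two_snapshots):
        s1, s2 = two_snapshots
        bmap = compute_threshold(build_bipartite_map(s1, s2))
        assert sorted(bmap.L) == sorted(
            [Fraction(3, 4), Fraction(2, 3), Fraction(3, 4), Fraction(2, 3)]
        )
        assert bmap.theta == Fraction(2, 3)

    def test_pruning_drops_subthreshold_edge(self, two_snapshots):
        s1, s2 = two_snapshots
        bmap = prune_map(compute_threshold(build_bipartite_map(s1, s2)))
        kept = {(e.source, e.target) for e in bmap.retained}
        assert kept == {("A", "X"), ("B", "Y")}

    def test_boundary_edge_equal_to_theta_is_retained(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1, 2}), "B": frozenset({3, 4})})
        s2 = SnapshotPartition(2, {"X": frozenset({1, 2, 3, 4})})
        bmap = prune_map(compute_threshold(build_bipartite_map(s1, s2)))
        assert bmap.theta == Fraction(1, 2)
        assert len(bmap.retained) == 2

    def test_oracle_min_of_max_on_random_pairs(self):
        rnd = random.Random(7)
        for _ in range(300):
            nodes = list(range(rnd.randint(4, 24)))
            s1 = _random_snapshot(1, nodes, rnd)
            s2 = _random_snapshot(2, nodes, rnd)
            bmap = compute_threshold(build_bipartite_map(s1, s2))
            # independent brute force over all pairwise Jaccards
            maxima = []
            for src, ms in s1.clusters.items():
                ws = [
                    jaccard_weight(ms, mt)
                    for mt in s2.clusters.values()
                    if ms & mt
                ]
                if ws:
                    maxima.append(max(ws))
            for tgt, mt in s2.clusters.items():
                ws = [
                    jaccard_weight(ms, mt)
                    for ms in s1.clusters.values()
                    if ms & mt
                ]
                if ws:
                    maxima.append(max(ws))
            expected = min(maxima) if maxima else None
            assert bmap.theta == expected
            # pruning never disconnects a cluster that had an edge
            pruned = prune_map(bmap)
            for src in bmap.sources:
                if any(e.source == src for e in bmap.edges):
                    assert any(e.source == src for e in pruned.retained)
            for tgt in bmap.targets:
                if any(e.target == tgt for e in bmap.edges):
                    assert any(e.target == tgt for e in pruned.retained)


def _random_snapshot(t, nodes, rnd):
    k = rnd.randint(1, 5)
    assignment = {n: rnd.randrange(k) for n in nodes}
    clusters = {}
    for n, c in assignment.items():
        clusters.setdefault(f"K{c}", set()).add(n)
    return SnapshotPartition(t, {lab: frozenset(m) for lab, m in clusters.items()})


class TestPseudoClusters:
    def test_death_and_birth_attachment(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1, 2, 3}), "B": frozenset({4, 5})})
        s2 = SnapshotPartition(2, {"X": frozenset({1, 2, 3}), "Z": frozenset({7, 8})})
        bmap = finish(build_bipartite_map(s1, s2), s1, s2)
        assert bmap.dump_attachments == ["B"]
        assert bmap.birth_attachments == [("C0", "Z")]

    def test_birth_sources_ordered_by_descending_size(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1})})
        s2 = SnapshotPartition(
            2,
            {
                "A": frozenset({1}),
                "Z": frozenset({10, 11, 12}),
                "Q": frozenset({20, 21, 22, 23, 24}),
            },
        )
        bmap = finish(build_bipartite_map(s1, s2), s1, s2)
        assert bmap.birth_attachments == [("C0", "Q"), ("C-1", "Z")]

    def test_no_events_no_pseudo(self, two_snapshots):
        s1, s2 = two_snapshots
        bmap = finish(build_bipartite_map(s1, s2), s1, s2)
        assert bmap.dump_attachments == [] and bmap.birth_attachments == []


class TestUserThreshold:
    def test_override_applies_within_tolerance(self):
        applied = apply_user_threshold(
            [0.40, 0.44], UserThresholdConfig(rho=0.4, nu=0.1)
        )
        assert [float(a) for a in applied] == [0.4, 0.4]

    def test_override_skipped_outside_tolerance(self):
        thetas = [0.40, 0.44]
        applied = apply_user_threshold(thetas, UserThresholdConfig(rho=0.9, nu=0.1))
        assert applied == thetas

    def test_boundary_zero_tolerance(self):
        applied = apply_user_threshold(
            [0.4, 0.4], UserThresholdConfig(rho=0.4, nu=0.0)
        )
        assert [float(a) for a in applied] == [0.4, 0.4]

    def test_invalid_rho_rejected(self):
        with pytest.raises(TrackingError):
            UserThresholdConfig(rho=1.5)

    def test_overridden_theta_can_orphan_clusters(self, two_snapshots):
        s1, s2 = two_snapshots
        dp = DynamicPartition((s1, s2))
        # force the override: mean theta is 2/3, rho=0.7 within nu=0.05
        maps, events = track_all(dp, UserThresholdConfig(rho=0.7, nu=0.05))
        assert maps[0].theta_overridden
        kept = {(e.source, e.target) for e in maps[0].retained}
        assert kept == {("A", "X")}  # 3/4 >= 0.7 > 2/3
        types = {(e.type, e.sources, e.targets) for e in events}
        assert ("death", ("B",), ()) in types
        assert ("birth", (), ("Y",)) in types


class TestEvents:
    def test_merge(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1, 2}), "B": frozenset({3, 4})})
        s2 = SnapshotPartition(2, {"X": frozenset({1, 2, 3, 4})})
        ev = classify_events(finish(build_bipartite_map(s1, s2), s1, s2), s1, s2)
        assert [(e.type, e.sources, e.targets) for e in ev] == [
            ("merge", ("A", "B"), ("X",))
        ]

    def test_split(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1, 2, 3, 4})})
        s2 = SnapshotPartition(2, {"X": frozenset({1, 2}), "Y": frozenset({3, 4})})
        ev = classify_events(finish(build_bipartite_map(s1, s2), s1, s2), s1, s2)
        assert [(e.type, e.sources, e.targets) for e in ev] == [
            ("split", ("A",), ("X", "Y"))
        ]

    def test_continuation_with_shrinkage(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1, 2, 3, 4})})
        s2 = SnapshotPartition(2, {"X": frozenset({1, 2, 3})})
        ev = classify_events(finish(build_bipartite_map(s1, s2), s1, s2), s1, s2)
        assert {e.type for e in ev} == {"continuation", "shrinkage"}

    def test_size_change_below_fraction_is_plain_continuation(self):
        s1 = SnapshotPartition(1, {"A": frozenset(range(10))})
        s2 = SnapshotPartition(2, {"X": frozenset(range(9))})  # -10% < 20%
        ev = classify_events(finish(build_bipartite_map(s1, s2), s1, s2), s1, s2)
        assert {e.type for e in ev} == {"continuation"}

    def test_no_edges_all_die_all_born(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1}), "B": frozenset({2})})
        s2 = SnapshotPartition(2, {"Z": frozenset({8}), "W": frozenset({9})})
        ev = classify_events(finish(build_bipartite_map(s1, s2), s1, s2), s1, s2)
        assert sorted((e.type, e.sources, e.targets) for e in ev) == [
            ("birth", (), ("W",)),
            ("birth", (), ("Z",)),
            ("death", ("A",), ()),
            ("death", ("B",), ()),
        ]

    def test_birth_unseen_fraction_annotation(self):
        s1 = SnapshotPartition(1, {"A": frozenset({1, 2})})
        s2 = SnapshotPartition(2, {"A": frozenset({1, 2}), "Z": frozenset({5, 6})})
        ev = classify_events(finish(build_bipartite_map(s1, s2), s1, s2), s1, s2)
        birth = next(e for e in ev if e.type == "birth")
        assert birth.unseen_frac == 1.0

    def test_event_record_contracts(self):
        with pytest.raises(TrackingError):
            EventRecord("merge", 2, ("A",), ("X",))
        with pytest.raises(TrackingError):
            EventRecord("birth", 2, ("A",), ("X",))


class TestTrackAll:
    def test_requires_two_snapshots(self):
        dp = DynamicPartition((SnapshotPartition(1, {"A": frozenset({1})}),))
        with pytest.raises(TrackingError):
            track_all(dp)

    def test_identity_partition_all_continuations(self):
        snaps = tuple(
            SnapshotPartition(t, {"A": frozenset({1, 2}), "B": frozenset({3, 4})})
            for t in (1, 2)
        )
        maps, events = track_all(DynamicPartition(snaps))
        assert len(maps) == 1 and maps[0].theta == 1
        assert {e.type for e in events} == {"continuation"}

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_event_partition_property(self, seed):
        """Every real cluster carries exactly one primary event role."""
        from lineagram.synthgen import generate_dynamic_partition, random_schedule

        dp, _ = generate_dynamic_partition(random_schedule(seed, n_nodes=120))
        maps, events = track_all(dp)
        for bmap in maps:
            t1 = bmap.t + 1
            roles_t = {src: [] for src in bmap.sources}
            roles_t1 = {tgt: [] for tgt in bmap.targets}
            for e in events:
                if e.time != t1 or e.type in ("growth", "shrinkage"):
                    continue
                for s in e.sources:
                    roles_t[s].append(e.type)
                for tg in e.targets:
                    roles_t1[tg].append(e.type)
            for lab, roles in {**roles_t, **roles_t1}.items():
                assert len(roles) == 1, (bmap.t, lab, roles)
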