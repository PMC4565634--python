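"""Synthetic dynamic partitions with planted evolution events.

The generator executes an explicit per-time schedule of community
events — deaths, births, merges, splits, growth and shrinkage — on an
initial set of clusters, producing both the resulting
:class:`~lineagram.partition.DynamicPartition` and the exact ground
truth as :class:`~lineagram.tracking.EventRecord` objects.  It emulates
dynamic-community benchmarks in which snapshots of roughly a thousand
nodes evolve over five time-stamps under a handful of planted events:

* ``birthdeath_schedule`` — 13 initial communities; one death at times
  3 and 4, one birth at times 4 and 5.
* ``hide_schedule`` — 7 initial communities; one death at every
  time-stamp after the first.
* ``mergesplit_schedule`` — 7 initial communities, 1000 nodes; one
  merge and two splits at every time-stamp after the first.

Newborn communities consist entirely of previously unseen nodes, nodes
of a dead community leave the network, and unscheduled communities
persist unchanged, so with zero churn the tracked events equal the
planted schedule exactly.  Optional churn moves a small random fraction
of nodes between communities per interval to emulate assignment noise
from a real evolutionary clustering method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np

from lineagram.partition import DynamicPartition, SnapshotPartition
from lineagram.tracking import EventRecord


class ScheduleError(ValueError):
    """Raised when a schedule references dead clusters or bad fractions."""


@dataclass(frozen=True)
class IntervalEvents:
    """Planted events taking effect at one time-stamp ``t > 1``.

    ``deaths`` lists labels removed at ``t``; ``births`` newborn sizes;
    ``merges`` label tuples pooled into the first listed label;
    ``splits`` are ``(label, fraction)`` pairs cutting a community in
    two; ``grows``/``shrinks`` are ``(label, fraction)`` size changes.
    """

    deaths: tuple = ()
    births: tuple = ()
    merges: tuple = ()
    splits: tuple = ()
    grows: tuple = ()
    shrinks: tuple = ()


@dataclass(frozen=True)
class EventSchedule:
    """A full planted schedule: initial sizes plus per-time events."""

    T: int
    initial_sizes: tuple
    events: dict = field(default_factory=dict)
    churn: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ScheduleError("schedule needs T >= 2")
        if not self.initial_sizes:
            raise ScheduleError("no initial clusters")
        if not 0 <= self.churn < 1:
            raise ScheduleError(f"churn {self.churn} outside [0, 1)")
        for t, ev in self.events.items():
            if not 2 <= t <= self.T:
                raise ScheduleError(f"events scheduled at time {t} outside 2..{self.T}")
            for lab, frac in list(ev.splits) + list(ev.grows) + list(ev.shrinks):
                if not 0 < frac < 1:
                    raise ScheduleError(f"fraction {frac} for {lab!r} outside (0, 1)")


def _ceil_frac(n: int, frac: float) -> int:
    return int(math.ceil(n * frac - 1e-9))


def generate_dynamic_partition(schedule: EventSchedule):
    """Execute a planted schedule; return ``(partition, ground_truth_events)``.

    Deterministic given ``schedule.seed``.  Ground-truth records carry
    the same observed-time convention as the tracker: an event between
    snapshots ``t-1`` and ``t`` is recorded at time ``t``.
    """
    rng = np.random.default_rng(schedule.seed)
    next_node = [0]

    def fresh(k: int) -> list:
        ids = [f"n{next_node[0] + i}" for i in range(k)]
        next_node[0] += k
        return ids

    clusters = {
        f"C{i + 1}": set(fresh(size))
        for i, size in enumerate(schedule.initial_sizes)
    }
    snapshots = [
        SnapshotPartition(1, {lab: frozenset(m) for lab, m in clusters.items()})
    ]
    truth: list = []

    for t in range(2, schedule.T + 1):
        ev = schedule.events.get(t, IntervalEvents())
        prev_sizes = {lab: len(m) for lab, m in clusters.items()}
        busy: set = set()

        def claim(lab: str) -> None:
            if lab not in clusters:
                raise ScheduleError(
                    f"event at time {t} references cluster {lab!r} which is "
                    f"not alive at time {t - 1}"
                )
            if lab in busy:
                raise ScheduleError(
                    f"cluster {lab!r} participates in two events at time {t}"
                )
            busy.add(lab)

        nxt: dict = {}
        for labels in ev.merges:
            for lab in labels:
                claim(lab)
            target = labels[0]
            pooled = set().union(*(clusters[lab] for lab in labels))
            nxt[target] = pooled
            sizes = {(t - 1, lab): prev_sizes[lab] for lab in labels}
            sizes[(t, target)] = len(pooled)
            truth.append(
                EventRecord("merge", t, tuple(sorted(labels)), (target,), sizes)
            )
        for lab, frac in ev.splits:
            claim(lab)
            members = sorted(clusters[lab])
            if len(members) < 2:
                raise ScheduleError(
                    f"cannot split cluster {lab!r} of size {len(members)} "
                    f"at time {t}"
                )
            k = max(1, min(len(members) - 1, round(len(members) * frac)))
            picked = rng.choice(len(members), size=k, replace=False)
            part_a = {members[i] for i in picked}
            part_b = set(members) - part_a
            la, lb = f"{lab}.1", f"{lab}.2"
            nxt[la], nxt[lb] = part_a, part_b
            truth.append(
                EventRecord(
                    "split", t, (lab,), (la, lb),
                    {(t - 1, lab): prev_sizes[lab], (t, la): len(part_a),
                     (t, lb): len(part_b)},
                )
            )
        for lab in ev.deaths:
            claim(lab)
            truth.append(
                EventRecord("death", t, (lab,), (), {(t - 1, lab): prev_sizes[lab]})
            )
        for lab, frac in ev.grows:
            claim(lab)
            k = max(1, _ceil_frac(prev_sizes[lab], frac))
            nxt[lab] = clusters[lab] | set(fresh(k))
        for lab, frac in ev.shrinks:
            claim(lab)
            members = sorted(clusters[lab])
            k = min(len(members) - 1, max(1, _ceil_frac(len(members), frac)))
            drop = rng.choice(len(members), size=k, replace=False)
            nxt[lab] = set(members) - {members[i] for i in drop}
        for lab in clusters:
            if lab not in busy:
                nxt[lab] = set(clusters[lab])
        for i, size in enumerate(ev.births):
            lab = f"B{t}.{i + 1}"
            nxt[lab] = set(fresh(size))
            truth.append(
                EventRecord("birth", t, (), (lab,), {(t, lab): size},
                            unseen_frac=1.0)
            )

        if schedule.churn > 0 and len(nxt) > 1:
            labels = sorted(nxt)
            for lab in labels:
                members = sorted(nxt[lab])
                moving = [m for m in members if rng.random() < schedule.churn]
                for node in moving:
                    if len(nxt[lab]) <= 1:
                        break
                    others = [l for l in labels if l != lab]
                    dest = others[int(rng.integers(len(others)))]
                    nxt[lab].discard(node)
                    nxt[dest].add(node)

        # continuation (+ growth/shrinkage annotation) for 1-to-1 survivors
        for lab in clusters:
            if lab in busy and not any(
                lab == g[0] for g in list(ev.grows) + list(ev.shrinks)
            ):
                continue
            if lab not in nxt:
                continue
            sizes = {(t - 1, lab): prev_sizes[lab], (t, lab): len(nxt[lab])}
            truth.append(EventRecord("continuation", t, (lab,), (lab,), sizes))
            rel = (len(nxt[lab]) - prev_sizes[lab]) / prev_sizes[lab]
            if rel >= 0.2 - 1e-12:
                truth.append(EventRecord("growth", t, (lab,), (lab,), sizes))
            elif -rel >= 0.2 - 1e-12:
                truth.append(EventRecord("shrinkage", t, (lab,), (lab,), sizes))

        clusters = nxt
        snapshots.append(
            SnapshotPartition(t, {lab: frozenset(m) for lab, m in clusters.items()})
        )

    truth.sort(key=lambda e: (e.time, e.type, e.sources, e.targets))
    return DynamicPartition(tuple(snapshots)), truth


def generate_edges(
    dp: DynamicPartition, p_in: float, p_out: float, seed: int = 0
):
    """Planted-partition edge sampling per snapshot.

    Within-cluster node pairs carry an edge with probability ``p_in``,
    between-cluster pairs with ``p_out`` (``0 <= p_out < p_in <= 1``).
    Returns an :class:`~lineagram.partition.EdgeSeries`; deterministic
    given ``seed``.
    """
    from collections import Counter

    from lineagram.partition import EdgeSeries

    if not 0 <= p_out < p_in <= 1:
        raise ScheduleError(f"need 0 <= p_out < p_in <= 1, got {p_out}, {p_in}")
    rng = np.random.default_rng(seed)
    series = EdgeSeries()
    for snap in dp.snapshots:
        counts: Counter = Counter()
        labs = sorted(snap.clusters)
        members = {lab: sorted(snap.clusters[lab]) for lab in labs}
        for lab in labs:
            ms = members[lab]
            n_pairs = len(ms) * (len(ms) - 1) // 2
            if n_pairs == 0 or p_in == 0:
                continue
            m = int(rng.binomial(n_pairs, p_in))
            for flat in rng.choice(n_pairs, size=m, replace=False):
                i = int((1 + math.isqrt(1 + 8 * int(flat))) // 2)
                j = int(flat) - i * (i - 1) // 2
                counts[(ms[j], ms[i])] += 1
        if p_out > 0:
            for ai, la in enumerate(labs):
                for lb in labs[ai + 1:]:
                    ma, mb = members[la], members[lb]
                    m = int(rng.binomial(len(ma) * len(mb), p_out))
                    for flat in rng.choice(len(ma) * len(mb), size=m, replace=False):
                        counts[(ma[int(flat) // len(mb)], mb[int(flat) % len(mb)])] += 1
        series.per_time[snap.time_index] = counts
    return series


def birthdeath_schedule(
    n_clusters: int = 13, n_nodes: int = 1000, seed: int = 0
) -> EventSchedule:
    """Deaths at times 3 and 4, births at times 4 and 5, over 5 snapshots."""
    sizes = _even_sizes(n_nodes, n_clusters)
    birth_size = max(2, n_nodes // n_clusters // 2)
    return EventSchedule(
        T=5,
        initial_sizes=sizes,
        events={
            3: IntervalEvents(deaths=(f"C{n_clusters}",)),
            4: IntervalEvents(deaths=(f"C{n_clusters - 1}",), births=(birth_size,)),
            5: IntervalEvents(births=(birth_size,)),
        },
        seed=seed,
    )


def hide_schedule(n_clusters: int = 7, n_nodes: int = 700, seed: int = 0) -> EventSchedule:
    """One community death at every time-stamp after the first."""
    sizes = _even_sizes(n_nodes, n_clusters)
    events = {
        t: IntervalEvents(deaths=(f"C{n_clusters - (t - 2)}",)) for t in range(2, 6)
    }
    return EventSchedule(T=5, initial_sizes=sizes, events=events, seed=seed)


def mergesplit_schedule(
    n_clusters: int = 7, n_nodes: int = 1000, seed: int = 0
) -> EventSchedule:
    """One merge and two splits at every time-stamp after the first."""
    sizes = _even_sizes(n_nodes, n_clusters)
    dp_labels = [f"C{i + 1}" for i in range(n_clusters)]
    events = {}
    alive = list(dp_labels)
    for t in range(2, 6):
        if len(alive) < 4:
            break
        a, b, s1, s2 = alive[0], alive[1], alive[2], alive[3]
        events[t] = IntervalEvents(merges=((a, b),), splits=((s1, 0.5), (s2, 0.4)))
        alive = [a] + [f"{s1}.1", f"{s1}.2", f"{s2}.1", f"{s2}.2"] + alive[4:]
    return EventSchedule(T=5, initial_sizes=sizes, events=events, seed=seed)


def random_schedule(
    seed: int,
    T: int = 5,
    max_clusters: int = 13,
    n_nodes: int = 1000,
    churn: float = 0.0,
) -> EventSchedule:
    """A random valid planted schedule at the benchmark scale.

    Each interval plants 0-2 events drawn from the full event taxonomy,
    never letting one cluster take part in two events at once and never
    exhausting the community set.
    """
    rng = np.random.default_rng(seed)
    n0 = int(rng.integers(4, max_clusters + 1))
    init = _even_sizes(n_nodes, n0)
    # track sizes with the generator's own arithmetic, so the schedule
    # never plants a split or shrink on a cluster too small to take it
    size = {f"C{i + 1}": s for i, s in enumerate(init)}
    alive = [f"C{i + 1}" for i in range(n0)]
    events = {}

    def pop_with_min_size(pool, minimum):
        for i, lab in enumerate(pool):
            if size[lab] >= minimum:
                return pool.pop(i)
        return None

    for t in range(2, T + 1):
        ev_deaths, ev_births, ev_merges, ev_splits = [], [], [], []
        ev_grows, ev_shrinks = [], []
        pool = list(alive)
        rng.shuffle(pool)
        for _ in range(int(rng.integers(0, 3))):
            kind = rng.choice(
                ["death", "birth", "merge", "split", "grow", "shrink"]
            )
            if kind == "birth":
                ev_births.append(int(rng.integers(10, 60)))
            elif kind == "death" and len(pool) > 3:
                ev_deaths.append(pool.pop())
            elif kind == "merge" and len(pool) >= 4:
                ev_merges.append((pool.pop(), pool.pop()))
            elif kind == "split":
                lab = pop_with_min_size(pool, 5)
                if lab is not None:
                    ev_splits.append((lab, float(rng.uniform(0.3, 0.6))))
            elif kind == "grow" and pool:
                ev_grows.append((pool.pop(), float(rng.uniform(0.25, 0.5))))
            elif kind == "shrink":
                lab = pop_with_min_size(pool, 4)
                if lab is not None:
                    ev_shrinks.append((lab, float(rng.uniform(0.25, 0.5))))
        events[t] = IntervalEvents(
            deaths=tuple(ev_deaths),
            births=tuple(ev_births),
            merges=tuple(ev_merges),
            splits=tuple(ev_splits),
            grows=tuple(ev_grows),
            shrinks=tuple(ev_shrinks),
        )
        # update alive labels and tracked sizes for later intervals
        for labels in ev_merges:
            for lab in labels[1:]:
                alive.remove(lab)
                size[labels[0]] += size.pop(lab)
        for lab, frac in ev_splits:
            alive.remove(lab)
            s = size.pop(lab)
            k = max(1, min(s - 1, round(s * frac)))
            alive.extend([f"{lab}.1", f"{lab}.2"])
            size[f"{lab}.1"], size[f"{lab}.2"] = k, s - k
        for lab in ev_deaths:
            alive.remove(lab)
            size.pop(lab)
        for lab, frac in ev_grows:
            size[lab] += max(1, _ceil_frac(size[lab], frac))
        for lab, frac in ev_shrinks:
            size[lab] -= min(size[lab] - 1, max(1, _ceil_frac(size[lab], frac)))
        for i, s in enumerate(ev_births):
            lab = f"B{t}.{i + 1}"
            alive.append(lab)
            size[lab] = s
    return EventSchedule(
        T=T, initial_sizes=init, events=events, churn=churn, seed=seed
    )


def _even_sizes(n_nodes: int, n_clusters: int) -> tuple:
    base, extra = divmod(n_nodes, n_clusters)
    return tuple(base + (1 if i < extra else 0) for i in range(n_clusters))
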