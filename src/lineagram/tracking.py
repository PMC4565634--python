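"""Bipartite community tracking between consecutive snapshots.

For every interval ``t -> t+1`` a weighted directed bipartite map is
built whose edges connect clusters at ``t`` to clusters at ``t+1`` with
weight equal to the Jaccard coefficient of their member sets,

    w(C_j^t, C_k^{t+1}) = |C_j^t ∩ C_k^{t+1}| / |C_j^t ∪ C_k^{t+1}|.

Only positive-weight pairs are edges.  The adaptive significance
threshold ``theta^t`` is the minimum over the list ``L^t`` that collects,
for every cluster at ``t``, its maximum outgoing weight and, for every
cluster at ``t+1``, its maximum incoming weight.  Edges with weight
``>= theta^t`` are retained.  Taking the minimum of the per-cluster
maxima (rather than, say, the mean weight) guarantees that every cluster
keeps its strongest correspondence, so sparse or small communities are
not silently disconnected, while sub-maximal noisy overlaps fall below
the threshold.

Clusters left without a retained outgoing edge are attached to the
``Dump`` pseudo-sink (death); clusters at ``t+1`` without a retained
incoming edge are attached to fresh pseudo-sources ``C0, C-1, C-2, ...``
(birth), assigned in descending order of newborn size.  Keeping separate
identifiers for birth and death means the two events can never be
conflated when the per-interval tables are later joined into a lineage
database.

Event classification on the pruned map:

* retained out-degree >= 2 at ``t``  -> split
* retained in-degree >= 2 at ``t+1`` -> merge
* Dump attachment                    -> death
* pseudo-source attachment           -> birth
* mutually unique correspondence     -> continuation, optionally
  annotated with growth or shrinkage when the relative size change
  reaches ``growth_frac`` (default 20%).

Weights are exact rationals (:class:`fractions.Fraction`), so the
boundary comparison ``weight >= theta`` is exact and an edge whose
weight equals the threshold is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from lineagram.partition import DynamicPartition, SnapshotPartition

DUMP = "Dump"

#: prefix used for birth pseudo-sources C0, C-1, C-2, ...
_BIRTH_START = 0


class TrackingError(ValueError):
    """Raised on contract violations in the tracking pipeline."""


@dataclass(frozen=True)
class WeightedEdge:
    """A directed edge of the bipartite map, weight in (0, 1]."""

    source: str
    target: str
    weight: Fraction

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise TrackingError(
                f"edge ({self.source!r} -> {self.target!r}) has weight "
                f"{self.weight} outside (0, 1]"
            )


@dataclass
class BipartiteMap:
    """Weighted bipartite tracking map for the interval ``t -> t+1``.

    ``L`` and ``theta`` are filled by :func:`compute_threshold`,
    ``retained`` by :func:`prune_map`, and the pseudo-cluster
    attachments by :func:`attach_pseudo_clusters`.  ``theta`` is ``None``
    for the degenerate interval with no positive-weight pair at all, in
    which case every cluster at ``t`` dies and every cluster at ``t+1``
    is newborn.
    """

    t: int
    edges: list
    sources: tuple  # real cluster labels at t
    targets: tuple  # real cluster labels at t+1
    L: Optional[list] = None
    theta: Optional[Fraction] = None
    theta_overridden: bool = False
    retained: Optional[list] = None
    dump_attachments: list = field(default_factory=list)
    birth_attachments: list = field(default_factory=list)  # [(pseudo, newborn), ...]

    def retained_out(self, source: str) -> list:
        return [e for e in (self.retained or []) if e.source == source]

    def retained_in(self, target: str) -> list:
        return [e for e in (self.retained or []) if e.target == target]


@dataclass(frozen=True)
class EventRecord:
    """One classified evolution event.

    ``time`` is the snapshot at which the event is observed, i.e. ``t+1``
    for the interval ``t -> t+1``.  ``sources`` are cluster labels at
    ``t``, ``targets`` at ``t+1``; births have no real source and deaths
    no real target.  ``sizes`` maps each participating (time, label) to
    its node count when known.  ``unseen_frac`` annotates birth events
    with the fraction of the newborn's members never observed before.
    """

    type: str
    time: int
    sources: tuple
    targets: tuple
    sizes: dict = field(default_factory=dict, compare=False)
    unseen_frac: Optional[float] = field(default=None, compare=False)

    _TYPES = ("birth", "death", "continuation", "merge", "split", "growth", "shrinkage")

    def __post_init__(self) -> None:
        if self.type not in self._TYPES:
            raise TrackingError(f"unknown event type {self.type!r}")
        if self.type == "merge" and (len(self.sources) < 2 or len(self.targets) != 1):
            raise TrackingError("merge needs >=2 sources and exactly 1 target")
        if self.type == "split" and (len(self.sources) != 1 or len(self.targets) < 2):
            raise TrackingError("split needs 1 source and >=2 targets")
        if self.type == "birth" and self.sources:
            raise TrackingError("birth has no real sources")
        if self.type == "death" and self.targets:
            raise TrackingError("death has no real targets")

    def key(self) -> tuple:
        """Hashable identity used when comparing against planted schedules."""
        return (self.type, self.time, frozenset(self.sources), frozenset(self.targets))


@dataclass(frozen=True)
class UserThresholdConfig:
    """User-facing significance parameters.

    ``rho`` is a user-preferred uniform minimum edge weight; it replaces
    every adaptive threshold only when it lies within ``nu`` of their
    mean, which prevents an aggressive ``rho`` from emptying the maps.
    ``growth_frac`` is the relative size change that counts as growth or
    shrinkage.
    """

    rho: Optional[float] = None
    nu: float = 0.1
    growth_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.rho is not None and not 0 <= self.rho <= 1:
            raise TrackingError(f"rho={self.rho} outside [0, 1]")
        if self.nu < 0:
            raise TrackingError(f"nu={self.nu} must be >= 0")


def jaccard_weight(a: Iterable, b: Iterable) -> Fraction:
    """Jaccard coefficient |a ∩ b| / |a ∪ b| as an exact rational."""
    a, b = frozenset(a), frozenset(b)
    if not a and not b:
        raise TrackingError("Jaccard coefficient undefined for two empty sets")
    return Fraction(len(a & b), len(a | b))


def build_bipartite_map(s_t: SnapshotPartition, s_t1: SnapshotPartition) -> BipartiteMap:
    """Edges between consecutive snapshots for every positive-Jaccard pair."""
    if s_t1.time_index != s_t.time_index + 1:
        raise TrackingError(
            f"snapshots at times {s_t.time_index} and {s_t1.time_index} "
            f"are not consecutive"
        )
    edges = []
    for src, members in s_t.clusters.items():
        for tgt, members1 in s_t1.clusters.items():
            inter = len(members & members1)
            if inter:
                w = Fraction(inter, len(members | members1))
                edges.append(WeightedEdge(src, tgt, w))
    return BipartiteMap(
        t=s_t.time_index,
        edges=edges,
        sources=tuple(sorted(s_t.clusters)),
        targets=tuple(sorted(s_t1.clusters)),
    )


def compute_threshold(bmap: BipartiteMap) -> BipartiteMap:
    """Fill ``L`` (per-cluster maximum weights) and ``theta = min(L)``.

    Clusters with no positive-weight edge contribute nothing to ``L``.
    An interval with no edges at all gets ``theta = None``; downstream
    every source then dies and every target is newborn.
    """
    L: list = []
    for src in bmap.sources:
        out = [e.weight for e in bmap.edges if e.source == src]
        if out:
            L.append(max(out))
    for tgt in bmap.targets:
        inc = [e.weight for e in bmap.edges if e.target == tgt]
        if inc:
            L.append(max(inc))
    theta = min(L) if L else None
    return replace(bmap, L=L, theta=theta, theta_overridden=False)


def prune_map(bmap: BipartiteMap) -> BipartiteMap:
    """Keep only edges with ``weight >= theta``.

    With the adaptive threshold this never disconnects a cluster that
    had a positive-weight edge (its maximum is in ``L`` so
    ``theta <= max``).  A user-overridden ``theta`` can orphan clusters;
    those are handed to the pseudo-cluster attachment step.
    """
    if bmap.theta is None and bmap.edges:
        raise TrackingError("prune_map called before compute_threshold")
    if bmap.theta is None:
        return replace(bmap, retained=[])
    retained = [e for e in bmap.edges if e.weight >= bmap.theta]
    return replace(bmap, retained=retained)


def attach_pseudo_clusters(
    bmap: BipartiteMap,
    s_t: SnapshotPartition,
    s_t1: SnapshotPartition,
) -> BipartiteMap:
    """Attach Dump (death) and birth pseudo-sources to orphaned clusters.

    Birth sources are labelled ``C0, C-1, C-2, ...`` in descending order
    of the newborn cluster's size (ties broken by label order), so the
    most prominent newcomer always gets the canonical ``C0`` identifier.
    """
    if bmap.retained is None:
        raise TrackingError("attach_pseudo_clusters called before prune_map")
    kept_src = {e.source for e in bmap.retained}
    kept_tgt = {e.target for e in bmap.retained}
    dumps = [src for src in bmap.sources if src not in kept_src]
    newborn = sorted(
        (tgt for tgt in bmap.targets if tgt not in kept_tgt),
        key=lambda lab: (-len(s_t1.clusters[lab]), lab),
    )
    births = [(f"C{_BIRTH_START - i}", lab) for i, lab in enumerate(newborn)]
    return replace(bmap, dump_attachments=dumps, birth_attachments=births)


def apply_user_threshold(
    thetas: Sequence, cfg: UserThresholdConfig
) -> list:
    """Replace every adaptive threshold with ``rho`` when it is admissible.

    The override applies iff ``|rho - mean(thetas)| <= nu``; otherwise
    the adaptive thresholds are returned unchanged.
    """
    if cfg.rho is None:
        raise TrackingError("apply_user_threshold requires cfg.rho to be set")
    thetas = list(thetas)
    if not thetas:
        raise TrackingError("empty threshold sequence")
    known = [float(th) for th in thetas if th is not None]
    if not known:
        return thetas
    mu_theta = sum(known) / len(known)
    if abs(cfg.rho - mu_theta) <= cfg.nu + 1e-12:
        return [Fraction(cfg.rho).limit_denominator(10**9) for _ in thetas]
    return thetas


def _unseen_fraction(newborn_members: frozenset, prev_nodes: frozenset) -> float:
    return len(newborn_members - prev_nodes) / len(newborn_members)


def classify_events(
    bmap: BipartiteMap,
    s_t: SnapshotPartition,
    s_t1: SnapshotPartition,
    growth_frac: float = 0.2,
) -> list:
    """Classify the seven event types on a pruned map with pseudo-clusters.

    Growth/shrinkage is evaluated only on mutually unique (1-to-1)
    correspondences, and is emitted alongside the continuation record
    for the same pair.
    """
    if bmap.retained is None:
        raise TrackingError("classify_events needs a pruned map")
    t1 = bmap.t + 1
    sizes_t = s_t.sizes()
    sizes_t1 = s_t1.sizes()
    events: list = []

    out_deg = {src: len(bmap.retained_out(src)) for src in bmap.sources}
    in_deg = {tgt: len(bmap.retained_in(tgt)) for tgt in bmap.targets}

    for src in bmap.dump_attachments:
        events.append(
            EventRecord("death", t1, (src,), (), {(bmap.t, src): sizes_t[src]})
        )
    for _pseudo, lab in bmap.birth_attachments:
        events.append(
            EventRecord(
                "birth",
                t1,
                (),
                (lab,),
                {(t1, lab): sizes_t1[lab]},
                unseen_frac=_unseen_fraction(s_t1.clusters[lab], s_t.nodes),
            )
        )
    for src in bmap.sources:
        succ = bmap.retained_out(src)
        if len(succ) >= 2:
            targets = tuple(sorted(e.target for e in succ))
            sizes = {(bmap.t, src): sizes_t[src]}
            sizes.update({(t1, lab): sizes_t1[lab] for lab in targets})
            events.append(EventRecord("split", t1, (src,), targets, sizes))
    for tgt in bmap.targets:
        pred = bmap.retained_in(tgt)
        if len(pred) >= 2:
            sources = tuple(sorted(e.source for e in pred))
            sizes = {(bmap.t, lab): sizes_t[lab] for lab in sources}
            sizes[(t1, tgt)] = sizes_t1[tgt]
            events.append(EventRecord("merge", t1, sources, (tgt,), sizes))
    # continuation: the unique successor of src is tgt AND the unique
    # predecessor of tgt is src ("holds in both time-directions"), which
    # automatically excludes merge and split participants
    for src in bmap.sources:
        succ = bmap.retained_out(src)
        if len(succ) != 1:
            continue
        tgt = succ[0].target
        if in_deg.get(tgt) != 1:
            continue
        sizes = {(bmap.t, src): sizes_t[src], (t1, tgt): sizes_t1[tgt]}
        events.append(EventRecord("continuation", t1, (src,), (tgt,), sizes))
        rel = (sizes_t1[tgt] - sizes_t[src]) / sizes_t[src]
        if rel >= growth_frac - 1e-12:
            events.append(EventRecord("growth", t1, (src,), (tgt,), sizes))
        elif -rel >= growth_frac - 1e-12:
            events.append(EventRecord("shrinkage", t1, (src,), (tgt,), sizes))

    events.sort(key=lambda e: (e.time, e.type, e.sources, e.targets))
    return events


def track_all(
    dp: DynamicPartition, cfg: Optional[UserThresholdConfig] = None
) -> tuple:
    """Run the full tracking pipeline over all ``T-1`` intervals.

    Returns ``(maps, events)`` where ``maps`` holds one finished
    :class:`BipartiteMap` per interval and ``events`` the classified
    records in time order.  When ``cfg.rho`` is set, the user-threshold
    override is consulted before pruning.
    """
    cfg = cfg or UserThresholdConfig()
    if dp.T < 2:
        raise TrackingError("at least 2 time-stamps required for tracking")
    maps = []
    for t in range(1, dp.T):
        bmap = compute_threshold(build_bipartite_map(dp[t], dp[t + 1]))
        maps.append(bmap)
    if cfg.rho is not None:
        thetas = [m.theta for m in maps]
        applied = apply_user_threshold(thetas, cfg)
        if applied != thetas:
            maps = [
                replace(m, theta=a, theta_overridden=True)
                for m, a in zip(maps, applied)
            ]
    events: list = []
    finished = []
    for bmap in maps:
        s_t, s_t1 = dp[bmap.t], dp[bmap.t + 1]
        bmap = attach_pseudo_clusters(prune_map(bmap), s_t, s_t1)
        finished.append(bmap)
        events.extend(classify_events(bmap, s_t, s_t1, cfg.growth_frac))
    return finished, events
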