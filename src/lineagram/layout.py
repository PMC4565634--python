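"""Timeline geometry: tracks, slots, cross-over counting and ordering.

Every thread origin owns one horizontal *track*; track ``k`` (1-based,
top to bottom) is centred at ``y = k`` and owns the band
``[k - 0.4, k + 0.4]``.  Within a band the main branch sits at slot 0
and every branch created by a split is appended at the next free slot
below; with ``B`` branches the slot spacing is ``0.8 / (B + 1)``, so all
lines stay inside the band.  On a split the child with the smallest
cluster label inherits the parent's slot.  Branches never re-collapse
("no-collapse" rule), even when they later share a cluster label.

When branches from *different* origins reach the same cluster at the
same time (a cross-track merge), all but one terminate: each absorbed
line ends with a dashed *merge segment* from its last slot position to
the surviving circle.  The survivor is the incoming line with the
greatest tracked edge weight when weights are available; otherwise an
explicit policy (or, by default, the line on the topmost track) decides.

A *cross-over* is a strict intersection of two segments within one time
interval; pairs sharing an endpoint circle do not count.  Within-band
crossings are invariant to the track ordering — only merge segments
spanning several tracks respond to it — so reordering tracks to place
frequently interacting origins next to each other reduces the total.
The exact minimisation is combinatorial; :func:`greedy_reorder` chains
origins by interaction strength and falls back to the initial ordering
if that would ever increase the count, while :func:`brute_force_order`
enumerates all permutations for small instances and serves as the
optimality oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union



BAND_HALF_WIDTH = 0.4
MAX_RADIUS = 0.35
DEFAULT_RADIUS = 0.15


class LayoutError(ValueError):
    """Raised on inconsistent layout inputs."""


@dataclass(frozen=True)
class TrackOrdering:
    """Top-to-bottom permutation of thread origins."""

    origins: tuple

    def __post_init__(self) -> None:
        if len(set(self.origins)) != len(self.origins):
            raise LayoutError("ordering repeats an origin")

    def __iter__(self):
        return iter(self.origins)

    def __len__(self) -> int:
        return len(self.origins)

    def index(self, origin: str) -> int:
        return self.origins.index(origin)


@dataclass(frozen=True)
class Circle:
    """One community disc: key = (origin, branch_id, time)."""

    key: tuple
    time: int
    track: int
    y: float
    radius: float
    label: str
    count: Optional[int]


@dataclass(frozen=True)
class Segment:
    """A line piece spanning one interval ``t_from -> t_from + 1``.

    ``kind`` is ``timeline`` (straight continuation), ``branch`` (split
    divergence) or ``merge`` (dashed cross-track merge).  ``c0``/``c1``
    are the endpoint circle keys.
    """

    t_from: int
    y0: float
    y1: float
    kind: str
    c0: tuple
    c1: tuple


@dataclass(frozen=True)
class MergeRecord:
    time: int
    label: str
    absorbed_origin: str
    survivor_origin: str
    absorbed_branch: int
    survivor_branch: int


@dataclass
class LayoutGeometry:
    ordering: TrackOrdering
    circles: list
    segments: list
    merges: list
    track_y: dict = field(default_factory=dict)
    band_half_width: float = BAND_HALF_WIDTH

    def segments_in_interval(self, t_from: int) -> list:
        return [s for s in self.segments if s.t_from == t_from]

    @property
    def n_times(self) -> int:
        return max((c.time for c in self.circles), default=0)


MergePolicy = Union[None, str, dict, Callable]


def default_ordering(trees: Sequence) -> TrackOrdering:
    """Initial-partition origins first (in tree order), newborns after."""

    def newc_key(origin: str):
        if origin.startswith("NewC") and origin[4:].isdigit():
            return (1, int(origin[4:]))
        return (0, 0)

    origins = [t.origin for t in trees]
    return TrackOrdering(tuple(sorted(origins, key=lambda o: (newc_key(o), origins.index(o)))))


def _pick_survivor(
    time: int,
    label: str,
    candidates: list,
    track_of: dict,
    merge_policy: MergePolicy,
    weights: Optional[dict],
) -> "_B":
    """Choose the surviving branch among merge-group candidates.

    Precedence: explicit policy (dict keyed by ``(time, label)`` mapping
    to an origin, or a callable), then greatest incoming edge weight,
    then the smallest track index.
    """
    by_track = sorted(candidates, key=lambda b: (track_of[b.origin], b.branch_id))
    chosen_origin = None
    if isinstance(merge_policy, dict):
        chosen_origin = merge_policy.get((time, label))
    elif callable(merge_policy):
        chosen_origin = merge_policy(time, label, [b.origin for b in by_track])
    if chosen_origin is not None:
        for b in by_track:
            if b.origin == chosen_origin:
                return b
        raise LayoutError(
            f"merge policy chose origin {chosen_origin!r} absent from the "
            f"merge of {label!r} at time {time}"
        )
    if weights:
        def incoming(b):
            prev = b.labels.get(time - 1)
            w = weights.get((time - 1, prev, label), 0.0)
            return float(w)

        best = max(incoming(b) for b in by_track)
        by_track = [b for b in by_track if incoming(b) == best]
    return by_track[0]


@dataclass
class _B:
    """Mutable working copy of a branch during layout."""

    origin: str
    branch_id: int
    start: int
    labels: dict
    parent: Optional[int]
    died_at: Optional[int]
    cancelled: bool = False


def assign_tracks(
    trees: Sequence,
    ordering: TrackOrdering,
    sizes: Optional[dict] = None,
    merge_policy: MergePolicy = None,
    weights: Optional[dict] = None,
) -> LayoutGeometry:
    """Build the full timeline geometry for the given track ordering.

    ``sizes`` maps ``(time, cluster label)`` to node counts (circle
    areas); ``weights`` maps ``(t, source label, target label)`` to the
    tracked edge weight and is used to pick merge survivors;
    ``merge_policy`` overrides the survivor choice explicitly.
    """
    tree_by_origin = {t.origin: t for t in trees}
    if set(ordering.origins) != set(tree_by_origin):
        unknown = set(ordering.origins) - set(tree_by_origin)
        missing = set(tree_by_origin) - set(ordering.origins)
        raise LayoutError(
            f"ordering does not match thread origins "
            f"(unknown: {sorted(unknown)}, missing: {sorted(missing)})"
        )
    track_of = {origin: i + 1 for i, origin in enumerate(ordering)}

    work: dict = {}
    for tree in trees:
        work[tree.origin] = [
            _B(b.origin, b.branch_id, b.start, dict(b.labels), b.parent, b.died_at)
            for b in tree.branches
        ]

    def cancel_descendants(origin: str, branch_id: int, after: int) -> None:
        for b in work[origin]:
            if b.parent == branch_id and b.start > after and not b.cancelled:
                b.cancelled = True
                b.labels.clear()
                cancel_descendants(origin, b.branch_id, after)

    # chronological cross-origin merge resolution
    all_times = sorted(
        {t for branches in work.values() for b in branches for t in b.labels}
    )
    merges: list = []
    for time in all_times:
        groups: dict = {}
        for branches in work.values():
            for b in branches:
                if not b.cancelled and time in b.labels:
                    groups.setdefault(b.labels[time], []).append(b)
        for label, members in sorted(groups.items()):
            if len({b.origin for b in members}) < 2:
                continue
            survivor = _pick_survivor(
                time, label, members, track_of, merge_policy, weights
            )
            for b in members:
                if b.origin == survivor.origin:
                    continue
                merges.append(
                    MergeRecord(
                        time, label, b.origin, survivor.origin,
                        b.branch_id, survivor.branch_id,
                    )
                )
                b.labels = {t: lab for t, lab in b.labels.items() if t < time}
                cancel_descendants(b.origin, b.branch_id, time)

    # slot assignment: creation order within each band
    slot_y: dict = {}
    for origin, branches in work.items():
        live = [b for b in branches if not b.cancelled and b.labels]
        delta = 2 * BAND_HALF_WIDTH / (len(live) + 1)
        base = track_of[origin] - BAND_HALF_WIDTH
        for slot, b in enumerate(sorted(live, key=lambda b: b.branch_id)):
            slot_y[(origin, b.branch_id)] = base + (slot + 1) * delta

    # circles
    sizes = sizes or {}
    counts = [
        sizes.get((t, b.labels[t]))
        for branches in work.values()
        for b in branches
        if not b.cancelled
        for t in b.labels
    ]
    known = [c for c in counts if c]
    max_count = max(known) if known else None

    def radius(count: Optional[int]) -> float:
        if count is None or max_count is None:
            return DEFAULT_RADIUS
        return MAX_RADIUS * (count / max_count) ** 0.5

    circles: dict = {}
    for origin, branches in work.items():
        for b in branches:
            if b.cancelled:
                continue
            for t, lab in b.labels.items():
                key = (origin, b.branch_id, t)
                circles[key] = Circle(
                    key, t, track_of[origin], slot_y[(origin, b.branch_id)],
                    radius(sizes.get((t, lab))), lab, sizes.get((t, lab)),
                )

    segments: list = []
    for origin, branches in work.items():
        by_id = {b.branch_id: b for b in branches}
        for b in branches:
            if b.cancelled or not b.labels:
                continue
            y = slot_y[(origin, b.branch_id)]
            times = sorted(b.labels)
            for t in times:
                if t + 1 in b.labels:
                    segments.append(
                        Segment(
                            t, y, y, "timeline",
                            (origin, b.branch_id, t), (origin, b.branch_id, t + 1),
                        )
                    )
            if b.parent is not None:
                parent = by_id[b.parent]
                f = b.start
                if f - 1 in parent.labels:
                    segments.append(
                        Segment(
                            f - 1,
                            slot_y[(origin, parent.branch_id)], y,
                            "branch",
                            (origin, parent.branch_id, f - 1), (origin, b.branch_id, f),
                        )
                    )
    for m in merges:
        ab = (m.absorbed_origin, m.absorbed_branch)
        if ab not in slot_y:  # absorbed branch left no drawable line
            continue
        start_key = (m.absorbed_origin, m.absorbed_branch, m.time - 1)
        end_key = (m.survivor_origin, m.survivor_branch, m.time)
        if start_key not in circles or end_key not in circles:
            continue
        segments.append(
            Segment(
                m.time - 1,
                circles[start_key].y, circles[end_key].y,
                "merge", start_key, end_key,
            )
        )

    track_y = {origin: float(track_of[origin]) for origin in ordering}
    return LayoutGeometry(
        ordering=ordering,
        circles=list(circles.values()),
        segments=segments,
        merges=merges,
        track_y=track_y,
    )


def count_crossovers(geom: LayoutGeometry) -> int:
    """Number of strictly crossing same-interval segment pairs.

    Two segments of one interval cross iff their endpoint orders flip:
    ``(y0a - y0b) * (y1a - y1b) < 0``.  Pairs sharing an endpoint circle
    are excluded (diverging or converging lines do not cross).
    """
    total = 0
    by_t: dict = {}
    for s in geom.segments:
        by_t.setdefault(s.t_from, []).append(s)
    for segs in by_t.values():
        for a, b in itertools.combinations(segs, 2):
            if {a.c0, a.c1} & {b.c0, b.c1}:
                continue
            if (a.y0 - b.y0) * (a.y1 - b.y1) < 0:
                total += 1
    return total


def crossings_of_segment(geom: LayoutGeometry, seg: Segment) -> int:
    """How many same-interval segments ``seg`` strictly crosses."""
    n = 0
    for other in geom.segments_in_interval(seg.t_from):
        if other is seg or {seg.c0, seg.c1} & {other.c0, other.c1}:
            continue
        if (seg.y0 - other.y0) * (seg.y1 - other.y1) < 0:
            n += 1
    return n


def _interaction_matrix(geom: LayoutGeometry) -> dict:
    M: dict = {}
    for m in geom.merges:
        a, b = m.absorbed_origin, m.survivor_origin
        M[(a, b)] = M.get((a, b), 0) + 1
        M[(b, a)] = M.get((b, a), 0) + 1
    return M


def greedy_reorder(
    trees: Sequence,
    initial: TrackOrdering,
    sizes: Optional[dict] = None,
    merge_policy: MergePolicy = None,
    weights: Optional[dict] = None,
) -> TrackOrdering:
    """Chain origins by merge-interaction strength to reduce cross-overs.

    Seeds with the origin of the largest total interaction, then
    repeatedly appends the unplaced origin interacting most with the
    last placed one (ties broken by interaction with any placed origin,
    then by initial-order index).  Origins without any interaction keep
    their relative initial order at the end.  Guaranteed never to return
    an ordering with more cross-overs than ``initial``: if the greedy
    order is worse, ``initial`` is returned.
    """
    kwargs = dict(sizes=sizes, merge_policy=merge_policy, weights=weights)
    base_geom = assign_tracks(trees, initial, **kwargs)
    M = _interaction_matrix(base_geom)
    idx = {origin: i for i, origin in enumerate(initial)}
    total = {o: sum(w for (a, _), w in M.items() if a == o) for o in initial}
    interacting = [o for o in initial if total[o] > 0]
    rest = [o for o in initial if total[o] == 0]
    order: list = []
    if interacting:
        seed = max(interacting, key=lambda o: (total[o], -idx[o]))
        order.append(seed)
        unplaced = [o for o in interacting if o != seed]
        while unplaced:
            last = order[-1]
            nxt = max(
                unplaced,
                key=lambda o: (
                    M.get((last, o), 0),
                    sum(M.get((p, o), 0) for p in order),
                    -idx[o],
                ),
            )
            order.append(nxt)
            unplaced.remove(nxt)
    candidate = TrackOrdering(tuple(order + rest))
    if count_crossovers(assign_tracks(trees, candidate, **kwargs)) <= count_crossovers(
        base_geom
    ):
        return candidate
    return initial


def brute_force_order(
    trees: Sequence,
    initial: Optional[TrackOrdering] = None,
    max_origins: int = 8,
    sizes: Optional[dict] = None,
    merge_policy: MergePolicy = None,
    weights: Optional[dict] = None,
) -> tuple:
    """Exhaustive minimum-crossing ordering for small instances.

    Returns ``(ordering, crossing count)``; among equal minima the
    permutation encountered first in lexicographic order (relative to
    ``initial``) wins.  Raises for more than ``max_origins`` origins —
    use :func:`greedy_reorder` there.
    """
    initial = initial or default_ordering(trees)
    if len(initial) > max_origins:
        raise LayoutError(
            f"{len(initial)} origins exceed the exhaustive-search cap of "
            f"{max_origins}; use the greedy ordering instead"
        )
    kwargs = dict(sizes=sizes, merge_policy=merge_policy, weights=weights)
    best = None
    best_count = None
    for perm in itertools.permutations(initial.origins):
        ordering = TrackOrdering(perm)
        c = count_crossovers(assign_tracks(trees, ordering, **kwargs))
        if best_count is None or c < best_count:
            best, best_count = ordering, c
    return best, best_count
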