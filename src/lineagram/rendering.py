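"""Figure output: timeline, bipartite heatmaps and network panels.

All figures are pure functions of their inputs: with the default SVG
format, identical geometry and spec produce byte-identical files (the
SVG hash salt is pinned and no timestamp metadata is written), which
makes the renderer testable.

Relabelling conventions applied at render time only (the tracking data
keeps true labels): a cluster whose outgoing weights vanish is shown as
``Dump`` on the heatmap axis, and newborn clusters get the ``NewC``
prefix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.lines import Line2D
from matplotlib.patches import Circle as MplCircle

from lineagram.layout import LayoutGeometry
from lineagram.partition import DynamicPartition, EdgeSeries

_HASHSALT = "lineagram"


class RenderError(ValueError):
    """Raised on unusable render input."""


@dataclass
class RenderSpec:
    """Output options shared by all figure types."""

    out_path: str
    fmt: str = "svg"
    panels_per_row: int = 5
    dash: tuple = (4, 2)
    palette: Optional[dict] = None
    figsize_per_panel: tuple = (3.0, 3.0)

    def __post_init__(self) -> None:
        if self.panels_per_row < 1:
            raise RenderError("panels_per_row must be >= 1")
        if self.fmt not in ("svg", "png"):
            raise RenderError(f"unsupported format {self.fmt!r}")


def _save(fig, spec: RenderSpec) -> str:
    with matplotlib.rc_context({"svg.hashsalt": _HASHSALT, "svg.fonttype": "none"}):
        if spec.fmt == "svg":
            fig.savefig(spec.out_path, format="svg", metadata={"Date": None})
        else:
            fig.savefig(spec.out_path, format="png", dpi=120)
    plt.close(fig)
    return spec.out_path


def _origin_colors(origins: Sequence, palette: Optional[dict]) -> dict:
    if palette:
        return dict(palette)
    cmap = plt.get_cmap("tab20")
    return {origin: cmap(i % 20) for i, origin in enumerate(origins)}


def render_timeline(geom: LayoutGeometry, spec: RenderSpec) -> str:
    """Draw the lineage timeline: one circle per (time, community), dashed
    evolution lines, one color per thread origin, newborn origins keeping
    their ``NewC`` identifier in the legend."""
    if not geom.circles:
        raise RenderError("empty geometry: nothing to draw")
    colors = _origin_colors(list(geom.ordering), spec.palette)
    T = geom.n_times
    n_tracks = len(geom.ordering)
    fig, ax = plt.subplots(figsize=(1.6 * T + 2, 0.9 * n_tracks + 1.5))
    for seg in geom.segments:
        origin = seg.c1[0] if seg.kind != "merge" else seg.c0[0]
        ax.plot(
            [seg.t_from, seg.t_from + 1],
            [seg.y0, seg.y1],
            linestyle=(0, spec.dash),
            linewidth=1.2,
            color=colors[origin],
            zorder=1,
        )
    for c in sorted(geom.circles, key=lambda c: c.key):
        ax.add_patch(
            MplCircle(
                (c.time, c.y), radius=c.radius,
                facecolor=colors[c.key[0]], edgecolor="black",
                linewidth=0.5, zorder=2,
            )
        )
    handles = [
        Line2D([], [], color=colors[o], marker="o", linestyle="", label=o)
        for o in geom.ordering
    ]
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5),
              fontsize=8, frameon=False)
    ax.set_xticks(range(1, T + 1))
    ax.set_xticklabels([f"T{j}" for j in range(1, T + 1)])
    ax.set_yticks(range(1, n_tracks + 1))
    ax.set_yticklabels(list(geom.ordering))
    ax.set_xlim(0.5, T + 0.5)
    ax.set_ylim(n_tracks + 0.8, 0.2)  # y grows downward
    ax.set_xlabel("time-stamp")
    fig.tight_layout()
    return _save(fig, spec)


def render_bipartite_heatmaps(
    maps: Sequence, spec: RenderSpec, dp: Optional[DynamicPartition] = None
) -> str:
    """One weight-matrix panel per interval, color scale spanning [0, 1].

    Rows are clusters at ``t`` and columns clusters at ``t+1``; a row
    whose weights sum to zero is relabelled ``Dump`` and newborn columns
    get the ``NewC`` prefix.
    """
    if not maps:
        raise RenderError("no bipartite maps to draw")
    n = len(maps)
    per_row = spec.panels_per_row
    n_rows = math.ceil(n / per_row)
    n_cols = min(n, per_row)
    w, h = spec.figsize_per_panel
    fig, axes = plt.subplots(
        n_rows, n_cols, figsize=(w * n_cols, h * n_rows), squeeze=False
    )
    im = None
    for k, bmap in enumerate(maps):
        ax = axes[k // per_row][k % per_row]
        srcs, tgts = list(bmap.sources), list(bmap.targets)
        weights = {(e.source, e.target): float(e.weight) for e in bmap.edges}
        mat = [[weights.get((s, t), 0.0) for t in tgts] for s in srcs]
        newborn = {lab for _p, lab in bmap.birth_attachments}
        row_labels = [
            "Dump" if sum(weights.get((s, t), 0.0) for t in tgts) == 0 else s
            for s in srcs
        ]
        col_labels = [f"NewC:{t}" if t in newborn else t for t in tgts]
        im = ax.imshow(mat, vmin=0.0, vmax=1.0, cmap="viridis", aspect="auto")
        ax.set_xticks(range(len(tgts)))
        ax.set_xticklabels(col_labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(srcs)))
        ax.set_yticklabels(row_labels, fontsize=7)
        ax.set_title(f"T{bmap.t} → T{bmap.t + 1}", fontsize=9)
    for k in range(n, n_rows * n_cols):
        axes[k // per_row][k % per_row].set_axis_off()
    if im is not None:
        fig.colorbar(im, ax=axes, fraction=0.025)
    return _save(fig, spec)


def _disc_positions(n: int) -> list:
    """Deterministic positions for ``n`` community discs on a unit circle."""
    if n == 1:
        return [(0.0, 0.0)]
    return [
        (math.cos(2 * math.pi * i / n), math.sin(2 * math.pi * i / n))
        for i in range(n)
    ]


def render_network_panels(
    dp: DynamicPartition, es: EdgeSeries, spec: RenderSpec
) -> str:
    """Per-snapshot community-level network view.

    Discs have area proportional to community size; inter-community
    edges are drawn in gray-scale with weight = (edge count between the
    pair) / (maximum count between any pair at that snapshot), darker
    meaning closer to 1.  At most ``panels_per_row`` panels per row.
    A snapshot without an edge list is skipped with a note.
    """
    n = dp.T
    per_row = spec.panels_per_row
    n_rows = math.ceil(n / per_row)
    n_cols = min(n, per_row)
    w, h = spec.figsize_per_panel
    fig, axes = plt.subplots(
        n_rows, n_cols, figsize=(w * n_cols, h * n_rows), squeeze=False
    )
    max_size = max(len(m) for s in dp.snapshots for m in s.clusters.values())
    for k, snap in enumerate(dp.snapshots):
        ax = axes[k // per_row][k % per_row]
        ax.set_title(f"T{snap.time_index}", fontsize=9)
        ax.set_aspect("equal")
        ax.set_axis_off()
        if snap.time_index not in es.per_time:
            ax.text(0.5, 0.5, "no edge data", ha="center", va="center",
                    transform=ax.transAxes, fontsize=8)
            continue
        labs = sorted(snap.clusters)
        pos = dict(zip(labs, _disc_positions(len(labs))))
        label_of = snap.label_of()
        flows: dict = {}
        for (u, v), m in es.counts(snap.time_index).items():
            cu, cv = label_of.get(u), label_of.get(v)
            if cu is None or cv is None or cu == cv:
                continue
            pair = tuple(sorted((cu, cv)))
            flows[pair] = flows.get(pair, 0) + m
        max_flow = max(flows.values()) if flows else 0
        for (ca, cb), m in sorted(flows.items()):
            wgt = m / max_flow
            shade = 1.0 - wgt  # darker = closer to 1
            ax.plot(
                [pos[ca][0], pos[cb][0]], [pos[ca][1], pos[cb][1]],
                color=(shade, shade, shade), linewidth=0.8 + 2.0 * wgt, zorder=1,
            )
        for lab in labs:
            r = 0.35 * math.sqrt(len(snap.clusters[lab]) / max_size)
            color = "tab:blue" if len(labs) == 1 else "tab:orange"
            ax.add_patch(
                MplCircle(pos[lab], radius=r, facecolor=color,
                          edgecolor="black", linewidth=0.5, zorder=2)
            )
            ax.annotate(lab, pos[lab], ha="center", va="center", fontsize=7,
                        zorder=3)
        ax.set_xlim(-1.6, 1.6)
        ax.set_ylim(-1.6, 1.6)
    for k in range(n, n_rows * n_cols):
        axes[k // per_row][k % per_row].set_axis_off()
    fig.tight_layout()
    return _save(fig, spec)
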