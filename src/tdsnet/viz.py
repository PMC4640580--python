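"""Graphical atlas of physiologic networks.

Brain-brain maps place one heptagon of seven band nodes at each vertex of
a hexagon (the six EEG channel locations); brain-organ maps add a central
organ hexagon with a radar chart whose segment lengths encode the 42
brain-link strengths; organ-organ maps size each organ node by its total
brain control.  Link styling follows the strength categories: very strong
(>= 80 %TDS) thick magenta, strong (65-80) thick blue, intermediate
(45-65) thin cyan.

Rendering is deterministic: layout contains no randomness, the SVG hash
salt is pinned, and no timestamps are embedded, so identical inputs yield
byte-identical figure files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .network import (
    AREA,
    LOCATIONS,
    ORGANS,
    NodeID,
    PhysioNetwork,
    classify_link,
    dominant_band,
    organ_node_size,
)
from .signal_features import BAND_NAMES

#: Band colours follow the conventional low-to-high frequency blue-to-red
#: progression (delta blue ... gamma2 red).
BAND_COLORS: dict[str, str] = {
    "delta": "#2166ac",
    "theta": "#17becf",
    "alpha": "#33a02c",
    "sigma": "#d4c400",
    "beta": "#ff7f00",
    "gamma1": "#e31a1c",
    "gamma2": "#99000d",
}

ORGAN_COLORS: dict[str, str] = {
    "eye": "#e377c2",
    "chin": "#ff7f0e",
    "leg": "#2ca02c",
    "heart": "#d62728",
    "resp": "#9467bd",
}

#: Link style per strength category: (color, line width).
CATEGORY_STYLES: dict[str, tuple[str, float]] = {
    "very_strong": ("magenta", 2.8),
    "strong": ("blue", 2.0),
    "intermediate": ("cyan", 1.0),
    "below": ("0.85", 0.5),
}

_SVG_SALT = "tdsnet"


@dataclass
class LayoutSpec:
    """Deterministic node layout for the hexagon-of-heptagons maps."""

    hex_radius: float = 1.0
    heptagon_radius: float = 0.28
    #: channel order around the hexagon, frontal at top
    channel_order: tuple[str, ...] = ("Fp1", "Fp2", "C4", "O2", "O1", "C3")
    band_colors: dict[str, str] = field(
        default_factory=lambda: dict(BAND_COLORS))
    organ_colors: dict[str, str] = field(
        default_factory=lambda: dict(ORGAN_COLORS))

    def channel_center(self, location: str) -> tuple[float, float]:
        i = self.channel_order.index(location)
        # Fp1 top-left, Fp2 top-right, occipitals at the bottom
        ang = math.pi / 2 + math.pi / 6 - i * math.pi / 3
        return (self.hex_radius * math.cos(ang),
                self.hex_radius * math.sin(ang))

    def node_position(self, node: NodeID) -> tuple[float, float]:
        if node.kind != "brain":
            return (0.0, 0.0)
        cx, cy = self.channel_center(node.location)
        j = BAND_NAMES.index(node.band)
        ang = math.pi / 2 - j * 2 * math.pi / 7
        return (cx + self.heptagon_radius * math.cos(ang),
                cy + self.heptagon_radius * math.sin(ang))


DEFAULT_LAYOUT = LayoutSpec()


def _new_axes(figsize=(6.0, 6.0)):
    fig, ax = plt.subplots(figsize=figsize)
    ax.set_aspect("equal")
    ax.axis("off")
    return fig, ax


def _save(fig, out_path) -> None:
    with plt.rc_context({"svg.hashsalt": _SVG_SALT}):
        fig.savefig(out_path, metadata=_no_date_metadata(out_path))
    plt.close(fig)


def _no_date_metadata(out_path) -> dict:
    s = str(out_path)
    if s.endswith(".svg"):
        return {"Date": None}
    if s.endswith(".png"):
        return {"Software": None}
    return {}


def _draw_brain_nodes(ax, spec: LayoutSpec) -> None:
    for loc in LOCATIONS:
        cx, cy = spec.channel_center(loc)
        ax.annotate(loc, (cx, cy), ha="center", va="center", fontsize=7)
        for band in BAND_NAMES:
            x, y = spec.node_position(NodeID.brain(loc, band))
            ax.plot([x], [y], "o", ms=6, color=spec.band_colors[band],
                    zorder=3)


def render_brain_brain(
    net: PhysioNetwork,
    spec: LayoutSpec = DEFAULT_LAYOUT,
    threshold: float = 45.0,
    out_path=None,
):
    """Hexagon-of-heptagons brain-brain map; links >= threshold, styled by
    strength category."""
    fig, ax = _new_axes()
    for pair, w in sorted(net.edges.items(),
                          key=lambda kv: tuple(sorted(n.label for n in kv[0]))):
        a, b = sorted(pair, key=lambda n: n.label)
        if a.kind != "brain" or b.kind != "brain" or w < threshold:
            continue
        color, lw = CATEGORY_STYLES[classify_link(w).name]
        xa, ya = spec.node_position(a)
        xb, yb = spec.node_position(b)
        ax.plot([xa, xb], [ya, yb], color=color, lw=lw, zorder=2,
                solid_capstyle="round")
    _draw_brain_nodes(ax, spec)
    ax.set_title(f"brain-brain network — stage {net.stage}", fontsize=9)
    if out_path is not None:
        _save(fig, out_path)
        return None
    return fig


@dataclass(frozen=True)
class RadarSegment:
    """One radar-chart segment: its radius (channel), band, angular span
    and length (= weight x scale)."""

    location: str
    band: str
    angle: float
    r0: float
    r1: float
    length: float
    color: str


def render_radar(
    organ: str,
    brain_link_weights: dict[NodeID, float],
    scale: float = 1.0,
    spec: LayoutSpec = DEFAULT_LAYOUT,
) -> list[RadarSegment]:
    """Radar-chart geometry for one organ's 42 brain-link weights.

    Six radii (channels, at the hexagon vertex angles) each carry seven
    stacked coloured segments (bands); each segment's length is
    ``weight * scale``.  The shared scale keeps charts comparable across
    stages and organs.
    """
    if organ not in ORGANS:
        raise ValueError(f"unknown organ {organ!r}")
    segments: list[RadarSegment] = []
    for loc in LOCATIONS:
        cx, cy = spec.channel_center(loc)
        angle = math.atan2(cy, cx)
        r = 0.0
        for band in BAND_NAMES:
            w = brain_link_weights.get(NodeID.brain(loc, band), 0.0)
            length = w * scale
            segments.append(RadarSegment(
                location=loc, band=band, angle=angle,
                r0=r, r1=r + length, length=length,
                color=spec.band_colors[band],
            ))
            r += length
    return segments


def _organ_weights(net: PhysioNetwork, organ: str) -> dict[NodeID, float]:
    target = NodeID.organ_node(organ)
    out: dict[NodeID, float] = {}
    for pair, w in net.edges.items():
        if target in pair:
            other = next(iter(pair - {target}))
            if other.kind == "brain":
                out[other] = w
    return out


def render_brain_organ(
    net: PhysioNetwork,
    organ: str,
    threshold: float = 5.0,
    out_path=None,
    spec: LayoutSpec = DEFAULT_LAYOUT,
    radar_scale: float = 0.004,
):
    """Brain-organ map: links >= threshold from the central organ hexagon
    to band nodes, coloured by band and widened with strength; a radar
    chart in the organ hexagon shows all 42 link strengths."""
    weights = _organ_weights(net, organ)
    fig, ax = _new_axes()
    for node in sorted(weights, key=lambda n: n.label):
        w = weights[node]
        if w < threshold:
            continue
        x, y = spec.node_position(node)
        ax.plot([0.0, x], [0.0, y], color=spec.band_colors[node.band],
                lw=0.5 + 0.03 * w, alpha=0.8, zorder=1)
    for seg in render_radar(organ, weights, radar_scale, spec):
        if seg.length <= 0:
            continue
        ax.plot(
            [seg.r0 * math.cos(seg.angle), seg.r1 * math.cos(seg.angle)],
            [seg.r0 * math.sin(seg.angle), seg.r1 * math.sin(seg.angle)],
            color=seg.color, lw=4, solid_capstyle="butt", zorder=4,
        )
    hexagon = plt.Polygon(
        [(0.3 * math.cos(a), 0.3 * math.sin(a))
         for a in np.pi / 2 + np.arange(6) * np.pi / 3],
        closed=True, fill=True, facecolor=spec.organ_colors[organ],
        alpha=0.25, edgecolor=spec.organ_colors[organ], zorder=2,
    )
    ax.add_patch(hexagon)
    _draw_brain_nodes(ax, spec)
    ax.set_title(f"brain-{organ} network — stage {net.stage}", fontsize=9)
    if out_path is not None:
        _save(fig, out_path)
        return None
    return fig


def render_organ_organ(
    nets: dict[str, PhysioNetwork] | PhysioNetwork,
    out_path=None,
    spec: LayoutSpec = DEFAULT_LAYOUT,
    size_scale: float = 0.002,
):
    """Organ-organ maps, one panel per stage.

    Node area grows linearly with the organ's total brain control; edge
    width and darkness grow with the organ-organ %TDS; node colour is the
    dominant band mediating the organ's brain coupling.
    """
    if isinstance(nets, PhysioNetwork):
        nets = {nets.stage: nets}
    stages = sorted(nets)
    ncol = min(len(stages), 2)
    nrow = (len(stages) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4.0 * ncol, 4.0 * nrow),
                             squeeze=False)
    pos = {
        o: (math.cos(math.pi / 2 + 2 * math.pi * i / 5),
            math.sin(math.pi / 2 + 2 * math.pi * i / 5))
        for i, o in enumerate(ORGANS)
    }
    for k, stage in enumerate(stages):
        ax = axes[k // ncol][k % ncol]
        ax.set_aspect("equal")
        ax.axis("off")
        net = nets[stage]
        max_w = max(
            (w for pair, w in net.edges.items()
             if all(n.kind == "organ" for n in pair)), default=1.0,
        ) or 1.0
        for pair, w in sorted(
            net.edges.items(),
            key=lambda kv: tuple(sorted(n.label for n in kv[0])),
        ):
            a, b = sorted(pair, key=lambda n: n.label)
            if a.kind != "organ" or b.kind != "organ" or w <= 0:
                continue
            shade = 0.8 * (1.0 - w / max_w)
            ax.plot(
                [pos[a.organ][0], pos[b.organ][0]],
                [pos[a.organ][1], pos[b.organ][1]],
                color=str(shade), lw=0.5 + 4.0 * w / max_w, zorder=1,
            )
        for o in ORGANS:
            size = organ_node_size(net, o)
            band = dominant_band(net, o)
            color = (BAND_COLORS[band] if band is not None
                     else ORGAN_COLORS[o])
            ax.plot([pos[o][0]], [pos[o][1]], "o",
                    ms=4 + size * size_scale * 100, color=color, zorder=2)
            ax.annotate(o, pos[o], ha="center", va="center", fontsize=7,
                        zorder=3)
        ax.set_title(stage, fontsize=9)
        ax.set_xlim(-1.5, 1.5)
        ax.set_ylim(-1.5, 1.5)
    for k in range(len(stages), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    if out_path is not None:
        _save(fig, out_path)
        return None
    return fig


def render_strength_histograms(
    nets: dict[str, PhysioNetwork],
    organ: str,
    out_path=None,
):
    """Bar charts of brain-organ link strength grouped by brain area and
    ordered from low to high frequency, one panel per stage."""
    stages = sorted(nets)
    fig, axes = plt.subplots(1, len(stages),
                             figsize=(3.2 * len(stages), 3.0),
                             squeeze=False, sharey=True)
    areas = ("Frontal", "Central", "Occipital")
    for k, stage in enumerate(stages):
        ax = axes[0][k]
        weights = _organ_weights(nets[stage], organ)
        xs, hs, cs = [], [], []
        x = 0.0
        for area in areas:
            for band in BAND_NAMES:
                vals = [w for n, w in weights.items()
                        if AREA[n.location] == area and n.band == band]
                xs.append(x)
                hs.append(float(np.mean(vals)) if vals else 0.0)
                cs.append(BAND_COLORS[band])
                x += 1.0
            x += 1.5
        ax.bar(xs, hs, color=cs, width=0.9)
        ax.set_title(f"{organ} — {stage}", fontsize=9)
        ax.set_xticks([3.0, 11.5, 20.0])
        ax.set_xticklabels(areas, fontsize=7)
        ax.set_ylabel("%TDS" if k == 0 else "")
    if out_path is not None:
        _save(fig, out_path)
        return None
    return fig
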