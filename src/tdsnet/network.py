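"""Assemble pairwise %TDS couplings into stage-resolved physiologic networks.

The canonical node set is 42 brain nodes (6 EEG channel locations x 7
frequency bands) plus 5 organ nodes (eye, chin, leg, heart, respiration).
Edges carry %TDS on the percent scale (0-100).  Subnetwork selectors mirror
the standard decompositions: intra- vs inter-channel links, links within a
hemisphere, and horizontal (same-area) vs diagonal (different-area) links
across hemispheres.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import Hypnogram, NodeSeries, STAGES
from .signal_features import BAND_ALIASES, BAND_NAMES
from .tds import DEFAULT_CONFIG, SegmentationConfig, TDSResult, tds_pair

LOCATIONS: tuple[str, ...] = ("Fp1", "Fp2", "C3", "C4", "O1", "O2")
ORGANS: tuple[str, ...] = ("eye", "chin", "leg", "heart", "resp")

HEMISPHERE: dict[str, str] = {
    "Fp1": "left", "C3": "left", "O1": "left",
    "Fp2": "right", "C4": "right", "O2": "right",
}
AREA: dict[str, str] = {
    "Fp1": "Frontal", "Fp2": "Frontal",
    "C3": "Central", "C4": "Central",
    "O1": "Occipital", "O2": "Occipital",
}
AREA_PAIRS: tuple[tuple[str, str], ...] = (
    ("Frontal", "Central"), ("Central", "Occipital"), ("Frontal", "Occipital"),
    ("Frontal", "Frontal"), ("Central", "Central"), ("Occipital", "Occipital"),
)


@dataclass(frozen=True, order=True)
class NodeID:
    """Identity of one network node.

    ``kind`` is ``"brain"`` (an EEG location x band), ``"organ"`` (one of
    the five organ systems) or ``"generic"`` for ad-hoc nodes used in
    simulations and plumbing.
    """

    kind: str
    location: str | None = None
    band: str | None = None
    organ: str | None = None

    @classmethod
    def brain(cls, location: str, band: str) -> "NodeID":
        band = BAND_ALIASES.get(band, band)
        if location not in LOCATIONS:
            raise ValueError(f"unknown EEG location {location!r}")
        if band not in BAND_NAMES:
            raise ValueError(f"unknown band {band!r}")
        return cls(kind="brain", location=location, band=band)

    @classmethod
    def organ_node(cls, organ: str) -> "NodeID":
        if organ not in ORGANS:
            raise ValueError(f"unknown organ {organ!r}")
        return cls(kind="organ", organ=organ)

    @classmethod
    def generic(cls, name: str) -> "NodeID":
        return cls(kind="generic", organ=name)

    @classmethod
    def parse(cls, label: str) -> "NodeID":
        if ":" in label:
            loc, band = label.split(":", 1)
            try:
                return cls.brain(loc, band)
            except ValueError:
                return cls.generic(label)
        if label in ORGANS:
            return cls.organ_node(label)
        return cls.generic(label)

    @property
    def label(self) -> str:
        if self.kind == "brain":
            return f"{self.location}:{self.band}"
        return str(self.organ)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def brain_nodes() -> list[NodeID]:
    """All 42 brain nodes: 6 locations x 7 bands."""
    return [NodeID.brain(loc, b) for loc in LOCATIONS for b in BAND_NAMES]


def organ_nodes() -> list[NodeID]:
    """All 5 organ nodes."""
    return [NodeID.organ_node(o) for o in ORGANS]


def all_nodes() -> list[NodeID]:
    return brain_nodes() + organ_nodes()


Edge = frozenset  # frozenset of two NodeID


@dataclass
class PhysioNetwork:
    """Weighted undirected network over physiologic nodes for one stage.

    ``edges`` maps unordered node pairs to %TDS on the percent scale.
    Every evaluated candidate pair is stored, including weight 0, so that
    averaged link strengths are taken over all candidate links rather than
    only displayed ones.
    """

    stage: str
    nodes: list[NodeID] = field(default_factory=list)
    edges: dict[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, w in self.edges.items():
            if len(pair) != 2:
                raise ValueError("self-edges are not allowed")
            if not (0.0 <= w <= 100.0):
                raise ValueError(f"edge weight {w} outside [0, 100]")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, a: NodeID, b: NodeID) -> float | None:
        return self.edges.get(frozenset((a, b)))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for pair, w in self.edges.items():
            a, b = tuple(pair)
            g.add_edge(a, b, weight=w)
        return g


@dataclass(frozen=True)
class LinkCategory:
    """A %TDS strength bin ``[lo, hi)`` (the top bin closes at 100)."""

    name: str
    lo: float
    hi: float


#: Strength categories used for display: very strong (>= 80 %TDS), strong
#: (65-80), intermediate (45-65), below display threshold (< 45).
LINK_CATEGORIES: tuple[LinkCategory, ...] = (
    LinkCategory("very_strong", 80.0, 100.0),
    LinkCategory("strong", 65.0, 80.0),
    LinkCategory("intermediate", 45.0, 65.0),
    LinkCategory("below", 0.0, 45.0),
)

#: Display thresholds (%TDS) per figure family: brain-brain maps show
#: links >= 45, brain-organ maps >= 5, brain-respiration maps >= 3.
DISPLAY_THRESHOLDS: dict[str, float] = {
    "brain_brain": 45.0,
    "brain_organ": 5.0,
    "brain_resp": 3.0,
}


def classify_link(weight: float) -> LinkCategory:
    """Bin a %TDS weight into its strength category (lower bounds closed)."""
    if not (0.0 <= weight <= 100.0):
        raise ValueError(f"weight {weight} outside [0, 100]")
    for cat in LINK_CATEGORIES:
        if weight >= cat.lo:
            return cat
    raise AssertionError("unreachable: categories cover [0, 100]")


@dataclass(frozen=True)
class SubnetworkSpec:
    """Selector describing one of the standard subnetwork decompositions.

    ``selector`` is one of ``inter_channel``, ``intra_channel``,
    ``within_hemisphere`` (with ``side``), ``cross_hemisphere_horizontal``,
    ``cross_hemisphere_diagonal``, ``brain_organ`` (with ``organ``) or
    ``organ_organ``.  ``area_pair`` optionally restricts brain selectors to
    one area pair (e.g. Frontal-Central); ``same_band_only`` keeps only
    links between identical frequency bands.
    """

    selector: str
    side: str | None = None
    organ: str | None = None
    area_pair: tuple[str, str] | None = None
    same_band_only: bool = False

    _SELECTORS = (
        "inter_channel", "intra_channel", "within_hemisphere",
        "cross_hemisphere_horizontal", "cross_hemisphere_diagonal",
        "brain_organ", "organ_organ",
    )

    def __post_init__(self) -> None:
        if self.selector not in self._SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.selector == "within_hemisphere" and self.side not in (
            "left", "right"
        ):
            raise ValueError("within_hemisphere needs side 'left' or 'right'")
        if self.selector == "brain_organ" and self.organ not in ORGANS:
            raise ValueError("brain_organ needs a valid organ")
        if self.area_pair is not None:
            ap = tuple(sorted(self.area_pair))
            if ap not in {tuple(sorted(p)) for p in AREA_PAIRS}:
                raise ValueError(f"unknown area pair {self.area_pair}")

    def matches(self, a: NodeID, b: NodeID) -> bool:
        sel = self.selector
        if sel == "organ_organ":
            return a.kind == "organ" and b.kind == "organ"
        if sel == "brain_organ":
            pair = {a, b}
            organs = [n for n in pair if n.kind == "organ"]
            brains = [n for n in pair if n.kind == "brain"]
            return (
                len(organs) == 1
                and len(brains) == 1
                and organs[0].organ == self.organ
            )
        if a.kind != "brain" or b.kind != "brain":
            return False
        if self.same_band_only and a.band != b.band:
            return False
        if self.area_pair is not None:
            got = tuple(sorted((AREA[a.location], AREA[b.location])))
            if got != tuple(sorted(self.area_pair)):
                return False
        if sel == "intra_channel":
            return a.location == b.location
        if sel == "inter_channel":
            return a.location != b.location
        if sel == "within_hemisphere":
            return (
                a.location != b.location
                and HEMISPHERE[a.location] == self.side
                and HEMISPHERE[b.location] == self.side
            )
        cross = HEMISPHERE[a.location] != HEMISPHERE[b.location]
        same_area = AREA[a.location] == AREA[b.location]
        if sel == "cross_hemisphere_horizontal":
            return cross and same_area
        if sel == "cross_hemisphere_diagonal":
            return cross and not same_area
        raise AssertionError("unreachable")


def extract_subnetwork(
    net: PhysioNetwork, spec: SubnetworkSpec
) -> PhysioNetwork:
    """Filter a network's edge set by a subnetwork selector."""
    edges = {
        pair: w
        for pair, w in net.edges.items()
        if spec.matches(*tuple(pair))
    }
    keep = {n for pair in edges for n in pair}
    return PhysioNetwork(
        stage=net.stage,
        nodes=[n for n in net.nodes if n in keep] or net.nodes,
        edges=edges,
    )


def build_networks(
    node_series: dict[NodeID, NodeSeries],
    hypnogram: Hypnogram,
    cfg: SegmentationConfig = DEFAULT_CONFIG,
) -> dict[str, PhysioNetwork]:
    """Compute %TDS for every unordered node pair and build per-stage nets.

    Each pair is analysed once with :func:`tdsnet.tds.tds_pair`; the
    per-stage stable fraction (x100) becomes the edge weight in that
    stage's network.  An ``"all"`` network holds the overall (whole-night)
    %TDS.  Missing stages (no attributable segment anywhere) are omitted.
    """
    nodes = sorted(node_series)
    if len(nodes) < 2:
        raise ValueError("need at least two node series")
    lengths = {len(s) for s in node_series.values()}
    t0s = {s.t0 for s in node_series.values()}
    if len(lengths) != 1 or len(t0s) != 1:
        raise ValueError("node series are not aligned; use align_series")

    results: dict[Edge, TDSResult] = {}
    for a, b in itertools.combinations(nodes, 2):
        results[frozenset((a, b))] = tds_pair(
            node_series[a], node_series[b], cfg=cfg, hypnogram=hypnogram
        )

    nets: dict[str, PhysioNetwork] = {
        "all": PhysioNetwork(
            stage="all",
            nodes=list(nodes),
            edges={p: 100.0 * r.pct_overall for p, r in results.items()},
        )
    }
    for stage in STAGES:
        edges = {
            p: 100.0 * r.pct_by_stage[stage]
            for p, r in results.items()
            if stage in r.pct_by_stage
        }
        if edges:
            nets[stage] = PhysioNetwork(
                stage=stage, nodes=list(nodes), edges=edges
            )
    return nets


def network_stats(
    net: PhysioNetwork, threshold: float = 45.0
) -> dict[str, float]:
    """Link count above threshold and mean strength over all candidates.

    ``n_links`` counts edges with weight >= ``threshold``; ``mean_strength``
    averages over *all* candidate edges stored in the network (including
    sub-threshold ones), so that count and strength remain independent
    summaries.
    """
    if not (0.0 <= threshold <= 100.0):
        raise ValueError("threshold must lie in [0, 100]")
    weights = np.array(list(net.edges.values()), dtype=float)
    n_links = int((weights >= threshold).sum()) if weights.size else 0
    mean = float(weights.mean()) if weights.size else float("nan")
    return {"n_links": n_links, "mean_strength": mean}


def group_average(nets: list[PhysioNetwork]) -> PhysioNetwork:
    """Edge-wise arithmetic mean over subjects' same-stage networks.

    All networks must share the stage label and node set; each edge is
    averaged over the subjects in which it was evaluated.
    """
    if not nets:
        raise ValueError("no networks to average")
    stage = nets[0].stage
    node_set = set(nets[0].nodes)
    for n in nets[1:]:
        if n.stage != stage:
            raise ValueError("networks have different stages")
        if set(n.nodes) != node_set:
            raise ValueError("networks have different node sets")
    sums: dict[Edge, float] = {}
    counts: dict[Edge, int] = {}
    for n in nets:
        for pair, w in n.edges.items():
            sums[pair] = sums.get(pair, 0.0) + w
            counts[pair] = counts.get(pair, 0) + 1
    edges = {pair: sums[pair] / counts[pair] for pair in sums}
    return PhysioNetwork(stage=stage, nodes=list(nets[0].nodes), edges=edges)


def organ_node_size(net: PhysioNetwork, organ: str) -> float:
    """Total brain control of one organ: sum of its brain-link weights."""
    if organ not in ORGANS:
        raise ValueError(f"unknown organ {organ!r}")
    target = NodeID.organ_node(organ)
    total = 0.0
    for pair, w in net.edges.items():
        if target in pair:
            other = next(iter(pair - {target}))
            if other.kind == "brain":
                total += w
    return total


def dominant_band(net: PhysioNetwork, organ: str) -> str | None:
    """Band with the largest summed link strength to one organ."""
    target = NodeID.organ_node(organ)
    sums: dict[str, float] = {b: 0.0 for b in BAND_NAMES}
    seen = False
    for pair, w in net.edges.items():
        if target in pair:
            other = next(iter(pair - {target}))
            if other.kind == "brain":
                sums[other.band] += w
                seen = True
    if not seen:
        return None
    return max(BAND_NAMES, key=lambda b: sums[b])
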