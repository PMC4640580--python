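"""File formats: EDF raw signals, delimited node series / hypnograms /
edge lists, and the YAML run configuration.

All tabular formats are tab-separated plain text.  Node-series tables have
one column per node (header = node id) and one row per second; hypnograms
are two columns (epoch start in seconds, single-letter stage code); edge
lists carry one pairwise %TDS result per row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    CODE_FOR_STAGE,
    Hypnogram,
    NodeSeries,
    SCORER_STAGE_MAP,
    STAGE_CODES,
)
from .network import NodeID, PhysioNetwork, classify_link
from .signal_features import RawSignal
from .tds import SegmentationConfig


def read_edf(path, channel_labels: list[str] | None = None) -> list[RawSignal]:
    """Read selected channels of an EDF/EDF+ recording as RawSignals."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = channel_labels if channel_labels is not None else raw.ch_names
    out: list[RawSignal] = []
    for label in labels:
        if label not in raw.ch_names:
            raise KeyError(f"channel {label!r} not in {path}")
        idx = raw.ch_names.index(label)
        data = raw.get_data(picks=[idx])[0]
        out.append(RawSignal(label=label, fs=float(raw.info["sfreq"]),
                             samples=np.asarray(data, dtype=float)))
    return out


def write_node_series(path, series: dict[str, NodeSeries]) -> None:
    """Write aligned node series as a TSV (header = node ids, rows = s)."""
    lengths = {len(s) for s in series.values()}
    if len(lengths) != 1:
        raise ValueError("series must share a common length; align first")
    df = pd.DataFrame({
        name: np.where(s.missing, np.nan, s.values)
        for name, s in series.items()
    })
    df.to_csv(path, sep="\t", index=False)


def read_node_series(path) -> dict[str, NodeSeries]:
    """Read a node-series TSV; NaN cells become missing samples."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: dict[str, NodeSeries] = {}
    for name in df.columns:
        vals = df[name].to_numpy(dtype=float)
        out[name] = NodeSeries(node_id=name, values=vals,
                               missing=~np.isfinite(vals))
    return out


def write_hypnogram(path, hyp: Hypnogram) -> None:
    """Two-column text: epoch start (s) and stage code in {W,R,L,D,A}."""
    with open(path, "w") as fh:
        fh.write("start_s\tstage\n")
        for i, stage in enumerate(hyp.stages):
            t = hyp.t0 + i * hyp.epoch_len
            fh.write(f"{t:g}\t{CODE_FOR_STAGE[stage]}\n")


def read_hypnogram(path, mapping: dict[str, str] | None = None) -> Hypnogram:
    """Read a two-column hypnogram; stages mapped to {W, REM, LS, DS, A}.

    ``mapping`` translates scorer vocabularies (e.g. ``N1 -> LS``,
    ``N3 -> DS``); the default accepts the common AASM/R&K codes.  The
    epoch grid is validated at 30 s spacing.
    """
    table = mapping or {**SCORER_STAGE_MAP, **STAGE_CODES}
    starts: list[float] = []
    stages: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split()
            if not parts or parts[0].lower().startswith("start"):
                continue
            if len(parts) != 2:
                raise ValueError(f"malformed hypnogram line: {line!r}")
            t, code = parts
            key = code.upper()
            if key not in table:
                raise ValueError(f"unknown stage code {code!r}")
            starts.append(float(t))
            stages.append(table[key])
    if not stages:
        raise ValueError("empty hypnogram")
    diffs = np.diff(starts)
    if starts and (np.any(diffs != 30.0)):
        raise ValueError("hypnogram epochs must be contiguous at 30 s")
    return Hypnogram(stages=stages, epoch_len=30.0, t0=starts[0])


def write_edge_list(path, nets: dict[str, PhysioNetwork]) -> None:
    """Write per-stage pairwise results: node_i, node_j, stage, weight,
    category."""
    rows = []
    for stage, net in sorted(nets.items()):
        for pair, w in sorted(
            net.edges.items(), key=lambda kv: tuple(sorted(n.label for n in kv[0]))
        ):
            a, b = sorted(pair, key=lambda n: n.label)
            rows.append({
                "node_i": a.label, "node_j": b.label, "stage": stage,
                "pct_tds": w, "category": classify_link(w).name,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> dict[str, PhysioNetwork]:
    """Read an edge-list TSV back into per-stage networks."""
    df = pd.read_csv(path, sep="\t")
    nets: dict[str, PhysioNetwork] = {}
    for stage, sub in df.groupby("stage"):
        edges = {}
        nodes: set[NodeID] = set()
        for _, row in sub.iterrows():
            a = NodeID.parse(str(row["node_i"]))
            b = NodeID.parse(str(row["node_j"]))
            nodes.update((a, b))
            edges[frozenset((a, b))] = float(row["pct_tds"])
        nets[str(stage)] = PhysioNetwork(
            stage=str(stage), nodes=sorted(nodes), edges=edges
        )
    return nets


@dataclass
class RunConfig:
    """Full, file-round-trippable configuration of an analysis run.

    Defaults are the standard analysis parameters: 60 s segments with 30 s
    stride, 4-of-5 stability within +-1 s, and the 45 / 5 / 3 %TDS display
    thresholds for brain-brain, brain-organ and brain-respiration maps.
    """

    L: int = 60
    step: int = 30
    stab_window: int = 5
    stab_min_agree: int = 4
    stab_tol: int = 1
    win_s: float = 2.0
    overlap_s: float = 1.0
    brain_brain_threshold: float = 45.0
    brain_organ_threshold: float = 5.0
    brain_resp_threshold: float = 3.0
    stage_map: dict = field(default_factory=lambda: dict(SCORER_STAGE_MAP))
    seed: int = 0

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            L=self.L, step=self.step, stab_window=self.stab_window,
            stab_min_agree=self.stab_min_agree, stab_tol=self.stab_tol,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def write_ground_truth(path, truth: dict) -> None:
    import json

    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
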