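"""Shared in-memory containers for 1 Hz node series and sleep-stage hypnograms.

Every downstream computation in this package operates on uniformly sampled
1 Hz scalar series (``NodeSeries``) — one per network node — and on a
``Hypnogram`` holding the sleep-stage label of each 30 s scoring epoch.
Heterogeneous raw recordings (EEG, EOG, EMG, heartbeat/breath event trains)
are reduced to this common representation by :mod:`tdsnet.signal_features`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical sleep-stage vocabulary: quiet wake, REM sleep, light sleep
#: (NREM 1-2) and deep sleep (NREM 3-4).
STAGES: tuple[str, ...] = ("W", "REM", "LS", "DS")

#: Label used for scoring epochs that carry no usable stage.
ARTIFACT: str = "artifact"

#: Single-letter stage codes used in plain-text hypnogram files.
STAGE_CODES: dict[str, str] = {
    "W": "W",
    "R": "REM",
    "L": "LS",
    "D": "DS",
    "A": ARTIFACT,
}
CODE_FOR_STAGE: dict[str, str] = {v: k for k, v in STAGE_CODES.items()}

#: Mapping from common scorer vocabularies to the canonical four stages.
#: N1/N2 collapse to light sleep, N3/N4 to deep sleep.
SCORER_STAGE_MAP: dict[str, str] = {
    "W": "W", "WAKE": "W", "0": "W",
    "R": "REM", "REM": "REM", "5": "REM",
    "N1": "LS", "N2": "LS", "S1": "LS", "S2": "LS", "1": "LS", "2": "LS",
    "L": "LS", "LS": "LS",
    "N3": "DS", "N4": "DS", "S3": "DS", "S4": "DS", "3": "DS", "4": "DS",
    "D": "DS", "DS": "DS",
    "A": ARTIFACT, "ARTIFACT": ARTIFACT, "?": ARTIFACT, "U": ARTIFACT,
}


@dataclass
class NodeSeries:
    """A named, uniformly sampled 1 Hz scalar time series (one network node).

    Parameters
    ----------
    node_id
        Node label, e.g. ``"Fp1:alpha"`` for an EEG channel x band node or
        ``"heart"`` for an organ node.
    values
        Samples at exactly 1 s spacing.
    missing
        Boolean mask marking samples that carry no valid value (artifacts,
        gaps).  Defaults to all-valid.
    t0
        Time of the first sample relative to the recording start (s).
    meta
        Free-form provenance (window/taper used, burst ground truth, ...).
    """

    node_id: str
    values: np.ndarray
    missing: np.ndarray | None = None
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("NodeSeries values must be one-dimensional")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            self.missing |= ~np.isfinite(self.values)
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask length must equal values length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span of the series in seconds (1 sample == 1 s)."""
        return float(self.values.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def crop(self, start: float, stop: float) -> "NodeSeries":
        """Return the sub-series covering absolute times ``[start, stop)``."""
        i0 = int(round(start - self.t0))
        i1 = int(round(stop - self.t0))
        if i0 < 0 or i1 > len(self) or i1 <= i0:
            raise ValueError(
                f"crop [{start}, {stop}) outside series span "
                f"[{self.t0}, {self.t_end})"
            )
        return NodeSeries(
            node_id=self.node_id,
            values=self.values[i0:i1].copy(),
            missing=self.missing[i0:i1].copy(),
            t0=float(start),
            meta=dict(self.meta),
        )


@dataclass
class Hypnogram:
    """Sleep-stage labels for consecutive fixed-length scoring epochs.

    ``stages[i]`` labels the epoch covering
    ``[t0 + i*epoch_len, t0 + (i+1)*epoch_len)``.
    """

    stages: list[str]
    epoch_len: float = 30.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        bad = {s for s in self.stages} - set(STAGES) - {ARTIFACT}
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_len

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def stage_at(self, t: float) -> str | None:
        """Stage label of the epoch containing absolute time ``t``.

        Returns ``None`` outside the scored span.
        """
        i = math.floor((t - self.t0) / self.epoch_len)
        if i < 0 or i >= len(self.stages):
            return None
        return self.stages[i]

    def stage_fractions(self) -> dict[str, float]:
        """Fraction of epochs spent in each stage (artifact included)."""
        n = len(self.stages)
        if n == 0:
            return {}
        out: dict[str, float] = {}
        for s in self.stages:
            out[s] = out.get(s, 0.0) + 1.0 / n
        return out

    def crop(self, start: float, stop: float) -> "Hypnogram":
        """Keep only epochs fully inside absolute times ``[start, stop)``."""
        i0 = math.ceil((start - self.t0) / self.epoch_len - 1e-9)
        i1 = math.floor((stop - self.t0) / self.epoch_len + 1e-9)
        i0 = max(i0, 0)
        i1 = min(i1, len(self.stages))
        if i1 <= i0:
            raise ValueError("crop span contains no complete epoch")
        return Hypnogram(
            stages=list(self.stages[i0:i1]),
            epoch_len=self.epoch_len,
            t0=self.t0 + i0 * self.epoch_len,
        )
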