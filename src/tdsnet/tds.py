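"""Time Delay Stability (TDS): a coupling measure for diverse 1 Hz signals.

Two signals of common length ``N`` are divided into ``N_L`` overlapping
segments of length ``L = 60`` s with stride ``L/2 = 30`` s, so that
``N_L = floor(2N/L) - 1``.  Each segment is z-normalized (zero mean, unit
standard deviation) and the circular (periodic-boundary) cross-correlation

    C_ab(tau) = (1/L) * sum_i a_i * b_{(i+tau) mod L}

is evaluated for every integer lag.  The per-segment delay ``tau0`` is the
lag maximizing ``|C(tau)|``.  A sliding window of five consecutive segments
is labelled stable when at least four of its delays agree within +-1 s of a
common reference; %TDS is the fraction of stable segments and is the link
strength used for physiologic networks.  Physiologically, stable delays
over >= 2.5 min (5 windows x 30 s stride) indicate sustained coupling
between bursting activations of two systems, independent of their very
different signal amplitudes and dynamics.

All functions here are deterministic; stochastic behaviour lives entirely
in :mod:`tdsnet.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import ARTIFACT, Hypnogram, NodeSeries


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the segmentation and stability rule.

    Defaults encode the standard analysis: 60 s segments, 30 s stride,
    stability when >= 4 of 5 consecutive delays agree within +-1 s.
    """

    L: int = 60
    step: int = 30
    stab_window: int = 5
    stab_min_agree: int = 4
    stab_tol: int = 1

    def __post_init__(self) -> None:
        if self.L <= 0 or self.step <= 0 or self.L % self.step:
            raise ValueError("need L > 0 and step dividing L")
        if not (0 < self.stab_min_agree <= self.stab_window):
            raise ValueError("need 0 < stab_min_agree <= stab_window")
        if self.stab_tol < 0:
            raise ValueError("stab_tol must be nonnegative")

    @property
    def lags(self) -> np.ndarray:
        """Integer lag range ``[-L/2, L/2)`` — all distinct circular lags."""
        half = self.L // 2
        return np.arange(-half, self.L - half)

    @property
    def min_stable_span(self) -> int:
        """Shortest coupling episode the stability rule can flag (s)."""
        return self.stab_window * self.step


DEFAULT_CONFIG = SegmentationConfig()


@dataclass
class CorrelationFunction:
    """Circular cross-correlation values over an integer lag range."""

    values: np.ndarray
    lags: np.ndarray


@dataclass
class TauSeries:
    """Per-segment optimal delays with validity and timing metadata."""

    taus: np.ndarray          # int, one per segment (0 where invalid)
    valid: np.ndarray         # bool, False for segments that could not be
                              # normalized (missing data or zero variance)
    seg_times: np.ndarray     # absolute segment start times (s)

    def __len__(self) -> int:
        return self.taus.size


@dataclass
class StabilityMask:
    """Boolean stability label per segment (stable implies valid)."""

    stable: np.ndarray


@dataclass
class TDSResult:
    """%TDS of one signal pair, overall and per sleep stage."""

    pct_overall: float
    pct_by_stage: dict[str, float]
    mask: StabilityMask
    taus: TauSeries
    seg_stages: list[str | None] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.taus)

    @property
    def n_valid(self) -> int:
        return int(self.taus.valid.sum())


def segment_count(N: int, cfg: SegmentationConfig = DEFAULT_CONFIG) -> int:
    """Number of overlapping segments of length ``L`` with stride ``step``.

    For the default half-overlap this equals ``floor(2N/L) - 1``.
    """
    if N < cfg.L:
        raise ValueError(f"series of length {N} shorter than segment {cfg.L}")
    return (int(N) - cfg.L) // cfg.step + 1


def normalize_segment(seg: np.ndarray) -> np.ndarray | None:
    """Z-normalize one segment; ``None`` if degenerate.

    A segment with any non-finite value or zero standard deviation cannot
    be normalized and is marked invalid (returned as ``None``), which
    downstream excludes it from the %TDS numerator and denominator.
    """
    seg = np.asarray(seg, dtype=float)
    if not np.all(np.isfinite(seg)):
        return None
    sd = seg.std()
    if sd == 0:
        return None
    return (seg - seg.mean()) / sd


def circular_xcorr(
    a_seg: np.ndarray, b_seg: np.ndarray,
    cfg: SegmentationConfig = DEFAULT_CONFIG,
) -> CorrelationFunction:
    """Circular cross-correlation of two z-normalized equal-length segments.

    ``C(tau) = (1/L) sum_i a_i b_{(i+tau) mod L}`` evaluated via the FFT
    correlation theorem at every lag in ``cfg.lags``.
    """
    a = np.asarray(a_seg, dtype=float)
    b = np.asarray(b_seg, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("segments must be 1-d and of equal length")
    L = a.size
    full = np.fft.irfft(
        np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n=L
    ) / L
    lags = cfg.lags if L == cfg.L else np.arange(-(L // 2), L - L // 2)
    return CorrelationFunction(values=full[lags % L], lags=lags)


def _tie_order(lags: np.ndarray) -> np.ndarray:
    """Column order implementing the tie rule: smallest |tau|, then
    positive before negative."""
    return np.lexsort((lags < 0, np.abs(lags)))


def find_tau0(C: CorrelationFunction) -> int:
    """Delay maximizing ``|C(tau)|``.

    Ties are broken deterministically in favour of the smallest ``|tau|``;
    an exact ``+-tau`` tie resolves to the positive lag (short physiologic
    delays are preferred).
    """
    order = _tie_order(C.lags)
    absC = np.abs(C.values)[order]
    return int(C.lags[order][int(np.argmax(absC))])


def stability_mask(
    taus: TauSeries, cfg: SegmentationConfig = DEFAULT_CONFIG
) -> StabilityMask:
    """Label segments stable via the sliding 4-of-5 agreement rule.

    Every window of ``stab_window`` consecutive segments is examined (step
    one).  Windows containing an invalid segment are skipped.  A window
    passes if some integer reference delay ``r`` captures at least
    ``stab_min_agree`` of the window's delays within ``+-stab_tol``; every
    captured segment of a passing window is marked stable, and marks
    accumulate (union) across overlapping windows.
    """
    n = len(taus)
    if n == 0:
        raise ValueError("empty delay series")
    stable = np.zeros(n, dtype=bool)
    w = cfg.stab_window
    tol = cfg.stab_tol
    for start in range(0, n - w + 1):
        sl = slice(start, start + w)
        if not taus.valid[sl].all():
            continue
        window = taus.taus[sl]
        candidates = set()
        for t in window:
            candidates.update(range(int(t) - tol, int(t) + tol + 1))
        for r in candidates:
            agree = np.abs(window - r) <= tol
            if agree.sum() >= cfg.stab_min_agree:
                stable[sl] |= agree
    return StabilityMask(stable=stable)


def percent_tds(
    mask: StabilityMask, valid: np.ndarray | None = None
) -> float:
    """Fraction of stable segments among valid segments, in ``[0, 1]``.

    Invalid segments (missing data / zero variance) count in neither the
    numerator nor the denominator; with no valid segment the fraction is 0.
    """
    if mask.stable.size == 0:
        raise ValueError("empty stability mask")
    if valid is None:
        valid = np.ones_like(mask.stable)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return 0.0
    return float(mask.stable.sum() / n_valid)


def _segment_matrix(values: np.ndarray, n_seg: int, cfg: SegmentationConfig
                    ) -> np.ndarray:
    idx = np.arange(n_seg)[:, None] * cfg.step + np.arange(cfg.L)[None, :]
    return values[idx]


def _segment_stage(
    hyp: Hypnogram, t_start: float, L: int
) -> str | None:
    """Stage attributed to the segment ``[t_start, t_start+L)``.

    The segment is attributed only if every scoring epoch it covers exists
    and carries the same (non-artifact) stage; segments spanning a stage
    transition are excluded from per-stage tallies.
    """
    e0 = math.floor((t_start - hyp.t0) / hyp.epoch_len + 1e-9)
    e1 = math.ceil((t_start + L - hyp.t0) / hyp.epoch_len - 1e-9)
    if e0 < 0 or e1 > len(hyp):
        return None
    found = set(hyp.stages[e0:e1])
    if len(found) != 1:
        return None
    stage = found.pop()
    return None if stage == ARTIFACT else stage


def tds_pair(
    x: NodeSeries,
    y: NodeSeries,
    cfg: SegmentationConfig = DEFAULT_CONFIG,
    hypnogram: Hypnogram | None = None,
) -> TDSResult:
    """Full TDS pipeline for one aligned pair of 1 Hz node series.

    Segments both series, z-normalizes each segment, locates the delay
    ``tau0`` maximizing the absolute circular cross-correlation, applies
    the sliding stability rule and reports the stable fraction — overall
    and, when a hypnogram is given, separately per sleep stage (a segment
    contributes to a stage only if all epochs it covers share that stage).
    """
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if x.t0 != y.t0:
        raise ValueError("series are not aligned (different t0)")
    N = len(x)
    n_seg = segment_count(N, cfg)
    L = cfg.L

    A = _segment_matrix(x.values, n_seg, cfg)
    B = _segment_matrix(y.values, n_seg, cfg)
    miss = (
        _segment_matrix(x.missing, n_seg, cfg).any(axis=1)
        | _segment_matrix(y.missing, n_seg, cfg).any(axis=1)
    )
    A = np.where(np.isfinite(A), A, 0.0)
    B = np.where(np.isfinite(B), B, 0.0)
    sa = A.std(axis=1)
    sb = B.std(axis=1)
    valid = ~miss & (sa > 0) & (sb > 0)
    sa_safe = np.where(sa > 0, sa, 1.0)
    sb_safe = np.where(sb > 0, sb, 1.0)
    An = (A - A.mean(axis=1, keepdims=True)) / sa_safe[:, None]
    Bn = (B - B.mean(axis=1, keepdims=True)) / sb_safe[:, None]

    full = np.fft.irfft(
        np.conj(np.fft.rfft(An, axis=1)) * np.fft.rfft(Bn, axis=1),
        n=L, axis=1,
    ) / L
    lags = cfg.lags
    C = full[:, lags % L]
    order = _tie_order(lags)
    taus = lags[order][np.argmax(np.abs(C)[:, order], axis=1)]
    taus = np.where(valid, taus, 0).astype(int)

    seg_times = x.t0 + np.arange(n_seg) * cfg.step
    tau_series = TauSeries(taus=taus, valid=valid,
                           seg_times=seg_times.astype(float))
    mask = stability_mask(tau_series, cfg)
    pct = percent_tds(mask, valid)

    seg_stages: list[str | None] = [None] * n_seg
    pct_by_stage: dict[str, float] = {}
    if hypnogram is not None:
        for i in range(n_seg):
            seg_stages[i] = _segment_stage(hypnogram, seg_times[i], L)
        counts: dict[str, int] = {}
        stables: dict[str, int] = {}
        for i in range(n_seg):
            s = seg_stages[i]
            if s is None or not valid[i]:
                continue
            counts[s] = counts.get(s, 0) + 1
            stables[s] = stables.get(s, 0) + int(mask.stable[i])
        pct_by_stage = {s: stables[s] / counts[s] for s in counts}

    return TDSResult(
        pct_overall=pct,
        pct_by_stage=pct_by_stage,
        mask=mask,
        taus=tau_series,
        seg_stages=seg_stages,
    )


def modal_tau(result: TDSResult) -> int | None:
    """Most frequent delay among valid segments (ties -> smallest |tau|,
    positive first); ``None`` with no valid segment."""
    taus = result.taus.taus[result.taus.valid]
    if taus.size == 0:
        return None
    vals, counts = np.unique(taus, return_counts=True)
    best = counts.max()
    cand = vals[counts == best]
    cand = sorted(cand, key=lambda t: (abs(int(t)), int(t) < 0))
    return int(cand[0])
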