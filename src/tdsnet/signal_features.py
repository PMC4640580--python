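"""Reduce raw physiological signals to 1 Hz node series.

Four reductions cover the modalities used in physiologic-network analysis:

* EEG  -> spectral power of seven conventional frequency bands, computed in
  moving 2 s windows advanced by 1 s (i.e. 1 s overlap);
* EOG / EMG -> moving-window variance with the same windowing;
* heartbeat / breath event trains -> instantaneous rate resampled into 1 s
  bins (interval tachogram sample-and-hold, then inverted);
* :func:`align_series` trims a set of series plus hypnogram to their common
  time span.

All outputs are :class:`~tdsnet.containers.NodeSeries` at exactly 1 Hz, the
common resolution at which the time-delay-stability measure operates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .containers import Hypnogram, NodeSeries


@dataclass
class RawSignal:
    """A raw recorded channel: label, sampling rate and samples.

    Non-finite samples are treated as missing and propagate to every moving
    window that touches them.
    """

    label: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-d sequence")


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"band {self.name}: need 0 <= lo < hi")


#: The seven conventional EEG bands used throughout: delta (0-4 Hz),
#: theta (4-8), alpha (8-12), sigma (12-16, sleep-spindle range),
#: beta (16-20), gamma1 (20-34) and gamma2 (34-100).
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("sigma", 12.0, 16.0),
    BandDefinition("beta", 16.0, 20.0),
    BandDefinition("gamma1", 20.0, 34.0),
    BandDefinition("gamma2", 34.0, 100.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)

#: Greek aliases accepted wherever a band name is parsed.
BAND_ALIASES: dict[str, str] = {
    "δ": "delta", "θ": "theta", "α": "alpha", "σ": "sigma",
    "β": "beta", "γ1": "gamma1", "γ2": "gamma2",
}


def band_by_name(name: str) -> BandDefinition:
    name = BAND_ALIASES.get(name, name)
    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")


@dataclass
class EventTrain:
    """Strictly increasing event times (s), e.g. R-peaks or breath onsets."""

    event_times: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.event_times.ndim != 1:
            raise ValueError("event_times must be one-dimensional")
        if np.any(self.event_times < 0):
            raise ValueError("event times must be nonnegative")
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")


def _frame(samples: np.ndarray, nper: int, step: int) -> np.ndarray:
    """View of ``samples`` as overlapping frames of length ``nper``."""
    n_out = (samples.size - nper) // step + 1
    if n_out < 1:
        raise ValueError("window longer than signal")
    idx = np.arange(n_out)[:, None] * step + np.arange(nper)[None, :]
    return samples[idx]


def band_power_series(
    raw: RawSignal,
    band: BandDefinition,
    win: float = 2.0,
    overlap: float = 1.0,
) -> NodeSeries:
    """Band power of ``raw`` in moving windows, as a 1 Hz node series.

    Each window of ``win`` seconds (advanced by ``win - overlap`` seconds;
    the defaults give one value per second) is mean-removed, Hann-tapered
    and transformed with a one-sided DFT periodogram; the value is the sum
    of the periodogram over bins whose centre frequency lies in
    ``[band.lo, band.hi)``.  Removing the per-window mean keeps constant
    offsets out of the delta band.

    Bands that extend beyond the Nyquist frequency are clipped; the clip is
    recorded in the output's ``meta['clipped']``.
    """
    step = win - overlap
    if step <= 0:
        raise ValueError("overlap must be smaller than the window")
    nper = int(round(win * raw.fs))
    nstep = int(round(step * raw.fs))
    if nper < 4:
        raise ValueError("window too short: need win*fs >= 4 samples")

    clipped = False
    hi = band.hi
    nyq = raw.fs / 2.0
    if hi > nyq:
        hi = nyq
        clipped = True
        warnings.warn(
            f"band {band.name} [{band.lo}, {band.hi}) clipped to Nyquist "
            f"{nyq} Hz for fs={raw.fs}",
            stacklevel=2,
        )

    finite = np.where(np.isfinite(raw.samples), raw.samples, 0.0)
    frames = _frame(finite, nper, nstep)
    bad = _frame(~np.isfinite(raw.samples), nper, nstep).any(axis=1)

    window = scipy.signal.get_window("hann", nper)
    detrended = frames - frames.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(detrended * window, axis=1)
    # One-sided periodogram, same scaling as scipy.signal.periodogram:
    # PSD in units of power per Hz, doubled off DC/Nyquist.
    scale = 1.0 / (raw.fs * np.sum(window**2))
    psd = (spec.real**2 + spec.imag**2) * scale
    psd[:, 1:] *= 2.0
    if nper % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nper, d=1.0 / raw.fs)
    sel = (freqs >= band.lo) & (freqs < hi)
    values = psd[:, sel].sum(axis=1)
    values[bad] = np.nan

    return NodeSeries(
        node_id=f"{raw.label}:{band.name}",
        values=values,
        missing=bad,
        t0=raw.t0,
        meta={
            "feature": "band_power",
            "band": (band.name, band.lo, band.hi),
            "window": "hann",
            "win_s": win,
            "overlap_s": overlap,
            "clipped": clipped,
        },
    )


def moving_variance_series(
    raw: RawSignal,
    win: float = 2.0,
    overlap: float = 1.0,
) -> NodeSeries:
    """Moving-window sample variance (ddof=1) of a raw signal at 1 Hz."""
    step = win - overlap
    if step <= 0:
        raise ValueError("overlap must be smaller than the window")
    nper = int(round(win * raw.fs))
    nstep = int(round(step * raw.fs))
    if nper < 2:
        raise ValueError("window too short: need win*fs >= 2 samples")

    finite = np.where(np.isfinite(raw.samples), raw.samples, 0.0)
    frames = _frame(finite, nper, nstep)
    bad = _frame(~np.isfinite(raw.samples), nper, nstep).any(axis=1)
    values = frames.var(axis=1, ddof=1)
    values[bad] = np.nan
    return NodeSeries(
        node_id=f"{raw.label}:var",
        values=values,
        missing=bad,
        t0=raw.t0,
        meta={"feature": "moving_variance", "win_s": win, "overlap_s": overlap},
    )


def events_to_rate(
    train: EventTrain, duration: float, node_id: str = "rate"
) -> NodeSeries:
    """Instantaneous rate series from an event train, one value per 1 s bin.

    The interval tachogram is resampled by sample-and-hold: each 1 s bin
    takes the inter-event interval of the event pair spanning the bin's
    midpoint, then the interval is inverted (rate = 1/interval, in 1/s).
    Bins whose midpoint falls before the first or after the last event are
    flagged missing.
    """
    times = train.event_times
    if times.size < 2:
        raise ValueError("need at least two events to define an interval")
    n = int(np.floor(duration))
    mids = np.arange(n) + 0.5
    idx = np.searchsorted(times, mids)
    missing = (idx == 0) | (idx == times.size)
    idx_c = np.clip(idx, 1, times.size - 1)
    intervals = times[idx_c] - times[idx_c - 1]
    values = 1.0 / intervals
    values[missing] = np.nan
    return NodeSeries(
        node_id=node_id,
        values=values,
        missing=missing,
        t0=0.0,
        meta={"feature": "event_rate"},
    )


def align_series(
    series_list: list[NodeSeries], hypnogram: Hypnogram | None = None
) -> tuple[list[NodeSeries], Hypnogram | None]:
    """Crop all series (and the hypnogram) to their common time span.

    The common span is ``[max(t0), min(t_end))`` over all inputs, rounded
    inward to whole seconds; the hypnogram is cropped to complete epochs
    inside the same span.
    """
    if not series_list:
        raise ValueError("no series to align")
    start = max(s.t0 for s in series_list)
    stop = min(s.t_end for s in series_list)
    if hypnogram is not None:
        start = max(start, hypnogram.t0)
        stop = min(stop, hypnogram.t_end)
    start = float(np.ceil(start))
    stop = float(np.floor(stop))
    if stop <= start:
        raise ValueError("series have no common time span")
    out = [s.crop(start, stop) for s in series_list]
    hyp = hypnogram.crop(start, stop) if hypnogram is not None else None
    return out, hyp
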