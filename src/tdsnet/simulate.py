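"""Synthetic 1 Hz bursting node series with stage-modulated couplings.

Real physiologic node series (EEG band power, muscle-tone variance, heart
and breathing rate) are intermittent: quiescent baselines punctuated by
bursts of activation, with coupled systems reproducing each other's bursts
at a characteristic delay.  This module generates that phenomenology
directly at the 1 Hz node-series level:

* :func:`generate_burst_signal` -- baseline Gaussian noise plus Poisson-
  placed smooth Gaussian bursts (circular in time, so a record behaves the
  same near its edges as in its middle);
* :func:`derive_coupled_signal` -- reproduces each source burst in a target
  series with a stage-dependent probability at a fixed delay (plus optional
  jitter); unreproduced bursts are replaced by independent ones so the
  burst rate is stage-independent.  Coupling therefore lives in the
  *timing* of bursts, which is exactly what the time-delay-stability
  measure responds to, not in raw amplitude correlation;
* :func:`generate_hypnogram` -- a semi-Markov stage sequence over 30 s
  epochs with geometric dwell times;
* :func:`generate_cohort` -- several subjects with a shared coupling graph
  and per-subject random streams, plus the ground truth for recovery
  scoring.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical configurations yield
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import Hypnogram, NodeSeries, STAGES


@dataclass(frozen=True)
class BurstModel:
    """Parameters of the bursting signal model.

    ``rate_per_min`` bursts are placed per minute on average; each burst is
    a Gaussian bump of standard width ``duration_s / 2`` seconds with a
    log-normal amplitude (median ``amp_median``, log-sd ``amp_sigma``) on
    top of white baseline noise of standard deviation ``noise_sd``.
    """

    rate_per_min: float = 4.0
    duration_s: float = 5.0
    amp_median: float = 1.0
    amp_sigma: float = 0.4
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if min(self.rate_per_min, self.duration_s, self.amp_median) <= 0:
            raise ValueError("rate, duration and amplitude must be positive")
        if self.noise_sd < 0 or self.amp_sigma < 0:
            raise ValueError("noise_sd and amp_sigma must be nonnegative")


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth coupling of one directed source -> target pair.

    ``strength`` maps each sleep stage to the probability in ``[0, 1]``
    that a source burst is reproduced in the target at ``delay`` seconds
    (1 = deterministic delayed copy, 0 = independent).  ``jitter`` is the
    standard deviation (s) of Gaussian noise added to the delay per burst.
    """

    pair: tuple[str, str]
    delay: int
    strength: dict[str, float] = field(default_factory=dict)
    jitter: float = 0.0

    def __post_init__(self) -> None:
        for s, v in self.strength.items():
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
            if not (0.0 <= v <= 1.0):
                raise ValueError("coupling strength must lie in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")

    def strength_at(self, stage: str | None) -> float:
        if stage is None:
            return 0.0
        return self.strength.get(stage, 0.0)


@dataclass(frozen=True)
class StageDynamics:
    """Semi-Markov sleep-stage dynamics over 30 s epochs.

    ``mean_dwell`` gives the mean episode length per stage in epochs
    (dwell times are geometric, i.e. memoryless per epoch; ``inf`` makes a
    stage absorbing).  ``transitions`` holds the embedded between-stage
    transition weights (no self-transitions; rows are normalized).
    """

    mean_dwell: dict[str, float] = field(
        default_factory=lambda: {"W": 10.0, "LS": 40.0, "DS": 20.0,
                                 "REM": 15.0}
    )
    transitions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "W": {"LS": 1.0},
            "LS": {"DS": 0.5, "REM": 0.3, "W": 0.2},
            "DS": {"LS": 1.0},
            "REM": {"LS": 0.7, "W": 0.3},
        }
    )

    def stage_list(self) -> list[str]:
        return [s for s in STAGES if s in self.mean_dwell]

    def embedded_matrix(self) -> np.ndarray:
        stages = self.stage_list()
        P = np.zeros((len(stages), len(stages)))
        for i, s in enumerate(stages):
            row = self.transitions.get(s, {})
            total = sum(row.values())
            if total <= 0:
                P[i, i] = 1.0  # absorbing in the embedded chain
                continue
            for t, w in row.items():
                P[i, stages.index(t)] = w / total
        return P

    def stationary_epoch_distribution(self) -> dict[str, float]:
        """Long-run fraction of epochs per stage.

        The embedded chain's stationary distribution weighted by mean
        dwell; stages with infinite dwell absorb all the mass.
        """
        stages = self.stage_list()
        dwell = np.array([self.mean_dwell[s] for s in stages])
        if np.isinf(dwell).any():
            w = np.isinf(dwell).astype(float)
        else:
            P = self.embedded_matrix()
            evals, evecs = np.linalg.eig(P.T)
            k = int(np.argmin(np.abs(evals - 1.0)))
            pi = np.real(evecs[:, k])
            pi = np.abs(pi) / np.abs(pi).sum()
            w = pi * dwell
        w = w / w.sum()
        return dict(zip(stages, w))


DEFAULT_DYNAMICS = StageDynamics()
DEFAULT_BURST_MODEL = BurstModel()


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_hypnogram(
    duration: float,
    dynamics: StageDynamics = DEFAULT_DYNAMICS,
    seed=0,
) -> Hypnogram:
    """Sample a 30 s-epoch hypnogram from the stage dynamics.

    The initial stage is drawn from the stationary epoch distribution, so
    with geometric (memoryless) dwells the epoch process is stationary
    from the first epoch on.
    """
    rng = _as_rng(seed)
    n_epochs = int(duration // 30)
    if n_epochs < 1:
        raise ValueError("duration shorter than one 30 s epoch")
    stages = dynamics.stage_list()
    stat = dynamics.stationary_epoch_distribution()
    probs = np.array([stat[s] for s in stages])
    current = stages[rng.choice(len(stages), p=probs)]
    P = dynamics.embedded_matrix()

    out: list[str] = []
    while len(out) < n_epochs:
        m = dynamics.mean_dwell[current]
        if np.isinf(m):
            dwell = n_epochs - len(out)
        else:
            dwell = int(rng.geometric(1.0 / m))
        out.extend([current] * min(dwell, n_epochs - len(out)))
        i = stages.index(current)
        current = stages[rng.choice(len(stages), p=P[i])]
    return Hypnogram(stages=out[:n_epochs])


def _burst_field(
    duration: int,
    times: np.ndarray,
    amps: np.ndarray,
    model: BurstModel,
) -> np.ndarray:
    """Superpose Gaussian bumps circularly onto a 1 Hz grid."""
    t = np.arange(duration, dtype=float)
    if times.size == 0:
        return np.zeros(duration)
    d = t[None, :] - times[:, None]
    d = (d + duration / 2.0) % duration - duration / 2.0
    sigma = model.duration_s / 2.0
    return (amps[:, None] * np.exp(-0.5 * (d / sigma) ** 2)).sum(axis=0)


def generate_burst_signal(
    duration: float,
    model: BurstModel = DEFAULT_BURST_MODEL,
    seed=0,
    node_id: str = "burst",
) -> NodeSeries:
    """Baseline noise plus Poisson-placed Gaussian bursts, at 1 Hz.

    Burst times and amplitudes are stored in ``meta['bursts']`` so that
    coupled series can be derived burst-by-burst.
    """
    rng = _as_rng(seed)
    n = int(duration)
    n_bursts = int(rng.poisson(model.rate_per_min * n / 60.0))
    times = np.sort(rng.uniform(0.0, n, size=n_bursts))
    amps = model.amp_median * np.exp(
        model.amp_sigma * rng.standard_normal(n_bursts)
    )
    values = _burst_field(n, times, amps, model)
    if model.noise_sd > 0:
        values = values + model.noise_sd * rng.standard_normal(n)
    return NodeSeries(
        node_id=node_id,
        values=values,
        t0=0.0,
        meta={"bursts": np.column_stack([times, amps])
              if n_bursts else np.empty((0, 2))},
    )


def derive_coupled_signal(
    source: NodeSeries,
    spec: CouplingSpec,
    hypnogram: Hypnogram | None,
    model: BurstModel = DEFAULT_BURST_MODEL,
    seed=0,
    node_id: str | None = None,
) -> NodeSeries:
    """Derive a target series coupled to ``source`` at the spec's delay.

    For each source burst at time ``t`` the stage of the hypnogram at
    ``t`` sets the reproduction probability: reproduced bursts appear at
    ``t + delay (+ jitter)`` with the source amplitude; unreproduced ones
    are replaced by an independent burst at a uniformly random time with a
    fresh amplitude, keeping the overall burst rate stage-independent.
    Burst positions wrap circularly at the record ends.  With no hypnogram
    the coupling applies with the maximum configured strength everywhere.
    """
    rng = _as_rng(seed)
    bursts = source.meta.get("bursts")
    if bursts is None:
        raise ValueError("source carries no burst ground truth in meta")
    n = len(source)
    full = max(spec.strength.values(), default=0.0)

    out_times: list[float] = []
    out_amps: list[float] = []
    for t, amp in np.asarray(bursts, dtype=float).reshape(-1, 2):
        if hypnogram is None:
            s = full
        else:
            s = spec.strength_at(hypnogram.stage_at(t))
        if rng.random() < s:
            t2 = t + spec.delay
            if spec.jitter > 0:
                t2 += rng.normal(0.0, spec.jitter)
            out_times.append(t2 % n)
            out_amps.append(amp)
        else:
            out_times.append(float(rng.uniform(0.0, n)))
            out_amps.append(
                float(model.amp_median
                      * np.exp(model.amp_sigma * rng.standard_normal()))
            )
    times = np.asarray(out_times)
    amps = np.asarray(out_amps)
    values = _burst_field(n, times, amps, model)
    if model.noise_sd > 0:
        values = values + model.noise_sd * rng.standard_normal(n)
    return NodeSeries(
        node_id=node_id or spec.pair[1],
        values=values,
        t0=source.t0,
        meta={"bursts": np.column_stack([times, amps])
              if times.size else np.empty((0, 2)),
              "coupled_to": spec.pair[0],
              "true_delay": spec.delay},
    )


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort; the seed is mandatory."""

    seed: int
    n_subjects: int = 1
    duration: float = 3600.0
    nodes: tuple[str, ...] = ("a", "b")
    couplings: tuple[CouplingSpec, ...] = ()
    burst_model: BurstModel = field(default_factory=BurstModel)
    dynamics: StageDynamics = field(default_factory=StageDynamics)

    def __post_init__(self) -> None:
        if self.duration < 600:
            raise ValueError("duration must cover at least ten 60 s segments")
        targets = [c.pair[1] for c in self.couplings]
        if len(targets) != len(set(targets)):
            raise ValueError("each node may be the target of one coupling")
        for c in self.couplings:
            for name in c.pair:
                if name not in self.nodes:
                    raise ValueError(f"coupling names unknown node {name!r}")
        if any(c.pair[0] in targets for c in self.couplings):
            raise ValueError("chained couplings (target used as source) "
                             "are not supported")


@dataclass
class Subject:
    node_series: dict[str, NodeSeries]
    hypnogram: Hypnogram


@dataclass
class Cohort:
    subjects: list[Subject]
    ground_truth: dict


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate a reproducible cohort with a known coupling graph.

    Source nodes get independent burst signals; each coupling target is
    derived from its source.  Per-subject and per-node random streams are
    spawned deterministically from ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    subject_seeds = root.spawn(cfg.n_subjects)
    targets = {c.pair[1]: c for c in cfg.couplings}

    subjects: list[Subject] = []
    for ss in subject_seeds:
        streams = ss.spawn(len(cfg.nodes) + 1)
        hyp = generate_hypnogram(
            cfg.duration, cfg.dynamics, np.random.default_rng(streams[0])
        )
        series: dict[str, NodeSeries] = {}
        for i, name in enumerate(cfg.nodes):
            if name in targets:
                continue
            series[name] = generate_burst_signal(
                cfg.duration, cfg.burst_model,
                np.random.default_rng(streams[i + 1]), node_id=name,
            )
        for i, name in enumerate(cfg.nodes):
            if name not in targets:
                continue
            c = targets[name]
            series[name] = derive_coupled_signal(
                series[c.pair[0]], c, hyp, cfg.burst_model,
                np.random.default_rng(streams[i + 1]), node_id=name,
            )
        subjects.append(Subject(node_series=series, hypnogram=hyp))

    truth = {
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "duration": cfg.duration,
        "nodes": list(cfg.nodes),
        "couplings": [
            {"source": c.pair[0], "target": c.pair[1], "delay": c.delay,
             "strength": dict(c.strength), "jitter": c.jitter}
            for c in cfg.couplings
        ],
        "burst_model": asdict(cfg.burst_model),
    }
    return Cohort(subjects=subjects, ground_truth=truth)
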