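# Methods

## The time-delay-stability model of coupling

The package treats two physiologic systems as coupled when bursts of
activation in one signal are consistently followed, at a stable time
delay, by bursts in the other.  The measure deliberately ignores the raw
correlation magnitude: per-segment z-normalization removes amplitude and
trend information, and only the *stability of the delay* across segments
enters the statistic.  This makes %TDS comparable across signals with
completely different dynamics and units (spectral band power, variance,
rates), at the cost of discarding any coupling that expresses itself
purely in amplitude co-modulation without delay stability.

Assumptions worth keeping in mind:

* both series are uniformly sampled at 1 Hz and aligned to the same clock;
* coupling episodes shorter than the minimum detectable span
  (`stab_window x step` = 150 s by default) are invisible by construction;
* the cross-correlation within a segment is circular (periodic boundary
  conditions), so the lag axis is L-periodic and the search range
  `[-L/2, L/2)` covers every distinct lag exactly once.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `L` | 60 | s | segment length; one cross-correlation per segment |
| `step` | 30 | s | segment stride (half-overlap); matches the 30 s scoring-epoch grid |
| `stab_window` | 5 | segments | width of the sliding stability window |
| `stab_min_agree` | 4 | segments | minimum agreeing delays per window |
| `stab_tol` | 1 | s | delay agreement tolerance |
| `win_s` / `overlap_s` | 2 / 1 | s | moving window for band power and variance |

Display thresholds for network maps are 45 %TDS (brain-brain), 5 %TDS
(brain-organ) and 3 %TDS (brain-respiration); strength categories are
very strong >= 80, strong 65-80, intermediate 45-65 %TDS.  All of these
are configuration constants (`RunConfig`, `DISPLAY_THRESHOLDS`,
`LINK_CATEGORIES`), not derived quantities.

## Numerical and rule-level choices

Several points of the procedure admit more than one reading; the package
fixes them as follows.

* **Spectral estimator.**  Band power uses a per-window Hann-tapered
  one-sided DFT periodogram, summed over bins whose centre frequency lies
  in the half-open band `[lo, hi)`.  The per-window mean is removed first,
  so constant offsets cannot masquerade as delta power; consequently the
  seven bands partition the total periodogram power below the Nyquist bin
  exactly.  Bands extending beyond Nyquist are clipped with a recorded
  warning.
* **Variance** is the unbiased (n-1) sample variance.
* **Rate resampling.**  The interval tachogram is resampled by
  sample-and-hold: each 1 s bin takes the inter-event interval spanning
  the bin midpoint, then inverts it.  Bins outside the event span are
  missing.
* **Tie-breaking for tau0.**  The delay maximizing |C| is selected; exact
  ties resolve to the smallest |tau|, and a +-tau tie to the positive lag
  (short physiologic delays preferred).  Ties are measure-zero for real
  data but the rule makes the pipeline fully deterministic.
* **Stability reference.**  The 4-of-5 rule requires the delays to sit in
  an interval `[r - 1, r + 1]` without naming `r`.  The implementation
  tests every integer candidate reference in the window's delay range and
  marks *all* captured segments of any passing window stable, with marks
  accumulating across the sliding windows.  This is the most permissive
  deterministic reading; an outlier delay inside an otherwise stable
  window is never itself marked stable.
* **Invalid segments.**  Segments containing missing samples or with zero
  variance cannot be normalized; they are excluded from both the numerator
  and denominator of %TDS, and any stability window containing one is
  skipped.
* **Stage attribution.**  A 60 s segment spans two scoring epochs; it is
  attributed to a stage only when both epochs agree (and are not
  artifact).  Transition-spanning segments count toward overall %TDS but
  toward no stage, keeping per-stage estimates uncontaminated.  Per-stage
  fractions pool segments across all episodes of a stage in the record.
* **Mean link strength** of a (sub)network averages over *all* candidate
  links, not only those above the display threshold, so link count and
  mean strength remain independent summaries.
* **Exchange symmetry.**  Swapping the two inputs negates the delay series
  (modulo the circular lag range) and leaves %TDS unchanged; the edge lag
  `-L/2` is its own negation.

## The synthetic generator

The generator emulates exactly the feature of real node series that TDS
measures: intermittent bursts whose *timing* is reproduced across signals
at a stable delay.  A source series is white baseline noise (SD 0.1) plus
Poisson-placed Gaussian bursts (4 per minute, 5 s standard width,
log-normal amplitudes with median 1 and log-SD 0.4) — a few multi-second
activation events per analysis segment, as in EEG band power or muscle
tone during sleep.  A coupled target reproduces each source burst with a
stage-dependent probability at a fixed delay (plus optional Gaussian
jitter); unreproduced bursts are replaced by independently placed ones, so
the burst rate itself carries no stage information and only delay
stability distinguishes coupled from uncoupled epochs.  Burst positions
wrap circularly at the record ends.  Hypnograms come from a semi-Markov
chain over 30 s epochs with geometric dwell times (defaults: mean dwells
of 10 / 40 / 20 / 15 epochs for W / LS / DS / REM and transition weights
favouring the W->LS->{DS,REM} cycle), started from the stationary epoch
distribution so the stage process is stationary from the first epoch.

What the generator does *not* emulate: autocorrelated baseline noise,
amplitude co-modulation, non-stationary burst rates, multi-delay or
chained couplings, and any raw-waveform physiology (the generator works at
the 1 Hz node-series level only).  Passing the recovery benchmark
therefore shows that the pipeline recovers burst-timing coupling under
realistic intermittency; it does not certify behaviour under every failure
mode of real polysomnography.

One idealization deserves a note: a delayed *record* is not a delayed
*segment*.  Because analysis windows crop a linearly shifted signal,
bursts near window edges lose their partners, and even a noise-free,
full-strength coupled pair shows a small fraction of mislocated
per-segment delays (measured %TDS typically 0.85-0.95 rather than 1.0).
The exact-recovery limit (%TDS = 1, every delay equal) holds for signals
with delta-like autocorrelation, e.g. a circularly shifted white-noise
record, and is tested in that form.

## Problem sizes used in the shipped checks

The recovery benchmark runs the grid of true delays {2, 5, 10, 20} s by
strengths {0, 0.25, 0.5, 0.75, 1} on hour-long (N = 3600 s) records — 20
seeds per cell in the test suite, 10 in the acceptance script — and the
stage-conditioning check uses 100 (suite) or 50 (script) seeded nights
with coupling confined to light sleep.  These sizes give per-cell binomial
standard errors of a few percent while keeping a full run in the tens of
seconds on one CPU; the measured quantities plateau well below these
sizes.

## Known limitations

* %TDS is symmetric: the package makes no directionality or causality
  claims.
* No surrogate-based significance machinery is built in beyond the
  permutation chance level used in the checks; the 5 % / 3 % brain-organ
  display thresholds are fixed constants, not estimated significance
  levels.
* R-peak and breath detection from raw traces are out of scope; event
  trains are inputs.
* Artifact handling is limited to missing-value propagation.
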