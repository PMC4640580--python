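# tdsnet

Physiologic systems — the brain, heart, lungs, eyes and skeletal muscles —
continuously coordinate their activity, and the pattern of that
coordination changes with physiologic state (wake, REM sleep, light sleep,
deep sleep).  `tdsnet` implements the **Time Delay Stability (TDS)**
measure for quantifying dynamic coupling between such very different
signals, and builds sleep-stage-resolved *physiologic networks*
(brain–brain, brain–organ, organ–organ) from the pairwise couplings.  It
is aimed at researchers analysing polysomnographic recordings (EEG, ECG,
respiration, EOG, EMG plus a scored hypnogram) as well as at method work
on coupling measures, for which a fully synthetic, ground-truth-bearing
benchmark generator is included.

## The measure

All signals are first reduced to a common 1 Hz resolution: EEG channels to
the spectral power of the seven conventional frequency bands
(δ 0–4 Hz, θ 4–8, α 8–12, σ 12–16, β 16–20, γ₁ 20–34, γ₂ 34–100) in moving
2 s windows with 1 s overlap; EOG and EMG to moving-window variance; R-peak
and breath-onset trains to instantaneous heart and respiratory rate in 1 s
bins.

Two series *{a}*, *{b}* of common length *N* are divided into
*N_L = ⌊2N/L⌋ − 1* overlapping segments of length *L* = 60 s (stride
*L*/2 = 30 s).  Each segment is normalized to zero mean and unit standard
deviation, and the cross-correlation

&nbsp;&nbsp;&nbsp;&nbsp;*C<sup>ν</sup><sub>ab</sub>(τ) = (1/L) Σᵢ aᵢ b₍ᵢ₊τ₎*

is evaluated with periodic boundary conditions for every integer lag.  The
per-segment delay τ₀<sup>ν</sup> is the lag maximizing |C(τ)|.  Sliding a
window of five consecutive segments (step one), segments are labelled
**stable** when at least four of the five delays agree within ±1 s of a
common reference.  **%TDS** is the fraction of stable segments — the link
strength of the physiologic network — computed overall and separately per
sleep stage (a segment counts toward a stage only if every 30 s epoch it
covers carries that stage).  The shortest coupling episode the rule can
flag spans 5 × 30 s = 2.5 min.

Networks use 42 brain nodes (6 EEG locations × 7 bands) and 5 organ nodes
(eye, chin, leg, heart, respiration); the 861 brain–brain candidate links
decompose into intra-channel (126), within-hemisphere (2 × 147),
cross-hemisphere horizontal (147) and diagonal (294) subnetworks.  Link
strengths are binned as very strong (≥ 80 %TDS), strong (65–80) and
intermediate (45–65) for display.

## Worked example

Simulate one hour of two coupled bursting node series whose coupling is
strong in wake and light sleep and weak otherwise, then measure it:

```python
from tdsnet import (BurstModel, CouplingSpec, generate_burst_signal,
                    derive_coupled_signal, generate_hypnogram, tds_pair,
                    modal_tau)

model = BurstModel()                       # 4 bursts/min, 5 s bursts
hyp = generate_hypnogram(3600, seed=1)
x = generate_burst_signal(3600, model, seed=2, node_id="heart")
spec = CouplingSpec(("heart", "chin"), delay=5,
                    strength={"W": 1.0, "LS": 1.0, "REM": 0.2, "DS": 0.2})
y = derive_coupled_signal(x, spec, hyp, model, seed=3, node_id="chin")

r = tds_pair(x, y, hypnogram=hyp)
print(f"%TDS overall: {100 * r.pct_overall:.1f}")
print(f"modal delay:  {modal_tau(r)} s")
for s, v in sorted(r.pct_by_stage.items()):
    print(f"  {s:4s} {100 * v:5.1f} %TDS")
```

prints

```
%TDS overall: 82.4
modal delay:  5 s
  DS    28.6 %TDS
  LS    94.6 %TDS
  REM    0.0 %TDS
  W     71.4 %TDS
```

The analysis recovers the true 5 s delay, and the per-stage %TDS ranks the
strongly coupled stages (LS, W) far above the weakly coupled ones (DS,
REM) — the stage-stratification signature the networks are built from.

The same pipeline is available from the shell:

```sh
tdsnet --seed 3 simulate --out sim --duration 1800 --delay 6
tdsnet tds --nodes sim/nodes.tsv --hypnogram sim/hypnogram.txt --out edges.tsv
tdsnet network --edges edges.tsv --out stats.tsv
tdsnet plot --edges edges.tsv --out figures --kind brain-brain
```

`tdsnet features` reduces EDF recordings (plus R-peak / breath-onset event
files) to the 1 Hz node-series table consumed by `tdsnet tds`.

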