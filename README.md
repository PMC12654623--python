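# hybridbci

A two-stage hybrid brain–computer interface (BCI) pipeline that combines a
steady-state visual evoked potential (SSVEP) *activation gate* with
eye-movement-trajectory *command decoding*, plus CORAL covariance alignment
so a decoder trained in a morning session keeps working on evening data.
Because the recordings the protocol was designed around are not publicly
deposited, the package ships a first-class, seeded synthetic two-session
simulator that emulates the acquisition protocol end to end.

It is written for BCI/neurophysiology researchers who want a tested,
reproducible reference implementation of this pipeline family: frontal-site
SSVEP gating, electrooculography (EOG) artefact decoding, and
cross-session domain adaptation.

## The method

**Protocol.** Four frontal EEG channels (Fp1, F7, F8, Fp2) at 256 Hz;
16 s trials with 3 s audio-warning periods at both ends. Five classes:
four visually guided gaze trajectories (left-cross, right-cross,
right–left, up–down) recorded while a 7 Hz LED flickers, and a random-gaze
control class with the LED off. 15 subjects × 2 sessions × 5 classes ×
10 repetitions = 1500 trials. Trials are trimmed to the central 10 s
(2560 samples) and cut into five 3 s windows (768 samples, 448-sample
stride).

**Stage 1 — activation gate.** Each window is band-passed 1–15 Hz
(order-5 Butterworth, forward–backward), its power spectral density is
estimated by Welch's method (640-sample Hamming windows, 639-sample
overlap, 0.4 Hz grid), and band areas are computed with the composite
trapezoid rule. The gate feature per channel is

&nbsp;&nbsp;&nbsp;&nbsp;r = A(6–8 Hz) / A(4–10 Hz) ∈ (0, 1],

which rises toward 1 when the 7 Hz flicker response concentrates power at
the stimulation frequency and sits near 1/3 for a flat spectrum. A binary
classifier on the four ratios decides LED-on vs LED-off per window.

**Stage 2 — trajectory decoding.** Windows passing the gate are
band-passed 0.5–32 Hz (order-4) and summarized per channel by power
(mean square), energy (sum of squares), and the 21 coefficients of a
degree-20 least-squares polynomial on a time axis scaled to [−1, 1] —
4 × 23 = 92 features. Features are z-scored per session, optionally
reduced by a one-way ANOVA F-test (p < 0.05), and classified over the four
trajectory classes by bagged trees (100 trees, depth 15), a random forest
(50 trees), or a one-vs-one SVM tuned by a 30-evaluation randomized
search.

**CORAL adaptation.** With source (morning) and target (evening)
covariances C_s, C_t, training rows are mapped by

&nbsp;&nbsp;&nbsp;&nbsp;x → x · (C_s + λI)^(−1/2) (C_t + λI)^(1/2),&nbsp;&nbsp;λ = 0.1,

i.e. whitened in the source geometry and recolored to the target geometry,
without reading a single target label.

**Evaluation.** Per-class accuracy (= recall), macro precision/recall/F1,
the Wolpaw information transfer rate
B = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1)) scaled to bits/min at a
2.5 s selection time, and an exact Wilcoxon signed-rank test (null
enumerated over all 2ⁿ sign assignments) comparing morning- vs
evening-tested class accuracies.

## Worked example

```bash
cat > demo.yml <<'EOF'
sim:
  n_subjects: 2
  reps_per_class: 10
n_repetitions: 2
EOF
hybridbci run-all --config demo.yml --seed 2 --out out
hybridbci report --out out
```

prints (numbers from this exact invocation):

```
stage-1 99.20% | stage-2 72.23% (coral=True)
       Metric  sub01  sub02   Avg.
   left_cross  33.00  73.47  53.23
  right_cross  72.00  80.61  76.31
   right_left  62.00  74.00  68.00
      up_down  88.00  94.90  91.45
     Acc. (%)  63.75  80.71  72.23
ITR (bit/min)  11.54  23.68  17.61
    Precision  63.36  80.71  72.03
       Recall  63.75  80.74  72.25
   F1-Measure  63.39  80.67  72.03
Wilcoxon signed-rank (morning vs evening): p = 0.125
```

The first line is the LED gate's evening accuracy (99.20%) and the
four-class trajectory accuracy of the morning-trained, CORAL-aligned
decoder on evening data (72.23%). The table breaks the latter down per
subject and class; the ITR row converts each accuracy into bits per
minute at one selection per 2.5 s. The signed-rank p compares the four
class accuracies between morning-tested and evening-tested runs —
p = 0.125 > 0.05 means no significant session difference. Re-running with
`--no-coral` shows the adaptation's value (accuracy drops by several
points on the default, shifted simulator).

The same experiment is available as a library:

```python
from hybridbci import PipelineConfig, SimulationConfig, run_experiment

cfg = PipelineConfig(sim=SimulationConfig(n_subjects=2, seed=2), seed=2)
report = run_experiment(cfg)
print(report["stage2"]["average"]["overall_accuracy"])
```

`hybridbci simulate --out DIR` writes the dataset itself as
self-describing trial CSVs plus a manifest, and `stage1`/`stage2`
subcommands run the stages separately from disk. `configs/default.yml` is
the frozen full-protocol profile.

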