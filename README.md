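# smrdyn

Sensorimotor-rhythm group comparison on motor-imagery EEG: event-related
desynchronization (band power), inter-channel phase locking, and
phase-pattern dynamics (instability index, global phase-synchronization
episodes, clustered episode patterns, discrete hidden Markov models), with
group-level stepwise statistics — all driven by a synthetic two-group EEG
cohort generator so the entire stack runs and is tested without any
recorded data.

## What it does

1. **`smrdyn.simulate`** — synthesizes continuous 10-channel EEG (the nine
   motor-cortex channels FC3…CP4 plus a frontal channel) with controllable
   per-band baseline amplitude, imagery-locked amplitude suppression
   (ERD depth), inter-channel phase coupling (von Mises jitter around a
   shared carrier phase), and Markov template switching that plants
   ground-truth phase-pattern dynamics, on a 1/f noise floor.
2. **`smrdyn.preprocess`** — common average reference, segmentation into
   8-s trials, ±80 µV artifact rejection (strict exceedance, analysis
   channels only), zero-phase Butterworth filtering into alpha (8–13 Hz),
   lower beta (13–16), mid beta (16–20) and upper beta (20–30 Hz).
3. **`smrdyn.features`** — sliding-RMS band power, per-trial baselining
   against the 1.5 s pre-cue window, nine-channel averaging, 2-s segment
   means (0–2, 2–4, 4–6, 6–8 s), and absolute baseline power.
4. **`smrdyn.plv`** — Hilbert instantaneous phase, across-trial PLV time
   courses for all 36 motor-channel pairs (averaged) and the
   frontal-to-M1 pair set, with the same baselining/segmenting.
5. **`smrdyn.phasedyn`** — relative phase against the circular-mean
   reference (FC3, FC4, CP3, CP4), instantaneous instability index,
   median-threshold GPS episode segmentation, circular-mean episode
   patterns, pooled K-means labeling (K = 6).
6. **`smrdyn.markov`** — discrete-emission HMMs (Baum–Welch, seeded
   uniform-random restarts), AIC+BIC state selection, leave-one-out
   group classification with exact binomial significance.
7. **`smrdyn.inference`** — stepwise OLS regressions (enter p < 0.05,
   remove p > 0.10) of every feature cell on group/age/gender/trial
   count, KS normality gating, pooled-variance post-hoc t-tests; all
   p-values reported uncorrected and flagged as such.

## CLI

```sh
smrdyn simulate   --config examples/cohort.toml --out cohort/ --seed 1
smrdyn preprocess --in cohort/ --out trials/
smrdyn features bandpower --in trials/ --out features_bp.tsv
smrdyn features plv       --in trials/ --out features_plv.tsv
smrdyn phasedyn   --in trials/ --band alpha --seed 1 --out phasedyn/
smrdyn stats      --features features_bp.tsv --features features_plv.tsv \
                  --llr phasedyn/classification.json \
                  --participants cohort/participants.tsv --out stats_report.tsv
```

Cohort directories are plain text: one `<id>_signal.tsv` matrix per
participant plus `participants.tsv` and `events.tsv`. See
`examples/cohort.toml` for the simulation config format.

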