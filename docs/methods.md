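# Methods

## Data model

The atomic record is a clickstream: an identifier, an ordered sequence of
events `(action label, timestamp)` with timestamps in seconds from task
onset (t = 0, millisecond-or-better precision as decimals), a binary
outcome (1 = failure, 0 = at-least-partial success; partial credit is
scored as success), and a time on task `t_i`. Timestamps must be
non-decreasing; ties keep file order, because action order feeds the
n-gram features. When a log does not carry `t_i` it defaults to the last
event's timestamp and a warning is logged; real logs usually end with a
proceed-to-next event, so the difference is small, but the two notions are
kept distinct in the data model.

Preprocessing is configuration, not code: a recode map collapses raw
labels into aggregate categories (with an explicit map, unmapped labels
are an error; recode targets pass through unchanged, which makes
preprocessing idempotent), drop rules remove score-revealing and
submission actions, an initial "Start" token, and a terminal
proceed/confirm bigram (removed only when it is the final pair, exactly
once). Streams left with zero events are excluded.

## Early windows

Inclusion is strict in both modes (`a_i > w^a`, `t_i > w^t`); event
retention in time mode uses the closed boundary `t ≤ w^t`, mirroring the
strict actions-mode rule on the other side. A retained time-mode stream
may have zero events left; it stays in the subset (the absence of actions
is itself informative) and its features degrade gracefully: all tf-idf
weights 0, all timing features missing, activity 0. Earliness is always
computed from the untrimmed `a_i` and `t_i`. Earliness quantiles
(median, middle-50% range) use numpy's default linear-interpolation
quantile convention.

Utility divides the failures surviving inclusion by the failures in the
full collection; it is 1 at window 0 by construction and non-increasing in
the window size. Base rate is reported as the proportion *correct*, so
base rate + failure rate = 1.

## Features

Natural logarithms in the tf-idf weight are forced by the worked example
the package reproduces ((1 + ln 3)·ln(500/300) = 1.07). The scope over
which `df`, `N`, the action vocabulary and the n-gram vocabulary are
computed is a deliberate dial:

- `idf_scope="subset"` (default) computes them over the whole early-window
  dataset. This is the straightforward reading of "number of sequences in
  the early-window data set", but it lets validation rows influence
  training features.
- `idf_scope="train"` refits the statistics inside every CV training
  partition and transforms held-out rows with training statistics only.
  The nested-CV driver then rebuilds features per fold; an audit test
  verifies held-out predictions are reproducible from training statistics
  alone.

Both conventions are exposed because the leakage-free variant is the
methodologically safer default for new studies while the subset variant
matches the descriptive convention of computing tf-idf over a whole
early-window dataset. N-grams unseen in the scope are dropped rather than materialized as zero columns, bounding
dimensionality; n-gram indicators are presence-only (no counts), and
unigram one-hots are intentionally absent (tf-idf and time-to-first
columns already carry occurrence information). Missing values are NaN
end-to-end — never sentinel numbers — and survive CSV serialization as
empty cells.

## Classifier and cross-validation

The learner is XGBoost (`binary:logistic`, `tree_method="hist"`, single
thread, fixed seed) because its sparsity-aware split finding consumes the
informative missingness directly. The hyperparameter grid is
trees {50, 100, 150} × depth {3, 6, 9} × learning rate {0.01, 0.10};
nested cross-validation uses 5 outer and 3 inner folds. Decisions taken
where the procedure was genuinely open, all configurable:

- inner-loop selection criterion: mean validation AUC (matching the
  headline metric), ties broken toward the simpler model (fewer trees,
  then smaller depth, then smaller learning rate);
- folds stratified by outcome by default, preventing single-class folds in
  imbalanced windows;
- minority upsampling (exact replicas drawn with replacement until counts
  match) applied *after* splitting, inside each training partition of both
  loops, so replicas never straddle a fold boundary;
- one master seed drives fold assignment, upsampling draws and tree
  training through documented sub-seeds, so a run is reproducible from a
  single integer.

## Evaluation

Failure is the positive class. A row is classified as failure when its
predicted failure probability strictly exceeds .50, so exactly .50 is
success. Zero-denominator rates are reported as missing with a warning; φ
with any zero marginal is set to 0 (the value of the Pearson correlation
limit convention, keeping reports total). AUC is the Mann–Whitney rank
form with midranks for ties. Gain importances are normalized per fold
before averaging, making the 0.05 reporting filter scale-free across
folds; the normalization is an explicit choice and can be read off the
importance table (per-fold importances sum to 1).

## Synthetic generator

The generator emulates the statistical shape of problem-solving log data,
not any real log: 28 aggregate action categories (aggregated repertoires
of such tasks typically span 25–35); class-conditional first-order Markov
chains over them;
negative-binomial sequence lengths; log-normal inter-event and initial
latencies; a dropout fraction of near-empty (1–3 actions, short duration)
forced-failure streams emulating early task abandonment. Three signal
dials (repertoire tilt in log-odds, latency log-location shift, log mean
length ratio) span the presets:

- `null`: all dials zero, dropout zero — both class generators are
  identical objects, so downstream AUC sits at chance;
- `paper-like`: length ratio 33/14 with higher failure dispersion (group
  length medians land near 11 vs. 30–32, group time medians near 80 vs.
  155 s — the class-conditional shape the generator targets), repertoire tilt 0.7,
  timing shift 0.25, dropout 0.15, failure rate 0.35;
- `separable`: strong dials (tilt 2.5, shift 0.6, ratio 33/10) so
  full-sequence classification is near-perfect.

First-order chains are the simplest process consistent with the n-gram
feature rationale; latencies are log-normal because the emulated data show
right-skewed positive times with no stated distributional form. What the
generator does *not* emulate: task-specific action semantics and
goal-directed pathway structure, higher-order sequential dependencies,
latency–action coupling, and population heterogeneity beyond the two
outcome classes. Passing tests therefore demonstrate that the pipeline
recovers signal of the injected kinds and stays at chance without signal —
not that any particular real task is predictable.

## Problem sizes and numerical choices

The heavier end-to-end checks run at deliberately modest sizes chosen to
exercise the contracts: chance-level recovery on the null preset at
n = 2000 (mean out-of-fold AUC within ±0.05 of 0.5 at that Monte-Carlo
resolution), near-perfect separation on the separable preset at n = 600,
cross-validation hygiene audits at n = 200, and a two-point hyperparameter
grid where the full 18-point grid would add nothing to the property under
test. The default full grid is used when the package is run as a tool.

Known limitations: no cost-sensitive learning, no adaptive per-examinee
stopping rules, no learned sequence embeddings, and no alternative
classifiers — the pipeline is a fixed-window, fixed-feature design by
scope. Duplicate window specs are allowed (with a warning) and produce
duplicate datasets; empty subsets raise immediately, naming the window.
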