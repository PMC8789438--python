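# Methods

## Problem setting

Three observers watch the same stream of short aerial-surveillance video
clips (4–10 s, preceded by a 2 s fixation cross) and silently detect
vehicles. A vehicle may enter the frame at any moment from 1 s after clip
onset, so the elicited P300 — the positive ERP deflection that marks
detection of a task-relevant target — jitters in latency from trial to
trial. EEG is recorded from 16 electrodes (10–20 layout) per subject,
time-synchronized across the group. The task is single-trial, *unsupervised*
detection: the observed group contributes no labels; all labels come from a
separate pool of previously recorded single-observer sessions.

## Pipeline

1. **Preprocessing.** Signals are band-passed 0.1–10 Hz with a zero-phase
   4th-order Butterworth (forward–backward, so P3 latency is not shifted),
   downsampled 600 → 100 Hz, and cut into 1500 ms trials: one trial per
   target video starting at the marked target onset, and non-overlapping
   1500 ms tiles of each nontarget video from video onset (partial tails
   discarded). Trials whose absolute amplitude exceeds 120 μV on any channel
   are flagged invalid (inclusive threshold: a peak of exactly 120 μV is
   valid); nothing is removed, so trial indices stay aligned across the
   group.

2. **ERP alignment.** A single CSP spatial filter `w` maximizing the
   target/nontarget variance ratio (generalized eigenproblem
   `C_t w = λ (C_t + C_n) w`, shrinkage `1e-6·trace/16`, unit norm, sign
   fixed so the mean projected target trial peaks positive) projects trials
   to one dimension. Projected target trials are averaged and cropped to
   the 1000 ms (100-sample) window of maximal energy — the target ERP
   template. Each 1500 ms trial is then aligned by sliding a 100-sample
   window over its projection (51 offsets) and keeping the offset with
   maximal Pearson correlation against the template, ties to the smallest
   offset; degenerate (zero-variance) windows score below any real
   correlation so flat trials default to offset 0. Output trials are
   16 × 100.

3. **Source selection.** Each pool subject's valid aligned target trials are
   averaged; the topography at the first maximum of the template-filter
   projection is that subject's P3 map. K-means (k = 2, 10 seeded restarts,
   raw 16-vectors) splits the pool into strong- and weak-P3 groups — the
   cluster with the larger mean centroid amplitude over the
   parietal/parieto-occipital/occipital channels is "strong" — and the
   strong group's pooled labeled trials form the source domain. For
   source-size sweeps, subjects are totally ordered by mean posterior
   topography amplitude, ties broken by subject id.

4. **Network unit.** One unit per observed subject: a compact convolutional
   ERP decoder written directly in numpy with hand-derived backpropagation —
   per-trial z-scored input, temporal convolution (8 kernels of length 25),
   spatial convolution collapsing the 16 channels (8 filters), ELU, average
   pooling (width 8), dense 64-unit embedding; two heads of identical shape
   (hidden 32, 2-way softmax): a category classifier and a domain
   discriminator coupled to the extractor through gradient reversal
   (constant coefficient 1). Losses are summed (not averaged)
   cross-entropies with a 1e-12 probability clamp; Adam (lr 3e-4) optimizes

       Σₙ α·L_adv + γ·L_class_src + β·L_class_tgt

   with α = 0.4 (0.2 when mutual learning is off), γ = 0.8, β = 0.2,
   batch size 40.

5. **Mutual learning.** The N units train on a shared class-balanced source
   batch plus per-subject target batches drawn at identical stimulus trial
   indices. Each iteration, the units' target-class probabilities are
   weighted-averaged (default weights (1,1,1)) and binarized at 0.5 (ties →
   target); this single pseudo-label vector is the target-category label for
   *every* unit. Pseudo-labels are constants in the backward pass (no
   gradient flows through the fusion).

6. **Evaluation.** All valid trials common to the group are predicted in
   evaluation mode; fused labels come from the same weighted-average-and-
   binarize rule. Metrics: accuracy, hit rate (target recall), false-alarm
   rate, and F1 over the target class (F1 = 0 when there are no true
   positives), with half-up rounding to 2 decimals for reported tables.

## Frameworks

* `sbci` — one subject, one unit, β = 0.
* `sc-cbci` — the group's aligned trials are averaged sample-wise into one
  pseudo-subject (validity = AND of members) and classified by a single
  unit. Averaging happens *after* alignment: subjects' P3 latencies differ,
  and averaging unaligned trials would smear the component.
* `mc-cbci` — N units trained independently (β = 0), probabilities fused
  only at evaluation.
* `mldanet` — decision fusion plus the pseudo-label feedback during
  training (β = 0.2).

With β = 0 the group trainer literally dispatches to independent
single-unit training, so the baselines are exact degenerations of the same
code path, and all four frameworks consume identical preprocessed inputs.

## Training schedule

Two choices here were genuinely open and matter in practice:

* **Class-balanced source batches** (default on). The trial stream is ~1:4.6
  target:nontarget. With uniform batches the classifier calibrates its
  target-class probability far below 0.5, the binarized fused pseudo-labels
  become strictly more conservative than the individual decisions, and the
  feedback loop ratchets the hit rate toward zero. Drawing half of each
  source batch from each class keeps the operating point near the hit
  0.6–0.8 / false-alarm 0.05–0.2 regime the method is designed for.
* **Warm-up — half the epochs, capped at 20** — with β = 0 before the
  target-domain selection is computed (once, then frozen) and the
  pseudo-label term engages. Engaging earlier feeds back labels from
  still-unconverged units and degrades the individuals instead of lifting
  them; the cap exists because units stabilize in a roughly fixed number of
  epochs, so long runs should not postpone the coupled phase
  proportionally.

Target-domain selection keeps the top 80 % of valid trials ranked by
predicted target probability — group-averaged over the units in the mutual
setting (one shared index set keeps batches synchronized), per-unit
otherwise — ties broken by stimulus index, so selection is invariant to
trial order.

For convergence monitoring, the per-epoch mini-batch loss average is noisy
at small problem sizes (few iterations per epoch), so an optional
deterministic end-of-epoch loss over the full source and target pools can
be recorded (`track_epoch_loss`). A plateau is declared at the first epoch
from which the trend — the relative difference between half-window means
over a 20-epoch window — stays below 1 %; requiring persistence prevents a
transient rise–fall crossing from masquerading as convergence.

## Synthetic data

The simulator generates what the pipeline assumes and nothing more: a
shared event stream (shuffled target/nontarget videos with uniform lengths,
target onset uniform in [1 s, length − 1.5 s]); per-subject signals of pink
(1/f) noise plus a low-amplitude 10 Hz oscillation; a P300 modeled as a
positive half-cosine bump (300 ms wide) times a fixed posterior-dominant
topography (peak channel Pz), scaled per subject, with peak latency uniform
0.3–0.7 s after target onset; and amplitude artifacts as ±150 μV step
offsets injected into a configured fraction of future trials on a random
channel. All randomness derives from one seed through spawned generators;
output is bit-reproducible.

What it does **not** emulate: ocular/muscle artifacts with realistic
morphology, volume conduction (channel correlations beyond the planted
topography), non-stationary background rhythms, subject-specific waveform
shape or latency distributions, and habituation across blocks. Passing
tests therefore demonstrate that the machinery is correct and that the
mutual-learning mechanism behaves as described *under the stated signal
model* — not that the absolute published performance transfers to real
recordings.

Benchmark conditions (used by the test suite and the acceptance script) are
scaled to a single desktop CPU: 40 target + 40 nontarget videos per session
(~225 trials, preserving the ~1:4.6 imbalance), a source pool of 4 strong +
2 weak subjects, 30 training epochs. The "medium" group has heterogeneous
P3 amplitudes (10, 7, 4 μV) against 6 μV noise with 5 % artifact trials —
one clearly weak responder, which is where mutual learning should help; the
"easy" variant (homogeneous 10 μV, 3 μV noise) is a near-separable sanity
condition.

## Numerical and degenerate-input choices

* Covariance shrinkage `1e-6·trace/16` before the CSP eigensolve; a pool
  still rank-deficient after shrinkage is an error.
* Identical class covariances: the eigensolve's deterministic ordering
  (eigenvalue, then index) picks a reproducible, arbitrary filter.
* ε = 1e-12 clamp inside every log-probability.
* Binarization threshold 0.5 with ties to the target class.
* `metrics_from_rates` reconstructs counts by half-up rounding of
  rate × class count.
* Epoching is 0-based with half-open sample windows; a trial extending past
  the recording raises rather than pads.

## Known limitations

* No ICA-based EOG removal is implemented; the hook is an identity
  transform with a warning.
* EDF is read (via mne, when importable) but not written; the native
  interchange format is the HDF5 container + TSV sidecar (docs/FORMATS.md).
* The network architecture is a small stand-in in the EEGNet family sized
  for 16 × 100 inputs; no pretrained weights, no architecture search.
* Fusion weights are fixed, not learned; majority voting and trained-weight
  fusion are out of scope.
* The mutual-learning uplift on the synthetic benchmark is directional and
  modest (a few F1 points per unit); its magnitude depends on how
  heterogeneous the group is.
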