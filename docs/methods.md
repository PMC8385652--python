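# Methods

## Measurement model and data layout

A frame under the adjacency protocol on an *N*-electrode ring holds
*N*(*N* − 3) scalar amplitude measurements with cycle structure: cycle *i*
fixes the injection pair (*i*, *i*+1 mod *N*) and reads the *N* − 3 adjacent
measurement pairs that do not touch it, walking the ring in increasing order
from *i*+2. Electrode and cycle indices are 0-based; iterations are numbered
from 1. The square "image" view places cycle *i* in row *i*, left-aligned;
the 3*N* cells with no measurement are zero-filled (not NaN) so the view
feeds zero-padded convolutions without a masking branch. The compact
(208-value) vector is the ground-truth representation; the padded
(*N*²-value) layout is accepted on input and flagged, since archived data
appears in both conventions.

The canonical on-disk format is a plain CSV with a `# n_electrodes=N`
declaration line, chosen for diff-ability and toolchain neutrality. The
writer emits 17 significant digits and the reader parses with round-trip
float precision, so write-then-read is bit-exact for finite values.

## Calibration

All three calibrations are built from one reference: the mean of the
neutral-gesture (label 6) frames within a scope. Global calibration
subtracts the session's iteration-1 reference from every frame of the
session; local calibration subtracts each iteration's own reference;
learned calibration performs no subtraction and instead pairs each frame
with its iteration-local reference as a second network input. The underlying
assumption is that placement offsets and warm-up drift are *additive and
common to all gestures* within the reference's scope — exactly the regime in
which subtracting the neutral reference cancels them. Multiplicative
effects (per-electrode gain) survive subtraction; this is a known limit of
reference-based calibration, and the simulator includes a gain term
precisely so tests do not overstate what calibration achieves.

A missing neutral reference is a hard error, never a silent fallback:
calibration correctness is the core of the method, and the error names the
offending iteration.

The pipeline order is fixed: min-max normalization to [0, 1] first (fitted
on the training split only, test values clipped), then calibration.
Calibrated values are signed and are not re-scaled, which keeps magnitudes
comparable across sessions. The two operations do not commute; the suite
asserts the non-commutativity so the order is load-bearing, not cosmetic.

## Synthetic session generator

The generator is statistical, not physical — no forward conductivity model
of the forearm. A frame of gesture *c* in iteration *t* of session *s* is

    v = g_s ⊙ rotate(μ_c + o_s + A(1 − e^{−t/τ}) u_s + ε, k_s),  clipped ≥ 0

| parameter | meaning | default |
|---|---|---|
| `baseline_level` | common amplitude level (device units) | 5.0 |
| `class_separation` | length of each prototype's class-specific component | 0.8 |
| `sigma_session` | per-measurement std of the additive session offset `o_s` | 1.0 |
| `gain_spread` | std of per-electrode log-gain; gain applies per cycle row | 0.05 |
| `rotation_prob` | probability of a discrete band rotation `k_s` per session | 0.0 |
| `drift_amplitude` (A) | asymptotic drift displacement | 4.5 |
| `drift_tau` (τ) | drift time constant, in iterations | 0.8 |
| `drift_class_overlap` | fraction of drift energy inside the class span | 0.7 |
| `sigma_noise` | i.i.d. frame noise std | 0.05 |

Defaults realize the study-scale regime: 1 subject, 8 sessions × 6
iterations × 12 gestures × 10 frames = 5,760 frames, within-session
classification near-perfect while raw cross-session accuracy collapses, and
local calibration recovering more of the gap than global. They were
calibrated once against a nearest-centroid oracle and then frozen; the
oracle (not the trained networks) defined the targets, so the networks'
results are genuinely out-of-sample with respect to this tuning.

Two modelling choices deserve justification:

- **Saturating-exponential drift.** The within-session drift converges —
  consistent with electrode warm-up toward an operating temperature — but no
  functional form is established; `A(1 − e^{−t/τ})` is the simplest
  converging form with a controllable early step, and `A = 0` switches it
  off for degenerate-case tests.
- **Drift direction partially inside the class subspace.** In 208
  dimensions an isotropic random direction is nearly orthogonal to the
  11-dimensional span of the class prototypes, so purely isotropic drift
  barely perturbs any classifier — an artifact of dimensionality, not a
  property of real drift, which alters the same contact impedances that
  carry gesture information. `drift_class_overlap` places 70% of the drift
  direction's energy inside the centered prototype span, restoring the
  empirically observed phenomenon that drift actually degrades
  next-iteration generalization.

Band rotation defaults to off because the emulated acquisition protocol
deliberately re-placed the device at the same position; the rotation path
shares its implementation with the circular-shift augmentation, so one
definition serves both.

What the generator does *not* emulate: gesture-specific drift interactions,
electrode-local artifacts (hair, salt spots) beyond the stationary gain
term, cross-subject physiology differences beyond independent session
draws, and any spatial correlation structure the forearm anatomy would
impose. Passing tests therefore certify the pipeline's behavior under the
stated variance model, not classifier performance on real recordings.

## Networks and training

The classifiers are built on a small numpy engine (dense and 3×3 dilated
convolutions with same-size zero padding, batch normalization, ReLU,
inverted dropout, feature concatenation, softmax cross-entropy, Adam),
gradient-checked numerically in the suite. Conv blocks follow the
convolution → batch norm → ReLU (→ dropout) pattern.

The dual-input CNN template is read as: per branch, `num_convs` conv blocks
with `filters_1`/`dropout_1` (for early fusion, one such stage on the
channel-stacked input); after fusion by channel concatenation, one conv
block with `filters_2`/`dropout_2`; then flatten and the 12-way softmax
layer. `dilation_rate` applies to every block of the template. The grid's
variants all use `filters_1 = filters_2` and `dropout_1 = dropout_2`, so the
interpretation risk is confined to block placement, which is isolated in
one builder function. Late-fusion branches are structurally identical but
independently initialized and trained — no weight sharing.

Unstated hyperparameters default to learning rate 1e-3, batch size 32, 100
epochs, all overridable per run. The headline metric is the maximum
test-set accuracy over epochs; it is optimistically biased (the test set
selects the epoch), but it is retained as the field's comparison metric.

One numerical caveat: with inputs normalized to [0, 1] the class signal
rides on a large common-mode component, and small training sets fit slowly
at the standard learning rate. Single-iteration training runs (120 frames,
the drift experiment) therefore train full-batch for several hundred
epochs, and single-session runs use a longer schedule than the pooled
cross-session runs. These are problem sizes chosen for the bundled
experiments (`eitgest.experiments`); they are arguments, not constants.

## Evaluation and statistics

Within-session stratification splits 75/25 per class at frame level;
leave-one-iteration/session/subject-out regimes hold out whole units, with
disjointness asserted by frame key on every split. Cross-session evaluation
pools all remaining sessions of the subject for training (one fold per
held-out session); a class missing from training produces a recorded
warning, not a rebalancing. The drift experiment trains on iteration *t*
alone and tests on *t* + 1, labels the transition by the evaluated
iteration, and aggregates across sessions with 95% t-intervals; sessions
contribute only the transitions they contain.

Model/condition comparisons use a one-way ANOVA gate at α = 0.05; only when
it fires are pairwise t-tests run, Holm-Bonferroni corrected. The t-tests
default to the classical pooled-variance Student form (matching the
procedure's name), with Welch behind a flag. Effect size is Cohen's *d*
with pooled standard deviation. Accuracy samples are treated as independent
across seeds; dependence induced by shared folds is acknowledged and not
modelled — a Monte-Carlo check in the suite bounds the family-wise error of
the full gated procedure under a global null at 10,000 reps.

## Diagnostics

t-SNE uses the scikit-learn implementation with the conventional settings
(seed 42, 5,000 optimization steps; perplexity 90 for the session view, 100
for the iteration view); determinism is pinned within one library version
only. Visual claims are operationalized as statistics: session clustering
as the silhouette score of session labels in the embedding, drift as the
rank correlation between iteration number and the position of iteration
centroids along their first-to-last direction, and calibration effect as
per-component PCA variance reduction `100(1 − var_cal/var_raw)` — reported
as computed, component by component, with each dataset PCA'd in its own
basis.

## Known limitations

- The numpy engine is CPU-only and single-threaded beyond BLAS; the large
  dual-CNN variants train slowly at full study scale.
- Reference-based calibration assumes additive, gesture-independent
  disturbance within the reference scope; multiplicative or gesture-coupled
  effects are only partially corrected (by design, also in the simulator).
- The loader plugin interface for deposited archives ships without a
  concrete archive loader; writing one requires the archive's actual
  on-disk layout.
- Session-global reference pairing for dual-input models is exposed but
  experimental: with drifting data it is known to yield near-chance
  classifiers, and the iteration-local scope is the supported default.
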