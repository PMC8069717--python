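# Methods

## Problem setting

Binary classification of mental state (pre-fatigue vs fatigue) from
multichannel resting EEG, with two goals beyond raw accuracy: reduce the
electrode montage to a common subset usable for all subjects, and fuse
heterogeneous per-channel features into a compact representation. The
classification unit is a fixed-length epoch; evaluation is within-subject
(train and test epochs come from the same subject's two recordings).

## Epoching and features

Recordings are cut into non-overlapping 1-s windows by default (epoch
length and overlap are configurable; a trailing partial window is
dropped, and no window ever spans two recordings). Five features are
extracted per channel and epoch:

* **Log band power**, four bands: delta 0.5–4 Hz, theta 4–8, alpha 8–12,
  beta 12–30. Welch PSD with a Hamming window, segment length
  min(epoch, 1 s of samples), 50% overlap, linear detrending; the PSD is
  integrated over the closed band interval by the trapezoid rule (adjacent
  bands share each edge bin at half weight, so nothing is double-counted),
  then log10-transformed with a 1e-12 floor. The log stabilizes the
  heavy-tailed power scale ahead of ReliefF's range normalization; the
  floor keeps a constant epoch finite.
* **Sample entropy**, embedding m = 2, tolerance r = 0.2 × epoch standard
  deviation, Chebyshev distance, self-matches excluded. The same n−m
  template start points are used at lengths m and m+1, so a constant
  series yields exactly 0. When no (m+1)-length template pair matches the
  estimate would be infinite; the finite surrogate −ln(1/(B+1)) is
  returned (and logged) so downstream matrices stay finite. Specifying r
  relative to the sd makes the estimate invariant under affine maps of
  the signal.

Columns are ordered channel-major with a fixed within-channel feature
order (beta, alpha, theta, delta power, sample entropy); 16 channels × 5
features = 80 columns.

## Relief and ReliefF

Relief weights a feature by how strongly it separates each sample from its
nearest same-class neighbor (hit) versus nearest other-class neighbor
(miss); ReliefF averages over k hits and, for each other class, k misses
weighted by that class's prior relative to the complement of the sample's
class. Per-feature differences are range-normalized to [0, 1]; a
zero-range feature contributes 0.

Choices the algorithm family leaves open, fixed here: the neighbor search
uses Manhattan distance on range-normalized features (consistent with the
per-feature diff); distance ties break to the lowest sample index; the
default "sampling" is one deterministic full pass over all samples
(seeded random subsampling is available); k defaults to 10 clipped to
(smallest class size − 1), while an explicitly requested k that a class
cannot honor is an error; feature ranges come from the data the weights
are fit on. Channel weights are the per-channel means of the feature
weights, defined only when every channel carries the same feature set.

## Common-channel selection

Per subject, ReliefF runs once on that subject's full 80-column table.
Single-channel accuracies Acc(C_l F_i S_j) are SRDA accuracies of each
1-D column under seeded stratified 5-fold cross-validation (a single
75/25 split of a 1-D feature is too noisy). Two aggregation schemes:

* **Weight addition**: per-subject channel weights are min-max normalized
  across channels (keeping each subject's contribution in [0, 1];
  sum-to-one normalization is available), then summed over subjects. A
  subject with all-equal channel weights contributes a constant 0.5
  vector, with a warning.
* **Accuracy weighting**: Σ_j Σ_i W(C_l F_i S_j)·Acc(C_l F_i S_j), the
  exact double sum of weight × accuracy products, without normalization.

Channels are ranked descending (ties keep original montage order) and the
top half kept. In the pipeline the selection is recomputed on the training
epochs of each split by default; a global mode selects once on all epochs,
matching the fixed-montage protocol a deployed system would use, at the
cost of a small optimistic bias.

## Sparse fusion (K-SVD + OMP)

Feature vectors are z-scored with training statistics (band powers and
entropy are not otherwise commensurable), then coded over an
undercomplete dictionary D (80 × 20) learned on the training epochs.

* **OMP**: greedy selection of the atom most correlated with the residual
  (ties to the lowest atom index), least-squares re-fit on the support
  after each selection (solved via the support's normal equations, with an
  lstsq fallback for degenerate supports), stop at T0 atoms or at a
  residual tolerance. A zero vector codes to the empty support.
* **K-SVD**: alternate OMP coding of all training signals with
  column-by-column atom updates. Each update takes the best rank-1
  approximation (leading SVD pair) of the residual restricted to the
  signals using that atom — optimal by Eckart–Young; the SVD sign
  ambiguity is fixed by making the atom's largest-magnitude entry
  positive. The coding stage keeps a column's previous code when the new
  one reconstructs worse, so the objective is monotone within an
  alternation. Atoms that are unused, used by fewer than 4 signals, or
  nearly collinear with another atom (|corr| > 0.95) are replaced by the
  worst-reconstructed training signal; when an iteration improves the
  relative error by less than 1e-4 the least-used atom is also replaced —
  a deliberate perturbation, since plain alternation reliably stalls in
  local minima (on planted 3-sparse data it plateaus at 0.12–0.21
  relative error, versus < 0.05 with the escape). Learning stops at
  max_iters (50 by default; recovery experiments use 150), at numerical
  exactness, or after 10 consecutive stalled iterations; the best iterate
  seen is returned. `training_error_trace` records the retained
  (best-so-far) model's error per iteration and is therefore
  non-increasing; raw per-iteration errors and atom replacements are kept
  alongside for diagnostics.
* **Defaults**: M = 20 atoms (the fused dimension), T0 = 8. The sparsity
  level was calibrated on development cohorts (seeds disjoint from the
  benchmark seeds): T0 = 5 loses roughly 1.5 accuracy points on the
  synthetic cohort, T0 = 8 is competitive with the PCA baseline while
  remaining a genuinely sparse code (40% of the atoms).

Baselines: concatenation (the standardized 80-dim features; constant
training columns dropped with a warning) and PCA to 20 components fit on
the standardized training features.

## SRDA

The LDA graph embedding is solved by regression: for c classes, c−1
class-indicator target vectors orthogonalized against the constant vector;
each solved by ridge regression on centered features (penalty 0.01 by
default — a weak regularizer whose main job is rank-deficiency safety; the
reported accuracies are insensitive to it over several orders of
magnitude). In the binary case this reduces to one regression on a
centered ±1 indicator. Prediction is nearest class centroid in the
projected space, ties to the lower label — exact for balanced classes and
robust otherwise.

## Evaluation protocol

Per subject, either five repeated seeded stratified 75/25 train/test
splits (default) or stratified 5-fold cross-validation. Accuracy,
precision and F1 (positive class = fatigue) are reported as mean ± sd per
subject. Channel selection, dictionary learning, standardization and the
classifier are fit strictly on training epochs. `compare_fusions` runs the
three fusion methods on byte-identical split plans so their accuracies are
paired.

## Synthetic cohort

Each channel is a sum of band-limited Gaussian processes — white noise
filtered by 501-tap Hamming FIR band-pass filters per canonical band
(continuous, realistic spectra for Welch-based features, unlike sums of
sinusoids) — plus 1/f-amplitude pink noise smoothed by an AR(1) recursion.
Defaults emulate the targeted study design: 8 subjects, 16 channels,
500 Hz, 120 s per state, 6 informative channels.

In the fatigue state, informative channels scale their band variances
(alpha ×1.8, theta ×1.5, beta ×0.6 — the classic drowsiness spectrum) and
raise the AR(1) coefficient of the broadband noise from 0.3 to 0.4, which
lowers sample entropy at constant variance (the pink component is
renormalized per block). Non-informative channels are drawn identically in
both states. Effect sizes get per-subject multiplicative jitter (sd 0.1).

Two non-stationarity terms apply to all channels in both states: a
log-normal band-power envelope (log-sd 0.2) and AR-coefficient drift
(sd 0.12), each redrawn every 2 s. Without them every epoch carries an
identical state effect and single features classify at ceiling (sample
entropy alone reaches accuracy 1.0 for every subject), which no real
cohort shows; with them, single-feature accuracies fall in the 0.35–0.95
range reported for comparable real cohorts, and the multi-feature fusion
question becomes non-trivial. The envelope has equal mean power in both
states, so configured band-power ratios are preserved in expectation
(the default cohort's measured informative-channel alpha ratio is ≈1.8).

What the generator does **not** model: volume conduction and inter-channel
correlation, eye-blink/EMG artifacts, line noise, electrode drift, and
gradual (rather than stationary-per-recording) fatigue onset. Passing
benchmarks on this cohort therefore demonstrates correctness and the
relative behavior of the pipeline's stages under known ground truth — not
performance on real recordings.

## Benchmark problem sizes

The multi-seed benchmark (`eegfatigue.benchmark.cohort_benchmark`) uses
one 75/25 split per subject per cohort and computes channel selection once
per cohort on all epochs; the acceptance script summarizes 5 cohorts and
the test suite 10. ReliefF ranking recovery uses 200-sample, 20-column
toy tables; K-SVD planted recovery uses 200 signals, 3-sparse over a
40 × 20 dictionary, with max_iters = 150.

## What the synthetic benchmarks show — and a negative result

On ten seeded default cohorts, the accuracy-weighted scheme places all six
planted channels in its top eight on every seed; halving the montage
changes sparse-fused accuracy by under half a point (median); sparse
fusion beats the best single feature (median +3.3 points) and beats
concatenation on every seed. One comparison goes the other way: PCA
fusion to the same 20 dimensions edges sparse fusion by ~1–2 points on
most seeds. That is expected here: the cohort is by construction a sum of
band-limited Gaussian processes, so the feature table is approximately
Gaussian with the class effect in high-variance directions — exactly the
regime where PCA is a near-optimal linear compressor, while OMP coding
adds approximation noise. Any advantage of sparse fusion over PCA on real
recordings would have to come from non-Gaussian feature structure this
generator deliberately does not model.

## Known limitations

* The within-subject protocol measures state separation, not
  subject-independent generalization; a cross-subject split would need a
  different evaluation design.
* EDF support targets the common case (equal sampling rates, 16-bit); the
  bundled writer is minimal (no EDF+ annotations) and quantizes to the
  per-channel physical range.
* Relief/ReliefF are O(n²·a) per subject via a dense distance matrix —
  fine for thousands of epochs, not for hundreds of thousands.
* K-SVD with the stall-escape is robust but not deterministic across
  BLAS implementations at the last-bit level (SVD); all tests use
  tolerances accordingly.
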