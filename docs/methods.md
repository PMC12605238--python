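# Methods

## Problem and pipeline

Motor-imagery (MI) brain–computer interfaces work markedly better when a
subject trains with the imagined action they can modulate best, but finding
that action by exhaustive MI experiments is slow. `cogmi` implements a
prediction pipeline that infers each subject's best ("strong") action from
short *cognitive-task* EEG instead:

1. **Ground truth from MI data.** For each of the three candidate actions,
   80 MI trials (40 left / 40 right hand, 12 sensorimotor channels, 6 s at
   1 kHz, 8–30 Hz band-pass) are decoded left-vs-right with two pairs of
   common-spatial-pattern (CSP) filters and a 4-100-50-10-2 feed-forward
   network under stratified ten-fold cross-validation (72 train / 8 test
   per fold). The action with the highest mean decoding accuracy (MI-ACC)
   is the subject's strong action; ties resolve to the lowest index with a
   logged warning.
2. **Multi-domain brain networks from cognitive data.** Each cognitive
   trial (19 channels, 1.2 s at 1 kHz; 0.5–20 Hz third-order Butterworth,
   0.2 s baseline subtraction, cropped to the final 1 s) yields three
   graphs on the 19 electrodes:
   * *time*: 40-point block-averaged time courses (25-sample means) as node
     features; absolute Pearson correlation (PCC) as edges;
   * *frequency*: mean Welch band power in 1–4 / 4–8 / 8–13 / 13–20 Hz as
     node features; phase-locking value (PLV) from analytic-signal phases,
     averaged over the four bands, as edges;
   * *spatial*: log normalized variance of CSP-projected components (CSP
     fitted on strong-vs-weak cognitive trials of *training* subjects only)
     as node features; min–max-normalized Manhattan distance converted to
     similarity (1 − distance) as edges.
3. **Classification.** A three-branch spectral graph convolutional network
   (two first-order Chebyshev layers per branch, 32 → 16 units, ReLU,
   dropout 0.5, mean pooling over nodes; concatenation → batch
   standardization → dense → softmax) labels each trial strong/weak. The
   propagation operator is the renormalized D̃^(−1/2)(A+I)D̃^(−1/2).
   Per-action counts of "strong" predictions are compared and the argmax
   becomes the subject's predicted personalized action.
4. **Evaluation.** Leave-one-subject-out cross-validation: the cognitive
   CSP and the classifier never see the held-out subject; that subject's
   MI-derived labels are used only for scoring. Metrics: confusion counts
   (positive = strong), F1, sensitivity, specificity, accuracy, Cohen's
   kappa, plus binary clustering coefficients of thresholded networks for
   the strong-vs-weak topology contrast.

## Design choices where the design was open

* **40 time points.** The published description of the time-domain feature
  is internally inconsistent (a "down-sampling rate of 40" on 1000 samples
  would give 25 points, yet the feature matrix is 19 × 40). The
  architecture's input shape is the binding constraint, so we emit 40
  block means of 25 samples each. The hyperparameter grid value
  "down-sampling factor ∈ {20, 40, 60}" is therefore interpreted as the
  number of retained points; 60 does not divide 1000 and fails loudly.
* **Band decomposition backend.** A 4-level dyadic Daubechies DWT at
  1 kHz cannot produce the stated non-dyadic band edges (8–13, 13–20 Hz).
  The default backend is zero-phase 4th-order Butterworth band-pass
  reconstruction at the printed edges; a DWT backend is declared in the
  configuration schema but deliberately not implemented (also: no wavelet
  library in the supported environment), and selecting it raises.
* **PLV pooling.** PLV produces one matrix per band but the model consumes
  one adjacency per trial; the default pools by averaging over the four
  bands (`max` is available in config). Phases come from the Hilbert
  analytic signal.
* **MD edge semantics.** Whether the Manhattan-distance edge encodes
  distance or similarity was unstated; the default is similarity
  (1 − normalized distance) so that in every domain a larger weight means
  a stronger connection. The raw-distance convention is available.
* **Output block.** Batch standardization is applied to the 48-dim
  concatenated features *before* the dense layer (standardizing 2 logits
  would be degenerate). Eval mode uses running statistics (momentum 0.1).
* **Optimizers.** Neither network's optimizer was specified. Both use
  full-batch Adam: the graph classifier at learning rate 0.001 (1000
  epochs by default; the acceptance experiments use 200), the labeling
  network at 0.01 with *decoupled* L2 weight decay 0.05 — routing a decay
  that large through Adam's normalized update crushes the weights and
  collapses the classifier to a constant, so the decay is applied as the
  classic per-step shrinkage `w ← (1 − lr·λ)w`. Hidden activations of the
  labeling network are sigmoid (consistent with its autoencoder-era
  architecture); its stated "sparsity regularization" options belong to
  sparse-autoencoder pretraining semantics that are not recoverable and
  are out of scope — the network's only role here is ranking actions.
* **Chebyshev order 2.** λ_max is fixed at its upper bound 2 instead of
  per-graph eigensolves; this only affects the optional K = 2 mode.
* **Class imbalance.** Training sets contain 25 strong vs 50 weak trials
  per subject; default is unweighted cross-entropy with an
  inverse-frequency weighting flag.
* **Clustering coefficient.** The formula is defined for binary graphs;
  weighted adjacencies are binarized by keeping the top 30% of
  off-diagonal weights (ties at the cut kept, zero weights never become
  edges), keeping density comparable across conditions. The
  strong-vs-weak contrast uses a two-sided within-subject permutation
  test (the original reports only a p-value without naming a test).
* **Metric edge cases.** Ratios with zero denominators return NaN plus an
  `undefined` flag, never a silent 0.

## Synthetic cohorts: the stated world

The real 10-subject dataset is private, so every stage is exercised on a
synthetic cohort that emulates its design: per subject, 3 actions × 25
cognitive trials (19 channels × 1.2 s) and 3 actions × 80 MI trials (12
channels × 6 s, 40 left / 40 right), with exactly one strong action per
subject, assigned by a balanced seeded permutation so each action is
strong for at least one subject in a cohort of ≥ 3.

Generator construction:

* **Background noise**: AR(1) (φ = 0.95, stationary sd = `noise_sd`) plus
  white noise at 0.3 × `noise_sd`, giving a 1/f-like spectrum without
  extra dependencies.
* **Cognitive trials**: three shared narrow-band sources (6, 10, 16 Hz
  sinusoids with random-walk phase jitter, seated at FCZ/CZ/CP3) are mixed
  into the 19 channels with weights decaying with electrode distance in a
  fixed schematic 10–20 layout. Strong-action trials use mixing gain
  `coupling_strong` (default 0.8) vs `coupling_weak` (0.3) and have
  alpha/beta source power boosted by 1 + `bandpower_shift` (default 1.5×).
  The first 0.2 s is source-free so baseline correction is meaningful.
* **MI trials**: a 10 Hz mu rhythm on the lateral channel groups
  (FC3/C5/C3/C1/CP3 vs FC4/C2/C4/C6/CP4), attenuated in amplitude by
  √(1 − d) over the hemisphere contralateral to the cued hand, with
  d = `erd_depth_strong` (0.6) for the strong action and `erd_depth_weak`
  (0.2) otherwise — the lateralized event-related desynchronization that
  makes the strong action more decodable.
* **Free scale parameters** (not fixed by the experimental description)
  were chosen once on physiological grounds and are not tuned: noise sd
  5 µV, oscillatory source amplitude 2 × noise sd, mu amplitude
  1.6 × noise sd, per-trial log-amplitude jitter 0.25 (shared) and 0.15
  (per hemisphere) so that weak actions decode imperfectly (~65–80%) and
  strong actions highly (~95%+), per-sample phase-jitter sd 0.03 rad.
* **Reproducibility**: every subject's randomness comes from one generator
  seeded by (cohort seed, subject id); identical specs produce
  bit-identical cohorts.

What a green test does *not* establish: the generator contains no
artifacts (EOG/EMG), no volume-conduction mixing of the noise, no
inter-subject variability in head geometry or rhythm frequency, and its
strong/weak contrast is by construction aligned with the features the
pipeline measures. Passing recovery tests validate the implementation and
the method's internal logic, not its clinical accuracy; the published
accuracy figures on the private dataset are out of reach by design.

## Numerical details

* Zero-phase (forward–backward) Butterworth filtering via second-order
  sections with odd-reflection padding; the stated filter orders are
  one-pass orders, so effective attenuation is |H(f)|².
* CSP solves the generalized eigenproblem (C₁, C₁ + C₂) of trace-normalized
  average covariances; composite covariances with condition number > 1e10
  get a logged ridge (1e-10 × trace/S).
* Welch PSD: Hann window, segment min(256, n), 50% overlap; band power is
  the mean PSD over the band's frequency range.
* Graph batches precompute each trial's propagation operator and its
  product with the (constant) input features, making 200-epoch full-batch
  training of ~700 19-node graphs a few seconds of NumPy.
* Degenerate inputs fail loudly: zero-variance channels (PCC), constant
  signals (PLV), zero-variance trials (CSP features), isolated nodes
  (Laplacian), single-class training sets.

## Known limitations

* No ICA artifact reduction (assumed done upstream; synthetic data is
  clean) and no re-referencing/resampling.
* The EDF codec is a minimal classic-EDF (16-bit) reader/writer for
  round-trips — not an EDF+ implementation; epoch events travel in a
  sidecar CSV.
* The DWT band-decomposition backend is unimplemented (see above).
* K = 2 Chebyshev mode is functional but not the default and is less
  thoroughly exercised than K = 1.
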