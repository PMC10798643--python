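# Methods

`featuredyn` implements a time-resolved multivariate analysis pipeline for
EEG responses to a factorial set of oriented gratings, together with a
synthetic-data generator that provides the statistical structure the
analyses assume. This note records the models, the parameters that matter,
and the design decisions taken where the design was genuinely open.

## Experimental structure assumed

Stimuli form a 4x4x4x4 factorial grid over orientation (22.5, 67.5,
112.5, 157.5 deg), spatial frequency (2.17, 1.58, 0.98, 0.39 cyc/deg),
colour (4 hues) and contrast (0.9, 0.7, 0.5, 0.3) — 256 gratings. All
analyses operate on the integer levels 0..3; physical values are metadata.
Stimuli are presented in rapid sequences, each sequence a random
permutation of all 256 stimuli, at 6.67 or 20 Hz (the rate is carried as
metadata only; the generator does not model the masking difference between
rates). Epochs span -100..600 ms around stimulus onset at 250 Hz (4 ms
steps, 176 samples).

## Decoding model

The classifier is a multiclass linear discriminant with diagonal
shrinkage. With pooled within-class covariance
S = sum_k sum_{i in k} (x_i - mu_k)(x_i - mu_k)' / (n - K),
the regularised covariance is S + lambda * mean(diag(S)) * I with
lambda = 0.01 by default (exposed as `reg` everywhere). Prediction is
argmax_k of x'S^-1 mu_k - mu_k'S^-1 mu_k / 2 + log pi_k, ties resolving
to the lowest class index. The exact shrinkage constant used by the
original MATLAB toolbox this style of analysis is usually run with is not
published, so absolute accuracies are not comparable across
implementations; all within-package comparisons hold lambda fixed.

Cross-validation is leave-one-sequence-out: folds are presentation
sequences, so train and test events never share a sequence, and each
feature analysis uses the same folds. Accuracy is the pooled proportion
of correct test predictions across folds, per timepoint. Chance is 0.25
for 4-class feature decoding and 0.5 for pairwise/conjunction decoding.
Single presentations are decoded directly; no pseudo-trial averaging.

Derived analyses reuse the same engine:

- **Temporal generalisation** trains at each timepoint and tests at all
  timepoints with the same folds; the diagonal therefore equals the
  standard timecourse exactly.
- **Channel searchlight** decodes each centre channel together with its 4
  nearest neighbours (straight-line Euclidean distance between 3-D sensor
  positions, ties broken by channel index), storing accuracy at the
  centre. Geodesic distance would differ only for very coarse montages.
- **Interaction decoding** repeats 4-class decoding within each level of a
  conditioning feature (one quarter of the events each, chance still
  0.25). Per-level results are summarised by the mean accuracy in a 20 ms
  window centred on the peak of the corresponding full-data analysis. On
  the 4 ms grid "peak +/- 10 ms inclusive" contains 5 samples; a 6-sample
  window cannot be centred on a grid point.
- **Conjunction decoding**: for a feature pair, choose two levels of each
  (6 x 6 = 36 choices); the four cells of the 2x2 level grid admit exactly
  one two-versus-two split balanced on both features — the diagonal split.
  Each split defines a 2-class problem with 32 stimuli per class once
  expanded over the untouched features; accuracies are averaged over the
  36 contrasts. Because the class means are identical for any purely
  additive feature code, above-chance accuracy indicates a response to the
  feature *combination*. The class containing the (min, min) cell is
  labelled class 1 for deterministic enumeration; accuracy is invariant to
  the labelling and to the order of the feature pair.
- **Pairwise RDM decoding** runs the 2-class analysis for every stimulus
  pair with the same folds, filling a symmetric per-timepoint RDM
  (diagonal 0). Stimulus subsetting is supported for reduced-scale runs;
  the full 256-stimulus analysis is 32640 pairs per timepoint.

## Representational similarity analysis

Feature-model RDMs use rank distance between levels: |l_i - l_j| for
spatial frequency, colour and contrast; the circular min(|d|, 4 - |d|)
for orientation (22.5 vs 157.5 deg is 45 deg apart, dissimilarity 1).
The four models are pairwise orthogonal on the full stimulus set: Spearman
rho = -0.008 between orientation and each other model and -0.007 between
the non-orientation pairs (reproducing these printed correlations,
including their p-values of .171/.189, confirms the original values were
Spearman).

Behavioural RDMs come from odd-one-out triplets: similarity(i, j) is the
fraction of triplets containing both i and j in which the *third* item
was chosen, dissimilarity = 1 - similarity. Pairs never co-presented are
missing and pairwise-deleted in correlations. RDM comparisons use
Spearman correlation (average ranks for ties) over the shared non-missing
lower-triangle entries; p-values use the large-n t approximation and are
reported but never used for inference.

## Group inference

Evidence at each timepoint is a one-sample Bayes factor across subjects:
point null at chance (or 0 for correlations) versus an interval
alternative — Cauchy(0, 0.707) on the standardized effect delta truncated
to delta >= 0.5, i.e. "at least a medium effect", so small systematic
deviations from chance do not accumulate spurious evidence. BF10 is the
ratio of the noncentral-t marginal likelihood of the observed t statistic
under the prior to the central-t likelihood under the null, computed by
adaptive quadrature on a compactified axis with a breakpoint at the
likelihood peak; a dense-grid quadrature oracle agrees to well under 4
significant digits. Condition comparisons use the two-sided variant
(|delta| >= 0.5) on paired differences. The scale (0.707), truncation
(0.5) and one/two-sidedness are configuration knobs; the original
analysis's exact prior settings are not published, so absolute BF values
are not expected to transfer. BFs are reported with a log10 companion;
degenerate zero-variance samples (e.g. every subject saturated at ceiling
accuracy) map to BF = inf/tiny by the sign of the unanimous displacement.

Onset latency is the first timepoint of the earliest run of >= 3
consecutive post-stimulus timepoints with BF10 > 10; the search is
restricted to t >= 0 because pre-stimulus runs are noise. Peak latency is
the post-stimulus argmax of the group mean (ties -> earliest). Confidence
intervals recompute the estimator on every leave-two-subjects-out subset
(C(n, 2) subsets; 120 for 16 subjects) — for onsets the group BF series is
recomputed per subset — and report the [2.5, 97.5] percentile range of
the defined estimates, with the number of undefined subsets recorded. The
percentile pair is configurable; a one-sided 95th percentile can be
requested instead, but two-sided intervals are the default reported form.
Subject-level significance marks use the 95th percentile of that
subject's pre-stimulus accuracies as a threshold for post-stimulus
timepoints.

## Synthetic data

The generator emits pre-epoched data: for each event,
data = sum_f pattern_f(level) * env(t) * a_f
     + sum_{(f,g)} pattern_fg(cell) * env(t) * a_fg + noise.

- **Temporal envelope**: a Gamma-like bump, zero before onset, rising to
  1 at the peak and decaying exponentially with scale `width_ms` (default
  60 ms). Only the onset/peak semantics matter for the recovery analyses;
  the waveform itself is not modelled on any measured component.
- **Spatial patterns**: per feature, each of the 4 levels receives a
  random channel pattern (i.i.d. Gaussian, channel-mean-centred, unit
  norm). By default each subject draws its own patterns from its subject
  seed, mimicking idiosyncratic sensor topographies; an explicit
  `pattern_seed` shares topographies across subjects. A `graded` flag
  interpolates the level patterns between two anchors so nearby levels
  have similar patterns — required when neural RDMs should mirror the
  rank models.
- **Conjunction patterns**: one pattern per cell of the 4x4 level grid of
  a feature pair, double-centred across rows and columns so the marginal
  mean pattern at every level of either feature is exactly zero. The
  injected conjunction signal therefore adds no single-feature
  information, and conversely additive-only signals leave conjunction
  decoding at chance (equal class means by construction) — the additivity
  null the conjunction analysis relies on.
- **Noise**: Gaussian with exponential spatial covariance
  sd^2 * rho^(d_ij / median distance) across channels (rho = 0.3 default)
  and AR(1) autocorrelation 0.3 in time, sd = 1 per channel. Amplitudes
  are therefore in units of per-channel noise SD.
- **Default latencies/amplitudes** (`default_signal_spec`): contrast
  onset 72 / peak 96 ms, amplitude 1.4; sf 72/112, 1.2; colour 72/112,
  1.2; orientation 92/120, 0.8. The latency layout echoes the observed
  dynamics (contrast peaks first, sf and colour together, orientation
  later and weaker); amplitudes were chosen so test-preset group decoding
  peaks in the 0.6-0.9 range, comfortably above chance at desk scale —
  the documented SNR at which the recovery properties (peak within
  +-8 ms, onset ordering preserved) are asserted.

Triplet judgements are simulated by sampling 3 distinct stimuli uniformly
and choosing item x of {x, y, z} with probability proportional to
exp(beta * (d(x,y) + d(x,z))), where d is a non-negative weighted sum of
the four feature-model RDMs. Default weights
(orientation 0.1, sf 1.0, colour 0.9, contrast 0.25) mirror the relative
behavioural weighting of the features reported for this paradigm; with
beta = 2 the choices are close to deterministic given the weighted
distances.

What the generator does *not* emulate: biophysical sources and volume
conduction, artefacts and eye movements, overlapping responses from
neighbouring rapid-presentation events, the accuracy difference between
presentation rates, and non-Gaussian noise. Passing recovery tests
therefore demonstrate correctness of the analysis chain under the assumed
signal+noise model, not robustness to real-EEG violations of it.

## Problem sizes

Group analyses in the test suite use 8 subjects x 32 channels x 10
sequences (2560 events/subject), the package's desk-scale preset; the
study-scale preset (16 x 128 x 40) is available behind a flag. Feature
decoding in the recovery tests runs on the -100..300 ms half of the
epoch (all injected dynamics end by 200 ms), conjunction analyses on
48..200 ms, and pairwise-RDM tests on 16-stimulus subsets; a 5-subject
"smoke" preset supports end-to-end CLI runs.

## Known limitations

- The behavioural RDM estimator is unbiased per pair but noisy at small
  trial counts: T trials provide 3T pair observations spread over 32640
  pairs, so 1e5 trials give ~9 observations per pair and binomial noise
  p(1-p)/9 attenuates the Spearman correlation with the generating
  distance structure to ~0.9; convergence toward 1 requires several
  hundred thousand trials (the study's 265,000 trials sit near the start
  of that asymptote). Even asymptotically the correlation stays below 1:
  a pair's expected survival rate is a noisy, not strictly monotone,
  function of its generating distance.
- Jackknife percentile CIs rely on leave-two-out subsets that share most
  of their subjects; when the group-level estimate is noise-limited
  (nearly flat peaks), the intervals undercover. The coverage property is
  asserted only at adequate SNR.
- Searchlight neighbourhoods use straight-line distances on an idealised
  hemispheric layout; real montage files are not parsed.
- `interval_bf` rejects zero-variance samples rather than inventing a
  limit; only the time-series wrapper maps saturation to infinite BFs.
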