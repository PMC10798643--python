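# featuredyn

Time-resolved EEG decoding, feature-conjunction analysis and
representational similarity analysis (RSA) for factorial visual-feature
designs — with a synthetic-data generator so the whole pipeline runs and
is tested at desk scale, without any recordings.

## The problem

How are the basic visual features of a stimulus — orientation, spatial
frequency (SF), colour, contrast — coded over time in the human brain,
how do they interact and combine, and how does that coding relate to
perceived similarity? A powerful paradigm presents a full factorial set
of 256 gratings (4 levels per feature) in rapid sequences during EEG,
then asks, at every timepoint:

- **Feature decoding.** Can a regularised linear discriminant (LDA,
  pooled covariance shrunk by `S + 0.01 * mean(diag(S)) * I`) classify
  the 4 levels of each feature from the sensor pattern? Cross-validation
  is leave-one-sequence-out, so train and test events never share a
  presentation sequence; chance is 0.25. Variants: channel searchlight
  (centre + 4 nearest sensors), temporal generalisation (train at t,
  test at all t'), and decoding within levels of another feature
  (interactions).
- **Conjunction decoding.** For each feature pair, classify stimulus
  groups matched on every single-feature marginal but differing in the
  *pairing* of levels (the diagonal split of a 2x2 level grid; 36 such
  contrasts per pair, 32 stimuli per class, chance 0.5). Above-chance
  accuracy is evidence of nonlinear conjunction (binding) codes.
- **RSA.** Pairwise decoding of all stimulus pairs yields a 256x256
  neural dissimilarity matrix per timepoint, compared (Spearman, lower
  triangle, 32640 values) against rank-distance feature models (circular
  for orientation) and a behavioural dissimilarity matrix estimated from
  odd-one-out triplet judgements.
- **Inference.** Group evidence is a Bayes factor per timepoint: point
  null at chance versus a Cauchy(0, 0.707) prior on the standardized
  effect truncated to delta >= 0.5. Onset latency = first of 3
  consecutive timepoints with BF10 > 10; peak latency = argmax of the
  group mean; confidence intervals from a leave-two-subjects-out
  jackknife (all C(n,2) subsets, percentiles 2.5/97.5).

The synthetic generator injects feature-selective and
conjunction-selective spatio-temporal signals with controllable
onset/peak latencies into spatially and temporally correlated noise, and
simulates triplet choices from a weighted sum of the feature-model
dissimilarities — providing ground truth for every analysis stage. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a small group, decode colour over time, and estimate the
group-level onset and peak with jackknife CIs:

```python
import numpy as np
from featuredyn import (NoiseSpec, bf_timecourse, build_sequences,
                        decode_feature_timecourse, default_signal_spec,
                        detect_onset, generate_epochs, jackknife_ci)

signal = default_signal_spec()       # contrast 72/96 ms, sf 72/112,
                                     # colour 72/112, orientation 92/120
group = [
    generate_epochs(build_sequences(10, 6.67, seed=100 + i), n_channels=32,
                    signal=signal, noise=NoiseSpec(), subject_seed=100 + i)
    for i in range(8)
]
tcs = [decode_feature_timecourse(ds, "colour") for ds in group]
acc = np.stack([tc.accuracy for tc in tcs])
times = tcs[0].times

print("peak accuracy", acc.mean(axis=0).max().round(3))
print("onset", detect_onset(bf_timecourse(acc, times, null_value=0.25)))
print(jackknife_ci(acc, times, "peak", null_value=0.25))
```

Output:

```
peak accuracy 0.772
onset 76.0
OnsetPeakEstimate(estimate_ms=116.0, ci_low=108.0, ci_high=116.0,
                  n_jackknife=28, n_missing=0, kind='peak')
```

Colour was injected with onset 72 ms and peak 112 ms: decoding rises
above chance (0.25) to 0.77, the Bayes-factor onset rule fires at 76 ms
(one sample after the injected onset — the envelope is still nearly zero
at 72 ms), and the group peak lands one 4 ms sample from the injected
peak, with the jackknife CI over the 28 leave-two-out subsets spanning
108-116 ms.

The same pipeline is available from the shell:

```
featuredyn simulate-eeg --preset test --seed 1 --out runs/sim
featuredyn decode --data runs/sim --feature colour --out runs/colour.tsv
featuredyn stats --results runs/colour.tsv --null 0.25 --out runs/colour-bf.tsv
featuredyn report --data runs/sim --out runs/report.tsv
```

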