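# eegfatigue

Detecting mental fatigue from multichannel EEG with fewer electrodes and
fused features.

Mental fatigue shifts the EEG power spectrum (alpha and theta power rise,
beta falls as alertness drops) and makes the signal more regular (sample
entropy falls). Classifiers built on a full electrode montage carry
redundant channels that cost acquisition and computation time, and any
single feature family wastes information the others carry. This package
implements a complete pipeline addressing both problems, for researchers
working on EEG-based vigilance and fatigue monitoring:

1. **Channel weighting (ReliefF).** Per subject, every (channel, feature)
   column of an epoch-by-feature table receives a Relief weight
   `W(C_l F_i)`: features that separate a sample from its nearest
   different-state neighbors more than from same-state neighbors gain
   weight. Channel weights are the per-channel means
   `W(C_l) = (1/b) Σ_i W(C_l F_i)`.
2. **Common-channel selection across subjects**, two schemes:
   *weight addition* — min-max normalize each subject's channel weights,
   sum across subjects: `W(C_i) = Σ_j W(C_i S_j)`; or
   *accuracy weighting* — weight each term by the single-channel SRDA
   classification accuracy:
   `W(C_l) = Σ_j Σ_i W(C_l F_i S_j) · Acc(C_l F_i S_j)`.
   The top half of the ranking (8 of 16 channels) becomes the common
   montage.
3. **Features.** Per channel and 1-s epoch: log Welch band power in the
   delta (0.5–4 Hz), theta (4–8), alpha (8–12) and beta (12–30) bands,
   plus sample entropy (m = 2, r = 0.2·sd) — 5 × 16 = 80 columns.
4. **Sparse multi-feature fusion (K-SVD + OMP).** An undercomplete
   dictionary `D ∈ R^{80×20}` is learned on training epochs by K-SVD
   (alternating OMP sparse coding `Y ≈ DX` with per-atom rank-1 SVD
   updates of the restricted residual); each epoch's sparse code `α ∈ R^20`
   is the fused feature vector. Concatenation and PCA fusion are included
   as baselines.
5. **Classification (SRDA).** Spectral Regression Discriminant Analysis:
   the LDA embedding solved as a ridge regression on class-indicator
   targets, with nearest-centroid decisions.

Because the method is evaluated on cohorts that are rarely shared, the
package ships a seeded synthetic cohort generator (8 subjects, 16 channels,
500 Hz, 2 min per state) with known informative channels and configurable
band-power/entropy effects, so every stage can be validated against ground
truth.

## Worked example

```python
import numpy as np
from eegfatigue import (
    SyntheticCohortConfig, generate_cohort, segment_all, extract_features,
    build_channel_weight_table, common_weights_accuracy, select_common_channels,
    PipelineConfig, run_pipeline,
)

recordings, truth = generate_cohort(SyntheticCohortConfig(seed=11))
features = extract_features(segment_all(recordings, epoch_len=1.0))
print(features.values.shape)

table = build_channel_weight_table(features, seed=11)
selected = select_common_channels(common_weights_accuracy(table),
                                  table.channel_labels)
print(sorted(selected), truth["informative_labels"])

report = run_pipeline(
    PipelineConfig(seed=11, selection_method=None, n_repeats=1),
    features=features.select_channels(selected),
)
print(report.per_subject["accuracy_mean"].round(3).to_dict())
```

prints

```
(1920, 80)
['ch00', 'ch01', 'ch02', 'ch03', 'ch04', 'ch05', 'ch07', 'ch09'] ['ch00', 'ch01', 'ch02', 'ch03', 'ch04', 'ch05']
{'S1': 0.933, 'S2': 0.95, 'S3': 0.917, 'S4': 0.933, 'S5': 0.967, 'S6': 0.967, 'S7': 0.967, 'S8': 0.95}
```

The 16 recordings (8 subjects × 2 states, 120 s at 500 Hz) segment into
1920 one-second epochs with 80 feature columns. The accuracy-weighted
scheme places all 6 planted informative channels in its top 8, and SRDA on
the 20-dimensional sparse-fused features of those 8 channels classifies
pre-fatigue vs fatigue epochs at 0.92–0.97 per subject on held-out splits.

The same stages are available from the shell:

```sh
eegfatigue simulate --out cohort/ --seed 11
eegfatigue extract --data cohort/ --out features.csv
eegfatigue select-channels --features features.csv --method accuracy --out channels.json
eegfatigue evaluate --seed 11 --single-features
eegfatigue compare-fusions --seed 11
```

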