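"""Cohort-level benchmark of the full method on synthetic ground truth.

One benchmark run generates a cohort with a known informative-channel set,
then measures everything the method claims: how many planted channels each
common-channel scheme recovers, how selected-channel accuracy compares with
full-channel accuracy, and how sparse fusion compares with each single
feature and with the PCA/concatenation baselines. Repeating over seeds
gives the distributions the acceptance checks summarize.
"""

from __future__ import annotations

import numpy as np

from .channel_selection import (
    build_channel_weight_table,
    common_weights_accuracy,
    common_weights_addition,
    select_common_channels,
)
from .features import extract_features
from .io import segment_all
from .pipeline import PipelineConfig, compare_fusions, run_pipeline
from .synthetic import SyntheticCohortConfig, generate_cohort

__all__ = ["cohort_benchmark"]


def cohort_benchmark(seed: int, cohort_config: SyntheticCohortConfig | None = None,
                     n_repeats: int = 1) -> dict:
    """Run the full method once on a seeded synthetic cohort.

    Returns a flat dict of the benchmark quantities (per-subject means over
    ``n_repeats`` 75/25 splits; channel selection is computed once on the
    whole cohort, the fixed-montage protocol).
    """
    cfg = cohort_config or SyntheticCohortConfig(seed=seed)
    recordings, truth = generate_cohort(cfg)
    X = extract_features(segment_all(recordings))
    informative = set(truth["informative_labels"])

    table = build_channel_weight_table(X, seed=seed)
    selections = {
        "accuracy": select_common_channels(
            common_weights_accuracy(table), table.channel_labels
        ),
        "addition": select_common_channels(
            common_weights_addition(table), table.channel_labels
        ),
    }
    pcfg = PipelineConfig(seed=seed, n_repeats=n_repeats, selection_method=None)

    # montage comparison: sparse-fused accuracy on the selected half vs all 16
    X_sel = X.select_channels(selections["accuracy"])
    rep_sel = run_pipeline(pcfg, features=X_sel)
    # fusion comparisons run on the full montage (80-dim input -> 20), the
    # configuration the fusion stage is designed around
    rep_full = run_pipeline(pcfg, features=X, include_single_features=True)
    fusion_table = compare_fusions(pcfg, features=X)

    best_single = rep_full.single_feature_accuracy.max(axis=1)
    return {
        "seed": seed,
        "n_channels": len(table.channel_labels),
        "n_selected": len(selections["accuracy"]),
        "recovered_accuracy_scheme": len(set(selections["accuracy"]) & informative),
        "recovered_addition_scheme": len(set(selections["addition"]) & informative),
        "selected_channels": selections["accuracy"],
        "acc_fused_selected": float(rep_sel.per_subject["accuracy_mean"].mean()),
        "acc_fused_full": float(rep_full.per_subject["accuracy_mean"].mean()),
        "acc_best_single_mean": float(best_single.mean()),
        "fused_minus_best_single": float(
            (rep_full.per_subject["accuracy_mean"] - best_single).mean()
        ),
        "single_feature_means": {
            f: float(v) for f, v in rep_full.single_feature_accuracy.mean(axis=0).items()
        },
        "acc_sparse": float(fusion_table["sparse"].mean()),
        "acc_pca": float(fusion_table["pca"].mean()),
        "acc_concat": float(fusion_table["concat"].mean()),
        "per_subject_fused": rep_sel.per_subject["accuracy_mean"].tolist(),
    }
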