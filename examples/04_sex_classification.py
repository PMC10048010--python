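"""Full pipeline: slide, superimpose, PCA, set-aside split, ANN, metrics.

Runs the complete analysis on a small synthetic cohort and prints the
held-out confusion-matrix panel ("female" is the positive class) plus the
most influential predictors (Garson connection-weight importance, scaled so
the top predictor is 100).
"""

import crownmorph as cm

config = cm.RunConfig(
    synthetic=cm.DimorphismSpec(
        teeth=(cm.Tooth.FP, cm.Tooth.SP), n_f=25, n_m=25, seed=5
    ),
    slide_cycles=6,
    slide_reference="mean",
    n_components=15,
    grid=[(3, 0.05), (3, 0.1)],
    cv_k=5,
    train_counts={"F": 18, "M": 18},
    repeat_round_size=0,
    seed=5,
)
result = cm.run_pipeline(config)

print(f"cohort shape effect: {result.cohort.shape_effect:.4f} "
      f"(Procrustes distance between sex means)")
print(f"cross-validation selected hidden={result.cv.selected['hidden']}, "
      f"decay={result.cv.selected['decay']} "
      f"(CV accuracy {result.cv.mean_accuracy[result.cv.selected_index]:.3f})")
print()
print(result.test_report)
print(f"\nROC AUC on the test partition: {result.roc.auc:.3f}")
print("\ntop 5 predictors by importance:")
print(result.importance.head(5).round(2).to_string())
# A test accuracy well above the no-information rate (with a small
# p-value for Acc > NIR) means crown shape+size carry usable sex signal.
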