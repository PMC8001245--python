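"""A complete small study: generate, extract, search, evaluate.

Creates a 60-image public-style synthetic dataset, extracts multiscale
Betti-curve features, runs the exhaustive configuration search (flags x
scale subsets x eight classifiers) selected on validation accuracy, and
reports the winner's test accuracy and confusion matrix.

Takes about half a minute on one CPU.
"""

from bettipath import make_preset, make_sweep, run_study

ds = make_preset("public-mimic", seed=4, n_per_class=20)
study = run_study(
    ds,
    counts=(36, 12, 12),
    method="HI",
    scales=[(768, 768), (384, 384), (192, 192), (96, 96)],
    sweep=make_sweep(0, 255, 15),
    seed=4,
)

best = study["best"]
print(f"configurations searched: {len(study['results'])}")
print(f"best configuration:      {best.config.describe()}")
print(f"validation accuracy:     {best.validation_accuracy:.4f}")
print(f"test accuracy:           {best.test_accuracy:.4f}")
print("confusion matrix (rows = truth, columns = prediction):")
print(best.confusion_matrix)
print()
print("With well-separated class recipes the search should find a perfect or")
print("near-perfect configuration; ties on validation accuracy are resolved")
print("by enumeration order (first flag/scale/algorithm combination wins).")
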