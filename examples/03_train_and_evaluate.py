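"""Run a simulated training session and evaluate SVM vs KNN.

Builds a small stimulus manifest (8 per class, 3 s displays), records
stimulus-locked labelled epochs, extracts Hjorth features per band on all
14 channels, and reports stratified 10-fold cross-validation accuracy for
both classifiers plus the mutual-information top features.
"""

import emorec as er

manifest = er.build_manifest(per_class=8, seed=0, display_duration=3.0)
epochs = er.record_training_session(manifest, seed=0)
print(f"manifest: {len(manifest)} stimuli -> {len(epochs)} labelled epochs")

X, labels, names = er.extract_features(epochs, family="hjorth14")
print(f"feature matrix: {X.shape[0]} epochs x {X.shape[1]} features")

for method in ("svm", "knn"):
    report = er.cross_validate(X, labels, method=method, k_folds=10, seed=0)
    print(f"{method}: mean 10-fold accuracy = {report.mean_accuracy:.3f}")

ranking = er.mi_rank(X, labels)
print("top 5 features by mutual information with the emotion label:")
for idx in ranking[:5]:
    print(f"  {names[idx]}")
print()
print("Accuracy near 1.0 reflects the well-separated synthetic spectra;")
print("the top-ranked features name the (channel, band, descriptor) that")
print("separate the classes most.")
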