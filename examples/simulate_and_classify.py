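"""Classify a synthetic case-control cohort with Riemann kernel PCA.

Simulates 60 patients and 60 controls (20 ROIs, 300 time points) whose
population FC differs by 0.3 on five planted edges, then compares 10-fold
cross-validated classification across feature-extraction methods.  Accuracy
near 50% would mean chance; the Riemann pipeline should approach 100% on
this strongly separable cohort.
"""

import riemannfc as rf
from riemannfc.classify import PipelineConfig

result = rf.simulate_cohort(rf.SimulationConfig(seed=1))
matrices = [rf.fc_from_timeseries(s) for s in result.series]

print(f"cohort: {len(matrices)} subjects, k = {matrices[0].n_rois} ROIs, "
      f"planted edges = {result.planted_edges}")
print(f"{'method':<10} {'classifier':<10} {'sens%':>7} {'spec%':>7} "
      f"{'acc%':>7}")
for method in ("riemann", "linear", "gaussian", "raw"):
    for classifier in ("gbt", "svm"):
        report = rf.cross_validate(
            matrices, result.cohort,
            PipelineConfig(method=method, classifier=classifier), seed=1)
        print(f"{method:<10} {classifier:<10} {report.sensitivity:>7.1f} "
              f"{report.specificity:>7.1f} {report.accuracy:>7.1f}")
print("\nEach row is a stratified 10-fold CV estimate; the decomposition is "
      "refitted on every training split, so test subjects are never seen "
      "during feature extraction.")
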