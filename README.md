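# riemannfc

Riemannian kernel PCA classification of functional connectomes, with
model-driven recovery of the brain connections that drive the
classification.

## The problem

Resting-state fMRI yields, per subject, a functional-connectivity (FC)
matrix `A ∈ R^{k×k}` of Pearson correlations between ROI time series.
Case-control classification usually flattens `A` into a feature vector,
discarding its structure. This package instead works on the manifold of
symmetric positive-definite matrices: each connectome becomes a regularized
graph Laplacian `L̂ = D − W + γI`, subjects are compared with the
log-Euclidean distance

    d(S₁, S₂) = ‖log S₁ − log S₂‖_F,

and a Gaussian kernel of that distance,
`K_ij = exp(−d(L̂_i, L̂_j)²/2σ²)`, drives a kernel PCA. The component
scores feed a gradient-boosted tree classifier (XGBoost), and the trees'
importances are mapped back from component space to an importance over
ROI-ROI connections by solving a kernel-PCA pre-image problem with a
fixed-point iteration on the manifold (a weighted log-Euclidean Fréchet
mean). Seed-based connectivity statistics (Fisher-Z seed maps, group GLMs
co-varying age and sex, severity regressions) round out the analysis.

It is intended for methods researchers in connectomics and biostatistics
who want a tested, self-contained implementation — clinical FC datasets are
rarely shareable, so the package ships a synthetic cohort generator with
planted group differences that makes every stage verifiable end to end.

## Worked example

Simulate a cohort of 60 patients and 60 controls (20 ROIs, 300 time
points) whose population correlation differs by 0.3 on five planted edges,
classify it, and recover the planted edges:

```python
import riemannfc as rf
from riemannfc.preimage import edge_importance, rank_edges

result = rf.simulate_cohort(rf.SimulationConfig(seed=1))
matrices = [rf.fc_from_timeseries(s) for s in result.series]

report = rf.cross_validate(matrices, result.cohort, seed=1)
print(report.sensitivity, report.specificity, report.accuracy)
# 98.3 98.3 98.3   <- stratified 10-fold CV, in percent

model = rf.RiemannKernelPCA().fit(matrices)
_, importance = rf.train_boosted_trees(model.training_scores_,
                                       result.cohort.indicator(), seed=1)
top = rank_edges(edge_importance(model, importance, seed=1), top_n=10)
print(list(zip(top.roi_i, top.roi_j))[:5])
# [(2, 3), (4, 5), (8, 9), (0, 1), (6, 7)]  <- all five planted edges
```

The CV numbers are percentages from pooled fold confusion counts; the
feature decomposition is refitted inside every training fold, so test
subjects are never seen during feature extraction. The ranked edges are
sorted by the magnitude of the reconstructed importance map — the deviation
of the pre-image connectome from the cohort mean along the discriminative
components — and here the five planted edges occupy the top five ranks.

The `examples/` directory has one short script per capability
(classification and baselines, edge recovery, σ/γ sensitivity, seed-based
GLMs); each prints the numbers it computes and what they mean. A thin CLI
wraps the same calls:

```sh
riemannfc simulate --n-per-group 60 --k 20 --t 300 --seed 1 --out cohort/
riemannfc cv --matrices cohort/ --phenotypes cohort/phenotypes.csv \
             --report report.json
```

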