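"""Seed-based connectivity statistics on a synthetic cohort.

Uses the first planted ROI pair's seed to build per-subject Fisher-Z seed
maps, then (a) tests group differences per unit co-varying age and sex and
(b) regresses connectivity on the symptom-severity score within patients.
The generator couples severity negatively to planted-edge connectivity, so
the severity slope at planted units should come out negative.
"""

import numpy as np

import riemannfc as rf

result = rf.simulate_cohort(rf.SimulationConfig(seed=1))
seed_rois = [result.planted_edges[0][0]]          # seed on a planted ROI
maps = rf.seed_maps_for_cohort(result.series, seed_rois)

stats = rf.group_glm(maps, result.cohort)
sig = stats.dropna(subset=["t"]).query("significant")
print(f"group GLM (z ~ 1 + group + age + sex), dof = {stats.attrs['dof']}:")
print(f"  {len(sig)} of {stats.t.notna().sum()} units significant at "
      f"p < .05")
partner = result.planted_edges[0][1]
row = stats.loc[stats.unit == partner].iloc[0]
print(f"  planted partner unit {partner}: t = {row.t:.2f}, "
      f"p = {row.p:.2g}, mean diff = {row.mean_diff:.3f} "
      "(patients above controls, as planted)")

sev = rf.severity_regression(maps, result.cohort)
row = sev.loc[sev.unit == partner].iloc[0]
print(f"\nseverity regression (patients only, z ~ 1 + ybocs + age + sex):")
print(f"  planted partner unit {partner}: slope = {row.slope:.4f}, "
      f"p = {row.p:.2g}")
print("  a negative slope reproduces the planted severity-connectivity "
      "coupling")

null_rate = rf.group_glm(*rf.simulate_null_maps(40, 1000, seed=2)
                         ).significant.mean()
print(f"\nnull calibration: {100 * null_rate:.1f}% of 1,000 effect-free "
      "units rejected at alpha = .05 (nominal 5%)")
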