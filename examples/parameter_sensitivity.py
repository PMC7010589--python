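"""Sweep the kernel bandwidth sigma and Laplacian regularization gamma.

Classification accuracy should be flat in gamma (the spectral shift barely
changes log-Euclidean geometry at these scales) but should degrade when
sigma is pushed far below the spread of the matrix set, where the kernel
matrix collapses toward the identity and carries no between-subject
information.
"""

import riemannfc as rf

result = rf.simulate_cohort(rf.SimulationConfig(seed=1))
matrices = [rf.fc_from_timeseries(s) for s in result.series]
auto = rf.default_sigma(matrices)
print(f"default sigma (spread of the log-matrix set): {auto:.3f}\n")

table = rf.sweep(matrices, result.cohort,
                 sigma_grid=[auto / 100, auto / 4, auto, 4 * auto],
                 gamma_grid=[0.1, 1.0, 10.0], seed=1)
print(table.round(1).to_string(index=False))

by_gamma = table[table.sigma == auto]
spread = by_gamma.accuracy_pct.max() - by_gamma.accuracy_pct.min()
print(f"\naccuracy spread across gamma at sigma=auto: {spread:.1f} points "
      "(regularization-insensitive); the sigma/100 rows sit at chance "
      "because the kernel degenerates.")
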