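"""Principal-curve pseudo-ordering of a developmental continuum.

A 200-cell continuum with 50 latent-time-modulated genes is projected into
a modified PCA space (top two components, each restricted to its 60
largest-|loading| genes) and ordered by arc length along a fitted principal
curve; direction is fixed by anchoring the earliest third of the continuum.
"""

import numpy as np
from scipy.stats import spearmanr

import avec

dataset, truth = avec.generate_vec_dataset(avec.continuum_spec(seed=4))
scores = avec.modified_pc_scores(dataset, n_top=60)
result = avec.fit_principal_curve(scores.to_numpy())

latent = truth.cells["latent_time"].to_numpy()
rho = spearmanr(result.lambda_, latent).statistic
print(f"|Spearman(lambda, true latent time)| = {abs(rho):.4f} over {dataset.n_cells} cells")
print(f"curve fit converged in {len(result.objective_history)} iterations; "
      f"mean squared projection distance {result.objective_history[-1]:.4f}")

oriented = avec.orient_pseudoorder(result, latent < 1 / 3, anchor_name="early")
rho_oriented = spearmanr(oriented.lambda_, latent).statistic
print(f"after anchoring the early cells at low lambda: Spearman = {rho_oriented:.4f}")
# A positive correlation means the pseudo-order now runs in developmental
# direction; the anchor mimics orienting a trajectory by sampling stage.

gene = truth.temporal_genes[0]
import pandas as pd
lam = pd.Series(oriented.lambda_, index=dataset.cells)
table = pd.DataFrame({"gene": [gene], "category": ["other"], "p_ep6_vs_ep7": [0.1]})
dyn = avec.pattern_dynamics(dataset, lam, table, window=20)
row = dyn.loc[gene]
print(f"{gene} smoothed over 20 adjacent cells: "
      f"{row.iloc[0]:.2f} -> {row.iloc[-1]:.2f} along the pseudo-order")
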