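"""Gate/fine trial-space axes and effort classification for one subject.

PCA over the CP trial components yields two axes: a gate axis separating
50% effort from {80, 100}% and a fine axis distinguishing 80% from 100%.
A small CART tree on the two axes classifies the three effort levels.
"""

import numpy as np

import pitchsynergy as ps

res = ps.run_pipeline(ps.PipelineConfig(
    seed=11, threshold=0.80, r_max=8, restarts=3, tol=1e-7, max_iter=400,
    holdout_repeats=100))

pca = res.trial_pca
print(f"two PCs explain {100 * pca.explained_fraction_2d:.1f}% of the "
      f"trial-component variance")
print(f"roles: gate = PC{pca.role['gate']}, fine = PC{pca.role['fine']}"
      + (" (swapped)" if pca.swap_applied else ""))

lab = res.tensor.effort_labels
for name in ("gate", "fine"):
    s = pca.role_scores(name)
    means = {e: round(float(s[lab == e].mean()), 3) for e in (50, 80, 100)}
    print(f"{name} score means by effort: {means}")
# the gate means step up sharply from 50% to 80% and barely from 80% to
# 100%; the fine means move most between 80% and 100%.

print(f"tree: min leaf size {res.tree.min_leaf_size}, "
      f"training error {res.tree.training_error:.3f}, "
      f"hold-out error {res.holdout_error:.3f} "
      f"(random baseline {res.baseline:.2f})")

gate = pca.role_scores("gate")
sep = gate[lab == 50].max() < gate[lab != 50].min()
print(f"gate axis alone separates 50% from higher efforts: {sep}")

gx, gy, regions = ps.decision_regions(
    res.tree, (gate.min() - 0.05, gate.max() + 0.05,
               pca.role_scores('fine').min() - 0.05,
               pca.role_scores('fine').max() + 0.05), 0.01)
print(f"decision grid {regions.shape} covers classes "
      f"{sorted(int(v) for v in np.unique(regions))}")
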