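"""Typology assignment with ordination and a permutation test.

Runs the full default-size panel (59 genotypes, 2 seasons, 3 blocks);
takes ~10 s.
"""

import warnings

import pamdsi as pm

spec = pm.DesignSpec(seed=0)
panel = pm.build_panel(spec)
fluor = pm.compute_table(pm.simulate_measurements(panel, spec))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    dsi = pm.dsi_pipeline(fluor)
    features = pm.build_feature_matrix(fluor, dsi["dsi"])

clusters = pm.ward_cluster(features, 4)
assignment = pm.label_classes(clusters, dsi["dsi"].reindex(features.index))
truth = panel.set_index("genotype")["class_true"].reindex(assignment.index)

print("assigned class sizes:", assignment["class_label"].value_counts().to_dict())
print(f"recovery of true classes: {(assignment['class_label'] == truth).mean():.1%}")

perm = pm.monte_carlo_inertia_test(
    features, assignment["class_label"].to_numpy(), n_permutations=999, seed=0
)
print(f"between-class inertia share: {perm.statistic:.2f} "
      f"(p = {perm.p_value:.4f}, {perm.n_permutations} permutations)")

letters = pm.lsd_groups(
    dsi["dsi"].reindex(assignment.index).to_numpy(),
    assignment["class_label"].to_numpy(),
)
print("\nclass-mean DSI with Fisher-LSD letters (shared letter = not separable):")
print(letters.round(3).to_string(index=False))
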