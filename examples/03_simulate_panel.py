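"""Simulate a small hierarchical trial and inspect infection contrasts.

One genotype per susceptibility class, three blocks, one season; prints
the healthy-vs-infected contrasts the generator is calibrated to.
"""

import pamdsi as pm

spec = pm.DesignSpec(n_genotypes=4, n_seasons=1, n_blocks=3, seed=7)
panel = pm.build_panel(spec, class_sizes={"MR": 1, "MS": 1, "S": 1, "HS": 1})
measurements = pm.simulate_measurements(panel, spec)
fluor = pm.compute_table(measurements)

print(f"{pm.count_design_units(spec)} AOI units per condition per block "
      f"-> {len(measurements)} reading rows")

dark = measurements.drop_duplicates(
    subset=["block", "genotype", "condition", "plant", "leaf", "leaflet", "aoi"]
)
f0 = dark.groupby("condition")["f0"].mean()
fm = dark.groupby("condition")["fm"].mean()
print(f"mean F0: infected/healthy = {f0['infected'] / f0['healthy']:.2f} "
      "(infection elevates minimal fluorescence)")
print(f"mean Fm: healthy/infected = {fm['healthy'] / fm['infected']:.2f} "
      "(infection depresses maximal fluorescence)")

at281 = fluor[fluor.par == 281]
gap = (
    at281.groupby(["class_true", "condition"], observed=True)["yii"].mean()
    .unstack("condition")
)
gap["drop"] = gap["healthy"] - gap["infected"]
print("\nY(II) at PAR 281 by class (healthy-minus-infected gap grows MR -> HS):")
print(gap.loc[["MR", "MS", "S", "HS"]].round(3).to_string())
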