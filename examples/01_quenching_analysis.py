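"""Quenching analysis of a single saturation-pulse reading.

Builds one dark-adapted pair plus three light steps and derives the full
chlorophyll-fluorescence parameter set.
"""

from pamdsi import AOIMeasurement, compute_all

# dark-adapted F0/Fm, then (PAR, Fs, Fm') per actinic step
reading = AOIMeasurement(
    keys={"genotype": "demo", "condition": "healthy"},
    f0=0.2,
    fm=1.0,
    steps=[(0.0, 0.2, 1.0), (111.0, 0.45, 0.75), (336.0, 0.42, 0.56)],
)

rec = compute_all(reading)
print(f"Fv/Fm = {rec.fvfm:.3f}  (max PSII yield; ~0.82 in unstressed leaves)")
for i, par in enumerate(rec.par):
    print(
        f"PAR {par:5.0f}: Y(II)={rec.yii[i]:.3f} Y(NPQ)={rec.ynpq[i]:.3f} "
        f"Y(NO)={rec.yno[i]:.3f}  qP={rec.qp[i]:.3f} NPQ={rec.npq[i]:.3f} "
        f"ETR={rec.etr[i]:6.2f}"
    )
print("The three yields always sum to 1: energy is fully partitioned")
print("between photochemistry, regulated and non-regulated dissipation.")
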