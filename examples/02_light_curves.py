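"""Rapid light curve summaries: empirical rule vs tanh fit.

Generates a noise-free curve from known parameters at the instrument's
13 PAR levels, then recovers them both ways.
"""

import numpy as np

from pamdsi import LightCurve, empirical_summary, fit_tanh, tanh_model
from pamdsi.synthgen import DEFAULT_PAR_LEVELS

true_etr_max, true_ek = 65.66, 458.10  # a moderately-resistant class pair
true_alpha = true_etr_max / true_ek

par = np.asarray(DEFAULT_PAR_LEVELS)
curve = LightCurve(par, tanh_model(par, true_etr_max, true_alpha))

emp = empirical_summary(curve)
fit = fit_tanh(curve)
print(f"truth:     ETR_max={true_etr_max:6.2f}  alpha={true_alpha:.4f}  Ek={true_ek:6.1f}")
print(f"empirical: ETR_max={emp.etr_max:6.2f}  alpha={emp.alpha:.4f}  Ek={emp.ek:6.1f}")
print(f"tanh fit:  ETR_max={fit.etr_max:6.2f}  alpha={fit.alpha:.4f}  Ek={fit.ek:6.1f}")
print()
print("The empirical rule reads ETR_max off the highest observed point, so it")
print("underestimates the tanh asymptote; the nonlinear fit recovers the")
print("generating parameters (and Ek = ETR_max/alpha) to ~0.1%.")
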