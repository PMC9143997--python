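"""Rapid light curves: ETR vs irradiance and their summary parameters.

A rapid light curve (RLC) records the apparent electron transport rate at
a stepwise PAR ramp.  Two summaries are provided:

* the empirical instrument rule — ETR_max is the highest observed ETR and
  alpha the least-squares initial slope through the origin over the first
  few nonzero-PAR points;
* a nonlinear fit of the saturating exponential-free model
  ``ETR = ETR_max * tanh(alpha * PAR / ETR_max)``.

Both report the saturation-onset irradiance E_k = ETR_max / alpha.  The
empirical rule necessarily underestimates the asymptotic ETR_max of a
tanh response (the curve keeps rising beyond the last PAR level), which
is why the fit is preferred for parameter-recovery work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LightCurve",
    "LightCurveFit",
    "tanh_model",
    "initial_slope",
    "empirical_summary",
    "fit_tanh",
    "fit_table",
]


@dataclass(frozen=True)
class LightCurve:
    """Matched PAR / ETR arrays for one AOI or aggregate."""

    par: np.ndarray
    etr: np.ndarray
    key: dict | None = None

    def __post_init__(self):
        par = np.asarray(self.par, dtype=float)
        etr = np.asarray(self.etr, dtype=float)
        if par.shape != etr.shape or par.ndim != 1:
            raise ValueError("par and etr must be matched 1-D arrays")
        order = np.argsort(par)
        par, etr = par[order], etr[order]
        if np.any(np.diff(par) <= 0):
            raise ValueError("par levels must be strictly increasing")
        if np.any(etr < 0):
            raise ValueError("etr must be non-negative")
        object.__setattr__(self, "par", par)
        object.__setattr__(self, "etr", etr)


@dataclass(frozen=True)
class LightCurveFit:
    """ETR_max (umol e- m-2 s-1), alpha (dimensionless slope) and
    E_k = ETR_max/alpha (umol photons m-2 s-1), plus fit diagnostics."""

    etr_max: float
    alpha: float
    ek: float
    method: str
    rss: float = np.nan
    converged: bool = True


def tanh_model(par, etr_max, alpha):
    """Saturating light-response model ETR_max * tanh(alpha*PAR/ETR_max)."""
    par = np.asarray(par, dtype=float)
    return etr_max * np.tanh(alpha * par / etr_max)


def initial_slope(curve: LightCurve, k: int = 3) -> float:
    """Initial slope alpha from a through-origin least-squares line.

    Uses the first ``k`` points with PAR > 0 (fewer if the curve is
    shorter).  An all-zero curve — e.g. a fully necrotic leaf with total
    loss of electron transport — returns 0 with a warning.
    """
    mask = curve.par > 0
    if mask.sum() < 1:
        raise ValueError("need at least one point with par > 0")
    par = curve.par[mask][:k]
    e = curve.etr[mask][:k]
    if np.all(curve.etr == 0):
        warnings.warn("all-zero ETR curve; alpha set to 0", stacklevel=2)
        return 0.0
    return float(par @ e / (par @ par))


def empirical_summary(curve: LightCurve, k: int = 3) -> LightCurveFit:
    """Instrument-style summary: ETR_max = max(ETR), alpha = initial slope.

    E_k = ETR_max/alpha; when alpha is 0 the curve carries no light
    response and E_k is undefined (NaN, flagged non-converged).
    """
    etr_max = float(np.max(curve.etr))
    alpha = initial_slope(curve, k=k)
    if alpha == 0.0:
        warnings.warn("alpha = 0; E_k undefined", stacklevel=2)
        return LightCurveFit(etr_max, 0.0, np.nan, "empirical", converged=False)
    pred = np.minimum(alpha * curve.par, etr_max)  # crude two-piece response
    rss = float(np.sum((curve.etr - pred) ** 2))
    return LightCurveFit(etr_max, alpha, etr_max / alpha, "empirical", rss=rss)


def fit_tanh(curve: LightCurve, k: int = 3, tol: float = 1e-10) -> LightCurveFit:
    """Nonlinear least-squares fit of the tanh light-response model.

    Initialised from the empirical summary, with positivity bounds.  On
    non-convergence (or a degenerate all-zero curve) the empirical values
    are returned with ``converged=False``.
    """
    if len(curve.par) < 4:
        raise ValueError("need at least 4 points to fit")
    if np.all(curve.etr == 0):
        warnings.warn("all-zero ETR curve; falling back to empirical", stacklevel=2)
        emp = empirical_summary(curve, k=k)
        return LightCurveFit(emp.etr_max, emp.alpha, emp.ek, "tanh_fit", converged=False)
    emp = empirical_summary(curve, k=k)
    x0 = np.array(
        [max(emp.etr_max, 1e-6), emp.alpha if emp.alpha > 0 else 1e-3]
    )

    def resid(x):
        return tanh_model(curve.par, x[0], x[1]) - curve.etr

    res = least_squares(
        resid, x0, bounds=([1e-9, 1e-9], [np.inf, np.inf]),
        ftol=tol, xtol=tol, gtol=tol,
    )
    etr_max, alpha = (float(v) for v in res.x)
    rss = float(2 * res.cost)
    if not res.success:
        return LightCurveFit(
            emp.etr_max, emp.alpha, emp.ek, "tanh_fit", rss=rss, converged=False
        )
    return LightCurveFit(etr_max, alpha, etr_max / alpha, "tanh_fit", rss=rss)


def fit_table(
    fluor: pd.DataFrame,
    by: list[str] = ("season", "genotype", "condition"),
    method: str = "empirical",
) -> pd.DataFrame:
    """Summarise light curves per group of a fluorescence parameter table.

    ETR is first averaged over replicate AOIs within each group at each
    PAR level, then summarised with the requested method.  Returns one
    row per group with etr_max, alpha, ek, rss and converged.
    """
    if method not in ("empirical", "tanh"):
        raise ValueError("method must be 'empirical' or 'tanh'")
    by = [c for c in by if c in fluor.columns]
    if not by:
        raise ValueError("no grouping columns present")
    mean_etr = fluor.groupby([*by, "par"], observed=True)["etr"].mean().reset_index()
    rows = []
    for key, grp in mean_etr.groupby(by, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        curve = LightCurve(grp["par"].to_numpy(), grp["etr"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = empirical_summary(curve) if method == "empirical" else fit_tanh(curve)
        rows.append(
            dict(zip(by, key))
            | {
                "etr_max": fit.etr_max,
                "alpha": fit.alpha,
                "ek": fit.ek,
                "method": fit.method,
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
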