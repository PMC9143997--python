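"""Chlorophyll a fluorescence parameters from saturation-pulse readings.

Implements the standard quenching analysis of pulse-amplitude-modulated
(PAM) fluorometry.  A dark-adapted leaf yields the minimal and maximal
fluorescence pair (F0, Fm); each actinic-light step yields the steady-state
fluorescence Fs and the light-adapted maximum Fm' obtained with a
saturating pulse.  From these four observables the module derives

* Fv/Fm      = (Fm - F0) / Fm           maximum PSII quantum yield
* Y(II)      = (Fm' - Fs) / Fm'         effective PSII quantum yield
* Y(NPQ)     = Fs/Fm' - Fs/Fm           regulated heat dissipation
* Y(NO)      = Fs/Fm                    non-regulated dissipation
* qP         = (Fm' - Fs) / (Fm' - Fo') photochemical quenching (puddle)
* qL         = qP * Fo'/Fs              photochemical quenching (lake)
* qN         = 1 - (Fm' - Fo')/(Fm - F0) non-photochemical coefficient
* NPQ        = (Fm - Fm') / Fm'         Stern-Volmer non-photochemical quenching
* ETR        = Y(II) * PAR * 0.5 * 0.84 apparent electron transport rate

The three quantum yields partition absorbed light exactly: their sum is 1
for every valid reading.  Fo', the light-adapted minimal fluorescence, is
rarely measured in imaging protocols and is estimated with the
Oxborough-Baker formula Fo' = F0 / (Fv/Fm + F0/Fm') unless supplied.

All quantities except ETR are dimensionless ratios of fluorescence in
arbitrary units, so every parameter is invariant to rescaling the raw
signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FluorRecord",
    "fv_fm",
    "estimate_fo_prime",
    "yields",
    "quenching",
    "etr",
    "compute_all",
    "compute_table",
    "PSII_FRACTION",
    "LEAF_ABSORPTANCE",
]

#: assumed stoichiometric split of absorbed quanta between the photosystems
PSII_FRACTION = 0.5
#: empirical absorptance of incident light for higher-plant leaves
LEAF_ABSORPTANCE = 0.84

_QP_SLACK = 1e-6  # fp tolerance before a qP outside [0, 1] is suspicious


def fv_fm(f0, fm):
    """Maximum quantum yield of PSII photochemistry, (Fm - F0)/Fm.

    Values of roughly 0.82 and above indicate an unstressed leaf; lower
    values flag photoinhibition or damage.

    Parameters
    ----------
    f0, fm : float or array
        Dark-adapted minimal and maximal fluorescence, ``0 < f0 <= fm``.
    """
    f0 = np.asarray(f0, dtype=float)
    fm = np.asarray(fm, dtype=float)
    if np.any(f0 <= 0) or np.any(fm <= 0):
        raise ValueError("f0 and fm must be positive")
    if np.any(f0 > fm):
        raise ValueError("f0 must not exceed fm")
    out = (fm - f0) / fm
    return out if out.ndim else float(out)


def estimate_fo_prime(f0, fm, fm_prime):
    """Light-adapted minimal fluorescence via the Oxborough-Baker estimator.

    Fo' = F0 / (Fv/Fm + F0/Fm').  Equals F0 when Fm' = Fm (no quenching)
    and decreases monotonically as quenching develops; always <= F0.
    """
    f0 = np.asarray(f0, dtype=float)
    fm = np.asarray(fm, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    if np.any(f0 <= 0) or np.any(f0 >= fm):
        raise ValueError("require 0 < f0 < fm")
    if np.any(fm_prime <= 0) or np.any(fm_prime > fm):
        raise ValueError("require 0 < fm_prime <= fm")
    out = f0 / ((fm - f0) / fm + f0 / fm_prime)
    return out if out.ndim else float(out)


def yields(fs, fm_prime, fm):
    """Quantum-yield partition (Y(II), Y(NPQ), Y(NO)).

    The three complementary fractions of absorbed excitation energy:
    photochemistry, regulated (ΔpH/xanthophyll) heat dissipation, and
    non-regulated dissipation.  They sum to 1 by construction.

    Parameters
    ----------
    fs, fm_prime, fm : float or array
        Steady-state, light-adapted maximal and dark-adapted maximal
        fluorescence with ``0 < fs <= fm_prime <= fm``.
    """
    fs = np.asarray(fs, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    fm = np.asarray(fm, dtype=float)
    if np.any(fs <= 0):
        raise ValueError("fs must be positive")
    if np.any(fs > fm_prime) or np.any(fm_prime > fm):
        raise ValueError("require fs <= fm_prime <= fm")
    yii = (fm_prime - fs) / fm_prime
    yno = fs / fm
    ynpq = fs / fm_prime - yno
    if yii.ndim:
        return yii, ynpq, yno
    return float(yii), float(ynpq), float(yno)


def quenching(fs, fm_prime, fo_prime, fm, f0):
    """Quenching coefficients (qP, qL, qN, NPQ).

    qP is the puddle-model fraction of open PSII centers,
    qL = qP * Fo'/Fs its lake-model counterpart, qN the classical
    non-photochemical coefficient and NPQ the Stern-Volmer magnitude.
    qP is clamped to [0, 1]; excursions beyond floating-point noise
    trigger a data-quality warning.
    """
    fs = np.asarray(fs, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    fo_prime = np.asarray(fo_prime, dtype=float)
    fm = np.asarray(fm, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if np.any(fo_prime >= fm_prime):
        raise ValueError("fo_prime must be below fm_prime")
    if np.any(fs <= 0) or np.any(fs > fm_prime) or np.any(fm_prime > fm):
        raise ValueError("require 0 < fs <= fm_prime <= fm")
    if np.any(f0 >= fm):
        raise ValueError("require f0 < fm")
    qp = (fm_prime - fs) / (fm_prime - fo_prime)
    if np.any(qp > 1 + _QP_SLACK) or np.any(qp < -_QP_SLACK):
        warnings.warn(
            "qP outside [0, 1] beyond floating-point tolerance; "
            "check Fs/Fo' consistency",
            stacklevel=2,
        )
    qp = np.clip(qp, 0.0, 1.0)
    # fs >= fo' for consistent readings; the dark limit fs = fo' makes
    # ql = qp exactly, so the same fp clamp applies
    ql = np.clip(qp * fo_prime / fs, 0.0, 1.0)
    qn = 1.0 - (fm_prime - fo_prime) / (fm - f0)
    npq = (fm - fm_prime) / fm_prime
    if qp.ndim:
        return qp, ql, qn, npq
    return float(qp), float(ql), float(qn), float(npq)


def etr(yii, par):
    """Apparent electron transport rate, Y(II) x PAR x 0.5 x 0.84.

    0.5 assumes equal excitation of the two photosystems and 0.84 is the
    canonical leaf absorptance; the result is in umol electrons m-2 s-1.
    """
    yii = np.asarray(yii, dtype=float)
    par = np.asarray(par, dtype=float)
    out = yii * par * PSII_FRACTION * LEAF_ABSORPTANCE
    return out if out.ndim else float(out)


@dataclass
class FluorRecord:
    """Derived fluorescence parameters for one AOI across all PAR steps."""

    keys: dict = field(default_factory=dict)
    fvfm: float = np.nan
    par: np.ndarray = None
    fo_prime: np.ndarray = None
    yii: np.ndarray = None
    ynpq: np.ndarray = None
    yno: np.ndarray = None
    qp: np.ndarray = None
    ql: np.ndarray = None
    qn: np.ndarray = None
    npq: np.ndarray = None
    etr: np.ndarray = None

    @property
    def n_steps(self) -> int:
        return 0 if self.par is None else len(self.par)


def compute_all(measurement, fo_prime=None) -> FluorRecord:
    """Full quenching analysis for a single AOI measurement.

    ``measurement`` is any object with scalar attributes ``f0`` and ``fm``
    and a ``steps`` sequence of (par, fs, fm_prime) triples (such as
    :class:`pamdsi.synthgen.AOIMeasurement`).  ``fo_prime`` optionally
    supplies measured Fo' per step, overriding the Oxborough-Baker
    estimate.
    """
    keys = dict(getattr(measurement, "keys", {}) or {})
    f0 = float(measurement.f0)
    fm = float(measurement.fm)
    steps = np.asarray([(p, fs, fmp) for p, fs, fmp in measurement.steps], dtype=float)
    par, fs, fm_prime = steps.T
    try:
        fvfm_val = fv_fm(f0, fm)
        if fo_prime is None:
            fop = estimate_fo_prime(f0, fm, fm_prime)
        else:
            fop = np.asarray(fo_prime, dtype=float)
        yii, ynpq, yno = yields(fs, fm_prime, fm)
        qp, ql, qn, npq = quenching(fs, fm_prime, fop, fm, f0)
    except ValueError as exc:
        raise ValueError(f"invalid measurement {keys or '(no keys)'}: {exc}") from exc
    return FluorRecord(
        keys=keys,
        fvfm=fvfm_val,
        par=par,
        fo_prime=np.atleast_1d(fop),
        yii=np.atleast_1d(yii),
        ynpq=np.atleast_1d(ynpq),
        yno=np.atleast_1d(yno),
        qp=np.atleast_1d(qp),
        ql=np.atleast_1d(ql),
        qn=np.atleast_1d(qn),
        npq=np.atleast_1d(npq),
        etr=np.atleast_1d(etr(yii, par)),
    )


def compute_table(df: pd.DataFrame, fo_prime_column: str | None = None) -> pd.DataFrame:
    """Vectorised quenching analysis over a long-format reading table.

    Expects one row per AOI x PAR step with columns ``f0, fm, par, fs,
    fm_prime`` (the synthgen/imaging schema); all other columns are
    carried through unchanged.  Returns the table with the derived
    parameter columns ``fvfm, fo_prime, yii, ynpq, yno, qp, ql, qn, npq,
    etr`` appended.
    """
    required = {"f0", "fm", "par", "fs", "fm_prime"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    f0 = out["f0"].to_numpy(float)
    fm = out["fm"].to_numpy(float)
    fs = out["fs"].to_numpy(float)
    fm_prime = out["fm_prime"].to_numpy(float)
    par = out["par"].to_numpy(float)

    out["fvfm"] = fv_fm(f0, fm)
    if fo_prime_column is not None:
        fop = out[fo_prime_column].to_numpy(float)
    else:
        fop = estimate_fo_prime(f0, fm, fm_prime)
    out["fo_prime"] = fop
    yii, ynpq, yno = yields(fs, fm_prime, fm)
    out["yii"], out["ynpq"], out["yno"] = yii, ynpq, yno
    qp, ql, qn, npq = quenching(fs, fm_prime, fop, fm, f0)
    out["qp"], out["ql"], out["qn"], out["npq"] = qp, ql, qn, npq
    out["etr"] = etr(yii, par)
    return out
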