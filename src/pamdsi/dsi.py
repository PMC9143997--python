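"""Disease Susceptibility Index (DSI) from healthy/infected contrasts.

The DSI scores each genotype's susceptibility on [0, 1] from a set of
chlorophyll-fluorescence variables measured on healthy (HL) and infected
(AL) leaves:

1. For each variable, genotype x condition means are pooled (HL and AL
   together), divided by the geometric mean of the experiment, and
   min-max rescaled to [0, 1].  Pooling the two conditions keeps them on
   one scale so the infection drop remains visible.
2. Variables where a high value signals damage (F0, qN, Y(NPQ), Y(NO) by
   default) are reflected (x -> 1 - x) so that "more is better" holds
   for every oriented variable.
3. Two sub-indices per genotype and variable:
   SI1 = max over genotypes of the healthy value minus the genotype's
   healthy value (the healthy-performance deficit), and
   SI2 = healthy minus infected value (the infection drop).
4. The raw score sums SI1 + SI2 over all variables; a final min-max over
   genotypes gives the per-season DSI in [0, 1].  Seasonal indices are
   averaged to a pooled DSI, absorbing season-to-season differences in
   disease pressure.

Note the geometric-mean ratio step is affine-equivalent to a rescaling
and is therefore a no-op under the subsequent min-max; it is retained
for fidelity to the published construction (and asserted as such in the
test suite).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "LESS_IS_BETTER_DEFAULT",
    "direction_for",
    "aoi_variable_table",
    "genotype_condition_means",
    "standardize",
    "orient",
    "sub_index_1",
    "sub_index_2",
    "compute_dsi",
    "dsi_pipeline",
]

#: variables for which an elevated value is a damage signature
LESS_IS_BETTER_DEFAULT = frozenset({"f0", "qn", "ynpq", "yno"})

#: the ten dark/light-adapted summary parameters of the default set
SUMMARY_VARIABLES = ("f0", "fm", "fvfm", "yii", "ynpq", "yno", "npq", "qn", "qp", "ql")

_AOI_KEYS = ("season", "block", "genotype", "condition", "plant", "leaf", "leaflet", "aoi")


def direction_for(variable: str, less_is_better=LESS_IS_BETTER_DEFAULT) -> str:
    """Default orientation of a variable name."""
    return "less_is_better" if variable in less_is_better else "more_is_better"


def aoi_variable_table(fluor: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-step parameter table to one row of variables per AOI.

    Dark parameters (f0, fm, fvfm) are constant within an AOI; the
    light-adapted parameters are averaged over the PAR steps with PAR >
    0; ETR is kept at every PAR level as its own variable (``etr_par_0``
    ... ``etr_par_701``), tracing the whole light-response curve.
    """
    keys = [k for k in _AOI_KEYS if k in fluor.columns]
    extra = [c for c in ("class_true",) if c in fluor.columns]
    dark = fluor.groupby(keys, observed=True, sort=False)[
        ["f0", "fm", "fvfm"] + extra
    ].first()
    light_cols = ["yii", "ynpq", "yno", "npq", "qn", "qp", "ql"]
    light = (
        fluor[fluor["par"] > 0]
        .groupby(keys, observed=True, sort=False)[light_cols]
        .mean()
    )
    etr_wide = fluor.pivot_table(
        index=keys, columns="par", values="etr", observed=True
    )
    etr_wide.columns = [f"etr_par_{int(p)}" for p in etr_wide.columns]
    out = dark.join(light).join(etr_wide).reset_index()
    return out


def genotype_condition_means(
    fluor: pd.DataFrame,
    variables: list[str] | None = None,
    season: int | None = None,
) -> pd.DataFrame:
    """Genotype x condition means of each variable (a variable panel).

    ``fluor`` is either a per-step parameter table (in which case the
    default AOI variable set is built first) or an AOI-level variable
    table.  Returns a frame indexed by genotype with a (variable,
    condition) column MultiIndex.  Errors if any genotype lacks one of
    the two leaf conditions.
    """
    df = fluor
    if season is not None:
        if "season" not in df.columns:
            raise ValueError("no season column to filter on")
        df = df[df["season"] == season]
        if df.empty:
            raise ValueError(f"no records for season {season}")
    if "par" in df.columns:
        df = aoi_variable_table(df)
    if variables is None:
        variables = [
            c for c in df.columns
            if c in SUMMARY_VARIABLES or c.startswith("etr_par_")
        ]
    if not variables:
        raise ValueError("empty variable list")
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    panel = df.groupby(["genotype", "condition"], observed=True)[list(variables)].mean()
    wide = panel.unstack("condition")
    for cond in ("healthy", "infected"):
        bad = (
            wide.loc[:, pd.IndexSlice[:, cond]].isna().any(axis=1)
            if cond in wide.columns.get_level_values(1)
            else pd.Series(True, index=wide.index)
        )
        if bad.any():
            raise ValueError(
                f"genotype(s) missing condition {cond!r}: "
                f"{list(wide.index[bad])[:5]}"
            )
    return wide


def standardize(values) -> np.ndarray:
    """Standardize a positive vector to [0, 1].

    Divides by the geometric mean of the vector, then min-max rescales.
    A constant vector is degenerate (no contrast to score) and maps to
    all zeros with a warning; nonconstant vectors must be strictly
    positive for the geometric-mean step.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if np.ptp(x) == 0:
        warnings.warn("constant variable; standardized to all zeros", stacklevel=2)
        return np.zeros_like(x)
    if np.any(x <= 0):
        raise ValueError("standardize requires strictly positive values")
    ratio = x / gmean(x)
    return (ratio - ratio.min()) / (ratio.max() - ratio.min())


def orient(standardized, direction: str) -> np.ndarray:
    """Orient a standardized vector so that larger always means better."""
    x = np.asarray(standardized, dtype=float)
    if direction == "more_is_better":
        return x
    if direction == "less_is_better":
        return 1.0 - x
    raise ValueError(f"unknown direction {direction!r}")


def sub_index_1(oriented_hl) -> np.ndarray:
    """Healthy-performance deficit: best healthy value minus each genotype's."""
    x = np.asarray(oriented_hl, dtype=float)
    return x.max(axis=0) - x


def sub_index_2(oriented_hl, oriented_al) -> np.ndarray:
    """Infection drop: healthy minus infected oriented value per genotype.

    Negative values (infected leaves outperforming healthy ones) are
    permitted and flow through with their sign.
    """
    hl = np.asarray(oriented_hl, dtype=float)
    al = np.asarray(oriented_al, dtype=float)
    if hl.shape != al.shape:
        raise ValueError("healthy and infected panels are not matched")
    return hl - al


def compute_dsi(
    panels: dict[int, pd.DataFrame],
    directions: dict[str, str] | None = None,
    return_detail: bool = False,
):
    """Disease susceptibility index per genotype, per season and pooled.

    ``panels`` maps season -> variable panel (the output of
    :func:`genotype_condition_means`).  Within each season every
    variable is standardized over the pooled HL/AL values, oriented, and
    scored with SI1 + SI2; the summed raw score is min-max rescaled over
    genotypes to the per-season DSI.  The pooled DSI is the mean across
    seasons.  Higher DSI = more susceptible.
    """
    if not panels:
        raise ValueError("no panels given")
    results = {}
    detail_rows = []
    genotypes = None
    for season, panel in panels.items():
        variables = sorted(panel.columns.get_level_values(0).unique())
        idx = panel.index
        if genotypes is None:
            genotypes = idx
        elif not idx.equals(genotypes):
            raise ValueError("panels disagree on the genotype set")
        raw = np.zeros(len(idx))
        for v in variables:
            hl = panel[(v, "healthy")].to_numpy(float)
            al = panel[(v, "infected")].to_numpy(float)
            std = standardize(np.concatenate([hl, al]))
            direction = (directions or {}).get(v, direction_for(v))
            oriented = orient(std, direction)
            hl_o, al_o = oriented[: len(idx)], oriented[len(idx):]
            si1 = sub_index_1(hl_o)
            si2 = sub_index_2(hl_o, al_o)
            raw += si1 + si2
            if return_detail:
                for gi, gname in enumerate(idx):
                    detail_rows.append(
                        {"season": season, "genotype": gname, "variable": v,
                         "si1": si1[gi], "si2": si2[gi]}
                    )
        if len(idx) < 2 or np.ptp(raw) == 0:
            warnings.warn(
                f"degenerate DSI for season {season}; index set to 0", stacklevel=2
            )
            dsi = np.zeros(len(idx))
        else:
            dsi = (raw - raw.min()) / (raw.max() - raw.min())
        results[season] = pd.DataFrame(
            {"raw": raw, "dsi": dsi}, index=idx
        )
    out = pd.DataFrame(index=genotypes)
    for season, res in results.items():
        out[f"raw_season{season}"] = res["raw"]
        out[f"dsi_season{season}"] = res["dsi"]
    out["dsi"] = out[[c for c in out.columns if c.startswith("dsi_season")]].mean(axis=1)
    if return_detail:
        return out, pd.DataFrame(detail_rows)
    return out


def dsi_pipeline(
    fluor: pd.DataFrame,
    variables: list[str] | None = None,
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """End-to-end DSI from a per-step fluorescence parameter table.

    Splits by season, builds genotype x condition variable panels, and
    computes the per-season and pooled index.
    """
    seasons = sorted(fluor["season"].unique()) if "season" in fluor.columns else [1]
    panels = {
        s: genotype_condition_means(fluor, variables=variables,
                                    season=s if "season" in fluor.columns else None)
        for s in seasons
    }
    return compute_dsi(panels, directions=directions)
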