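"""Synthetic genotype panels and hierarchical PAM measurements.

The field study this package analyses — a two-season randomized block
trial of 59 common-bean genotypes, each with healthy and web-blight
infected leaves measured by Imaging-PAM at 13 PAR levels — did not
deposit raw data, so this module generates panels with the same
hierarchical design and the same qualitative contrasts:

* infected leaves show elevated F0, depressed Fm, depressed Y(II)/qP/ETR
  and elevated Y(NO), with the magnitude scaling with a genotype's latent
  susceptibility;
* genotypes fall into four susceptibility classes (MR, MS, S, HS) of
  increasing severity, with class sizes 6/16/29/8 by default;
* a single multiplicative severity factor distinguishes seasons.

Generative mechanism.  Each genotype carries a latent tanh light
response (ETR_max, alpha) plus Fv/Fm and an NPQ capacity.  Raw readings
are constructed by inverting the derived quantities: Y(II) at each PAR
level follows from the tanh ETR via the ETR formula, NPQ follows a
saturating trajectory, and then

    Fm' = Fm / (1 + NPQ),      Fs = Fm' * (1 - Y(II))

which guarantees 0 < Fs <= Fm' <= Fm and hence internal consistency of
every downstream parameter.  Lognormal multiplicative noise enters at
the plant, leaf and AOI levels.  All randomness is driven by the design
seed; identical inputs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import AOICircle, ImageStack, circular_mask

__all__ = [
    "CLASS_LABELS",
    "DEFAULT_PAR_LEVELS",
    "DEFAULT_CLASS_SIZES",
    "DEFAULT_CLASS_PARAMS",
    "DesignSpec",
    "GenotypeClassParams",
    "AOIMeasurement",
    "build_panel",
    "simulate_measurements",
    "count_design_units",
    "render_parameter_image",
    "simulate_agronomics",
    "measurements_to_aoi_records",
]

#: susceptibility classes in order of increasing severity
CLASS_LABELS = ("MR", "MS", "S", "HS")

#: the instrument's printed PAR ramp (umol photons m-2 s-1)
DEFAULT_PAR_LEVELS = (
    0.0, 1.0, 21.0, 56.0, 111.0, 186.0, 281.0,
    336.0, 396.0, 461.0, 531.0, 611.0, 701.0,
)

DEFAULT_CLASS_SIZES = {"MR": 6, "MS": 16, "S": 29, "HS": 8}


@dataclass(frozen=True)
class DesignSpec:
    """Hierarchical sampling design of a simulated trial.

    Defaults mirror the field layout: 2 seasons x 3 blocks x 59 genotypes
    x 4 plants x 4 leaves x 3 leaflets x 2 AOIs, in both leaf conditions,
    giving 5664 AOI units per condition per block per season.
    """

    n_genotypes: int = 59
    n_seasons: int = 2
    n_blocks: int = 3
    plants_per_genotype: int = 4
    leaves_per_plant: int = 4
    leaflets_per_leaf: int = 3
    aois_per_leaflet: int = 2
    conditions: tuple[str, ...] = ("healthy", "infected")
    par_levels: tuple[float, ...] = DEFAULT_PAR_LEVELS
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_genotypes, self.n_seasons, self.n_blocks,
            self.plants_per_genotype, self.leaves_per_plant,
            self.leaflets_per_leaf, self.aois_per_leaflet,
        )
        if any(int(c) != c or c < 1 for c in counts):
            raise ValueError("all design counts must be integers >= 1")
        if not self.conditions or not set(self.conditions) <= {"healthy", "infected"}:
            raise ValueError("conditions must be a nonempty subset of {healthy, infected}")
        par = np.asarray(self.par_levels, dtype=float)
        if par[0] != 0 or np.any(np.diff(par) <= 0):
            raise ValueError("par_levels must start at 0 and be strictly increasing")


@dataclass(frozen=True)
class GenotypeClassParams:
    """Latent population parameters for one susceptibility class.

    ``infection_severity`` (d, in [0, 1]) drives every infected-leaf
    shift: F0 is multiplied by ``1 + f0_rise * d``, Fm by
    ``1 - fm_drop * d``, ETR_max by ``1 - d``, alpha by
    ``1 - 0.5 * d`` and the NPQ capacity by ``1 - npq_drop * d``.
    Elevated qN and Y(NO) under infection then emerge from the derived
    formulas.  The noise fields are lognormal coefficients of variation
    (or additive SDs for Fv/Fm and severity) at each level of the
    hierarchy.
    """

    class_label: str
    mean_fvfm: float
    etr_max_mu: float
    alpha_mu: float
    npq_capacity: float
    infection_severity: float
    f0_rise: float = 0.88
    fm_drop: float = 0.455
    npq_drop: float = 0.2
    genotype_cv: float = 0.08
    alpha_cv: float = 0.04
    fvfm_sd: float = 0.015
    severity_sd: float = 0.04
    plant_cv: float = 0.06
    leaf_cv: float = 0.04
    aoi_cv: float = 0.03

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.class_label!r}")
        if not 0 < self.mean_fvfm < 1:
            raise ValueError("mean_fvfm must lie in (0, 1)")
        if self.etr_max_mu <= 0 or self.alpha_mu <= 0:
            raise ValueError("etr_max_mu and alpha_mu must be positive")
        if not 0 <= self.infection_severity <= 1:
            raise ValueError("infection_severity must lie in [0, 1]")
        for name in ("genotype_cv", "alpha_cv", "fvfm_sd", "severity_sd",
                     "plant_cv", "leaf_cv", "aoi_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Class latents anchored on the published class summaries: ETR_max and
# E_k class means (alpha = ETR_max / E_k), Fv/Fm below the 0.82 stress
# threshold, NPQ capacity decreasing and infection severity increasing
# with susceptibility.
DEFAULT_CLASS_PARAMS: dict[str, GenotypeClassParams] = {
    "MR": GenotypeClassParams("MR", 0.80, 65.66, 65.66 / 458.10, 1.20, 0.10),
    "MS": GenotypeClassParams("MS", 0.79, 49.40, 49.40 / 365.31, 1.10, 0.30),
    "S": GenotypeClassParams("S", 0.78, 46.84, 46.84 / 358.17, 1.00, 0.50),
    "HS": GenotypeClassParams("HS", 0.76, 19.71, 19.71 / 163.00, 0.90, 0.75),
}


@dataclass
class AOIMeasurement:
    """Raw fluorescence record for one AOI: dark pair + light steps."""

    keys: dict
    f0: float
    fm: float
    steps: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self):
        if not 0 < self.f0 < self.fm:
            raise ValueError("require 0 < f0 < fm")
        for par, fs, fmp in self.steps:
            if not 0 < fs <= fmp <= self.fm:
                raise ValueError(f"invalid step at par={par}: 0 < fs <= fm' <= fm violated")


def count_design_units(spec: DesignSpec) -> int:
    """AOI units per condition per block per season (the study's 5664)."""
    return (
        spec.n_genotypes
        * spec.plants_per_genotype
        * spec.leaves_per_plant
        * spec.leaflets_per_leaf
        * spec.aois_per_leaflet
    )


def default_class_sizes(n_genotypes: int) -> dict[str, int]:
    """Class sizes for a panel of ``n_genotypes``.

    The standard 59-genotype panel uses the observed 6/16/29/8 split;
    other sizes scale those proportions by largest remainder, keeping
    every class represented when there is room for all four.
    """
    if n_genotypes == 59:
        return dict(DEFAULT_CLASS_SIZES)
    weights = np.array([DEFAULT_CLASS_SIZES[c] for c in CLASS_LABELS], dtype=float)
    ideal = n_genotypes * weights / weights.sum()
    sizes = np.floor(ideal).astype(int)
    if n_genotypes >= len(CLASS_LABELS):
        sizes = np.maximum(sizes, 1)
    while sizes.sum() > n_genotypes:
        sizes[np.argmax(sizes)] -= 1
    remainder = ideal - np.floor(ideal)
    while sizes.sum() < n_genotypes:
        order = np.argsort(-remainder)
        bumped = False
        for j in order:
            if sizes.sum() < n_genotypes:
                sizes[j] += 1
                remainder[j] = -1
                bumped = True
                break
        if not bumped:  # pragma: no cover
            sizes[0] += 1
    return {c: int(s) for c, s in zip(CLASS_LABELS, sizes) if s > 0}


def build_panel(
    spec: DesignSpec,
    class_sizes: dict[str, int] | None = None,
    class_params: dict[str, GenotypeClassParams] | None = None,
) -> pd.DataFrame:
    """Draw per-genotype latent parameters from their class populations.

    Returns one row per genotype with its true class, latent healthy-leaf
    light-response parameters and infection severity.  Deterministic
    given ``spec.seed``.
    """
    if class_sizes is None:
        class_sizes = default_class_sizes(spec.n_genotypes)
    class_sizes = dict(class_sizes)
    class_params = dict(DEFAULT_CLASS_PARAMS if class_params is None else class_params)
    total = sum(class_sizes.values())
    if total != spec.n_genotypes:
        raise ValueError(
            f"class sizes sum to {total}, but the design has {spec.n_genotypes} genotypes"
        )
    _check_severity_ordering(class_params, class_sizes)
    rng = np.random.default_rng(spec.seed)
    rows = []
    gid = 0
    for label in CLASS_LABELS:
        n = class_sizes.get(label, 0)
        if n == 0:
            continue
        p = class_params[label]
        etr_max = p.etr_max_mu * _lognormal(rng, p.genotype_cv, n)
        alpha = p.alpha_mu * _lognormal(rng, p.alpha_cv, n)
        fvfm = np.clip(rng.normal(p.mean_fvfm, p.fvfm_sd, n), 0.40, 0.88)
        npq_cap = p.npq_capacity * _lognormal(rng, 0.05, n)
        severity = np.clip(
            rng.normal(p.infection_severity, p.severity_sd, n), 0.02, 0.92
        )
        fm_scale = _lognormal(rng, 0.05, n)
        for i in range(n):
            rows.append(
                {
                    "genotype": f"G{gid:03d}",
                    "class_true": label,
                    "etr_max_h": etr_max[i],
                    "alpha_h": alpha[i],
                    "fvfm_h": fvfm[i],
                    "npq_cap_h": npq_cap[i],
                    "severity": severity[i],
                    "fm_scale": fm_scale[i],
                    "f0_rise": p.f0_rise,
                    "fm_drop": p.fm_drop,
                    "npq_drop": p.npq_drop,
                    "plant_cv": p.plant_cv,
                    "leaf_cv": p.leaf_cv,
                    "aoi_cv": p.aoi_cv,
                    "fvfm_sd": p.fvfm_sd,
                }
            )
            gid += 1
    return pd.DataFrame(rows)


def _check_severity_ordering(class_params, class_sizes):
    present = [c for c in CLASS_LABELS if class_sizes.get(c, 0) > 0]
    sev = [class_params[c].infection_severity for c in present]
    if any(b < a for a, b in zip(sev, sev[1:])):
        raise ValueError("infection severity must be non-decreasing MR -> HS")


def _lognormal(rng, cv, size):
    """Unit-mean lognormal multiplicative noise with coefficient cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def _season_severity_factors(n_seasons: int) -> np.ndarray:
    """One multiplicative disease-intensity factor per season."""
    if n_seasons == 1:
        return np.array([1.0])
    return np.linspace(0.9, 1.1, n_seasons)


def simulate_measurements(panel: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Simulate raw readings for every cell of the design.

    Returns a long-format table with one row per AOI x PAR step and
    columns (season, block, genotype, class_true, plant, leaf, leaflet,
    aoi, condition, f0, fm, par, fs, fm_prime).
    """
    if len(panel) != spec.n_genotypes:
        raise ValueError("panel size does not match the design")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    S, B, G = spec.n_seasons, spec.n_blocks, spec.n_genotypes
    C = len(spec.conditions)
    P, L, F, A = (
        spec.plants_per_genotype, spec.leaves_per_plant,
        spec.leaflets_per_leaf, spec.aois_per_leaflet,
    )
    dims = (S, B, G, C, P, L, F, A)
    n_units = int(np.prod(dims))
    idx = np.arange(n_units)
    digits = []
    rem = idx
    for d in dims[::-1]:
        digits.append(rem % d)
        rem = rem // d
    a_i, f_i, l_i, p_i, c_i, g_i, b_i, s_i = digits

    g = panel.iloc[g_i].reset_index(drop=True)
    infected = np.array([spec.conditions[c] == "infected" for c in c_i])

    season_fac = _season_severity_factors(S)[s_i]
    d_eff = np.where(infected, np.clip(g["severity"].to_numpy() * season_fac, 0.0, 0.95), 0.0)

    # hierarchical lognormal growth factors shared at plant and leaf level
    plant_group = idx // (L * F * A)
    leaf_group = idx // (F * A)
    z_plant = rng.standard_normal(S * B * G * C * P)[plant_group]
    z_leaf = rng.standard_normal(S * B * G * C * P * L)[leaf_group]
    z_aoi = rng.standard_normal(n_units)
    growth = (
        _scaled_ln(z_plant, g["plant_cv"].to_numpy())
        * _scaled_ln(z_leaf, g["leaf_cv"].to_numpy())
        * _scaled_ln(z_aoi, g["aoi_cv"].to_numpy())
    )

    etr_max_u = g["etr_max_h"].to_numpy() * growth * (1.0 - d_eff)
    alpha_u = (
        g["alpha_h"].to_numpy()
        * _scaled_ln(rng.standard_normal(n_units), 0.03)
        * (1.0 - 0.5 * d_eff)
    )
    npq_cap_u = (
        g["npq_cap_h"].to_numpy()
        * _scaled_ln(rng.standard_normal(n_units), 0.05)
        * (1.0 - g["npq_drop"].to_numpy() * d_eff)
    )

    fvfm_u = np.clip(
        g["fvfm_h"].to_numpy() + rng.normal(0.0, 1.0, n_units) * g["fvfm_sd"].to_numpy(),
        0.40, 0.88,
    )
    fm_healthy = g["fm_scale"].to_numpy() * _scaled_ln(rng.standard_normal(n_units), 0.08)
    fm_u = fm_healthy * (1.0 - g["fm_drop"].to_numpy() * d_eff)
    f0_u = fm_healthy * (1.0 - fvfm_u) * (1.0 + g["f0_rise"].to_numpy() * d_eff)
    f0_u = np.minimum(f0_u, 0.95 * fm_u)

    par = np.asarray(spec.par_levels, dtype=float)
    K = len(par)
    npq_steps = npq_cap_u[:, None] * (1.0 - np.exp(-par[None, :] / 250.0))
    fm_prime = fm_u[:, None] / (1.0 + npq_steps)
    fvfm_eff = 1.0 - f0_u / fm_u
    with np.errstate(divide="ignore", invalid="ignore"):
        etr_steps = etr_max_u[:, None] * np.tanh(
            alpha_u[:, None] * par[None, :] / etr_max_u[:, None]
        )
        yii_steps = np.where(
            par[None, :] > 0,
            etr_steps / (0.42 * np.where(par[None, :] > 0, par[None, :], 1.0)),
            fvfm_eff[:, None],
        )
    # photochemical ceiling: Y(II) cannot exceed 1 - Fo'/Fm' (qP <= 1);
    # severely diseased leaves hit it at low PAR
    yii_ceiling = (
        fvfm_eff[:, None] * fm_prime / (fvfm_eff[:, None] * fm_prime + f0_u[:, None])
    )
    yii_steps = np.where(
        par[None, :] > 0,
        np.minimum(yii_steps, 0.99 * yii_ceiling),
        yii_steps,
    )
    yii_steps = np.clip(yii_steps, 1e-9, 0.95)
    fs = fm_prime * (1.0 - yii_steps)

    out = pd.DataFrame(
        {
            "season": np.repeat(s_i + 1, K),
            "block": np.repeat(b_i + 1, K),
            "genotype": np.repeat(g["genotype"].to_numpy(), K),
            "class_true": np.repeat(g["class_true"].to_numpy(), K),
            "plant": np.repeat(p_i + 1, K),
            "leaf": np.repeat(l_i + 1, K),
            "leaflet": np.repeat(f_i + 1, K),
            "aoi": np.repeat(a_i + 1, K),
            "condition": np.repeat(np.asarray(spec.conditions)[c_i], K),
            "f0": np.repeat(f0_u, K),
            "fm": np.repeat(fm_u, K),
            "par": np.tile(par, n_units),
            "fs": fs.ravel(),
            "fm_prime": fm_prime.ravel(),
        }
    )
    return out


def _scaled_ln(z, cv):
    """Unit-mean lognormal factor from standard-normal draws."""
    cv = np.asarray(cv, dtype=float)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(sigma * z - 0.5 * sigma**2)


def measurements_to_aoi_records(df: pd.DataFrame) -> list[AOIMeasurement]:
    """Regroup a long measurement table into AOIMeasurement objects."""
    keys = [
        c for c in ("season", "block", "genotype", "plant", "leaf", "leaflet",
                    "aoi", "condition")
        if c in df.columns
    ]
    records = []
    for key, grp in df.groupby(keys, observed=True, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        grp = grp.sort_values("par")
        records.append(
            AOIMeasurement(
                keys=dict(zip(keys, key)),
                f0=float(grp["f0"].iloc[0]),
                fm=float(grp["fm"].iloc[0]),
                steps=list(zip(grp["par"], grp["fs"], grp["fm_prime"])),
            )
        )
    return records


def render_parameter_image(
    values: dict[str, float],
    lesion_fraction: float = 0.0,
    shape: tuple[int, int] = (480, 640),
    aois: list[AOICircle] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 0.0,
) -> ImageStack:
    """Render synthetic parameter maps with circular AOIs and lesions.

    Each channel is filled with ``background`` outside the AOIs; AOI
    pixels take the channel's value plus Gaussian pixel noise.  A
    ``lesion_fraction`` of AOI pixels (shared across channels, as
    necrosis is spatial) is set to exactly 0, emulating the black
    necrotic patches of heavily infected leaves.
    """
    if not 0 <= lesion_fraction <= 1:
        raise ValueError("lesion_fraction must lie in [0, 1]")
    if aois is None:
        aois = default_aoi_layout(shape)
    rng = np.random.default_rng(seed)
    union = np.zeros(shape, dtype=bool)
    for circle in aois:
        union |= circular_mask(circle, shape)
    lesion = union & (rng.random(shape) < lesion_fraction)
    channels = {}
    for name, value in values.items():
        arr = np.full(shape, float(background))
        vals = np.full(int(union.sum()), float(value))
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, vals.size)
        arr[union] = vals
        arr[lesion] = 0.0
        channels[name] = np.clip(arr, 0.0, None)
    return ImageStack(channels)


def default_aoi_layout(
    shape: tuple[int, int] = (480, 640),
    leaflets: int = 3,
    aois_per_leaflet: int = 2,
    radius: float = 15.0,
) -> list[AOICircle]:
    """Two AOIs centred on each of three leaflets across the frame."""
    h, w = shape
    circles = []
    for li in range(leaflets):
        cx = (li + 1) * w / (leaflets + 1)
        for ai in range(aois_per_leaflet):
            cy = (ai + 1) * h / (aois_per_leaflet + 1)
            circles.append(AOICircle(cx, cy, radius, leaflet_id=li + 1, aoi_index=ai + 1))
    return circles


# Class-mean agronomic profiles (grams per plant for biomass, counts for
# seeds, degC for leaf temperature) reflecting decreasing shoot biomass
# and pod set with susceptibility, elevated root biomass in MS/HS, and a
# roughly twofold MR-vs-HS canopy-biomass ratio.
_AGRO_CLASS_MEANS = {
    "MR": dict(root=1.05, stem=8.45, leaf=8.62, flower_bud=0.01, flower=0.04,
               pod=4.60, viable_seeds=4.8, nonviable_seeds=0.6,
               leaf_temp=28.0, cci=42.0, gs=220.0),
    "MS": dict(root=2.10, stem=7.12, leaf=9.26, flower_bud=0.04, flower=0.34,
               pod=3.36, viable_seeds=4.2, nonviable_seeds=0.9,
               leaf_temp=28.8, cci=40.0, gs=200.0),
    "S": dict(root=1.40, stem=5.35, leaf=7.80, flower_bud=0.01, flower=0.05,
              pod=0.72, viable_seeds=3.0, nonviable_seeds=1.4,
              leaf_temp=29.6, cci=38.0, gs=170.0),
    "HS": dict(root=1.55, stem=3.48, leaf=5.87, flower_bud=0.01, flower=0.10,
               pod=0.34, viable_seeds=2.2, nonviable_seeds=2.0,
               leaf_temp=30.5, cci=36.0, gs=150.0),
}
# canopy biomass as multiple of the shoot-component sum, per class
_CANOPY_RATIO = {"MR": 1.058, "MS": 0.982, "S": 1.093, "HS": 1.112}
_AMBIENT_TEMP_MEAN = 26.5


def simulate_agronomics(panel: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """One agronomic/environment record per genotype.

    Biomass components get multiplicative lognormal noise around their
    class means; the leaf temperature differential is computed exactly as
    LTD = leaf temperature - ambient temperature.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    rows = []
    for _, gp in panel.iterrows():
        m = _AGRO_CLASS_MEANS[gp["class_true"]]
        noise = lambda cv=0.15: float(_lognormal(rng, cv, 1)[0])
        root = m["root"] * noise()
        stem = m["stem"] * noise()
        leaf = m["leaf"] * noise()
        bud = m["flower_bud"] * noise(0.3)
        flower = m["flower"] * noise(0.3)
        pod = m["pod"] * noise()
        canopy = (stem + leaf + bud + flower + pod) * _CANOPY_RATIO[gp["class_true"]] * noise(0.03)
        leaf_temp = m["leaf_temp"] + rng.normal(0.0, 0.6)
        ambient = _AMBIENT_TEMP_MEAN + rng.normal(0.0, 0.5)
        rows.append(
            {
                "genotype": gp["genotype"],
                "class_true": gp["class_true"],
                "root_biomass": root,
                "stem_biomass": stem,
                "leaf_biomass": leaf,
                "flower_bud_biomass": bud,
                "flower_biomass": flower,
                "pod_biomass": pod,
                "canopy_biomass": canopy,
                "viable_seeds": max(0.0, m["viable_seeds"] + rng.normal(0.0, 0.4)),
                "nonviable_seeds": max(0.0, m["nonviable_seeds"] + rng.normal(0.0, 0.3)),
                "leaf_temp": leaf_temp,
                "ambient_temp": ambient,
                "rh": float(np.clip(84.0 + rng.normal(0.0, 3.0), 40.0, 100.0)),
                "ltd": leaf_temp - ambient,
                "cci": m["cci"] + rng.normal(0.0, 2.0),
                "gs": max(10.0, m["gs"] + rng.normal(0.0, 20.0)),
            }
        )
    return pd.DataFrame(rows)
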