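"""Genotype typologies and the supporting multivariate statistics.

Genotypes are grouped into four susceptibility classes — moderately
resistant (MR), moderately susceptible (MS), susceptible (S) and highly
susceptible (HS) — by Ward agglomerative clustering on z-scored
fluorescence summaries plus the DSI, with cluster labels ordered by
ascending class-mean DSI.  The module also provides a correlation-matrix
PCA with per-variable contributions, a Monte-Carlo permutation test of
between-class inertia, Fisher-LSD compact letter displays, and starred
Pearson correlation matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr, t as t_dist

from .synthgen import CLASS_LABELS

__all__ = [
    "zscore_features",
    "build_feature_matrix",
    "ward_cluster",
    "label_classes",
    "PCAResult",
    "pca",
    "PermutationTestResult",
    "monte_carlo_inertia_test",
    "lsd_groups",
    "PearsonResult",
    "pearson_matrix",
]


def zscore_features(features: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column; constant columns are dropped with a warning."""
    X = features.astype(float)
    sd = X.std(ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"dropping constant feature(s): {list(constant)}", stacklevel=2)
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    if X.shape[1] == 0:
        raise ValueError("no non-constant features left")
    return (X - X.mean()) / sd


def build_feature_matrix(
    fluor: pd.DataFrame,
    dsi: pd.Series,
    variables=None,
    include_levels: bool = False,
) -> pd.DataFrame:
    """Genotype-level feature matrix for clustering and ordination.

    The susceptibility typologies are defined by how a genotype responds
    to infection, so the default features are the pooled DSI plus the
    per-variable infection drop (healthy-mean minus infected-mean) of
    each fluorescence summary.  Absolute healthy/infected levels carry
    genotype background unrelated to susceptibility and blur adjacent
    classes; set ``include_levels=True`` to add them as extra features.
    All features are z-scored.
    """
    from .dsi import SUMMARY_VARIABLES, aoi_variable_table

    df = fluor
    if "par" in df.columns:
        df = aoi_variable_table(df)
    if variables is None:
        variables = [v for v in SUMMARY_VARIABLES if v in df.columns]
        variables += [c for c in df.columns if c == "etr_par_281"]
    means = (
        df.groupby(["genotype", "condition"], observed=True)[list(variables)]
        .mean()
        .unstack("condition")
    )
    wide = pd.DataFrame(
        {
            f"{v}_drop": means[(v, "healthy")] - means[(v, "infected")]
            for v in variables
        }
    )
    if include_levels:
        for v in variables:
            for cond in ("healthy", "infected"):
                wide[f"{v}_{cond}"] = means[(v, cond)]
    wide["dsi"] = dsi.reindex(wide.index)
    if wide["dsi"].isna().any():
        raise ValueError("DSI missing for some genotypes")
    return zscore_features(wide)


def ward_cluster(features: pd.DataFrame, k: int) -> np.ndarray:
    """Ward-linkage agglomerative clustering on Euclidean distances.

    Returns integer cluster ids (1..k), aligned with the feature rows.
    """
    n = len(features)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genotypes ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    Z = linkage(np.asarray(features, dtype=float), method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def label_classes(clusters: np.ndarray, dsi: pd.Series) -> pd.DataFrame:
    """Order clusters by ascending mean DSI and name them MR/MS/S/HS.

    Requires exactly four clusters.  Equal class means are broken by
    descending cluster size, with a warning.  Returns a frame indexed by
    genotype with columns ``cluster``, ``class_label`` and
    ``class_mean_dsi``.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(dsi):
        raise ValueError("clusters and dsi are not aligned")
    ids = np.unique(clusters)
    if len(ids) != len(CLASS_LABELS):
        raise ValueError(f"expected {len(CLASS_LABELS)} clusters, got {len(ids)}")
    means = {c: float(dsi[clusters == c].mean()) for c in ids}
    sizes = {c: int((clusters == c).sum()) for c in ids}
    if len({round(m, 12) for m in means.values()}) < len(ids):
        warnings.warn("tied cluster mean DSI; breaking ties by size", stacklevel=2)
    order = sorted(ids, key=lambda c: (means[c], -sizes[c], c))
    name = {c: CLASS_LABELS[i] for i, c in enumerate(order)}
    return pd.DataFrame(
        {
            "cluster": clusters,
            "class_label": [name[c] for c in clusters],
            "class_mean_dsi": [means[c] for c in clusters],
        },
        index=dsi.index,
    )


@dataclass
class PCAResult:
    """Correlation-matrix PCA: scores, orthonormal loadings, variance
    fractions and per-variable contributions (% per axis; the reference
    threshold 100/p is the expected contribution under equal weighting)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray
    contributions: pd.DataFrame
    threshold: float


def pca(features: pd.DataFrame) -> PCAResult:
    """Eigendecomposition of the feature correlation matrix."""
    X = zscore_features(features)
    n, p = X.shape
    if p < 2 or n < 3:
        raise ValueError("need at least 2 features and 3 observations")
    corr = np.corrcoef(X.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude element of each axis positive
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(p)])
    eigvec = eigvec * flip
    axes = [f"PC{i+1}" for i in range(p)]
    scores = pd.DataFrame(X.to_numpy() @ eigvec, index=X.index, columns=axes)
    loadings = pd.DataFrame(eigvec, index=X.columns, columns=axes)
    contributions = pd.DataFrame(100.0 * eigvec**2, index=X.columns, columns=axes)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained=eigval / eigval.sum(),
        contributions=contributions,
        threshold=100.0 / p,
    )


@dataclass(frozen=True)
class PermutationTestResult:
    """Between-class inertia share and its Monte-Carlo permutation p-value."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int


def _between_share(X: np.ndarray, labels: np.ndarray) -> float:
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    if total == 0:
        return 0.0
    between = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        between += len(sub) * float(((sub.mean(axis=0) - grand) ** 2).sum())
    return between / total


def monte_carlo_inertia_test(
    features: pd.DataFrame,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of class separation in feature space.

    The statistic is the between-class share of total inertia (sum of
    squares), in [0, 1].  Class labels are permuted ``n_permutations``
    times; the p-value is (1 + #{permuted >= observed}) /
    (n_permutations + 1), so its smallest attainable value is
    1/(n_permutations + 1).
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    observed = _between_share(X, labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    grand = X.mean(axis=0)
    Xc = X - grand
    total = float((Xc**2).sum())
    between = np.zeros(n_permutations)
    if total > 0:
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            # class sums under every permutation at once
            sums = Xc[perms[:, members]].sum(axis=1)
            between += (sums**2).sum(axis=1) / len(members)
    permuted = between / total if total > 0 else between
    p = (1.0 + np.count_nonzero(permuted >= observed)) / (n_permutations + 1.0)
    return PermutationTestResult(observed, float(p), n_permutations, seed)


def lsd_groups(values, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Fisher's protected LSD with a compact letter display.

    One-way ANOVA supplies the pooled error mean square; each pair of
    groups is compared with the least significant difference at level
    ``alpha``.  Groups sharing a letter are not significantly different.
    Returns one row per group (sorted by descending mean) with n, mean,
    se and letters; the display is a deterministic function of the group
    means, MSE, sizes and alpha.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: values[labels == g] for g in groups}
    if any(len(v) < 2 for v in data.values()):
        raise ValueError("each group needs at least 2 observations")
    ns = {g: len(v) for g, v in data.items()}
    means = {g: float(v.mean()) for g, v in data.items()}
    N, k = len(values), len(groups)
    sse = sum(float(((v - means[g]) ** 2).sum()) for g, v in data.items())
    df = N - k
    mse = sse / df
    if mse == 0:
        raise ValueError("zero within-group variance; LSD undefined")
    tcrit = t_dist.ppf(1 - alpha / 2, df)

    ordered = sorted(groups, key=lambda g: (-means[g], str(g)))
    different = {
        (a, b): abs(means[a] - means[b])
        > tcrit * np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
        for a, b in combinations(ordered, 2)
    }

    def compatible(subset):
        return all(
            not different.get((a, b), different.get((b, a), False))
            for a, b in combinations(subset, 2)
        )

    # maximal cliques of the "not significantly different" graph
    cliques = []
    for size in range(k, 0, -1):
        for subset in combinations(ordered, size):
            if compatible(subset) and not any(
                set(subset) <= set(c) for c in cliques
            ):
                cliques.append(subset)
    cliques.sort(key=lambda c: ordered.index(c[0]))
    letters = {g: "" for g in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in clique:
            letters[g] += letter
    return pd.DataFrame(
        {
            "group": ordered,
            "n": [ns[g] for g in ordered],
            "mean": [means[g] for g in ordered],
            "se": [float(np.sqrt(mse / ns[g])) for g in ordered],
            "letters": [letters[g] for g in ordered],
        }
    )


@dataclass
class PearsonResult:
    """Pairwise Pearson correlations with two-sided p-values and stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_matrix(table: pd.DataFrame) -> PearsonResult:
    """Starred correlation matrix over pairwise-complete observations.

    Significance stars mark two-sided p-values below 0.05 (*), 0.01 (**)
    and 0.001 (***).  A constant variable has no defined correlation and
    yields NaN with a warning.
    """
    cols = list(table.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    warned = set()
    for a, b in combinations(cols, 2):
        sub = table[[a, b]].dropna()
        xa, xb = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if len(sub) < 3:
            raise ValueError(f"need >= 3 paired observations for ({a}, {b})")
        undefined = [c for c, x in ((a, xa), (b, xb)) if np.ptp(x) == 0]
        if undefined:
            for c in undefined:
                if c not in warned:
                    warnings.warn(f"constant variable {c!r}; r undefined", stacklevel=2)
                    warned.add(c)
            rv, pv = np.nan, np.nan
        else:
            rv, pv = pearsonr(xa, xb)
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
    stars = p.map(_stars)
    np.fill_diagonal(stars.values, "")
    return PearsonResult(r=r, p=p, stars=stars)
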