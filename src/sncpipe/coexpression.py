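"""Weighted coexpression network analysis over pooled sncRNA features.

The pooled log-CPM matrix (miRNAs + 5' tRNA halves + 5' YRNA fragments) is
turned into an unsigned weighted network, a_ij = |cor(x_i, x_j)|^beta, and
clustered on topological-overlap dissimilarity.  Modules are colour-labelled
by decreasing size through the conventional palette (largest = turquoise);
unassigned features form the Gray module.  Each module is summarized by its
eigengene (first principal component of the standardized member profiles),
and features are scored by module membership (kME, correlation with the
eigengene) and trait gene significance (absolute correlation with the
binary trait).

Branch cutting is a deliberately simple "hybrid-lite" scheme: the average-
linkage tree is cut at a height fraction that tightens as ``deep_split``
grows, and candidate clusters must both reach the minimum module size and
be internally cohesive (mean within-cluster dissimilarity well below the
cut height) to escape the Gray module.  Fidelity target is planted-module
recovery, not parity with any reference dynamic-tree-cut implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "SoftPowerScan",
    "ModuleAssignment",
    "Eigengenes",
    "mad_filter",
    "adjacency_matrix",
    "scale_free_fit",
    "tom_from_adjacency",
    "cluster_and_cut",
    "module_eigengenes",
    "membership_and_significance",
    "module_trait_stats",
    "mm_gs_scatter_stats",
]

# conventional module palette, assigned by decreasing module size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
]
GRAY = "gray"

_DEEP_SPLIT_CUT_FRACTION = {0: 0.99, 1: 0.96, 2: 0.93, 3: 0.90, 4: 0.87}
# a cluster escapes Gray only if its mean internal dissimilarity is clearly
# below the background (all-pairs) level, or absolutely tight
_COHESION_RATIO = 0.93
_TIGHT_INTRA = 0.50


def mad_filter(matrix: pd.DataFrame, threshold: float = 0.0):
    """Keep features whose median absolute deviation exceeds ``threshold``.

    The variability filter for pooling heterogeneous feature classes;
    MAD > 0 (the default) drops constant features.  Returns
    ``(filtered, n_dropped)``.
    """
    x = np.asarray(matrix, dtype=float)
    mad = np.median(np.abs(x - np.median(x, axis=1, keepdims=True)), axis=1)
    keep = mad > threshold
    if not keep.any():
        raise ValueError("MAD filter removed every feature")
    filtered = matrix.loc[keep] if hasattr(matrix, "loc") else x[keep]
    return filtered, int((~keep).sum())


def adjacency_matrix(matrix, beta: float = 6.0) -> np.ndarray:
    """Unsigned weighted adjacency a_ij = |cor(x_i, x_j)|^beta (diagonal 1)."""
    x = np.asarray(matrix, dtype=float)
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(x)
    cor = np.nan_to_num(cor, nan=0.0)
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return a


@dataclass
class SoftPowerScan:
    table: pd.DataFrame  # per-beta: r_squared, slope, mean_connectivity


def _scale_free_r2(k: np.ndarray, n_bins: int = 10):
    """R^2 and slope of log10 p(k) vs log10 mean(k) over equal-width k bins."""
    k = np.asarray(k, dtype=float)
    if np.ptp(k) < 1e-12:
        return np.nan, np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        freq = sel.mean()
        if mean_k <= 0 or freq <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq))
    if len(xs) < 3:
        return np.nan, np.nan
    res = stats.linregress(xs, ys)
    return float(res.rvalue**2), float(res.slope)


def scale_free_fit(matrix, powers=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12), n_bins: int = 10) -> SoftPowerScan:
    """Scale-free topology fit index and mean connectivity per soft power.

    Connectivity k_i = sum_{j != i} a_ij; the fit is the R^2 of the log-log
    regression of the degree distribution (slope reported with its sign).
    Degenerate all-equal connectivities give NaN.
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 20:
        raise ValueError("need >= 20 features for a meaningful scale-free scan")
    rows = []
    for beta in powers:
        a = adjacency_matrix(x, beta=beta)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope = _scale_free_r2(k, n_bins=n_bins)
        rows.append(
            {"beta": beta, "r_squared": r2, "slope": slope, "mean_connectivity": k.mean()}
        )
    return SoftPowerScan(pd.DataFrame(rows).set_index("beta"))


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, with
    L_ij = sum_{u != i,j} a_iu a_uj and k the connectivity with zeroed
    diagonal; the diagonal is 1 by definition.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a  # L_ij includes u=i,j terms, but a_ii = 0 so they vanish
    num = L + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


@dataclass
class ModuleAssignment:
    labels: pd.Series  # feature -> colour (GRAY = unassigned)
    sizes: pd.Series  # colour -> member count (non-gray)
    linkage: np.ndarray
    cut_height: float

    def members(self, color: str) -> list:
        return list(self.labels.index[self.labels == color])


def cluster_and_cut(
    dissimilarity,
    deep_split: int = 3,
    min_module_size: int = 10,
    feature_ids=None,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with adaptive branch cutting.

    ``deep_split`` in 0..4 maps to a cut-height fraction of the tallest
    merge (higher values cut lower, splitting more aggressively).  Clusters
    below ``min_module_size`` or lacking internal cohesion are sent to the
    Gray module.  Colours are assigned by decreasing module size (ties by
    first feature index).
    """
    if deep_split not in _DEEP_SPLIT_CUT_FRACTION:
        raise ValueError("deep_split must be an integer in 0..4")
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    n = d.shape[0]
    if feature_ids is None:
        feature_ids = pd.RangeIndex(n)
    feature_ids = pd.Index(feature_ids)
    dsym = (d + d.T) / 2.0
    np.fill_diagonal(dsym, 0.0)
    Z = hierarchy.linkage(squareform(dsym, checks=False), method="average")
    hmax = Z[:, 2].max() if len(Z) else 0.0
    cut = _DEEP_SPLIT_CUT_FRACTION[deep_split] * hmax
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance") if n > 1 else np.array([1])

    bg = float(np.median(dsym[np.triu_indices(n, 1)])) if n > 1 else 0.0
    clusters = []
    for cid in np.unique(raw):
        members = np.nonzero(raw == cid)[0]
        if len(members) < max(min_module_size, 2):
            continue
        sub = dsym[np.ix_(members, members)]
        intra = sub[np.triu_indices(len(members), 1)].mean()
        if intra > _COHESION_RATIO * bg and intra > _TIGHT_INTRA:
            continue
        clusters.append((len(members), members.min(), members))
    clusters.sort(key=lambda t: (-t[0], t[1]))

    labels = np.full(n, GRAY, dtype=object)
    sizes = {}
    for rank, (size, _, members) in enumerate(clusters):
        color = (
            MODULE_COLORS[rank]
            if rank < len(MODULE_COLORS)
            else f"module{rank + 1}"
        )
        labels[members] = color
        sizes[color] = size
    return ModuleAssignment(
        labels=pd.Series(labels, index=feature_ids, name="module"),
        sizes=pd.Series(sizes, dtype=int, name="size"),
        linkage=Z,
        cut_height=float(cut),
    )


@dataclass
class Eigengenes:
    eigengenes: pd.DataFrame  # samples x modules
    var_explained: pd.Series  # module -> proportion of variance


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def module_eigengenes(matrix, labels: pd.Series) -> Eigengenes:
    """First principal component of each module's standardized profiles.

    The eigengene is sign-oriented so that the mean correlation with its
    member features is nonnegative; variance explained is the leading
    singular value's share.  A size-1 module degenerates to the feature's
    own standardized profile (with a warning).
    """
    import warnings

    x = np.asarray(matrix, dtype=float)
    samples = matrix.columns if hasattr(matrix, "columns") else pd.RangeIndex(x.shape[1])
    labels = pd.Series(labels)
    cols, ve = {}, {}
    for color in [c for c in pd.unique(labels) if c != GRAY]:
        idx = np.nonzero((labels == color).to_numpy())[0]
        if len(idx) == 1:
            warnings.warn(f"module {color!r} has a single feature", stacklevel=2)
            e = _standardize_rows(x[idx])[0]
            cols[color] = e / np.linalg.norm(e)
            ve[color] = 1.0
            continue
        sub = _standardize_rows(x[idx])
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        e = vt[0]
        cors = np.array([np.corrcoef(row, e)[0, 1] for row in sub])
        if np.nanmean(cors) < 0:
            e = -e
        cols[color] = e
        ve[color] = float(s[0] ** 2 / (s**2).sum())
    eg = pd.DataFrame(cols, index=samples)
    return Eigengenes(eg, pd.Series(ve, name="var_explained"))


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def membership_and_significance(matrix, eigengenes: Eigengenes, trait):
    """Module membership (kME) and trait gene significance per feature.

    MM(feature, module) = Pearson cor(profile, eigengene); GS(feature) =
    |Pearson cor(profile, trait)| with a t-test p on n-2 df.  The signed GS
    is also emitted.  Zero-variance features get NaN (flagged).
    Returns ``(mm_table, gs_table)``.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[1]
    trait = np.asarray(trait, dtype=float)
    if np.ptp(trait) == 0:
        raise ValueError("trait is constant")
    index = matrix.index if hasattr(matrix, "index") else pd.RangeIndex(x.shape[0])
    xs = _standardize_rows(x)
    sd_zero = np.asarray(matrix, dtype=float).std(axis=1) == 0

    eg = eigengenes.eigengenes
    egs = _standardize_rows(eg.to_numpy().T)
    mm = xs @ egs.T / n
    mm[sd_zero] = np.nan
    mm_table = pd.DataFrame(mm, index=index, columns=eg.columns)

    tz = (trait - trait.mean()) / trait.std()
    gs_signed = xs @ tz / n
    gs_signed[sd_zero] = np.nan
    gs = np.abs(gs_signed)
    gs_table = pd.DataFrame(
        {"gs": gs, "gs_signed": gs_signed, "gs_p": _corr_pvalue(gs_signed, n)},
        index=index,
    )
    return mm_table, gs_table


def module_trait_stats(eigengenes: Eigengenes, trait, gs_table=None, labels=None):
    """Pearson correlation (and p) of every module eigengene with the trait.

    If ``gs_table`` and ``labels`` are given, per-module mean GS and mean
    -log10(GS p) bar statistics are appended.
    """
    trait = np.asarray(trait, dtype=float)
    if np.ptp(trait) == 0:
        raise ValueError("trait is constant")
    eg = eigengenes.eigengenes
    n = eg.shape[0]
    rows = []
    for color in eg.columns:
        r = float(np.corrcoef(eg[color].to_numpy(), trait)[0, 1])
        rows.append({"module": color, "r": r, "p": float(_corr_pvalue(np.array([r]), n)[0])})
    out = pd.DataFrame(rows, columns=["module", "r", "p"]).set_index("module")
    if gs_table is not None and labels is not None:
        labels = pd.Series(labels)
        out["mean_gs"] = [
            gs_table.loc[labels[labels == c].index, "gs"].mean() for c in out.index
        ]
        out["mean_neglog10_gs_p"] = [
            -np.log10(np.clip(gs_table.loc[labels[labels == c].index, "gs_p"], 1e-300, None)).mean()
            for c in out.index
        ]
    return out


def mm_gs_scatter_stats(mm_table, gs_table, labels, module: str, classes=None):
    """Correlation between MM and GS over one module's features.

    The scatter-plot statistic for trait-relevant modules.  ``classes``
    (feature -> class tag) selects the non-miRNA member labels reported for
    annotation.  Requires module size >= 3.
    """
    labels = pd.Series(labels)
    members = labels.index[labels == module]
    if len(members) < 3:
        raise ValueError(f"module {module!r} has fewer than 3 features")
    mm = mm_table.loc[members, module].to_numpy()
    gs = gs_table.loc[members, "gs"].to_numpy()
    res = stats.pearsonr(mm, gs)
    annotated = []
    if classes is not None:
        classes = pd.Series(classes)
        annotated = [f for f in members if classes.get(f, "miRNA") != "miRNA"]
    return {
        "module": module,
        "n": len(members),
        "r": float(res.statistic),
        "p": float(res.pvalue),
        "non_mirna_members": annotated,
    }
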