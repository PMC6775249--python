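"""Negative-binomial differential abundance for small-RNA count matrices.

Implements the two designs used for serum and tissue small-RNA studies:

* unpaired two-group comparison: TMM normalization, common/tagwise NB
  dispersion, and the conditional exact test on group sums;
* paired tumour/normal comparison: NB log-linear model with the patient as
  an additive blocking factor, tested by likelihood ratio against chi2(1).

Counts are modelled as NB with variance mu + phi * mu^2; BCV = sqrt(phi).
P-values are adjusted by Benjamini-Hochberg step-up and features are called
significant below an FDR threshold (default 5%).  Sample-level structure is
summarized by classical MDS on leading-log-fold-change distances.

Dispersion is estimated by Cox-Reid adjusted profile likelihood on a grid
(common = maximizer of the summed APL; tagwise = per-feature maximizer of a
weighted sum shrunk toward the common value), which targets simulation
calibration rather than bit-parity with any particular package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "DispersionEstimates",
    "MDSCoordinates",
    "tmm_factors",
    "average_cpm",
    "estimate_dispersion",
    "exact_test",
    "paired_lrt",
    "bh_adjust",
    "significant_set",
    "display_fc",
    "mds_coordinates",
    "de_unpaired",
    "de_paired",
]

_PHI_GRID = np.logspace(-4, 1, 31)


# ---------------------------------------------------------------------------
# normalization

def tmm_factors(
    counts, lib_sizes=None, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    The reference sample is the column whose CPM upper quartile is closest
    to the mean upper quartile.  For every sample, gene-wise log2 ratios M
    against the reference are trimmed (``trim_m`` of M, ``trim_a`` of A,
    split between both tails) and averaged with precision weights; the
    factor is 2 to that mean.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("need a features x samples matrix with >= 2 samples")
    columns = counts.columns if hasattr(counts, "columns") else range(y.shape[1])
    lib = np.asarray(lib_sizes, dtype=float) if lib_sizes is not None else y.sum(axis=0)
    if (lib <= 0).any():
        bad = list(np.asarray(columns)[lib <= 0])
        raise ValueError(f"all-zero / empty sample(s): {bad}")

    uq = np.array([np.quantile(y[:, i] / lib[i], 0.75) for i in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for i in range(y.shape[1]):
        if i == ref:
            continue
        yi, ni = y[:, i], lib[i]
        ok = (yi > 0) & (yr > 0)
        if ok.sum() == 0:
            continue
        pi, pr = yi[ok] / ni, yr[ok] / nr
        m = np.log2(pi / pr)
        a = 0.5 * np.log2(pi * pr)
        w = (ni - yi[ok]) / (ni * yi[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        fin = np.isfinite(m) & np.isfinite(a) & (w > 0)
        m, a, w = m[fin], a[fin], w[fin]
        n = len(m)
        if n == 0:
            continue
        # trim the stated fraction from EACH tail of M and A
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        rank_m = stats.rankdata(m, method="ordinal")
        rank_a = stats.rankdata(a, method="ordinal")
        keep = (
            (rank_m >= lo_m)
            & (rank_m <= n + 1 - lo_m)
            & (rank_a >= lo_a)
            & (rank_a <= n + 1 - lo_a)
        )
        if keep.sum() == 0:
            continue
        factors[i] = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=columns, name="tmm_factor")


def effective_lib_sizes(counts, lib_sizes=None, factors=None) -> np.ndarray:
    y = np.asarray(counts, dtype=float)
    lib = np.asarray(lib_sizes, dtype=float) if lib_sizes is not None else y.sum(axis=0)
    f = np.asarray(factors, dtype=float) if factors is not None else np.ones(y.shape[1])
    return lib * f


def average_cpm(counts, lib_sizes=None, factors=None, prior_count: float = 2.0):
    """Per-feature average log-scale CPM over all libraries (back-transformed).

    CPM uses effective (TMM-scaled) library sizes with a library-size-
    proportional prior count; the average is the mean of per-sample log2 CPM,
    returned on the CPM scale.
    """
    y = np.asarray(counts, dtype=float)
    eff = effective_lib_sizes(counts, lib_sizes, factors)
    prior = prior_count * eff / eff.mean()
    cpm = (y + prior[None, :]) / (eff + 2 * prior)[None, :] * 1e6
    ave = 2.0 ** np.log2(cpm).mean(axis=1)
    if hasattr(counts, "index"):
        return pd.Series(ave, index=counts.index, name="avg_cpm")
    return ave


# ---------------------------------------------------------------------------
# NB GLM machinery (shared by dispersion estimation and the paired test)

def _nb_loglik(y, mu, phi):
    mu = np.clip(mu, 1e-10, None)
    if np.ndim(phi) == 0 and phi < 1e-12:
        return (y * np.log(mu) - mu - gammaln(y + 1)).sum(axis=-1)
    phi = np.asarray(phi, dtype=float)
    r = 1.0 / np.clip(phi, 1e-12, None)
    if r.ndim == 1:
        r = r[:, None]
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=-1)


def _nb_glm_fit(y, X, offset, phi, max_iter: int = 60, tol: float = 1e-9, beta0=None):
    """Batched IRLS fit of an NB log-linear model across features.

    ``y``: (G, n); ``X``: (n, p); ``offset``: (n,); ``phi``: scalar or (G,).
    Returns (beta, ll, info_matrices, converged).
    """
    G, n = y.shape
    p = X.shape[1]
    phi_col = np.asarray(phi, dtype=float)
    phi_col = np.broadcast_to(phi_col, (G,))[:, None] if phi_col.ndim <= 1 else phi_col
    if beta0 is None:
        eta0 = np.log(y + 0.5)
        beta = (np.linalg.pinv(X) @ (eta0 - offset[None, :]).T).T
    else:
        beta = beta0.copy()
    converged = np.zeros(G, dtype=bool)
    A = np.empty((G, p, p))
    for _ in range(max_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -40, 40)
        mu = np.exp(eta)
        W = mu / (1.0 + phi_col * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        A = np.einsum("ni,gn,nj->gij", X, W, X)
        A[:, np.arange(p), np.arange(p)] += 1e-8
        b = np.einsum("gn,ni->gi", W * z, X)
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = new_beta
        converged |= delta < tol
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset[None, :], -40, 40)
    mu = np.exp(eta)
    ll = _nb_loglik(y, mu, np.broadcast_to(np.asarray(phi, float), (G,)))
    W = mu / (1.0 + phi_col * mu)
    A = np.einsum("ni,gn,nj->gij", X, W, X)
    A[:, np.arange(p), np.arange(p)] += 1e-10
    return beta, ll, A, converged


def _group_levels(groups: pd.Series):
    """Two group levels; a Categorical fixes their order explicitly,
    otherwise order of appearance is used (second level = numerator)."""
    if isinstance(groups.dtype, pd.CategoricalDtype):
        levels = [c for c in groups.cat.categories if (groups == c).any()]
    else:
        levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    return levels


def _design_matrices(groups, blocks=None):
    groups = pd.Series(groups)
    levels = _group_levels(groups)
    cond = (groups == levels[1]).to_numpy(float)
    if blocks is None:
        X = np.column_stack([1.0 - cond, cond])  # group means
        return X, None, levels
    blocks = pd.Series(blocks)
    tab = pd.crosstab(blocks, groups)
    if not ((tab == 1).all().all()):
        raise ValueError("paired design requires exactly one sample per group per block")
    blevels = pd.unique(blocks)
    Xb = np.column_stack(
        [np.ones(len(groups))]
        + [(blocks == b).to_numpy(float) for b in blevels[1:]]
        + [cond]
    )
    Xn = Xb[:, :-1]
    return Xb, Xn, levels


@dataclass
class DispersionEstimates:
    """Common and tagwise NB dispersions (phi); BCV = sqrt(phi)."""

    common: float
    tagwise: pd.Series
    prior_df: float

    @property
    def bcv(self) -> float:
        return float(np.sqrt(self.common))


def _parabolic_argmax(logphi, score):
    """Vertex of the parabola through the grid argmax and its neighbours."""
    score = np.atleast_2d(score)
    j = np.argmax(score, axis=1)
    j = np.clip(j, 1, score.shape[1] - 2)
    x0, x1, x2 = logphi[j - 1], logphi[j], logphi[j + 1]
    y0 = np.take_along_axis(score, (j - 1)[:, None], 1)[:, 0]
    y1 = np.take_along_axis(score, j[:, None], 1)[:, 0]
    y2 = np.take_along_axis(score, (j + 1)[:, None], 1)[:, 0]
    denom = (y0 - 2 * y1 + y2)
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = x1 + 0.5 * (y0 - y2) / denom
    vertex = np.where((denom < -1e-12) & np.isfinite(vertex), vertex, x1)
    vertex = np.clip(vertex, x0, x2)
    # boundary maxima stay at the boundary
    raw = np.argmax(score, axis=1)
    vertex = np.where(raw == 0, logphi[0], vertex)
    vertex = np.where(raw == score.shape[1] - 1, logphi[-1], vertex)
    return vertex


def estimate_dispersion(
    counts, groups, blocks=None, lib_sizes=None, factors=None, prior_df: float = 10.0
) -> DispersionEstimates:
    """Common + tagwise NB dispersion by Cox-Reid adjusted profile likelihood.

    For each candidate phi the group (or block + condition) means are
    profiled out by IRLS with log effective-library-size offsets and the
    adjusted likelihood ll - 0.5 log det(X'WX) is recorded.  The common phi
    maximizes the per-feature sum; each tagwise phi maximizes
    ``APL_g + (prior_df / residual_df) * mean(APL)``, an empirical-Bayes
    weighted likelihood that shrinks toward the common value (and collapses
    onto it as prior_df -> infinity).
    """
    y = np.asarray(counts, dtype=float)
    if y.shape[1] < 2:
        raise ValueError("need at least two samples")
    X, _, _ = _design_matrices(groups, blocks)
    if blocks is None:
        sizes = pd.Series(groups).value_counts()
        if (sizes < 2).any():
            raise ValueError("need >= 2 samples per group to estimate dispersion")
    eff = effective_lib_sizes(counts, lib_sizes, factors)
    offset = np.log(eff)
    keep = y.sum(axis=1) > 0
    yk = y[keep]
    G = yk.shape[0]
    if G == 0:
        raise ValueError("no features with nonzero counts")
    df_res = max(y.shape[1] - np.linalg.matrix_rank(X), 1)

    apl = np.empty((G, len(_PHI_GRID)))
    beta = None
    for j, phi in enumerate(_PHI_GRID):
        beta, ll, A, _ = _nb_glm_fit(yk, X, offset, phi, beta0=beta)
        sign, logdet = np.linalg.slogdet(A)
        apl[:, j] = ll - 0.5 * logdet

    logphi = np.log(_PHI_GRID)
    common = float(np.exp(_parabolic_argmax(logphi, apl.sum(axis=0)[None, :]))[0])
    weight = prior_df / df_res
    score = apl + weight * apl.mean(axis=0)[None, :]
    tag_k = np.exp(_parabolic_argmax(logphi, score))
    tagwise = np.full(y.shape[0], common)
    tagwise[keep] = tag_k
    index = counts.index if hasattr(counts, "index") else pd.RangeIndex(y.shape[0])
    return DispersionEstimates(common, pd.Series(tagwise, index=index, name="phi"), prior_df)


# ---------------------------------------------------------------------------
# exact test (unpaired)

def _equalized_pseudo_counts(counts, lib_sizes=None, factors=None):
    y = np.asarray(counts, dtype=float)
    eff = effective_lib_sizes(counts, lib_sizes, factors)
    n0 = np.exp(np.mean(np.log(eff)))  # common effective library size
    return np.rint(y * (n0 / eff)[None, :]), n0


def _exact_nb_pvalue(z1: int, z2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional NB exact p for one feature's group sums."""
    z = int(z1 + z2)
    if z == 0:
        return 1.0
    k = np.arange(z + 1)
    if phi < 1e-12:
        lp = stats.binom.logpmf(k, z, n1 / (n1 + n2))
    else:
        m = z / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        mu1, mu2 = n1 * m, n2 * m
        p1, p2 = r1 / (r1 + mu1), r2 / (r2 + mu2)
        lp = stats.nbinom.logpmf(k, r1, p1) + stats.nbinom.logpmf(z - k, r2, p2)
    lp -= logsumexp(lp)
    obs = lp[int(z1)]
    sel = lp <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(lp[sel]))))


def exact_test(counts, groups, dispersion, lib_sizes=None, factors=None):
    """Conditional NB exact test on equalized pseudo-counts.

    ``dispersion`` may be a scalar, a vector of per-feature phi, or a
    :class:`DispersionEstimates` (tagwise values used).  Returns a DataFrame
    with per-feature p-value and log2FC (group 2 over group 1, prior 0.125
    on mean pseudo-counts).  Features with zero total get p = 1.
    """
    y = np.asarray(counts, dtype=float)
    groups = pd.Series(groups)
    levels = _group_levels(groups)
    g2 = (groups == levels[1]).to_numpy()
    n1, n2 = int((~g2).sum()), int(g2.sum())
    if isinstance(dispersion, DispersionEstimates):
        phi = dispersion.tagwise.to_numpy()
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],))
    pseudo, _ = _equalized_pseudo_counts(counts, lib_sizes, factors)
    z1 = pseudo[:, ~g2].sum(axis=1)
    z2 = pseudo[:, g2].sum(axis=1)
    pvals = np.array(
        [_exact_nb_pvalue(int(a), int(b), n1, n2, float(f)) for a, b, f in zip(z1, z2, phi)]
    )
    prior = 0.125
    lfc = np.log2((z2 / n2 + prior) / (z1 / n1 + prior))
    index = counts.index if hasattr(counts, "index") else pd.RangeIndex(y.shape[0])
    return pd.DataFrame({"log2fc": lfc, "p": pvals}, index=index)


# ---------------------------------------------------------------------------
# paired LRT

def paired_lrt(counts, groups, blocks, dispersion, lib_sizes=None, factors=None):
    """Paired NB log-linear model: condition effect tested by LRT vs chi2(1).

    The model has an intercept, additive patient (block) effects and a
    condition coefficient, with log effective-library-size offsets.
    Features whose IRLS fit fails to converge get p = NaN (flagged, never
    silent).  Returns a DataFrame with log2fc, p and a converged flag.
    """
    y = np.asarray(counts, dtype=float)
    Xf, Xn, _ = _design_matrices(groups, blocks)
    if isinstance(dispersion, DispersionEstimates):
        phi = dispersion.tagwise.to_numpy()
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],))
    eff = effective_lib_sizes(counts, lib_sizes, factors)
    offset = np.log(eff)
    beta_f, ll_f, _, conv_f = _nb_glm_fit(y, Xf, offset, phi)
    _, ll_n, _, conv_n = _nb_glm_fit(y, Xn, offset, phi)
    lrt = np.maximum(2.0 * (ll_f - ll_n), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    ok = conv_f & conv_n
    p = np.where(ok, p, np.nan)
    lfc = beta_f[:, -1] / np.log(2.0)
    index = counts.index if hasattr(counts, "index") else pd.RangeIndex(y.shape[0])
    return pd.DataFrame({"log2fc": lfc, "p": p, "converged": ok}, index=index)


# ---------------------------------------------------------------------------
# multiplicity, significance, display

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaN entries are passed through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    res = np.empty(m)
    res[order] = q
    out[ok] = res
    return out


def significant_set(results: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Features with FDR below the threshold, sorted by p-value."""
    if "fdr" not in results.columns:
        raise ValueError("results need an 'fdr' column (run bh_adjust first)")
    sig = results[results["fdr"] < fdr_threshold]
    return sig.sort_values("p")


def display_fc(log2fc) -> np.ndarray:
    """Signed fold-change display: 2^lfc for up, -2^(-lfc) for down."""
    lfc = np.asarray(log2fc, dtype=float)
    return np.where(lfc >= 0, 2.0**lfc, -(2.0 ** (-lfc)))


# ---------------------------------------------------------------------------
# MDS diagnostics

@dataclass
class MDSCoordinates:
    coords: pd.DataFrame  # samples x (dim1, dim2)
    distances: pd.DataFrame  # pairwise leading-logFC distances


def mds_coordinates(
    counts, lib_sizes=None, factors=None, top_n: int = 500, prior_count: float = 2.0
) -> MDSCoordinates:
    """Classical MDS of samples on leading-log-fold-change distances.

    The distance between two samples is the root mean square of the
    ``top_n`` largest absolute log2 differences of their prior-augmented
    log-CPM profiles (the BCV-style distance of small-RNA MDS plots).
    """
    y = np.asarray(counts, dtype=float)
    G, n = y.shape
    if n < 3:
        raise ValueError("need >= 3 samples for MDS")
    if top_n > G:
        import warnings

        warnings.warn(f"top_n={top_n} exceeds {G} features; clamped", stacklevel=2)
        top_n = G
    eff = effective_lib_sizes(counts, lib_sizes, factors)
    prior = prior_count * eff / eff.mean()
    lcpm = np.log2((y + prior[None, :]) / (eff + 2 * prior)[None, :] * 1e6)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2 = (lcpm[:, i] - lcpm[:, j]) ** 2
            top = np.sort(d2)[-top_n:]
            D[i, j] = D[j, i] = np.sqrt(top.mean())
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:2]
    lam = np.clip(vals[idx], 0, None)
    coords = vecs[:, idx] * np.sqrt(lam)[None, :]
    samples = counts.columns if hasattr(counts, "columns") else pd.RangeIndex(n)
    return MDSCoordinates(
        pd.DataFrame(coords, index=samples, columns=["dim1", "dim2"]),
        pd.DataFrame(D, index=samples, columns=samples),
    )


# ---------------------------------------------------------------------------
# assembled pipelines

def _assemble(counts, res, factors, lib_sizes):
    tab = pd.DataFrame(
        {
            "feature": res.index,
            "avg_cpm": average_cpm(counts, lib_sizes, factors).to_numpy(),
            "log2fc": res["log2fc"].to_numpy(),
            "fc_display": display_fc(res["log2fc"].to_numpy()),
            "p": res["p"].to_numpy(),
            "fdr": bh_adjust(res["p"].to_numpy()),
        }
    ).set_index("feature")
    return tab


def _drop_all_zero(counts):
    y = np.asarray(counts, dtype=float)
    keep = y.sum(axis=1) > 0
    dropped = int((~keep).sum())
    if hasattr(counts, "loc"):
        return counts.loc[keep], dropped
    return counts[keep], dropped


def de_unpaired(counts, groups, prior_df: float = 10.0, lib_sizes=None):
    """Full unpaired pipeline: TMM -> dispersion -> exact test -> BH.

    Returns ``(table, info)``; the table has avg_cpm, log2fc, fc_display, p
    and fdr per feature, ``info`` records factors, dispersions and the
    all-zero-feature tally.
    """
    if lib_sizes is None:
        lib_sizes = np.asarray(counts, dtype=float).sum(axis=0)
    kept, dropped = _drop_all_zero(counts)
    factors = tmm_factors(kept, lib_sizes)
    disp = estimate_dispersion(kept, groups, lib_sizes=lib_sizes, factors=factors,
                               prior_df=prior_df)
    res = exact_test(kept, groups, disp, lib_sizes, factors)
    table = _assemble(kept, res, factors, lib_sizes)
    return table, {"factors": factors, "dispersion": disp, "n_dropped_all_zero": dropped}


def de_paired(counts, groups, blocks, prior_df: float = 10.0, lib_sizes=None):
    """Full paired pipeline: TMM -> dispersion -> block-adjusted LRT -> BH."""
    if lib_sizes is None:
        lib_sizes = np.asarray(counts, dtype=float).sum(axis=0)
    kept, dropped = _drop_all_zero(counts)
    factors = tmm_factors(kept, lib_sizes)
    disp = estimate_dispersion(kept, groups, blocks=blocks, lib_sizes=lib_sizes,
                               factors=factors, prior_df=prior_df)
    res = paired_lrt(kept, groups, blocks, disp, lib_sizes, factors)
    table = _assemble(kept, res, factors, lib_sizes)
    table["converged"] = res["converged"].to_numpy()
    return table, {"factors": factors, "dispersion": disp, "n_dropped_all_zero": dropped}
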