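"""miRNA-overtargeting analysis over a validated interaction universe.

A gene is *overtargeted* by a selected miRNA set (e.g. the top module
miRNAs by kME) when it receives significantly more interactions from the
selection than expected by chance under a hypergeometric model of the
interaction universe: with N miRNAs in the universe, T_g of them targeting
gene g, and k selected, the upper-tail p is P(X >= x) for
X ~ Hypergeometric(N, T_g, k), where x counts the selected miRNAs that
target g.  Genes untargeted by the selection (x = 0) are not tested, and
BH adjustment runs over tested genes only.

Module-level significance is an empirical p from random equivalent
networks: k miRNAs are redrawn uniformly from the universe many times and
the number of significantly overtargeted genes per draw is compared with
the observed count.  The raw fraction is reported (no +1 continuity
correction), optionally switchable.

Term (GO/KEGG-style) enrichment of the overtargeted gene list uses the
same upper-tail hypergeometric on a gene -> term annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "InteractionUniverse",
    "RandomSetSimulation",
    "build_universe",
    "select_top_module_mirnas",
    "overtargeting_test",
    "random_set_pvalue",
    "export_network",
    "term_enrichment",
]

STRONG_EVIDENCE_TERMS = ("reporter assay", "western blot")


def _norm_id(x: str) -> str:
    return " ".join(str(x).split()).lower()


@dataclass
class InteractionUniverse:
    """Deduplicated validated miRNA -> gene edges with index maps."""

    edges: pd.DataFrame  # columns: mirna, gene (normalized ids)
    mirnas: list[str] = field(init=False)
    genes: list[str] = field(init=False)
    matrix: np.ndarray = field(init=False)  # genes x mirnas boolean

    def __post_init__(self):
        self.mirnas = sorted(self.edges["mirna"].unique())
        self.genes = sorted(self.edges["gene"].unique())
        mi = {m: j for j, m in enumerate(self.mirnas)}
        gi = {g: i for i, g in enumerate(self.genes)}
        self.matrix = np.zeros((len(self.genes), len(self.mirnas)), dtype=bool)
        self.matrix[
            [gi[g] for g in self.edges["gene"]], [mi[m] for m in self.edges["mirna"]]
        ] = True

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def targets_per_gene(self) -> np.ndarray:
        """T_g: number of universe miRNAs targeting each gene."""
        return self.matrix.sum(axis=1)


def build_universe(
    table: pd.DataFrame,
    mirna_col: str = "mirna",
    gene_col: str = "gene",
    evidence_col: str = "evidence",
    strong_terms=STRONG_EVIDENCE_TERMS,
) -> InteractionUniverse:
    """Filter an interaction table to strong-evidence edges and deduplicate.

    A row passes when its evidence string contains any of ``strong_terms``
    case-insensitively (reporter assay / Western blot by default, the
    strong-experimental-evidence convention of curated target databases).
    Identifiers are whitespace- and case-normalized.
    """
    for c in (mirna_col, gene_col, evidence_col):
        if c not in table.columns:
            raise ValueError(f"interaction table lacks column {c!r}")
    ev = table[evidence_col].astype(str).str.lower()
    mask = np.zeros(len(table), dtype=bool)
    for term in strong_terms:
        mask |= ev.str.contains(term.lower(), regex=False).to_numpy()
    kept = table.loc[mask, [mirna_col, gene_col]].copy()
    kept.columns = ["mirna", "gene"]
    kept["mirna"] = kept["mirna"].map(_norm_id)
    kept["gene"] = kept["gene"].map(_norm_id)
    kept = kept[(kept["mirna"] != "") & (kept["gene"] != "")]
    kept = kept.drop_duplicates(ignore_index=True)
    if len(kept) == 0:
        raise ValueError("no edges pass the strong-evidence filter")
    return InteractionUniverse(kept)


def select_top_module_mirnas(
    mm_table: pd.DataFrame,
    gs_table: pd.DataFrame,
    labels: pd.Series,
    module: str,
    universe: InteractionUniverse,
    classes=None,
    k: int = 10,
):
    """Top-k module miRNAs by module membership (ties by GS, then id).

    ``classes`` maps feature -> class tag; only miRNA-class members are
    ranked.  Members absent from the universe are reported, not silently
    dropped from the ranking outcome.  Returns ``(selected, missing)``.
    """
    import warnings

    labels = pd.Series(labels)
    members = labels.index[labels == module]
    if classes is not None:
        classes = pd.Series(classes)
        members = [f for f in members if classes.get(f, "miRNA") == "miRNA"]
    else:
        members = list(members)
    if not members:
        raise ValueError(f"module {module!r} contains no miRNA-class feature")
    ranking = pd.DataFrame(
        {
            "mm": mm_table.loc[members, module].to_numpy(),
            "gs": gs_table.loc[members, "gs"].to_numpy(),
        },
        index=pd.Index(members, name="feature"),
    )
    ranking = ranking.sort_values(
        by=["mm", "gs", "feature"], ascending=[False, False, True]
    )
    top = list(ranking.index[:k])
    if len(top) < k:
        warnings.warn(
            f"module {module!r} has only {len(top)} miRNAs (requested {k})",
            stacklevel=2,
        )
    in_universe = set(universe.mirnas)
    selected = [m for m in top if _norm_id(m) in in_universe]
    missing = [m for m in top if _norm_id(m) not in in_universe]
    if not selected:
        raise ValueError("none of the selected miRNAs are present in the universe")
    return selected, missing


def overtargeting_test(
    selected, universe: InteractionUniverse, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-gene upper-tail hypergeometric overtargeting test.

    Only genes hit by at least one selected miRNA are tested; BH runs over
    tested genes.  Returns a DataFrame (gene, x, t_g, p, fdr, significant)
    sorted by p.
    """
    sel_norm = [_norm_id(m) for m in selected]
    k = len(sel_norm)
    if k == 0:
        raise ValueError("empty miRNA selection")
    pos = {m: j for j, m in enumerate(universe.mirnas)}
    missing = [m for m in sel_norm if m not in pos]
    if missing:
        raise ValueError(f"selected miRNAs absent from universe: {missing}")
    cols = [pos[m] for m in sel_norm]
    x = universe.matrix[:, cols].sum(axis=1)
    t_g = universe.targets_per_gene()
    tested = x >= 1
    N = universe.n_mirnas
    p = stats.hypergeom.sf(x[tested] - 1, N, t_g[tested], k)
    out = pd.DataFrame(
        {
            "gene": np.asarray(universe.genes)[tested],
            "x": x[tested],
            "t_g": t_g[tested],
            "p": p,
            "fdr": bh_adjust(p),
        }
    )
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values(["p", "gene"], ignore_index=True)


def _significant_counts(
    universe: InteractionUniverse, selections: np.ndarray, fdr_threshold: float
) -> np.ndarray:
    """Significant-overtargeted-gene count for each row of ``selections``.

    Vectorized across draws: per draw, hypergeometric p-values come from a
    precomputed (x, T_g) lookup and BH is applied column-wise over tested
    genes.
    """
    k = selections.shape[1]
    N = universe.n_mirnas
    t_g = universe.targets_per_gene()
    t_vals = np.arange(0, t_g.max() + 1)
    # lookup[x, T] = P(X >= x), X ~ Hypergeom(N, T, k)
    lookup = np.empty((k + 1, len(t_vals)))
    for xx in range(k + 1):
        lookup[xx] = stats.hypergeom.sf(xx - 1, N, t_vals, k)
    counts = np.empty(selections.shape[0], dtype=int)
    B = selections.shape[0]
    chunk = max(1, int(2e7 // max(universe.n_genes, 1)))
    for s in range(0, B, chunk):
        sel = selections[s : s + chunk]
        x = universe.matrix[:, sel.reshape(-1)].reshape(
            universe.n_genes, sel.shape[0], k
        ).sum(axis=2)  # genes x draws
        p = lookup[x, t_g[:, None]]
        tested = x >= 1
        p = np.where(tested, p, np.inf)
        m = tested.sum(axis=0)  # tested genes per draw
        ps = np.sort(p, axis=0)
        ranks = np.arange(1, universe.n_genes + 1)[:, None]
        with np.errstate(invalid="ignore"):
            ok = ps <= fdr_threshold * ranks / np.maximum(m, 1)[None, :]
        ok &= np.isfinite(ps)
        # BH: all genes up to the largest passing rank are significant
        nsig = np.where(ok.any(axis=0), universe.n_genes - np.argmax(ok[::-1], axis=0), 0)
        counts[s : s + chunk] = nsig
    return counts


@dataclass
class RandomSetSimulation:
    n_iter: int
    observed_count: int
    counts: np.ndarray
    empirical_p: float
    seed: int


def random_set_pvalue(
    universe: InteractionUniverse,
    k: int,
    observed_count: int,
    n_iter: int = 100_000,
    fdr_threshold: float = 0.05,
    seed: int = 0,
    add_one: bool = False,
) -> RandomSetSimulation:
    """Module-level empirical p from random equivalent networks.

    Each iteration draws k miRNAs uniformly without replacement from the
    universe, reruns the overtargeting test, and records the significant
    gene count; empirical p is the fraction of iterations reaching the
    observed count (``add_one`` applies the +1 continuity correction).
    """
    import warnings

    if k > universe.n_mirnas:
        raise ValueError("k exceeds the number of universe miRNAs")
    if n_iter < 100:
        warnings.warn("n_iter < 100 gives an unstable empirical p", stacklevel=2)
    rng = np.random.default_rng(seed)
    N = universe.n_mirnas
    selections = np.empty((n_iter, k), dtype=np.int64)
    for i in range(n_iter):
        selections[i] = rng.choice(N, size=k, replace=False)
    counts = _significant_counts(universe, selections, fdr_threshold)
    hits = int((counts >= observed_count).sum())
    if add_one:
        emp = (hits + 1) / (n_iter + 1)
    else:
        emp = hits / n_iter
    return RandomSetSimulation(n_iter, observed_count, counts, float(emp), seed)


def export_network(selected, result: pd.DataFrame, universe: InteractionUniverse, out_prefix):
    """Write the selected-miRNA x significant-gene bipartite network.

    Emits ``<prefix>.sif``, ``<prefix>.graphml``, ``<prefix>_edges.tsv`` and
    ``<prefix>_nodes.tsv``.  Returns the edge table.
    """
    import warnings

    import networkx as nx

    sel_norm = [_norm_id(m) for m in selected]
    sig = result[result["significant"]]
    sig_genes = set(sig["gene"])
    pos = {m: j for j, m in enumerate(universe.mirnas)}
    gpos = {g: i for i, g in enumerate(universe.genes)}
    edges = []
    for m in sel_norm:
        targets = np.nonzero(universe.matrix[:, pos[m]])[0]
        for gi in targets:
            g = universe.genes[gi]
            if g in sig_genes:
                edges.append({"mirna": m, "gene": g})
    edge_df = pd.DataFrame(edges, columns=["mirna", "gene"])
    if edge_df.empty:
        warnings.warn("empty overtargeting network", stacklevel=2)

    out_prefix = str(out_prefix)
    with open(out_prefix + ".sif", "w") as fh:
        fh.write("")
        for _, row in edge_df.iterrows():
            fh.write(f"{row['mirna']}\ttargets\t{row['gene']}\n")
    edge_df.to_csv(out_prefix + "_edges.tsv", sep="\t", index=False)

    nodes = pd.concat(
        [
            pd.DataFrame({"node": sel_norm, "type": "miRNA"}),
            sig.rename(columns={"gene": "node"})[["node", "x", "t_g", "p", "fdr"]].assign(
                type="gene"
            ),
        ],
        ignore_index=True,
    )
    nodes.to_csv(out_prefix + "_nodes.tsv", sep="\t", index=False)

    g = nx.DiGraph()
    for _, row in nodes.iterrows():
        attrs = {kk: vv for kk, vv in row.items() if kk != "node" and pd.notna(vv)}
        g.add_node(row["node"], **attrs)
    for _, row in edge_df.iterrows():
        g.add_edge(row["mirna"], row["gene"])
    nx.write_graphml(g, out_prefix + ".graphml")
    return edge_df


def term_enrichment(
    query_genes,
    annotation: pd.DataFrame,
    universe_genes,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment over an annotation table.

    ``annotation`` needs columns (gene, term) and optionally term_name; the
    population is ``universe_genes`` and the draw is ``query_genes`` (must
    be a subset).  The ``enriched`` flag combines both thresholds.
    """
    if annotation is None or len(annotation) == 0:
        raise ValueError("empty annotation table")
    for c in ("gene", "term"):
        if c not in annotation.columns:
            raise ValueError(f"annotation lacks column {c!r}")
    universe = {_norm_id(g) for g in universe_genes}
    query = {_norm_id(g) for g in query_genes}
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    ann = annotation.copy()
    ann["gene"] = ann["gene"].map(_norm_id)
    ann = ann[ann["gene"].isin(universe)].drop_duplicates(["gene", "term"])
    N, q = len(universe), len(query)
    rows = []
    for term, sub in ann.groupby("term"):
        term_genes = set(sub["gene"])
        overlap = len(term_genes & query)
        p = float(stats.hypergeom.sf(overlap - 1, N, len(term_genes), q))
        rows.append(
            {
                "term": term,
                "term_name": sub["term_name"].iloc[0] if "term_name" in sub else term,
                "overlap": overlap,
                "term_size": len(term_genes),
                "query_size": q,
                "universe_size": N,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = (out["p"] < p_threshold) & (out["fdr"] < fdr_threshold)
    return out.sort_values(["p", "term"], ignore_index=True)
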