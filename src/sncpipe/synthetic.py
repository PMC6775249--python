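"""Synthetic inputs with the statistical structure the analysis assumes.

Four generators cover the four data surfaces of the pipeline:

* aligned small-RNA reads anchored at gene 5' ends plus off-target decoys,
  for the fragment caller;
* negative-binomial count matrices with library-size variation, planted
  fold changes and dispersion, for the differential-abundance stage;
* a feature x sample expression matrix with planted latent-factor modules
  and a binary trait, for the coexpression stage;
* a miRNA -> gene interaction universe with a planted overtargeted gene
  set, for the overtargeting stage.

Every generator is a pure function of its :class:`SimulationConfig`:
identical configuration (including seed) gives bit-identical output, and
each one returns a truth table covering every emitted feature/read/edge
exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "UniverseSpec",
    "SimulationConfig",
    "simulate_annotation",
    "simulate_fragment_reads",
    "simulate_counts",
    "simulate_module_data",
    "simulate_interaction_universe",
    "simulate_ct_table",
]


@dataclass(frozen=True)
class UniverseSpec:
    """Shape of the synthetic miRNA -> gene interaction universe."""

    n_mirnas: int = 150
    n_genes: int = 1500
    background_edge_prob: float = 0.10
    planted_gene_count: int = 50
    planted_target_prob: float = 0.80
    planted_mirna_count: int = 10

    def validate(self) -> None:
        if self.n_mirnas < 1 or self.n_genes < 1:
            raise ValueError("universe must contain at least one miRNA and one gene")
        for name in ("background_edge_prob", "planted_target_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.planted_target_prob <= self.background_edge_prob:
            raise ValueError("planted_target_prob must exceed background_edge_prob")
        if not 0 <= self.planted_gene_count <= self.n_genes:
            raise ValueError("planted_gene_count out of range")
        if not 0 < self.planted_mirna_count <= self.n_mirnas:
            raise ValueError("planted_mirna_count out of range")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for all synthetic generators.

    ``dispersion`` is the NB dispersion phi (BCV = sqrt(phi)).  The defaults
    emulate a 5-versus-5 small-RNA serum/tissue study: ~2,000 features with
    log-normal mean abundances, moderate biological variation, a tenth of
    the features perturbed six-fold, three coexpression modules (the first
    linked to a binary cancer trait), and a validated-interaction universe
    with 10 designated miRNAs preferentially targeting 50 genes.
    """

    seed: int = 0
    n_samples_per_group: int = 5
    n_features: int = 2000
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    dispersion: float = 0.1
    de_fraction: float = 0.1
    de_fold: float = 6.0
    module_spec: tuple[tuple[int, bool], ...] = ((40, True), (30, False), (20, False))
    noise_sd: float = 0.5
    universe_spec: UniverseSpec = field(default_factory=UniverseSpec)
    # fragment-read generation
    reads_per_locus: int = 100
    decoy_wrong_length_frac: float = 0.10
    decoy_three_prime_frac: float = 0.05
    decoy_internal_frac: float = 0.05
    # gene-mean distribution (log-normal, heavy right tail)
    mean_log: float = 4.0
    sd_log: float = 1.5

    def validate(self) -> None:
        if self.n_samples_per_group < 1 or self.n_features < 1:
            raise ValueError("sample and feature counts must be >= 1")
        lo, hi = self.library_size_range
        if not (1 <= lo <= hi):
            raise ValueError("library_size_range must satisfy 1 <= lo <= hi")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.de_fold < 1:
            raise ValueError("de_fold must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(size < 1 for size, _ in self.module_spec):
            raise ValueError("module sizes must be >= 1")
        decoy_total = (
            self.decoy_wrong_length_frac
            + self.decoy_three_prime_frac
            + self.decoy_internal_frac
        )
        for name in (
            "decoy_wrong_length_frac",
            "decoy_three_prime_frac",
            "decoy_internal_frac",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if decoy_total > 1.0:
            raise ValueError("decoy fractions must sum to <= 1")
        if self.reads_per_locus < 0:
            raise ValueError("reads_per_locus must be nonnegative")
        self.universe_spec.validate()

    @property
    def n_samples(self) -> int:
        return 2 * self.n_samples_per_group

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


_STREAM_IDS = {
    "annotation": 1,
    "reads": 2,
    "counts": 3,
    "modules": 4,
    "universe": 5,
    "ct": 6,
}


def _stream_rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, _STREAM_IDS[stream]]))


def simulate_annotation(
    n_trna: int = 20,
    n_yrna: int = 4,
    gene_length: int = 73,
    spacing: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Make a small BED-like gene annotation (1-based inclusive coordinates).

    Loci alternate strands and are spread over two chromosomes; tRNA loci
    get gtRNAdb-flavoured names, YRNA loci GENCODE-flavoured ones.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pos = 10_000
    for i in range(n_trna):
        start = pos
        end = start + gene_length - 1
        rows.append(
            {
                "locus_id": f"tRNA-Syn-AAA-{i + 1}-1",
                "chrom": "chr1" if i % 2 == 0 else "chr2",
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "gene_class": "tRNA",
            }
        )
        pos += spacing
    for j in range(n_yrna):
        start = pos
        end = start + 95  # YRNA genes run ~96 nt
        rows.append(
            {
                "locus_id": f"RNY-syn{j + 1}-201",
                "chrom": "chr2",
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "gene_class": "YRNA",
            }
        )
        pos += spacing
    return pd.DataFrame(rows)


def simulate_fragment_reads(
    annotation: pd.DataFrame, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit 5'-anchored 30-34 nt reads plus decoys for every locus and sample.

    Per locus and sample the planned read total is ``reads_per_locus``; of
    these, the decoy fractions are diverted to wrong-length (20-29 / 35-40 nt,
    still 5'-anchored), 3'-anchored (30-34 nt ending at the locus 3' end) and
    internal-offset (30-34 nt, 5' terminus 3-10 nt inside the gene) classes.
    The truth table records the intended per-locus, per-sample 5' count.

    Returns ``(reads, truth)`` where ``reads`` has the aligned-read columns
    (read_id, chrom, start, end, strand, length, sample_id) and ``truth``
    has (locus_id, sample_id, true_count).
    """
    cfg.validate()
    if annotation is None or len(annotation) == 0:
        raise ValueError("annotation must be non-empty")
    rng = _stream_rng(cfg, "reads")
    samples = [f"N{i + 1}" for i in range(cfg.n_samples_per_group)] + [
        f"C{i + 1}" for i in range(cfg.n_samples_per_group)
    ]
    read_rows = []
    truth_rows = []
    counter = 0
    for _, locus in annotation.iterrows():
        gene_len = locus["end"] - locus["start"] + 1
        for sample in samples:
            n_total = cfg.reads_per_locus
            n_wrong = int(round(n_total * cfg.decoy_wrong_length_frac))
            n_three = int(round(n_total * cfg.decoy_three_prime_frac))
            n_internal = int(round(n_total * cfg.decoy_internal_frac))
            n_true = n_total - n_wrong - n_three - n_internal
            truth_rows.append(
                {"locus_id": locus["locus_id"], "sample_id": sample, "true_count": n_true}
            )
            specs = (
                [("five", None)] * n_true
                + [("wrong_length", None)] * n_wrong
                + [("three", None)] * n_three
                + [("internal", None)] * n_internal
            )
            for kind, _ in specs:
                if kind == "wrong_length":
                    length = int(
                        rng.choice(np.r_[np.arange(20, 30), np.arange(35, 41)])
                    )
                else:
                    length = int(rng.integers(30, 35))
                length = min(length, gene_len)
                if kind in ("five", "wrong_length"):
                    offset = 0
                elif kind == "three":
                    offset = gene_len - length
                else:  # internal
                    hi = max(4, min(11, gene_len - length))
                    offset = int(rng.integers(3, hi)) if hi > 3 else 1
                if locus["strand"] == "+":
                    start = locus["start"] + offset
                    end = start + length - 1
                else:
                    end = locus["end"] - offset
                    start = end - length + 1
                counter += 1
                read_rows.append(
                    {
                        "read_id": f"r{counter:07d}",
                        "chrom": locus["chrom"],
                        "start": start,
                        "end": end,
                        "strand": locus["strand"],
                        "length": length,
                        "sample_id": sample,
                    }
                )
    reads = pd.DataFrame(
        read_rows,
        columns=["read_id", "chrom", "start", "end", "strand", "length", "sample_id"],
    )
    truth = pd.DataFrame(truth_rows)
    return reads, truth


def simulate_counts(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix with planted fold changes.

    Gene means are log-normal (heavy right tail, mimicking the wide CPM
    range of abundant fragments); counts are NB with mean scaled by each
    sample's library-size factor and dispersion phi; ``de_fraction`` of the
    features change ``de_fold``-fold in group 2 (half up, half down).

    Returns ``(counts, truth)``: counts indexed by feature with sample
    columns N1..C<n>; truth columns (feature, is_de, true_log2fc).
    """
    cfg.validate()
    rng = _stream_rng(cfg, "counts")
    G, n = cfg.n_features, cfg.n_samples_per_group
    samples = [f"N{i + 1}" for i in range(n)] + [f"C{i + 1}" for i in range(n)]
    means = rng.lognormal(mean=cfg.mean_log, sigma=cfg.sd_log, size=G)
    lo, hi = cfg.library_size_range
    lib = rng.integers(lo, hi + 1, size=2 * n)
    lib_scale = lib / lib.mean()

    n_de = int(round(cfg.de_fraction * G))
    de_idx = rng.choice(G, size=n_de, replace=False)
    true_lfc = np.zeros(G)
    if n_de:
        half = n_de // 2
        true_lfc[de_idx[:half]] = np.log2(cfg.de_fold)
        true_lfc[de_idx[half:]] = -np.log2(cfg.de_fold)

    mu = np.empty((G, 2 * n))
    mu[:, :n] = means[:, None] * lib_scale[None, :n]
    mu[:, n:] = (means * 2.0**true_lfc)[:, None] * lib_scale[None, n:]

    phi = cfg.dispersion
    if phi <= 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        # NB as gamma-Poisson mixture: lambda ~ Gamma(shape=r, scale=mu/r)
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam)
    features = [f"feat{i + 1:05d}" for i in range(G)]
    counts_df = pd.DataFrame(counts, index=pd.Index(features, name="feature"), columns=samples)
    truth = pd.DataFrame(
        {"feature": features, "is_de": true_lfc != 0.0, "true_log2fc": true_lfc}
    )
    return counts_df, truth


def simulate_module_data(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Latent-factor expression matrix with planted coexpression modules.

    Each module of ``module_spec`` is a latent sample factor plus Gaussian
    feature noise of sd ``noise_sd``; a trait-linked module's factor is a
    noisy copy of the binary trait (cancer = 1, normal = 0; noise sd equals
    ``noise_sd`` so a noiseless configuration gives an exact trait copy).
    Features beyond the module budget are pure N(0, 1) noise with truth
    label ``"unassigned"``.

    Returns ``(matrix, trait, truth)``; matrix is features x samples, truth
    has (feature, true_module) with modules named M1, M2, ...
    """
    cfg.validate()
    total = sum(size for size, _ in cfg.module_spec)
    if total > cfg.n_features:
        raise ValueError(
            f"module sizes sum to {total} but only {cfg.n_features} features available"
        )
    if cfg.n_samples < 4:
        raise ValueError("need at least 4 samples for module simulation")
    rng = _stream_rng(cfg, "modules")
    n = cfg.n_samples
    trait = np.r_[np.zeros(cfg.n_samples_per_group), np.ones(cfg.n_samples_per_group)]
    samples = [f"N{i + 1}" for i in range(cfg.n_samples_per_group)] + [
        f"C{i + 1}" for i in range(cfg.n_samples_per_group)
    ]
    rows, labels = [], []
    for m, (size, trait_linked) in enumerate(cfg.module_spec, start=1):
        if trait_linked:
            centered = trait - trait.mean()
            factor = centered / (centered.std() if centered.std() > 0 else 1.0)
            factor = factor + rng.normal(0.0, cfg.noise_sd, size=n)
        else:
            factor = rng.normal(0.0, 1.0, size=n)
        loadings = rng.uniform(0.5, 1.5, size=size)
        block = loadings[:, None] * factor[None, :] + rng.normal(
            0.0, cfg.noise_sd, size=(size, n)
        )
        rows.append(block)
        labels += [f"M{m}"] * size
    n_noise = cfg.n_features - total
    if n_noise:
        rows.append(rng.normal(0.0, 1.0, size=(n_noise, n)))
        labels += ["unassigned"] * n_noise
    matrix = np.vstack(rows)
    features = [f"feat{i + 1:05d}" for i in range(cfg.n_features)]
    mat = pd.DataFrame(matrix, index=pd.Index(features, name="feature"), columns=samples)
    truth = pd.DataFrame({"feature": features, "true_module": labels})
    return mat, pd.Series(trait, index=samples, name="trait"), truth


def simulate_interaction_universe(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Bernoulli interaction universe with a planted overtargeted gene set.

    Every (miRNA, gene) pair receives an edge with ``background_edge_prob``;
    pairs between the designated miRNA set and the planted genes receive an
    edge with ``planted_target_prob`` instead.  All edges carry a strong
    evidence label so the universe passes the strong-evidence filter.

    Returns ``(edge_table, planted_genes, planted_mirnas)``; the edge table
    has columns (mirna, gene, evidence).
    """
    cfg.validate()
    spec = cfg.universe_spec
    rng = _stream_rng(cfg, "universe")
    mirnas = [f"hsa-miR-s{i + 1:03d}" for i in range(spec.n_mirnas)]
    genes = [f"GENE{j + 1:04d}" for j in range(spec.n_genes)]
    planted_mirnas = mirnas[: spec.planted_mirna_count]
    planted_genes = genes[: spec.planted_gene_count]
    prob = np.full((spec.n_mirnas, spec.n_genes), spec.background_edge_prob)
    prob[: spec.planted_mirna_count, : spec.planted_gene_count] = spec.planted_target_prob
    adj = rng.random((spec.n_mirnas, spec.n_genes)) < prob
    mi, gi = np.nonzero(adj)
    edges = pd.DataFrame(
        {
            "mirna": [mirnas[i] for i in mi],
            "gene": [genes[j] for j in gi],
            "evidence": "Luciferase reporter assay//Western blot",
        }
    )
    return edges, planted_genes, planted_mirnas


def simulate_ct_table(
    cfg: SimulationConfig,
    target_genes: tuple[str, ...] = ("FBXO31", "WEE1", "RB1", "E2F1"),
    true_folds: tuple[float, ...] = (0.4, 0.45, 0.8, 0.85),
    reference_gene: str = "B2M",
    base_ct: float = 24.0,
    reference_ct: float = 20.0,
    ct_sd: float = 0.3,
) -> pd.DataFrame:
    """qPCR Ct table for paired tumour/normal tissue with planted folds.

    Each patient pair contributes a normal and a tumour sample; the
    target genes carry tumour/normal fold changes ``true_folds``
    (fold f shifts the tumour dCt by -log2 f) with Gaussian Ct noise.
    The reference (housekeeping) gene is present for every sample.
    """
    cfg.validate()
    if len(true_folds) != len(target_genes):
        raise ValueError("true_folds must match target_genes in length")
    rng = _stream_rng(cfg, "ct")
    rows = []
    for p in range(cfg.n_samples_per_group):
        pair = f"P{p + 1}"
        for group, suffix in (("normal", "N"), ("tumor", "T")):
            sample = f"{pair}{suffix}"
            rows.append(
                {
                    "sample_id": sample,
                    "gene_id": reference_gene,
                    "ct": reference_ct + rng.normal(0, ct_sd),
                    "group": group,
                    "pair_id": pair,
                }
            )
            for gene, fold in zip(target_genes, true_folds):
                shift = -np.log2(fold) if group == "tumor" else 0.0
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": gene,
                        "ct": base_ct + shift + rng.normal(0, ct_sd),
                        "group": group,
                        "pair_id": pair,
                    }
                )
    return pd.DataFrame(rows)
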