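# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `sncpipe`. Everything stated here is computed by the
test suite or the analysis drivers; nothing is asserted beyond what the
code measures.

## Fragment calling

Circulating tRNA- and YRNA-derived small RNAs of the class this package
profiles are 30–34 nt long and derive almost exclusively from the 5′ end
of their parent gene. The caller therefore accepts an aligned read for a
locus iff

1. its aligned length is within [30, 34] nt,
2. its strand matches the locus strand, and
3. its biological 5′ terminus lies within `tol` nt of the locus 5′
   terminus (plus strand: gene start; minus strand: gene end).

`tol` defaults to 0 (strict anchoring) because the biological signature
is a sharply defined 5′ boundary; it is configurable for noisier
protocols. Coordinates are 1-based inclusive internally — the convention
of printed tRNA gene tables — and the BED/SAM readers convert on input.

**Multi-mapping.** A read increments *every* locus whose 5′ end it
matches. Identical tRNA paralogs (same mature sequence, several genomic
copies) then receive near-identical counts, which matches how per-locus
count tables for these families are conventionally reported. The
alternative (fractional or primary-only assignment) would silently
down-weight large families; per-locus counting keeps the bookkeeping
conserved and auditable: per sample, assigned + rejected(length) +
rejected(no_overlap) + rejected(strand) + rejected(position) equals the
input read count, and the QC table reports every tally.

The bundled exact-substring aligner exists so the synthetic FASTA path is
testable end to end; it is deliberately mismatch-intolerant and is not a
general-purpose aligner.

## Negative-binomial differential abundance

Counts are modelled as NB with variance μ + φμ², BCV = √φ.

**TMM normalization.** The reference column is the one whose CPM upper
quartile is closest to the mean upper quartile. Per sample, gene-wise
log2 ratios *M* against the reference are computed over genes positive in
both libraries; the stated trim fractions (30% of M, 5% of A) are removed
from *each* tail, and the factor is 2 to the precision-weighted mean of
the surviving M values, with factors rescaled to geometric mean 1. On a
shared fixture the factors agree with the Bioconductor implementation to
4 decimals (cross-checked in the test suite). One caveat the tests
quantify: with strongly asymmetric composition bias and shallow
libraries, count noise interacts with the asymmetric trim to leave a
small residual offset (≈0.08 log2 units at mean count ≈150 — identical in
the reference implementation); the composition-bias benchmark therefore
uses deep libraries (mean count ≈1100, as for abundant sncRNA fragments)
so it measures the composition correction itself, where the residual
median M is ≈0.03.

**Dispersion.** Common φ maximizes the summed Cox–Reid adjusted profile
likelihood (group or block+condition means profiled out by IRLS with log
effective-library-size offsets; adjustment −½ log det(XᵀWX)), evaluated
on a 31-point log-spaced grid over [10⁻⁴, 10] with parabolic refinement.
Tagwise φ_g maximizes APL_g + (prior_df / residual_df) · mean(APL), an
empirical-Bayes weighted likelihood that shrinks single-feature estimates
toward the common value; prior_df defaults to 10 and tagwise collapses
onto common as prior_df → ∞. This is a deliberate re-derivation, not a
port: the fidelity target is simulation calibration (the suite checks φ̂
< 0.01 on Poisson data, φ̂ ∈ [0.07, 0.13] for true φ = 0.1, null
rejection at 5% within [3.5%, 6.5%]).

**Exact test (unpaired).** Counts are mean-scaled to a common effective
library size (geometric mean of TMM-scaled library sizes) and rounded;
per feature, conditional on the two-group total z, the two-sided p sums
the probabilities of all splits no more probable than the observed one,
with group sums distributed NB(nμ, φ/n). Full enumeration over z+1
splits is used for every feature (no tail approximation); at φ = 0 this
reduces to the conditional binomial test. Zero-total features get p = 1
and are reported, not dropped silently. Log2FC is computed from mean
pseudo-counts with a 0.125 prior, displayed with the signed convention
(−2^(−lfc) for decreases, so a 6.1-fold decrease prints as −6.1).

**Paired LRT.** The tissue design fits an NB log-linear model with
intercept, additive patient (block) effects and a condition coefficient,
by batched IRLS at the tagwise dispersions; the condition effect is
tested by likelihood ratio against χ²(1). Blocks must be complete (one
sample per condition per patient); incomplete blocks are rejected rather
than imputed. Non-converged features are flagged with p = NaN. The suite
checks type-I error within [3%, 7%] under strong patient effects and
median log2FC within ±0.2 of 1 for a planted 2-fold effect.

**Multiplicity.** BH step-up, verified exactly against an independent
descending-scan implementation on 1,000 random vectors. Significance is
FDR < 5% by default.

**MDS diagnostics.** Pairwise sample distance = root-mean-square of the
`top_n` (default 500) largest absolute log2 differences of
prior-augmented log-CPM profiles, embedded by classical metric scaling;
dimension 1 separates condition groups in the planted simulations.

## Weighted coexpression modules

Input is the pooled log-scale matrix of miRNAs, 5′ tRNA halves and 5′
YRNA fragments with a per-feature class tag. A MAD > 0 variability filter
removes constant features (the threshold is exposed because a nonnegative
statistic admits no sensible "< 0" rule). The network is unsigned,
a_ij = |cor(x_i, x_j)|^β with β = 6 — the soft-power scan on the default
synthetic matrix reaches scale-free fit R² ≈ 0.81 at β = 6 — and
features are clustered by average linkage on 1 − TOM, where
TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij).

**Branch cutting ("hybrid-lite").** The tree is cut at a height fraction
of the tallest merge that tightens with `deep_split` (0.99, 0.96, 0.93,
0.90, 0.87 for deepSplit 0–4; default 3). A candidate cluster becomes a
module only if it has ≥ `min_module_size` members (default 10) *and* is
internally cohesive: mean within-cluster dissimilarity either ≤ 0.93 of
the background (median all-pairs) dissimilarity or ≤ 0.5 absolutely. The
relative criterion matters because many uncorrelated features compress
TOM dissimilarities toward 1, so "tight" is only meaningful against the
background level. Everything else is Gray (unassigned). This is a
deliberately simple reconstruction of dynamic tree cutting; its fidelity
target is planted-module recovery (ARI ≥ 0.8 on the default benchmark,
≥ 90% Gray on pure noise), not branch-for-branch parity with the
reference dynamic-tree-cut algorithm. Colours follow the conventional
palette by decreasing module size (largest = turquoise), ties broken by
first feature index, making labels order-invariant.

**Eigengenes and feature statistics.** The module eigengene is the first
right singular vector of the row-standardized member submatrix, signed so
the mean correlation with members is ≥ 0 (this orientation makes reruns
reproducible). MM/kME = Pearson correlation of a feature with a module
eigengene; GS = |Pearson correlation with the binary trait| (the signed
value is also emitted, since scatter plots can use either), with t-test
p on n − 2 df. Module–trait association is the eigengene–trait Pearson r
with the same test. No eigengene-merging step is applied by default.

## miRNA overtargeting

The interaction universe is a strong-evidence-filtered, deduplicated
miRNA → gene edge set (evidence strings matched case-insensitively
against a configurable list, default "reporter assay" and "Western
blot"). For a selected set of k miRNAs (default: top 10 module miRNAs by
MM, ties by GS then id), a gene g targeted by x of them, out of T_g
universe miRNAs, has upper-tail p = P(X ≥ x), X ~
Hypergeometric(N_miRNAs, T_g, k). Genes with x = 0 contribute no network
proportion and are not tested; BH runs over tested genes. The p-values
agree with exhaustive subset enumeration on small universes, and adding
an edge from a selected miRNA can only decrease a gene's p.

**Random-set module significance.** k miRNAs are redrawn uniformly
without replacement n_iter times (default 100,000) from the same
universe; each draw reruns the overtargeting test and records its
significant-gene count; the empirical p is the raw fraction of draws
reaching the observed count (no +1 correction by default, matching the
convention in which a reported value like 0.01137 is an exact fraction of
100,000; the correction is available as an option). Because the count is
a small integer, the empirical p is discrete and *conservative*; the
calibration test therefore checks the one-sided Kolmogorov–Smirnov
statistic D⁺ (no anti-conservative deviation from uniformity, the
defining property of a valid Monte-Carlo p) rather than two-sided
uniformity, which no discrete conservative p can satisfy.

Term enrichment over the overtargeted genes is the same upper-tail
hypergeometric on a gene → term table (taken as given — no GO-graph
propagation), BH-adjusted, reported with the dual p < 0.01 / FDR < 0.05
flag.

## qPCR relative quantification

ΔCt = Ct(target) − Ct(reference) per sample after averaging technical
replicates; ΔΔCt subtracts the control group's mean ΔCt (equivalently,
normalizes relative quantities by the control geometric mean, so control
folds geometric-average to exactly 1); fold = 2^−ΔΔCt. Groups are
compared by Student's t (equal variances, Welch optional) on log2 folds.
A pairwise mode subtracts the matched control sample's ΔCt instead, for
tumour/adjacent-normal pairs; it is off by default since group-mean
centring is the more common convention.

## Synthetic study conditions

The generators define, once, the conditions all calibration and recovery
claims refer to:

| surface | conditions |
| --- | --- |
| reads | 24 loci (20 tRNA, 4 YRNA), 10 samples, 100 reads/locus; decoys 10% wrong-length, 5% 3′-anchored, 5% internal-offset |
| counts | 2,000 features, 5 vs 5; gene means log-normal(meanlog 4, sdlog 1.5) (wide CPM range with a heavy right tail); library sizes uniform 0.8–1.2 M; φ = 0.1 (BCV ≈ 0.32); 10% DE at 6-fold, half up / half down |
| modules | three latent-factor modules (40/30/20), feature noise sd 0.5, 20 samples; the first module's factor is a noisy copy of the binary trait (cancer = 1) |
| universe | 150 miRNAs × 1,500 genes, background edge probability 0.10; 10 designated miRNAs target 50 planted genes with probability 0.80 |
| Ct table | 5 patient pairs; reference gene Ct ≈ 20, targets ≈ 24, Ct noise sd 0.3; planted tumour/normal folds 0.4/0.45/0.8/0.85 |

What the generators deliberately do **not** emulate: sequencing error,
adapter contamination, quality scores, mature-vs-precursor miRNA identifier
ambiguity, GC/length biases, batch effects, or clinical covariates.
Passing tests therefore demonstrate statistical correctness and
calibration of the methods under their own model assumptions — not
robustness to the full messiness of real sequencing data.

Problem sizes in the test and acceptance benchmarks (2,000 features,
100,000 random-set iterations, 100-experiment null calibration at 2,000
iterations) were chosen as the smallest sizes at which the measured
quantities are stable to the reported precision.

## Determinism

Every generator is a pure function of its configuration; streams are
separated by `SeedSequence([seed, stream_id])`. The pipeline fans one
global seed out to per-stage seeds the same way, so a rerun with the same
config reproduces every table byte-for-byte (checked in the suite). Every
written table carries the config hash in a header comment.

## Known limitations

- The exact test enumerates all splits of the per-feature total; for
  extremely abundant features (totals ≫ 10⁶) this is memory-proportional
  to the total. Fine at sncRNA scale; a saddlepoint tail would be the
  next step for much deeper data.
- The branch cutter is a two-rule approximation of dynamic tree cutting;
  deeply nested module hierarchies may be merged or sent to Gray.
- The paired LRT relies on the χ²(1) asymptotics at 4 residual df; its
  measured type-I error (~6%) is mildly liberal, inside the accepted
  band.
- miRNA identifiers are matched exactly after case/whitespace
  normalization; no mature/precursor remapping is attempted (mismatches
  are reported, not guessed).
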