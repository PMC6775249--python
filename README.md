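# sncpipe

Analysis pipeline for small non-coding RNA fragments in serum and tissue:
profiling of **5′ tRNA halves** and **5′ YRNA fragments** from aligned
small-RNA reads, negative-binomial differential abundance for unpaired
(serum) and patient-paired (tissue) designs, weighted coexpression module
discovery over the pooled miRNA + fragment matrix, **miRNA-overtargeting**
functional inference against a validated interaction universe, and qPCR
relative quantification. It is written for computational biologists who
want a tested, deterministic reimplementation of this analysis chain that
runs on synthetic data with known ground truth — every stage ships with a
generator that plants the structure the stage is supposed to find.

## The statistics at the core

- **Fragment rule.** tRNA/YRNA-derived serum fragments are 30–34 nt and
  5′-anchored; a read is counted for a locus iff its length ∈ [30, 34],
  strands match, and its 5′ terminus lies within `tol` (default 0) nt of
  the locus 5′ terminus. Multi-mapped reads count toward every matching
  locus, and read bookkeeping is conserved (assigned + rejected = input).
- **Differential abundance.** Counts are NB with variance μ + φμ²
  (BCV = √φ). After TMM normalization, the unpaired design uses the
  conditional exact test on equalized group sums; the paired design fits
  log μ = patient + condition + log(effective library size) and tests the
  condition coefficient by LRT against χ²(1). p-values are BH-adjusted;
  significance is FDR < 5%.
- **Coexpression modules.** Unsigned weighted network a_ij = |cor|^β
  (β = 6), topological overlap
  TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
  average-linkage clustering of 1 − TOM with an adaptive cut
  (deepSplit 3, min module size 10, unassigned = Gray), module eigengenes
  (first PC), module membership kME, trait gene significance |cor(x, trait)|,
  and eigengene–trait correlations.
- **Overtargeting.** For k selected module miRNAs, a gene targeted by x
  of them out of T_g universe miRNAs has upper-tail p = P(X ≥ x),
  X ~ Hypergeom(N, T_g, k); BH over tested genes; module-level empirical
  p from 100,000 random k-miRNA sets drawn from the same universe.
- **qPCR.** fold = 2^−ΔΔCt against a housekeeping reference and control
  group, Student's t on log2 folds.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic cohort (seed 1) and write tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_profile_fragments.py
python analysis/03_differential_abundance.py
python analysis/04_coexpression_modules.py
python analysis/05_overtargeting.py
python analysis/06_qpcr_validation.py
```

Step 2 prints the fragment-rule check — with the default decoy mix
(10% wrong-length, 5% 3′-anchored, 5% internal) the caller recovers the
planted per-locus counts exactly:

```
tRNA: 88.89% of 30-34 nt reads are 5'-anchored
YRNA: 88.89% of 30-34 nt reads are 5'-anchored
counts match planted truth exactly: True
```

Step 3 reports both designs (200 of 2,000 features planted at 6-fold,
BCV ≈ 0.32) with signed fold-change display, e.g.:

```
unpaired design: BCV 0.307; 218 significant at FDR<5% (sensitivity 0.99, observed FDR 0.087)
             avg_cpm  fc_display    p  fdr
feat01737   699.6203      8.5362  0.0  0.0
feat00861  4666.0575     -7.8043  0.0  0.0
...
MDS dimension 1 separates the groups: True
```

Step 4 shows the soft-power scan reaching scale-free fit R² ≈ 0.81 at
β = 6 and finds the planted trait-linked module
(`turquoise, r = 0.947`); step 5 selects its top miRNAs by kME and finds
47 significantly overtargeted genes (47 of the 50 planted genes, zero
false positives) with a random-set empirical p < 10⁻⁵, then exports the
bipartite network
(SIF/GraphML/TSV) plus term enrichment (the planted term at
p = 5.6 × 10⁻⁸⁶). Step 6 recovers the planted qPCR folds:

```
  gene  mean_fold_case  mean_fold_control      p
FBXO31          0.3466                1.0 0.0000
  WEE1          0.5310                1.0 0.0017
   RB1          0.8457                1.0 0.3938
  E2F1          0.7161                1.0 0.0966
```

The same stages are scriptable through the `sncpipe` CLI
(`simulate`, `profile`, `de`, `coexpress`, `overtarget`, `enrich`,
`relquant`, `run`, `report`); `sncpipe run --seed 1 --out run/` executes
the full pipeline from a YAML config and writes a machine-readable
`report.json` with versions, per-stage seeds, row counts and warnings.
Reruns with the same config are byte-identical.

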