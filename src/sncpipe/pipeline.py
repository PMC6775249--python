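"""End-to-end orchestration with a declarative config and a run report.

Stages: simulate -> profile -> de (unpaired serum-style and paired
tissue-style) -> coexpress (pooled matrix) -> overtarget -> enrich ->
relquant.  A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])``, so reruns with the
same config reproduce every stochastic stage bit-identically.  Every
output table carries a header comment with the config hash; the report
records versions, seeds, parameters, per-stage row counts and warnings.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import coexpression as coex
from . import diffexpr as de
from . import overtargeting as ot
from . import profiling, relquant, synthetic

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "config_hash",
           "stage_seed", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "profile": True,
        "de_unpaired": True,
        "de_paired": True,
        "coexpress": True,
        "overtarget": True,
        "enrich": True,
        "relquant": True,
    },
    "inputs": {},  # optional external files: counts, annotation, reads, ...
    "simulate": {
        "n_samples_per_group": 5,
        "n_features": 2000,
        "dispersion": 0.1,
        "de_fraction": 0.1,
        "de_fold": 6.0,
        "noise_sd": 0.5,
        "reads_per_locus": 100,
    },
    "profile": {"tol": 0},
    "de": {"fdr": 0.05, "prior_df": 10.0},
    "coexpress": {"beta": 6.0, "deep_split": 3, "min_module_size": 10, "mad_threshold": 0.0},
    "overtarget": {"k": 10, "n_iter": 2000, "fdr": 0.05},
    "enrich": {"p": 0.01, "fdr": 0.05},
    "relquant": {"reference_gene": "B2M", "control_group": "normal"},
}

_STAGE_INDEX = {
    "simulate": 0, "profile": 1, "de_unpaired": 2, "de_paired": 3,
    "coexpress": 4, "overtarget": 5, "enrich": 6, "relquant": 7,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path) -> dict:
    """Read a YAML config and merge it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def validate_config(cfg: dict) -> None:
    """Fail before any stage runs: referenced files must exist, parameters
    must be in range."""
    for key, path in (cfg.get("inputs") or {}).items():
        if path and not Path(path).exists():
            raise FileNotFoundError(f"configured input {key!r} not found: {path}")
    if cfg["coexpress"]["deep_split"] not in range(5):
        raise ValueError("coexpress.deep_split must be in 0..4")
    if not 0 < cfg["de"]["fdr"] <= 1:
        raise ValueError("de.fdr must be in (0, 1]")
    if cfg["overtarget"]["k"] < 1:
        raise ValueError("overtarget.k must be >= 1")


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def _write_tsv(df: pd.DataFrame, path: Path, chash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sncpipe config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Execute the configured stages, writing tables and report.json.

    Stage failure aborts with the stage name in the error; partial outputs
    are kept next to a FAILED marker naming the stage.
    """
    cfg = _merge(DEFAULT_CONFIG, cfg)
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    report: dict = {
        "versions": {
            "sncpipe": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": cfg["seed"],
        "config_hash": chash,
        "parameters": {k: cfg[k] for k in
                       ("simulate", "profile", "de", "coexpress", "overtarget",
                        "enrich", "relquant")},
        "stage_seeds": {},
        "stages": {},
        "warnings": [],
    }
    stages = cfg["stages"]
    state: dict = {}

    def _run(name, fn):
        if not stages.get(name, False):
            return
        report["stage_seeds"][name] = stage_seed(cfg["seed"], name)
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                rows = fn()
            report["warnings"] += [f"{name}: {w.message}" for w in caught]
            report["stages"][name] = {
                "rows": rows,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        except Exception as exc:
            (out / "FAILED").write_text(f"{name}: {exc}\n")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # ---- simulate ---------------------------------------------------------
    def _simulate():
        sim = cfg["simulate"]
        scfg = synthetic.SimulationConfig(
            seed=stage_seed(cfg["seed"], "simulate"),
            n_samples_per_group=sim["n_samples_per_group"],
            n_features=sim["n_features"],
            dispersion=sim["dispersion"],
            de_fraction=sim["de_fraction"],
            de_fold=sim["de_fold"],
            noise_sd=sim["noise_sd"],
            reads_per_locus=sim["reads_per_locus"],
        )
        state["scfg"] = scfg
        ann = synthetic.simulate_annotation(seed=scfg.seed)
        reads, read_truth = synthetic.simulate_fragment_reads(ann, scfg)
        counts, de_truth = synthetic.simulate_counts(scfg)
        # pooled expression matrix: rename features to universe miRNA ids and
        # fragment ids so the coexpression and overtargeting stages connect
        mat, trait, mod_truth = synthetic.simulate_module_data(scfg)
        edges, planted_genes, planted_mirnas = synthetic.simulate_interaction_universe(scfg)
        # the trait-linked module holds the designated (planted) miRNAs plus
        # tRNA-half features; other modules get background miRNAs -- mirrors
        # a miRNA-enriched cancer module that also contains 5' tRNA halves
        planted_norm = [m.lower() for m in planted_mirnas]
        background = sorted(set(edges["mirna"].str.lower()) - set(planted_norm))
        new_names, classes = [], []
        bi = pi = 0
        for i, feat in enumerate(mat.index):
            module = mod_truth.loc[i, "true_module"]
            trait_linked = module == "M1" and any(t for _, t in scfg.module_spec[:1])
            if trait_linked and pi < len(planted_norm):
                new_names.append(planted_norm[pi])
                classes.append("miRNA")
                pi += 1
            elif module != "unassigned" and not trait_linked and bi < len(background):
                new_names.append(background[bi])
                classes.append("miRNA")
                bi += 1
            elif i % 2 == 0:
                new_names.append(f"tRNA-Syn-AAA-{i + 1}-1-5p-half")
                classes.append("tRNA_half")
            else:
                new_names.append(f"RNY-syn{i + 1}-5p-frag")
                classes.append("YRNA_fragment")
        mat.index = pd.Index(new_names, name="feature")
        mod_truth = mod_truth.assign(feature=new_names, feature_class=classes)
        ct = synthetic.simulate_ct_table(scfg)

        _write_tsv(ann, out / "annotation.tsv", chash, index=False)
        _write_tsv(reads, out / "reads.tsv", chash, index=False)
        _write_tsv(read_truth, out / "read_truth.tsv", chash, index=False)
        _write_tsv(counts, out / "counts.tsv", chash)
        _write_tsv(de_truth, out / "de_truth.tsv", chash, index=False)
        _write_tsv(mat, out / "expression_pooled.tsv", chash)
        _write_tsv(trait.to_frame(), out / "trait.tsv", chash)
        _write_tsv(mod_truth, out / "module_truth.tsv", chash, index=False)
        _write_tsv(edges, out / "interactions.tsv", chash, index=False)
        universe_truth = pd.concat([
            pd.DataFrame({"kind": "planted_gene", "id": planted_genes}),
            pd.DataFrame({"kind": "planted_mirna", "id": planted_mirnas}),
        ], ignore_index=True)
        _write_tsv(universe_truth, out / "universe_truth.tsv", chash, index=False)
        _write_tsv(ct, out / "ct_values.tsv", chash, index=False)
        state.update(
            ann=ann, reads=reads, counts=counts, mat=mat, trait=trait,
            mod_truth=mod_truth, edges=edges, planted_genes=planted_genes,
            planted_mirnas=planted_mirnas, ct=ct, classes=pd.Series(classes, index=mat.index),
        )
        return {"loci": len(ann), "reads": len(reads), "features": len(counts)}

    # ---- profile ----------------------------------------------------------
    def _profile():
        fc = profiling.count_fragments(state["reads"], state["ann"], tol=cfg["profile"]["tol"])
        qc = fc.rejections.copy()
        qc["library_size"] = fc.library_sizes
        qc["five_prime_fraction_trna"] = profiling.five_prime_fraction(
            state["reads"], state["ann"], "tRNA", tol=cfg["profile"]["tol"]
        )
        _write_tsv(fc.counts, out / "fragment_counts.tsv", chash)
        _write_tsv(qc, out / "fragment_qc.tsv", chash)
        state["fragment_counts"] = fc
        return {"loci": fc.counts.shape[0], "samples": fc.counts.shape[1]}

    # ---- differential expression -----------------------------------------
    def _groups(columns):
        return pd.Series(["N" if c.startswith("N") else "C" for c in columns],
                         index=columns)

    def _de_unpaired():
        counts = state["counts"]
        table, info = de.de_unpaired(counts, _groups(counts.columns),
                                     prior_df=cfg["de"]["prior_df"])
        _write_tsv(table, out / "de_serum_style.tsv", chash)
        sig = de.significant_set(table, cfg["de"]["fdr"])
        _write_tsv(sig, out / "de_serum_style_significant.tsv", chash)
        mds = de.mds_coordinates(counts, factors=info["factors"])
        _write_tsv(mds.coords, out / "mds_serum_style.tsv", chash)
        state["de_table"] = table
        return {"features": len(table), "significant": len(sig),
                "dropped_all_zero": info["n_dropped_all_zero"],
                "bcv": round(info["dispersion"].bcv, 4)}

    def _de_paired():
        counts = state["counts"]
        n = counts.shape[1] // 2
        blocks = pd.Series([f"P{i % n + 1}" for i in range(2 * n)], index=counts.columns)
        table, info = de.de_paired(counts, _groups(counts.columns), blocks,
                                   prior_df=cfg["de"]["prior_df"])
        _write_tsv(table, out / "de_tissue_style.tsv", chash)
        sig = de.significant_set(table, cfg["de"]["fdr"])
        _write_tsv(sig, out / "de_tissue_style_significant.tsv", chash)
        return {"features": len(table), "significant": len(sig)}

    # ---- coexpression -----------------------------------------------------
    def _coexpress():
        cx = cfg["coexpress"]
        mat, _ = coex.mad_filter(state["mat"], cx["mad_threshold"])
        a = coex.adjacency_matrix(mat, beta=cx["beta"])
        tom = coex.tom_from_adjacency(a)
        assign = coex.cluster_and_cut(1.0 - tom, deep_split=cx["deep_split"],
                                      min_module_size=cx["min_module_size"],
                                      feature_ids=mat.index)
        eig = coex.module_eigengenes(mat, assign.labels)
        mm, gs = coex.membership_and_significance(mat, eig, state["trait"])
        mt = coex.module_trait_stats(eig, state["trait"], gs, assign.labels)
        _write_tsv(assign.labels.to_frame(), out / "modules.tsv", chash)
        _write_tsv(eig.eigengenes, out / "eigengenes.tsv", chash)
        _write_tsv(mm.join(gs), out / "mm_gs.tsv", chash)
        _write_tsv(mt, out / "module_trait.tsv", chash)
        state.update(assign=assign, eig=eig, mm=mm, gs=gs, mt=mt)
        n_modules = len(assign.sizes)
        return {"features": len(mat), "modules": n_modules,
                "gray": int((assign.labels == coex.GRAY).sum())}

    # ---- overtargeting ----------------------------------------------------
    def _overtarget():
        otc = cfg["overtarget"]
        universe = ot.build_universe(state["edges"])
        if state["mt"].empty:
            raise ValueError("no modules found; cannot pick a trait module")
        trait_module = state["mt"]["r"].abs().idxmax()
        selected, missing = ot.select_top_module_mirnas(
            state["mm"], state["gs"], state["assign"].labels, trait_module,
            universe, classes=state["classes"], k=otc["k"],
        )
        result = ot.overtargeting_test(selected, universe, otc["fdr"])
        observed = int(result["significant"].sum())
        sim = ot.random_set_pvalue(
            universe, k=len(selected), observed_count=observed,
            n_iter=otc["n_iter"], fdr_threshold=otc["fdr"],
            seed=stage_seed(cfg["seed"], "overtarget"),
        )
        _write_tsv(result, out / "overtargeting.tsv", chash, index=False)
        summary = pd.DataFrame(
            [{"trait_module": trait_module, "k": len(selected),
              "missing_from_universe": len(missing),
              "observed_significant": observed, "n_iter": sim.n_iter,
              "empirical_p": sim.empirical_p}]
        )
        _write_tsv(summary, out / "overtargeting_summary.tsv", chash, index=False)
        ot.export_network(selected, result, universe, out / "network")
        state.update(universe=universe, ot_result=result, selected=selected)
        return {"selected": len(selected), "tested_genes": len(result),
                "significant_genes": observed, "empirical_p": sim.empirical_p}

    # ---- enrichment -------------------------------------------------------
    def _enrich():
        universe = state["universe"]
        # synthetic annotation: planted genes share a term; background terms random
        rng = np.random.default_rng(stage_seed(cfg["seed"], "enrich"))
        genes = universe.genes
        terms = [f"TERM{t:03d}" for t in range(20)]
        ann_rows = [{"gene": g, "term": rng.choice(terms), "term_name": "background"}
                    for g in genes]
        planted = [g for g in (p.lower() for p in state["planted_genes"])
                   if g in set(genes)]
        ann_rows += [{"gene": g, "term": "TERM_PLANTED", "term_name": "planted process"}
                     for g in planted]
        ann = pd.DataFrame(ann_rows)
        query = state["ot_result"].loc[state["ot_result"]["significant"], "gene"]
        enr = ot.term_enrichment(query, ann, genes, cfg["enrich"]["p"], cfg["enrich"]["fdr"])
        _write_tsv(enr, out / "enrichment.tsv", chash, index=False)
        return {"terms": len(enr), "enriched": int(enr["enriched"].sum())}

    # ---- relquant ---------------------------------------------------------
    def _relquant():
        rq = cfg["relquant"]
        ct = state["ct"]
        targets = [g for g in ct["gene_id"].unique() if g != rq["reference_gene"]]
        table = relquant.relquant_table(ct, targets, rq["reference_gene"],
                                        rq["control_group"])
        _write_tsv(table, out / "relquant.tsv", chash, index=False)
        return {"genes": len(table)}

    _run("simulate", _simulate)
    _run("profile", _profile)
    _run("de_unpaired", _de_unpaired)
    _run("de_paired", _de_paired)
    _run("coexpress", _coexpress)
    _run("overtarget", _overtarget)
    _run("enrich", _enrich)
    _run("relquant", _relquant)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
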