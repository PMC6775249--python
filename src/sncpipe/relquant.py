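"""qPCR relative quantification by the 2^-ddCt method.

dCt = Ct(target) - Ct(reference) per sample; ddCt subtracts the control
group's mean dCt (equivalently, divides by the control group's geometric
mean relative quantity); fold change = 2^-ddCt.  Group differences are
tested with Student's t on log-transformed fold changes (Welch optional).
Technical replicates are averaged per (sample, gene) before dCt.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct_fold_changes", "log_fold_test", "relquant_table"]

CT_COLUMNS = ["sample_id", "gene_id", "ct", "group"]


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return ct


def ddct_fold_changes(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str,
    pairwise: bool = False,
) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes for one target gene.

    Default mode centres every sample's dCt on the control group's mean
    dCt.  ``pairwise`` mode instead subtracts the matched control sample's
    dCt within each pair (requires a ``pair_id`` column), for designs where
    tumour and adjacent-normal tissue come from the same patient.
    """
    ct = _validate_ct(ct)
    # technical replicates -> one Ct per (sample, gene)
    agg = (
        ct.groupby(["sample_id", "gene_id", "group"], sort=False)
        .agg(ct=("ct", "mean"), **({"pair_id": ("pair_id", "first")} if "pair_id" in ct else {}))
        .reset_index()
    )
    tgt = agg[agg["gene_id"] == target_gene].set_index("sample_id")
    ref = agg[agg["gene_id"] == reference_gene].set_index("sample_id")
    if len(tgt) == 0:
        raise ValueError(f"no Ct rows for target gene {target_gene!r}")
    missing_ref = [s for s in tgt.index if s not in ref.index]
    if missing_ref:
        raise ValueError(
            f"reference gene {reference_gene!r} missing for sample(s): {missing_ref}"
        )
    dct = tgt["ct"] - ref.loc[tgt.index, "ct"]
    groups = tgt["group"]
    control = groups == control_group
    if control.sum() == 0:
        raise ValueError(f"no samples in control group {control_group!r}")
    if pairwise:
        if "pair_id" not in tgt.columns:
            raise ValueError("pairwise mode needs a pair_id column")
        ctrl_by_pair = dct[control].groupby(tgt.loc[control, "pair_id"]).mean()
        baseline = tgt["pair_id"].map(ctrl_by_pair)
        if baseline.isna().any():
            bad = list(tgt.index[baseline.isna()])
            raise ValueError(f"no matched control dCt for sample(s): {bad}")
        ddct = dct - baseline
    else:
        ddct = dct - dct[control].mean()
    return pd.DataFrame(
        {
            "sample_id": tgt.index,
            "group": groups.to_numpy(),
            "dct": dct.to_numpy(),
            "ddct": ddct.to_numpy(),
            "fold": 2.0 ** (-ddct.to_numpy()),
        }
    ).reset_index(drop=True)


def log_fold_test(folds_a, folds_b, equal_var: bool = True) -> float:
    """Two-sided two-sample t-test on log2 fold changes."""
    a = np.asarray(folds_a, dtype=float)
    b = np.asarray(folds_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 fold changes per group")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("fold changes must be positive for the log transform")
    la, lb = np.log2(a), np.log2(b)
    if la.var(ddof=1) == 0 and lb.var(ddof=1) == 0:
        # degenerate zero-variance case: identical means are indistinguishable
        return 1.0 if np.isclose(la.mean(), lb.mean()) else 0.0
    res = stats.ttest_ind(la, lb, equal_var=equal_var)
    return float(res.pvalue)


def relquant_table(
    ct: pd.DataFrame,
    target_genes,
    reference_gene: str,
    control_group: str,
    case_group: str | None = None,
    pairwise: bool = False,
) -> pd.DataFrame:
    """Fold-change summary and t-test p per target gene."""
    ct = _validate_ct(ct)
    groups = [g for g in pd.unique(ct["group"]) if g != control_group]
    if case_group is None:
        if len(groups) != 1:
            raise ValueError("specify case_group when more than two groups are present")
        case_group = groups[0]
    rows = []
    for gene in target_genes:
        folds = ddct_fold_changes(ct, gene, reference_gene, control_group, pairwise=pairwise)
        fa = folds.loc[folds["group"] == case_group, "fold"]
        fb = folds.loc[folds["group"] == control_group, "fold"]
        rows.append(
            {
                "gene": gene,
                "mean_fold_case": float(np.exp(np.log(fa).mean())),
                "mean_fold_control": float(np.exp(np.log(fb).mean())),
                "p": log_fold_test(fa, fb),
            }
        )
    return pd.DataFrame(rows)
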