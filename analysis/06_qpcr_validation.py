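#!/usr/bin/env python
"""Step 6 -- qPCR validation of overtargeted-gene downregulation.

2^-ddCt relative quantification against the housekeeping reference with
control-group centring, followed by Student's t on the log-transformed
fold changes -- the wet-lab style confirmation step of the analysis.
"""

from pathlib import Path

import pandas as pd

from sncpipe import relquant as rq

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ct = pd.read_csv(BASE / "data" / "ct_values.tsv", sep="\t", comment="#")
    targets = [g for g in ct["gene_id"].unique() if g != "B2M"]
    table = rq.relquant_table(ct, targets, "B2M", "normal")
    out = BASE / "relquant"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "relquant.tsv", sep="\t", index=False)
    print("tumour/normal fold changes (2^-ddCt, geometric means):")
    print(table.round(4).to_string(index=False))
    sig = table[table["p"] < 0.05]
    print(f"{len(sig)} of {len(table)} genes significantly changed "
          f"(t-test on log folds, p < 0.05)")


if __name__ == "__main__":
    main()
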