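#!/usr/bin/env python
"""Step 1 -- generate the synthetic study cohort.

Emulates a 5-versus-5 small-RNA study: aligned 30-34 nt reads anchored at
tRNA/YRNA gene 5' ends (with decoys), an NB count matrix with planted
six-fold changes, a pooled expression matrix with three planted
coexpression modules (the first trait-linked and populated with the
designated miRNAs), a validated miRNA->gene interaction universe with a
planted overtargeted gene set, and a qPCR Ct table.

Writes everything under results/data/ plus the matching truth tables.
"""

import sys
from pathlib import Path

from sncpipe import pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 1) -> None:
    cfg = {
        "seed": seed,
        "stages": {name: name == "simulate" for name in pipeline.DEFAULT_CONFIG["stages"]},
    }
    report = pipeline.run_pipeline(cfg, OUT)
    rows = report["stages"]["simulate"]["rows"]
    print(f"simulated {rows['loci']} loci, {rows['reads']} aligned reads, "
          f"{rows['features']} count features -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
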