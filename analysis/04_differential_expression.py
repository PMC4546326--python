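#!/usr/bin/env python
"""Tumor-vs-normal fold-change DEG screen (|log2FC| > 1, strict).

Writes results/degs.tsv and reports the up/down split.
"""

from pathlib import Path

import pandas as pd

from cnvdrive.diffexpr import compute_log2fc, screen_degs
from cnvdrive.formats_io import read_expression

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix = read_expression(
        BASE / "cohort" / "expression.tsv", BASE / "cohort" / "groups.tsv"
    )
    log2fc = compute_log2fc(matrix)
    degs = screen_degs(log2fc, cutoff=1.0)
    table = pd.DataFrame(
        [{"gene": d.gene, "log2_fc": d.log2_fc, "direction": d.direction}
         for d in degs]
    )
    table.to_csv(BASE / "degs.tsv", sep="\t", index=False)
    n_up = sum(d.direction == "up" for d in degs)
    print(f"{len(degs)} DEGs of {len(matrix.genes)} measured genes "
          f"({n_up} up, {len(degs) - n_up} down) -> results/degs.tsv")


if __name__ == "__main__":
    main()
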