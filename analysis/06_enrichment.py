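#!/usr/bin/env python
"""Hypergeometric over-representation of the driven genes in toy gene sets.

Universe = all genes measured on the (synthetic) expression platform.
Writes results/enrichment.tsv.
"""

from pathlib import Path

import pandas as pd

from cnvdrive.enrichment import enrich
from cnvdrive.formats_io import read_expression, read_gene_sets

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    driven = pd.read_csv(BASE / "driven.tsv", sep="\t")
    matrix = read_expression(
        BASE / "cohort" / "expression.tsv", BASE / "cohort" / "groups.tsv"
    )
    gene_sets = read_gene_sets(BASE / "cohort" / "gene_sets.gmt")
    results = enrich(driven.gene, gene_sets, matrix.genes, alpha=0.05)
    pd.DataFrame(
        [
            {
                "term": r.term, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p_value": r.p_value, "q_value_bh": r.q_value_bh,
                "significant": r.significant, "hits": ",".join(r.hits),
            }
            for r in results
        ]
    ).to_csv(BASE / "enrichment.tsv", sep="\t", index=False)
    n_sig = sum(r.significant for r in results)
    print(f"{n_sig} of {len(results)} gene sets significant at p < 0.05 "
          "-> results/enrichment.tsv")
    if n_sig:
        top = results[0]
        print(f"  top term {top.term}: k={top.k}, K={top.K}, p={top.p_value:.3g}")


if __name__ == "__main__":
    main()
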