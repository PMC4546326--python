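"""Bundled reference table of lung squamous-cell carcinoma candidate genes.

The table lists genes found recurrently copy-number altered in the TCGA
LUSC tumor/normal SNP6 cohort (gain or loss in more than 80% of tumors,
absent from matched normals) that were also differentially expressed
(|log2 fold change| > 1) in the GSE17710 tumor/normal expression cohort,
together with their mean log2 absolute copy number, log2 fold change and
karyotype band.  It serves as an in-package worked example and as the input
for re-deriving the concordance-classified driven-gene list at desk scale.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .driver_integration import DriverCandidate

_DATA_FILE = "lusc_candidates.tsv"


def load_lusc_candidate_table() -> pd.DataFrame:
    """The candidate table as a DataFrame (chromosome, gene, log2_copy_number,
    log2_fc, band)."""
    with resources.files("cnvdrive.data").joinpath(_DATA_FILE).open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_lusc_candidates() -> list[DriverCandidate]:
    """The candidate table as :class:`DriverCandidate` records, ready for
    :func:`cnvdrive.driver_integration.classify_driven`."""
    table = load_lusc_candidate_table()
    return [
        DriverCandidate(
            gene=row.gene,
            chromosome=int(row.chromosome),
            log2_copy_number=float(row.log2_copy_number),
            log2_fc=float(row.log2_fc),
            band=row.band,
        )
        for row in table.itertuples()
    ]
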