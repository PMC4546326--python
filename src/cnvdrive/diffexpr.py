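"""Tumor-vs-normal fold-change screening.

The screen is fold-change-only: log2FC(g) = mean log2 expression over tumor
samples minus mean over normal samples, and a gene is a DEG iff
|log2FC| > cutoff (strict; default cutoff 1).  No variance model or p-value
enters at this stage.  A matched-pair mode (mean of within-patient tumor
minus normal differences) is available for paired designs; with complete
pairs it equals the group-mean difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .formats_io import ExpressionMatrix

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class DegRecord:
    """A gene passing the fold-change screen."""

    gene: str
    log2_fc: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise DataError(f"direction must be up/down, got {self.direction!r}")
        if (self.log2_fc > 0) != (self.direction == UP):
            raise DataError(
                f"gene {self.gene}: direction {self.direction} inconsistent "
                f"with log2FC {self.log2_fc}"
            )


def compute_log2fc(matrix: ExpressionMatrix, paired: bool = False) -> pd.Series:
    """Per-gene log2 fold change (tumor minus normal), on the log2 scale.

    Genes with all-missing values in either group are excluded with a
    warning.  ``paired=True`` pairs tumor and normal samples by their order
    in the matrix (requires equal group sizes) and averages within-pair
    differences.
    """
    tumor = matrix.values[matrix.tumor_samples]
    normal = matrix.values[matrix.normal_samples]
    if paired:
        if len(matrix.tumor_samples) != len(matrix.normal_samples):
            raise DataError("paired mode requires equally sized groups")
        diffs = tumor.to_numpy() - normal.to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            log2fc = pd.Series(np.nanmean(diffs, axis=1), index=matrix.values.index)
    else:
        log2fc = tumor.mean(axis=1, skipna=True) - normal.mean(axis=1, skipna=True)
    dropped = log2fc.index[log2fc.isna()]
    if len(dropped):
        warnings.warn(
            f"excluded {len(dropped)} gene(s) with all-missing values in a "
            f"group: {', '.join(map(str, dropped[:5]))}"
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
        log2fc = log2fc.dropna()
    log2fc.name = "log2_fc"
    return log2fc


def screen_degs(log2fc: pd.Series, cutoff: float = 1.0) -> list[DegRecord]:
    """Strict fold-change screen: keep genes with |log2FC| > cutoff."""
    if cutoff < 0:
        raise DataError("cutoff must be non-negative")
    if not np.isfinite(log2fc.to_numpy(dtype=float)).all():
        raise DataError("log2 fold changes must be finite")
    records = []
    for gene, value in log2fc.items():
        if abs(value) > cutoff:
            records.append(
                DegRecord(gene=str(gene), log2_fc=float(value),
                          direction=UP if value > 0 else DOWN)
            )
    return records
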