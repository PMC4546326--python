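"""CNV-driven gene calling: the copy-number / expression concordance rule.

A *CNV-driven gene* is a recurrently copy-number-altered gene whose
differential-expression direction matches its copy-number direction: an
up-regulated DEG must show a copy-number gain (log2 absolute CN > 1) and a
down-regulated DEG a loss (< 1).  Concordance is evaluated on signs relative
to the neutral values (1 for log2 copy number, 0 for log2 fold change),
never on magnitudes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .cnv_events import DELETION, DUPLICATION, NEUTRAL_LOG2_CN
from .diffexpr import DOWN, UP
from .errors import DataError


@dataclass(frozen=True)
class DriverCandidate:
    """A gene that is both a recurrent CNV gene and a DEG, pre-concordance."""

    gene: str
    chromosome: int
    log2_copy_number: float
    log2_fc: float
    cnv_state: Optional[str] = None  # derived from log2_copy_number if None
    deg_direction: Optional[str] = None  # derived from log2_fc if None
    band: Optional[str] = None


@dataclass(frozen=True)
class DrivenGene:
    """A concordant CNV-driven gene; the invariant is asserted on construction."""

    gene: str
    chromosome: int
    log2_copy_number: float
    log2_fc: float
    cnv_state: str
    deg_direction: str
    band: Optional[str] = None

    def __post_init__(self) -> None:
        concordant = (self.cnv_state == DUPLICATION and self.deg_direction == UP) or (
            self.cnv_state == DELETION and self.deg_direction == DOWN
        )
        if not concordant:
            raise DataError(
                f"gene {self.gene}: {self.cnv_state}/{self.deg_direction} is "
                "not a concordant CNV-driven combination"
            )


def overlap_genes(
    cnv_genes: Iterable[str],
    deg_genes: Iterable[str],
    measured_genes: Iterable[str],
) -> tuple[set[str], set[str]]:
    """The candidate funnel: CNV genes measured on the expression platform,
    and the subset of those that are DEGs."""
    cnv = set(cnv_genes)
    measured_cnv = cnv & set(measured_genes)
    deg_cnv = measured_cnv & set(deg_genes)
    return measured_cnv, deg_cnv


def _state_of(candidate: DriverCandidate) -> str:
    if candidate.cnv_state is not None:
        state = candidate.cnv_state
    elif candidate.log2_copy_number > NEUTRAL_LOG2_CN:
        state = DUPLICATION
    elif candidate.log2_copy_number < NEUTRAL_LOG2_CN:
        state = DELETION
    else:
        state = "neutral"
    if state not in (DELETION, DUPLICATION):
        raise DataError(
            f"gene {candidate.gene}: neutral copy-number state among driver "
            "candidates (should have been filtered upstream)"
        )
    return state


def _direction_of(candidate: DriverCandidate) -> str:
    if candidate.deg_direction is not None:
        if candidate.deg_direction not in (UP, DOWN):
            raise DataError(
                f"gene {candidate.gene}: unknown DEG direction "
                f"{candidate.deg_direction!r}"
            )
        return candidate.deg_direction
    if candidate.log2_fc == 0:
        raise DataError(f"gene {candidate.gene}: zero fold change has no direction")
    return UP if candidate.log2_fc > 0 else DOWN


def classify_driven(candidates: Sequence[DriverCandidate]) -> list[DrivenGene]:
    """Keep candidates whose copy-number and expression signs agree.

    Output is sorted by chromosome, then |log2FC| descending.  The function
    is idempotent: rerunning it on its own output changes nothing.
    """
    driven = []
    for cand in candidates:
        state = _state_of(cand)
        direction = _direction_of(cand)
        concordant = (state == DUPLICATION and direction == UP) or (
            state == DELETION and direction == DOWN
        )
        if concordant:
            driven.append(
                DrivenGene(
                    gene=cand.gene,
                    chromosome=cand.chromosome,
                    log2_copy_number=cand.log2_copy_number,
                    log2_fc=cand.log2_fc,
                    cnv_state=state,
                    deg_direction=direction,
                    band=cand.band,
                )
            )
    driven.sort(key=lambda d: (d.chromosome, -abs(d.log2_fc), d.gene))
    return driven


def chromosome_summary(driven: Iterable[DrivenGene]) -> dict[int, int]:
    """Count of driven genes per chromosome (empty input -> empty map)."""
    return dict(Counter(d.chromosome for d in driven))
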