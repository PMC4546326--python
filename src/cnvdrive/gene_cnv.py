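"""Gene-level copy-number calls and the case-recurrence filter.

A gene is *called* in a sample when a CNV event of that sample contains the
gene interval (default semantics: full containment — the gene lies within
the event; ``any_overlap`` is available as an escape hatch).  A gene is
retained as a recurrent, cohort-specific CNV gene only when one copy-number
state (deletion or duplication) is called in strictly more than
``min_case_fraction`` of the cases while no more than ``max_control_fraction``
of the controls carry any call (default 0: absent from every control).

Samples with no covering event are neutral (log2 absolute copy number 1),
matching the missing-value rule of the segment layer.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .cnv_events import DELETION, DUPLICATION, NEUTRAL_LOG2_CN, CnvEvent
from .errors import DataError
from .formats_io import GeneModel

Call = tuple[str, float]  # (state, log2 absolute copy number)

CONTAINMENT_MODES = ("full", "any_overlap")


@dataclass
class GeneCnvProfile:
    """Per-gene, per-sample copy-number calls with cohort frequencies.

    ``calls`` holds only non-neutral calls; absent samples are neutral.
    """

    gene: str
    chromosome: int
    calls: dict[str, Call]
    case_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def state_fraction(self, state: str) -> float:
        """Fraction of case samples called with ``state``."""
        hits = sum(1 for s in self.case_samples if self.calls.get(s, (None,))[0] == state)
        return hits / len(self.case_samples)

    @property
    def case_frequency(self) -> float:
        hits = sum(1 for s in self.case_samples if s in self.calls)
        return hits / len(self.case_samples)

    @property
    def control_frequency(self) -> float:
        hits = sum(1 for s in self.control_samples if s in self.calls)
        return hits / len(self.control_samples)

    @property
    def recurrent_state(self) -> str:
        """Modal non-neutral state among cases (ties favor duplication)."""
        dup = self.state_fraction(DUPLICATION)
        dele = self.state_fraction(DELETION)
        if dup == 0 and dele == 0:
            raise DataError(f"gene {self.gene}: no non-neutral case calls")
        return DUPLICATION if dup >= dele else DELETION

    def log2cn(self, sample: str) -> float:
        """Call value for a sample, neutral fill when uncalled."""
        return self.calls.get(sample, (None, NEUTRAL_LOG2_CN))[1]

    @property
    def mean_case_log2cn(self) -> float:
        """Mean log2 absolute CN over all cases, neutral fill for uncalled."""
        return sum(self.log2cn(s) for s in self.case_samples) / len(self.case_samples)


def _better(a: Call, b: Call) -> Call:
    """Conflict resolution: the call further from neutral wins; exact ties
    resolve to the larger log2 copy number (deterministic)."""
    key = lambda c: (abs(c[1] - NEUTRAL_LOG2_CN), c[1])
    return a if key(a) >= key(b) else b


def map_events_to_genes(
    events: Sequence[CnvEvent],
    gene_models: Sequence[GeneModel],
    containment: str = "full",
) -> dict[str, dict[str, Call]]:
    """Per-gene, per-sample state calls from event/gene interval overlap.

    Under ``full`` a gene is called in a sample iff some event of that sample
    entirely contains the gene interval; the call takes the event's state and
    log2 copy number.  Conflicting calls in one sample resolve to the one
    with the larger |log2CN - 1|.
    """
    if containment not in CONTAINMENT_MODES:
        raise DataError(f"containment must be one of {CONTAINMENT_MODES}")
    trees: dict[int, IntervalTree] = defaultdict(IntervalTree)
    for idx, e in enumerate(events):
        trees[e.chromosome].addi(e.start, e.end, idx)
    calls: dict[str, dict[str, Call]] = {}
    for gene in gene_models:
        per_sample: dict[str, Call] = {}
        tree = trees.get(gene.chromosome)
        if tree is not None:
            for interval in tree.overlap(gene.start, gene.end):
                e = events[interval.data]
                if containment == "full" and not (
                    e.start <= gene.start and e.end >= gene.end
                ):
                    continue
                call = (e.state, e.log2_copy_number)
                if e.sample in per_sample:
                    call = _better(per_sample[e.sample], call)
                per_sample[e.sample] = call
        calls[gene.symbol] = per_sample
    return calls


def build_profiles(
    events: Sequence[CnvEvent],
    gene_models: Sequence[GeneModel],
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    containment: str = "full",
) -> list[GeneCnvProfile]:
    """Gene profiles for the whole cohort, ordered by genomic position."""
    if not case_samples or not control_samples:
        raise DataError("both cohorts must be non-empty")
    calls = map_events_to_genes(events, gene_models, containment=containment)
    ordered = sorted(gene_models, key=lambda g: (g.chromosome, g.start, g.symbol))
    return [
        GeneCnvProfile(
            gene=g.symbol,
            chromosome=g.chromosome,
            calls=calls[g.symbol],
            case_samples=tuple(case_samples),
            control_samples=tuple(control_samples),
        )
        for g in ordered
    ]


def frequency_filter(
    profiles: Iterable[GeneCnvProfile],
    min_case_fraction: float = 0.8,
    max_control_fraction: float = 0.0,
) -> list[GeneCnvProfile]:
    """Recurrence filter defining cohort-specific CNV genes.

    Retains a gene iff one single state is called in strictly more than
    ``min_case_fraction`` of cases (a gene duplicated in half the cases and
    deleted in the other half is not recurrent) and the fraction of controls
    with any call is at most ``max_control_fraction``.
    """
    if not 0 <= min_case_fraction <= 1:
        raise DataError("min_case_fraction must be in [0, 1]")
    if not 0 <= max_control_fraction <= 1:
        raise DataError("max_control_fraction must be in [0, 1]")
    retained = []
    for p in profiles:
        if p.control_frequency > max_control_fraction:
            continue
        if max(p.state_fraction(DUPLICATION), p.state_fraction(DELETION)) > min_case_fraction:
            retained.append(p)
    return retained


def summarize_gene_copy_number(profile: GeneCnvProfile) -> float:
    """Mean log2 absolute copy number over the case samples carrying the
    gene's recurrent state (the per-gene copy-number summary reported next
    to the fold change)."""
    state = profile.recurrent_state
    values = [
        call[1]
        for sample, call in profile.calls.items()
        if sample in profile.case_samples and call[0] == state
    ]
    if not values:
        raise DataError(f"gene {profile.gene}: no carriers of state {state}")
    return sum(values) / len(values)
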