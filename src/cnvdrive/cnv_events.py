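"""Segment-to-CNV-event classification.

Conventions
-----------
A *segment mean* is the log2 ratio of the measured copy number of a genomic
segment to the diploid reference copy number 2, i.e. ``log2(CN / 2)``; 0 means
two copies.  Tumor-suite tables instead report the log2 of the *absolute*
copy number, ``log2(CN)``, whose neutral value is ``log2(2) = 1``.  The two
scales differ by exactly 1:

    log2(CN) = log2(CN / 2) + 1 = segment_mean + 1

All classification in this package happens on the absolute scale, where a
value above 1 is a copy-number gain (duplication) and a value below 1 a loss
(deletion).  A dead-band of ``epsilon`` around 1 absorbs floating-point
neutrality.

A copy-number *variant* is a segment of at least 1 kb; shorter segments are
never promoted to events.  Qualifying events are stratified into three length
bins: 1-10 kb, 10-50 kb and >50 kb.  The shared boundaries are assigned to
the lower bin (10,000 bp -> 1-10 kb; 50,000 bp -> 10-50 kb).

Coordinates are 0-based half-open throughout the package; autosomes 1..22
only (sex chromosomes are out of scope for burden tabulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import DataError

# state labels
DELETION = "deletion"
NEUTRAL = "neutral"
DUPLICATION = "duplication"
STATES = (DELETION, DUPLICATION)

# length bins (bp); closed on the left bin at shared boundaries
BIN_SMALL = "1-10kb"
BIN_MEDIUM = "10-50kb"
BIN_LARGE = ">50kb"
LENGTH_BINS = (BIN_SMALL, BIN_MEDIUM, BIN_LARGE)

MIN_CNV_LENGTH = 1_000
NEUTRAL_LOG2_CN = 1.0
DEFAULT_EPSILON = 1e-9

GROUPS = ("case", "control")
AUTOSOMES = tuple(range(1, 23))


@dataclass(frozen=True)
class Segment:
    """One copy-number segment of one sample.

    ``start``/``end`` are 0-based half-open base-pair coordinates on an
    autosome.  ``segment_mean`` is log2(CN/2) and may be NaN when the source
    file lacked a value (filled neutral downstream by :func:`fill_missing`).
    """

    sample: str
    group: str
    chromosome: int
    start: int
    end: int
    segment_mean: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.chromosome not in AUTOSOMES:
            raise DataError(
                f"chromosome must be an autosome 1..22, got {self.chromosome!r}"
            )
        if not self.end > self.start:
            raise DataError(
                f"segment end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvEvent:
    """A classified, length-binned copy-number event (never neutral)."""

    sample: str
    group: str
    chromosome: int
    start: int
    end: int
    segment_mean: float
    log2_copy_number: float
    state: str
    length_bin: str

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise DataError(f"CnvEvent state must be deletion/duplication, got {self.state!r}")
        if self.length_bin not in LENGTH_BINS:
            raise DataError(f"unknown length bin {self.length_bin!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cell(self) -> tuple[int, str, str]:
        """The burden-table cell this event counts toward."""
        return (self.chromosome, self.state, self.length_bin)


def fill_missing(segment_mean: Optional[float]) -> float:
    """Missing segment means are treated as neutral diploid (log2 ratio 0).

    A missing value therefore yields log2 absolute copy number 1 and never
    becomes an event.
    """
    if segment_mean is None:
        return 0.0
    value = float(segment_mean)
    if math.isnan(value):
        return 0.0
    return value


def segment_mean_to_log2cn(segment_mean: float) -> float:
    """Convert log2(CN/2) to log2(CN); the gain/loss threshold sits at 1."""
    value = float(segment_mean)
    if not math.isfinite(value):
        raise DataError(f"segment mean must be finite, got {segment_mean!r}")
    return value + 1.0


def classify_state(log2cn: float, epsilon: float = DEFAULT_EPSILON) -> str:
    """Three-way gain/neutral/loss call around log2 absolute CN = 1."""
    value = float(log2cn)
    if not math.isfinite(value):
        raise DataError(f"log2 copy number must be finite, got {log2cn!r}")
    if value > NEUTRAL_LOG2_CN + epsilon:
        return DUPLICATION
    if value < NEUTRAL_LOG2_CN - epsilon:
        return DELETION
    return NEUTRAL


def assign_length_bin(length_bp: int) -> Optional[str]:
    """Map an event length to its bin; sub-1 kb segments are not CNVs."""
    if length_bp < 1:
        raise DataError(f"length must be >= 1 bp, got {length_bp}")
    if length_bp < MIN_CNV_LENGTH:
        return None
    if length_bp <= 10_000:
        return BIN_SMALL
    if length_bp <= 50_000:
        return BIN_MEDIUM
    return BIN_LARGE


def segments_to_events(
    segments: Iterable[Segment],
    epsilon: float = DEFAULT_EPSILON,
    min_length: int = MIN_CNV_LENGTH,
) -> list[CnvEvent]:
    """Classify segments into CNV events.

    Drops neutral segments (within ``epsilon`` of diploid after the missing
    fill) and segments shorter than ``min_length``.  Output order follows
    input order; counts are insensitive to input permutation by construction.
    """
    events: list[CnvEvent] = []
    for seg in segments:
        if seg.length < min_length:
            continue
        log2cn = segment_mean_to_log2cn(fill_missing(seg.segment_mean))
        state = classify_state(log2cn, epsilon=epsilon)
        if state == NEUTRAL:
            continue
        length_bin = assign_length_bin(seg.length)
        if length_bin is None:  # pragma: no cover - guarded by min_length
            continue
        events.append(
            CnvEvent(
                sample=seg.sample,
                group=seg.group,
                chromosome=seg.chromosome,
                start=seg.start,
                end=seg.end,
                segment_mean=fill_missing(seg.segment_mean),
                log2_copy_number=log2cn,
                state=state,
                length_bin=length_bin,
            )
        )
    return events
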