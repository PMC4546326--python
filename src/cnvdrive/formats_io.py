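"""Readers and writers for every on-disk format the pipeline touches.

Formats: SEG-style segment tables (dialect-configurable coordinates),
a gene x sample expression matrix (TSV plus a side-car sample->group file),
BED-like gene models, GMT gene sets, and plain-text Circos track files.

Internal coordinate convention is 0-based half-open everywhere; the SEG
reader normalizes whatever the declared dialect uses into that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cnv_events import CnvEvent, Segment
from .errors import DataError

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}


def normalize_chromosome(label: str) -> int:
    """Accept '7' or 'chr7'; autosomes only."""
    text = str(label).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    try:
        chrom = int(text)
    except ValueError:
        raise DataError(f"unknown chromosome label {label!r} (autosomes 1..22 only)")
    if not 1 <= chrom <= 22:
        raise DataError(f"unknown chromosome label {label!r} (autosomes 1..22 only)")
    return chrom


@dataclass(frozen=True)
class SegmentFileDialect:
    """Declared layout and coordinate convention of a segment file.

    Column order is fixed: sample, chromosome, start, end,
    [num_probes], segment_mean.  ``one_based``/``end_inclusive`` describe the
    file; coordinates are normalized to 0-based half-open on read.
    """

    has_header: bool = True
    one_based: bool = True
    end_inclusive: bool = True
    num_probes_column: bool = True

    def to_internal(self, start: int, end: int) -> tuple[int, int]:
        start0 = start - (1 if self.one_based else 0)
        end0 = end - (1 if self.one_based else 0) + (1 if self.end_inclusive else 0)
        return start0, end0


#: The common SEG dialect (1-based inclusive, num.mark column present).
SEG_DIALECT = SegmentFileDialect()

#: Canonical dialect used by :func:`write_segments` (already internal).
INTERNAL_DIALECT = SegmentFileDialect(
    has_header=True, one_based=False, end_inclusive=False, num_probes_column=False
)


def read_segments(
    path: str | Path,
    dialect: SegmentFileDialect = SEG_DIALECT,
    group: str = "case",
) -> list[Segment]:
    """Parse a segment file into normalized :class:`Segment` records.

    Malformed rows raise :class:`DataError` naming the offending line;
    missing segment means become NaN (filled neutral downstream).
    """
    path = Path(path)
    n_cols = 6 if dialect.num_probes_column else 5
    segments: list[Segment] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if lineno == 1 and dialect.has_header:
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise DataError(
                    f"{path.name}:{lineno}: expected {n_cols} tab-separated "
                    f"columns, found {len(fields)}"
                )
            sample = fields[0].strip()
            chrom = normalize_chromosome(fields[1])
            try:
                start = int(fields[2])
                end = int(fields[3])
            except ValueError:
                raise DataError(
                    f"{path.name}:{lineno}: unparseable coordinates "
                    f"{fields[2]!r}/{fields[3]!r}"
                )
            mean_field = fields[-1].strip()
            if mean_field.lower() in _MISSING_TOKENS:
                mean = math.nan
            else:
                try:
                    mean = float(mean_field)
                except ValueError:
                    raise DataError(
                        f"{path.name}:{lineno}: unparseable segment mean {mean_field!r}"
                    )
            start0, end0 = dialect.to_internal(start, end)
            if not end0 > start0:
                raise DataError(
                    f"{path.name}:{lineno}: empty interval after normalization "
                    f"([{start0}, {end0}))"
                )
            segments.append(
                Segment(
                    sample=sample,
                    group=group,
                    chromosome=chrom,
                    start=start0,
                    end=end0,
                    segment_mean=mean,
                )
            )
    return segments


def write_segments(path: str | Path, segments: Iterable[Segment]) -> None:
    """Write segments in the canonical internal dialect (0-based half-open).

    ``read_segments(path, INTERNAL_DIALECT)`` is the exact inverse; floats
    use the shortest round-tripping representation so write-read-write is
    byte-identical.
    """
    path = Path(path)
    with path.open("w") as handle:
        handle.write("sample\tchromosome\tstart\tend\tsegment_mean\n")
        for seg in segments:
            mean = "NA" if math.isnan(seg.segment_mean) else repr(seg.segment_mean)
            handle.write(
                f"{seg.sample}\t{seg.chromosome}\t{seg.start}\t{seg.end}\t{mean}\n"
            )


# ---------------------------------------------------------------------------
# expression matrix


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 expression with tumor/normal sample labels."""

    values: pd.DataFrame  # index: gene symbols; columns: sample ids
    groups: pd.Series  # sample id -> 'tumor' | 'normal'

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise DataError(f"duplicated gene symbols: {', '.join(map(str, dupes))}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise DataError(f"samples without a group label: {', '.join(missing)}")
        self.groups = self.groups.loc[list(self.values.columns)]
        bad = sorted(set(self.groups) - {"tumor", "normal"})
        if bad:
            raise DataError(f"group labels must be tumor/normal, got {bad}")
        if not self.tumor_samples or not self.normal_samples:
            raise DataError("both tumor and normal groups must be non-empty")

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "tumor"]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "normal"]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def read_expression(expr_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read the TSV matrix (first column = gene symbol) and its group file."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0).astype(float)
    values.index = values.index.astype(str)
    values.index.name = None
    groups_df = pd.read_csv(groups_path, sep="\t", dtype=str)
    if list(groups_df.columns[:2]) != ["sample", "group"]:
        raise DataError(
            f"{Path(groups_path).name}: expected header 'sample\\tgroup', "
            f"got {list(groups_df.columns[:2])}"
        )
    if groups_df["sample"].duplicated().any():
        raise DataError(f"{Path(groups_path).name}: duplicated sample ids")
    groups = groups_df.set_index("sample")["group"]
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(
    matrix: ExpressionMatrix, expr_path: str | Path, groups_path: str | Path
) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(expr_path, sep="\t", float_format="%.6g")
    with Path(groups_path).open("w") as handle:
        handle.write("sample\tgroup\n")
        for sample in matrix.values.columns:
            handle.write(f"{sample}\t{matrix.groups[sample]}\n")


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (0-based half-open) on an autosome."""

    symbol: str
    chromosome: int
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise DataError(f"gene {self.symbol}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.symbol}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """BED-like TSV: chromosome, start, end, symbol, strand (0-based half-open)."""
    path = Path(path)
    models: list[GeneModel] = []
    seen: set[str] = set()
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise DataError(
                    f"{path.name}:{lineno}: expected at least 4 columns"
                )
            chrom = normalize_chromosome(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise DataError(f"{path.name}:{lineno}: unparseable coordinates")
            symbol = fields[3].strip()
            if symbol in seen:
                raise DataError(f"{path.name}:{lineno}: duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            strand = fields[4].strip() if len(fields) > 4 and fields[4].strip() else "+"
            models.append(GeneModel(symbol, chrom, start, end, strand))
    return models


def write_gene_models(path: str | Path, models: Iterable[GeneModel]) -> None:
    with Path(path).open("w") as handle:
        for m in models:
            handle.write(f"{m.chromosome}\t{m.start}\t{m.end}\t{m.symbol}\t{m.strand}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass(frozen=True)
class GeneSet:
    term: str
    description: str
    genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """term id -> gene set; symbols upper-cased for exact matching."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, gs in self.sets.items():
            if not gs.genes:
                raise DataError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term: str) -> GeneSet:
        return self.sets[term]


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """GMT: term, description, then member symbols, tab-delimited."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path.name}:{lineno}: GMT line needs term, description "
                    "and at least one member gene"
                )
            term, description = fields[0], fields[1]
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not members:
                raise DataError(f"{path.name}:{lineno}: gene set {term!r} is empty")
            if term in sets:
                raise DataError(f"{path.name}:{lineno}: duplicate term {term!r}")
            sets[term] = GeneSet(term, description, members)
    return GeneSetCollection(sets)


def write_gene_sets(path: str | Path, collection: GeneSetCollection) -> None:
    with Path(path).open("w") as handle:
        for gs in collection:
            members = "\t".join(sorted(gs.genes))
            handle.write(f"{gs.term}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# Circos tracks


def write_circos_tracks(
    events: Sequence[CnvEvent],
    degs: Sequence,
    out_dir: str | Path,
    gene_models: Optional[Mapping[str, GeneModel]] = None,
) -> dict[str, Path]:
    """Emit plain-text tracks (chromosome, start, end, value) for circular plots.

    One track per {case, control} x {deletion, duplication} with the event's
    log2 absolute copy number as the value, plus one DEG track whose value is
    the signed log2 fold change (positions joined from ``gene_models``; DEGs
    without a model are skipped).  No plotting happens here.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tracks: dict[str, Path] = {}
    for group in ("case", "control"):
        for state in ("deletion", "duplication"):
            name = f"cnv_{group}_{state}.txt"
            track_path = out_dir / name
            with track_path.open("w") as handle:
                for e in events:
                    if e.group == group and e.state == state:
                        handle.write(
                            f"chr{e.chromosome}\t{e.start}\t{e.end}\t"
                            f"{e.log2_copy_number:.6g}\n"
                        )
            tracks[name] = track_path
    deg_path = out_dir / "degs.txt"
    with deg_path.open("w") as handle:
        if gene_models:
            for rec in degs:
                model = gene_models.get(rec.gene)
                if model is None:
                    continue
                handle.write(
                    f"chr{model.chromosome}\t{model.start}\t{model.end}\t"
                    f"{rec.log2_fc:.6g}\n"
                )
    tracks["degs.txt"] = deg_path
    return tracks
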