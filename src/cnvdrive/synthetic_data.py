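"""Synthetic paired tumor/normal cohorts with planted CNV-driven genes.

The generator emulates the statistical structure the pipeline is built to
detect: a toy genome of a few autosomes, paired case/control copy-number
segment profiles carrying planted recurrent focal events of controlled
length-bin composition, and a log2 expression matrix in which planted driven
genes shift concordantly with their copy-number state on top of Gaussian
(log-scale) noise.  Only non-neutral segments are emitted, matching the
missing-as-neutral convention of the segment layer.

Randomness: one global integer seed; four child streams are spawned from it
in a fixed, documented order — genome, segments, expression, gene sets — so
each generator is independently deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnv_events import (
    BIN_LARGE,
    BIN_MEDIUM,
    BIN_SMALL,
    DELETION,
    DUPLICATION,
    Segment,
    classify_state,
)
from .errors import ConfigError
from .formats_io import (
    ExpressionMatrix,
    GeneModel,
    GeneSet,
    GeneSetCollection,
    write_expression,
    write_gene_models,
    write_gene_sets,
    write_segments,
)

# length ranges sampled per bin (bp, inclusive)
_BIN_LENGTH_RANGES = {
    BIN_SMALL: (1_000, 10_000),
    BIN_MEDIUM: (10_001, 50_000),
    BIN_LARGE: (50_001, 150_000),
}

_STREAM_GENOME, _STREAM_SEGMENTS, _STREAM_EXPRESSION, _STREAM_GENE_SETS = range(4)


@dataclass(frozen=True)
class PlantedDriver:
    """One planted recurrent focal event with a concordant (or deliberately
    discordant, for decoys) expression shift."""

    gene_index: int
    state: str  # deletion | duplication
    carrier_fraction: float = 0.9
    expression_shift: float = 2.0  # log2 units, applied to carrier cases
    event_length: int = 30_000

    def __post_init__(self) -> None:
        if self.state not in (DELETION, DUPLICATION):
            raise ConfigError(f"driver state must be deletion/duplication, got {self.state!r}")
        if not 0 < self.carrier_fraction <= 1:
            raise ConfigError("carrier_fraction must be in (0, 1]")

    @property
    def concordant(self) -> bool:
        expected = 1 if self.state == DUPLICATION else -1
        return math.copysign(1, self.expression_shift) == expected


def default_drivers() -> list[PlantedDriver]:
    """10 concordant drivers (5 gains up, 5 losses down) plus 2 discordant
    decoys that the concordance classifier must reject."""
    gains = [PlantedDriver(i, DUPLICATION, 0.9, +2.0) for i in (10, 30, 50, 70, 90)]
    losses = [PlantedDriver(i, DELETION, 0.9, -2.0) for i in (110, 130, 150, 170, 190)]
    decoys = [
        PlantedDriver(25, DUPLICATION, 0.9, -2.0),
        PlantedDriver(145, DELETION, 0.9, +2.0),
    ]
    return gains + losses + decoys


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the standard recovery scenario: 20 cases / 20 controls,
    a 3 x 10 Mb genome carrying 200 genes of 5 kb, 10 concordant planted
    drivers at carrier fraction 0.9 with |log2 shift| 2 (plus 2 discordant
    decoys), expression noise SD 0.3, and a modest uniform background CNV
    load per sample per length bin.
    """

    seed: int = 0
    n_cases: int = 20
    n_controls: int = 20
    chromosome_lengths: dict[int, int] = field(
        default_factory=lambda: {1: 10_000_000, 2: 10_000_000, 3: 10_000_000}
    )
    n_genes: int = 200
    gene_length: int = 5_000
    drivers: tuple[PlantedDriver, ...] = field(
        default_factory=lambda: tuple(default_drivers())
    )
    background_rate: dict[str, float] = field(
        default_factory=lambda: {BIN_SMALL: 1.0, BIN_MEDIUM: 0.5, BIN_LARGE: 0.25}
    )
    noise_sd: float = 0.3
    baseline_range: tuple[float, float] = (4.0, 12.0)
    gain_log2cn: float = 1.6  # log2 absolute CN of planted/background gains
    loss_log2cn: float = 0.4  # ... and losses
    log2cn_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError("need at least one case and one control")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if any(rate < 0 for rate in self.background_rate.values()):
            raise ConfigError("background rates must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        max_event = max(
            [hi for _, hi in _BIN_LENGTH_RANGES.values()]
            + [d.event_length for d in self.drivers]
        )
        if min(self.chromosome_lengths.values()) <= max_event:
            raise ConfigError("every chromosome must exceed the largest event length")
        for d in self.drivers:
            if not 0 <= d.gene_index < self.n_genes:
                raise ConfigError(f"driver gene index {d.gene_index} out of range")
            if d.event_length < self.gene_length:
                raise ConfigError(
                    f"driver event length {d.event_length} shorter than the gene"
                )

    @property
    def case_samples(self) -> list[str]:
        return [f"case{i:03d}" for i in range(1, self.n_cases + 1)]

    @property
    def control_samples(self) -> list[str]:
        return [f"ctrl{i:03d}" for i in range(1, self.n_controls + 1)]


def _stream(config: SimulationConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[index])


def simulate_genome(config: SimulationConfig) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping genes uniformly on the toy genome.

    Genes are apportioned to chromosomes proportionally to length and placed
    by drawing sorted random offsets into the free space; deterministic given
    the seed.
    """
    rng = _stream(config, _STREAM_GENOME)
    chroms = sorted(config.chromosome_lengths)
    total = sum(config.chromosome_lengths.values())
    alloc = {
        c: int(round(config.n_genes * config.chromosome_lengths[c] / total))
        for c in chroms
    }
    while sum(alloc.values()) != config.n_genes:  # fix rounding drift
        delta = config.n_genes - sum(alloc.values())
        alloc[chroms[0]] += 1 if delta > 0 else -1
    genes: list[GeneModel] = []
    index = 0
    for chrom in chroms:
        k = alloc[chrom]
        if k == 0:
            continue
        free = config.chromosome_lengths[chrom] - k * config.gene_length
        if free < 0:
            raise ConfigError(f"chromosome {chrom} cannot fit {k} genes")
        cuts = np.sort(rng.integers(0, free + 1, size=k))
        starts = cuts + config.gene_length * np.arange(k)
        for start in starts:
            index += 1
            genes.append(
                GeneModel(
                    symbol=f"G{index:04d}",
                    chromosome=chrom,
                    start=int(start),
                    end=int(start) + config.gene_length,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    return genes


def _draw_segment_mean(config, rng, state: str) -> float:
    center = (config.gain_log2cn if state == DUPLICATION else config.loss_log2cn) - 1.0
    floor = 0.1
    value = rng.normal(center, config.log2cn_sd)
    if state == DUPLICATION:
        return max(value, floor)
    return min(value, -floor)


def simulate_segments(
    config: SimulationConfig, genes: Sequence[GeneModel]
) -> tuple[list[Segment], list[Segment]]:
    """Case and control segment profiles.

    Every planted driver is fully covered by an event of its state in
    ``ceil(carrier_fraction * n_cases)`` randomly chosen cases and in zero
    controls; background events land uniformly in all samples of both groups
    with Poisson counts per length bin at the configured expectations (they
    may hit any gene by chance — removing those is the frequency filter's
    job, not the generator's).
    """
    rng = _stream(config, _STREAM_SEGMENTS)
    chroms = sorted(config.chromosome_lengths)
    weights = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    case_segments: list[Segment] = []
    control_segments: list[Segment] = []

    for driver in config.drivers:
        gene = genes[driver.gene_index]
        n_carriers = math.ceil(driver.carrier_fraction * config.n_cases)
        carriers = rng.choice(config.case_samples, size=n_carriers, replace=False)
        chrom_len = config.chromosome_lengths[gene.chromosome]
        for sample in sorted(carriers):
            slack = driver.event_length - gene.length
            offset = int(rng.integers(0, slack + 1))
            start = max(0, gene.start - offset)
            end = min(chrom_len, start + driver.event_length)
            case_segments.append(
                Segment(
                    sample=sample,
                    group="case",
                    chromosome=gene.chromosome,
                    start=start,
                    end=end,
                    segment_mean=_draw_segment_mean(config, rng, driver.state),
                )
            )

    for group, samples, bucket in (
        ("case", config.case_samples, case_segments),
        ("control", config.control_samples, control_segments),
    ):
        for sample in samples:
            for length_bin, (lo, hi) in _BIN_LENGTH_RANGES.items():
                rate = config.background_rate.get(length_bin, 0.0)
                for _ in range(rng.poisson(rate)):
                    chrom = int(rng.choice(chroms, p=weights))
                    length = int(rng.integers(lo, hi + 1))
                    start = int(
                        rng.integers(0, config.chromosome_lengths[chrom] - length + 1)
                    )
                    state = DUPLICATION if rng.random() < 0.5 else DELETION
                    bucket.append(
                        Segment(
                            sample=sample,
                            group=group,
                            chromosome=chrom,
                            start=start,
                            end=start + length,
                            segment_mean=_draw_segment_mean(config, rng, state),
                        )
                    )
    return case_segments, control_segments


def _carriers_from_segments(
    driver: PlantedDriver, gene: GeneModel, case_segments: Sequence[Segment]
) -> set[str]:
    carriers = set()
    for seg in case_segments:
        if (
            seg.chromosome == gene.chromosome
            and seg.start <= gene.start
            and seg.end >= gene.end
            and classify_state(seg.segment_mean + 1.0) == driver.state
        ):
            carriers.add(seg.sample)
    return carriers


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    case_segments: Sequence[Segment],
) -> ExpressionMatrix:
    """log2 expression matrix over all genes and samples.

    Gene g in sample s takes ``baseline_g + shift_g * carrier(g, s) +
    N(0, noise_sd)``; carrier status is read off the case segment profiles
    (full containment by an event of the driver's state), so the expression
    shift is concordant with the realized copy-number change.  Non-driver
    genes shift 0; normals are never shifted.
    """
    rng = _stream(config, _STREAM_EXPRESSION)
    samples = config.case_samples + config.control_samples
    lo, hi = config.baseline_range
    baselines = rng.uniform(lo, hi, size=len(genes))
    values = baselines[:, None] + rng.normal(
        0.0, config.noise_sd, size=(len(genes), len(samples))
    )
    col = {s: j for j, s in enumerate(samples)}
    for driver in config.drivers:
        gene = genes[driver.gene_index]
        for sample in _carriers_from_segments(driver, gene, case_segments):
            values[driver.gene_index, col[sample]] += driver.expression_shift
    frame = pd.DataFrame(values, index=[g.symbol for g in genes], columns=samples)
    groups = pd.Series(
        ["tumor"] * config.n_cases + ["normal"] * config.n_controls, index=samples
    )
    return ExpressionMatrix(values=frame, groups=groups)


def simulate_gene_sets(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    n_sets: int = 20,
    set_size: int = 10,
) -> GeneSetCollection:
    """Toy annotation: random disjointly seeded gene sets for exercising the
    enrichment stage (no biological structure implied)."""
    rng = _stream(config, _STREAM_GENE_SETS)
    symbols = [g.symbol for g in genes]
    sets = {}
    for i in range(1, n_sets + 1):
        size = min(set_size, len(symbols))
        members = rng.choice(symbols, size=size, replace=False)
        term = f"SET{i:03d}"
        sets[term] = GeneSet(term, f"synthetic set {i}", frozenset(m.upper() for m in members))
    return GeneSetCollection(sets)


@dataclass
class SyntheticCohort:
    """Everything one simulated study produces, plus the planted ground truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    case_segments: list[Segment]
    control_segments: list[Segment]
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection

    @property
    def truth(self) -> pd.DataFrame:
        rows = [
            {
                "gene": self.genes[d.gene_index].symbol,
                "state": d.state,
                "expression_shift": d.expression_shift,
                "carrier_fraction": d.carrier_fraction,
                "concordant": d.concordant,
            }
            for d in self.config.drivers
        ]
        return pd.DataFrame(rows)


def simulate_cohort(config: Optional[SimulationConfig] = None) -> SyntheticCohort:
    """Run all generators in their documented order for one cohort."""
    config = config if config is not None else SimulationConfig()
    genes = simulate_genome(config)
    case_segments, control_segments = simulate_segments(config, genes)
    expression = simulate_expression(config, genes, case_segments)
    gene_sets = simulate_gene_sets(config, genes)
    return SyntheticCohort(
        config=config,
        genes=genes,
        case_segments=case_segments,
        control_segments=control_segments,
        expression=expression,
        gene_sets=gene_sets,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort in the pipeline's input formats plus a ground-truth
    TSV of planted drivers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cases_seg": out_dir / "cases.seg",
        "controls_seg": out_dir / "controls.seg",
        "genes_bed": out_dir / "genes.bed",
        "expression_tsv": out_dir / "expression.tsv",
        "groups_tsv": out_dir / "groups.tsv",
        "gene_sets_gmt": out_dir / "gene_sets.gmt",
        "truth_tsv": out_dir / "planted_drivers.tsv",
    }
    write_segments(paths["cases_seg"], cohort.case_segments)
    write_segments(paths["controls_seg"], cohort.control_segments)
    write_gene_models(paths["genes_bed"], cohort.genes)
    write_expression(cohort.expression, paths["expression_tsv"], paths["groups_tsv"])
    write_gene_sets(paths["gene_sets_gmt"], cohort.gene_sets)
    cohort.truth.to_csv(paths["truth_tsv"], sep="\t", index=False)
    return paths


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A no-signal scenario for null calibration: no planted drivers, one
    10 Mb chromosome, an elevated small-event background so every burden
    cell of interest is populated."""
    defaults = dict(
        seed=seed,
        drivers=(),
        chromosome_lengths={1: 10_000_000},
        n_genes=50,
        background_rate={BIN_SMALL: 5.0, BIN_MEDIUM: 0.0, BIN_LARGE: 0.0},
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
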