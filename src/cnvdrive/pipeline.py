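"""End-to-end pipeline orchestration with a reproducible run manifest.

Stage order: segments -> events -> burden table -> gene-level CNV calls ->
frequency filter -> fold-change screen -> concordance classification ->
enrichment (optional) -> Circos tracks.  Outputs are plain TSV; the manifest
records the config hash, seed and per-stage row counts, so a rerun with the
same config and inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import burden_stats, diffexpr, driver_integration, gene_cnv
from .cnv_events import segments_to_events
from .enrichment import enrich
from .errors import ConfigError
from .formats_io import (
    SegmentFileDialect,
    read_expression,
    read_gene_models,
    read_gene_sets,
    read_segments,
    write_circos_tracks,
)
from .synthetic_data import SimulationConfig, simulate_cohort


@dataclass
class PipelineConfig:
    """All paths, thresholds and dialect declarations for one run."""

    cases_seg: str = ""
    controls_seg: str = ""
    genes_bed: str = ""
    expression_tsv: str = ""
    groups_tsv: str = ""
    gene_sets_gmt: Optional[str] = None
    out_dir: str = "cnvdrive_run"

    seed: int = 0
    epsilon: float = 1e-9
    min_cnv_length: int = 1000
    min_case_fraction: float = 0.8
    max_control_fraction: float = 0.0
    deg_cutoff: float = 1.0
    paired: bool = False
    alpha: float = 0.05
    ease: bool = False
    n_replicates: int = 1000
    containment: str = "full"

    # SEG dialect of the input segment files
    seg_has_header: bool = True
    seg_one_based: bool = True
    seg_end_inclusive: bool = True
    seg_num_probes_column: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_case_fraction <= 1:
            raise ConfigError("min_case_fraction must be in [0, 1]")
        if not 0 <= self.max_control_fraction <= 1:
            raise ConfigError("max_control_fraction must be in [0, 1]")
        if self.deg_cutoff < 0 or self.epsilon < 0:
            raise ConfigError("deg_cutoff and epsilon must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.containment not in gene_cnv.CONTAINMENT_MODES:
            raise ConfigError(f"containment must be one of {gene_cnv.CONTAINMENT_MODES}")

    @property
    def dialect(self) -> SegmentFileDialect:
        return SegmentFileDialect(
            has_header=self.seg_has_header,
            one_based=self.seg_one_based,
            end_inclusive=self.seg_end_inclusive,
            num_probes_column=self.seg_num_probes_column,
        )

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - known
        if stray:
            raise ConfigError(f"unknown config keys: {sorted(stray)}")
        return cls(**raw)

    def sha256(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _preflight(config: PipelineConfig) -> None:
    required = {
        "cases_seg": config.cases_seg,
        "controls_seg": config.controls_seg,
        "genes_bed": config.genes_bed,
        "expression_tsv": config.expression_tsv,
        "groups_tsv": config.groups_tsv,
    }
    missing = [name for name, p in required.items() if not p or not Path(p).exists()]
    if config.gene_sets_gmt and not Path(config.gene_sets_gmt).exists():
        missing.append("gene_sets_gmt")
    if missing:
        raise ConfigError(f"missing input file(s): {', '.join(missing)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    _preflight(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    case_segments = read_segments(config.cases_seg, config.dialect, group="case")
    control_segments = read_segments(config.controls_seg, config.dialect, group="control")
    genes = read_gene_models(config.genes_bed)
    expression = read_expression(config.expression_tsv, config.groups_tsv)

    events = segments_to_events(
        case_segments + control_segments,
        epsilon=config.epsilon,
        min_length=config.min_cnv_length,
    )
    case_samples = sorted({s.sample for s in case_segments} | set(expression.tumor_samples))
    control_samples = sorted(
        {s.sample for s in control_segments} | set(expression.normal_samples)
    )

    burden = burden_stats.burden_table(
        events,
        case_samples,
        control_samples,
        n_replicates=config.n_replicates,
        seed=config.seed,
    )
    burden.to_csv(out_dir / "burden.tsv", sep="\t", index=False)

    profiles = gene_cnv.build_profiles(
        events, genes, case_samples, control_samples, containment=config.containment
    )
    retained = gene_cnv.frequency_filter(
        profiles,
        min_case_fraction=config.min_case_fraction,
        max_control_fraction=config.max_control_fraction,
    )
    gene_rows = [
        {
            "gene": p.gene,
            "chromosome": p.chromosome,
            "state": p.recurrent_state,
            "case_frequency": p.case_frequency,
            "control_frequency": p.control_frequency,
            "log2_copy_number": gene_cnv.summarize_gene_copy_number(p),
        }
        for p in retained
    ]
    pd.DataFrame(
        gene_rows,
        columns=[
            "gene", "chromosome", "state", "case_frequency",
            "control_frequency", "log2_copy_number",
        ],
    ).to_csv(out_dir / "gene_cnv.tsv", sep="\t", index=False)

    log2fc = diffexpr.compute_log2fc(expression, paired=config.paired)
    degs = diffexpr.screen_degs(log2fc, cutoff=config.deg_cutoff)
    pd.DataFrame(
        [{"gene": d.gene, "log2_fc": d.log2_fc, "direction": d.direction} for d in degs],
        columns=["gene", "log2_fc", "direction"],
    ).to_csv(out_dir / "degs.tsv", sep="\t", index=False)

    deg_by_gene = {d.gene: d for d in degs}
    measured_cnv, deg_cnv = driver_integration.overlap_genes(
        [r["gene"] for r in gene_rows], deg_by_gene, expression.genes
    )
    candidates = [
        driver_integration.DriverCandidate(
            gene=row["gene"],
            chromosome=row["chromosome"],
            log2_copy_number=row["log2_copy_number"],
            log2_fc=deg_by_gene[row["gene"]].log2_fc,
            cnv_state=row["state"],
            deg_direction=deg_by_gene[row["gene"]].direction,
        )
        for row in gene_rows
        if row["gene"] in deg_cnv
    ]
    driven = driver_integration.classify_driven(candidates)
    pd.DataFrame(
        [
            {
                "chromosome": d.chromosome,
                "gene": d.gene,
                "log2_copy_number": d.log2_copy_number,
                "log2_fc": d.log2_fc,
                "state": d.cnv_state,
                "direction": d.deg_direction,
            }
            for d in driven
        ],
        columns=["chromosome", "gene", "log2_copy_number", "log2_fc", "state", "direction"],
    ).to_csv(out_dir / "driven.tsv", sep="\t", index=False)

    n_enrichment = 0
    if config.gene_sets_gmt and driven:
        gene_sets = read_gene_sets(config.gene_sets_gmt)
        results = enrich(
            [d.gene for d in driven],
            gene_sets,
            expression.genes,
            alpha=config.alpha,
            ease=config.ease,
        )
        pd.DataFrame(
            [
                {
                    "term": r.term,
                    "description": r.description,
                    "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                    "p_value": r.p_value,
                    "q_value_bh": r.q_value_bh,
                    "significant": r.significant,
                    "hits": ",".join(r.hits),
                }
                for r in results
            ]
        ).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        n_enrichment = len(results)

    write_circos_tracks(
        events, degs, out_dir / "circos", gene_models={g.symbol: g for g in genes}
    )

    manifest = {
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "thresholds": {
            "epsilon": config.epsilon,
            "min_cnv_length": config.min_cnv_length,
            "min_case_fraction": config.min_case_fraction,
            "max_control_fraction": config.max_control_fraction,
            "deg_cutoff": config.deg_cutoff,
            "alpha": config.alpha,
            "n_replicates": config.n_replicates,
            "containment": config.containment,
        },
        "rows": {
            "case_segments": len(case_segments),
            "control_segments": len(control_segments),
            "events": len(events),
            "burden_cells": len(burden),
            "cnv_genes": len(gene_rows),
            "degs": len(degs),
            "cnv_genes_measured": len(measured_cnv),
            "cnv_genes_deg": len(deg_cnv),
            "driven_genes": len(driven),
            "enrichment_terms": n_enrichment,
        },
    }
    with (out_dir / "manifest.json").open("w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


@dataclass
class RecoveryResult:
    """Outcome of one synthetic-cohort recovery experiment."""

    n_drivers: int
    recovered: int
    decoys_driven: int
    false_driven: int
    driven_genes: list[str] = field(default_factory=list)

    @property
    def success(self) -> bool:
        """The recovery standard: at least 9 of 10 concordant drivers found,
        no decoy and no unplanted gene called driven."""
        return (
            self.recovered >= self.n_drivers - 1
            and self.decoys_driven == 0
            and self.false_driven == 0
        )


def evaluate_recovery(config: SimulationConfig) -> RecoveryResult:
    """Simulate one cohort and run the in-memory driver-calling chain
    (events -> gene profiles -> frequency filter -> fold-change screen ->
    concordance), comparing the driven-gene list with the planted truth."""
    cohort = simulate_cohort(config)
    events = segments_to_events(cohort.case_segments + cohort.control_segments)
    profiles = gene_cnv.build_profiles(
        events, cohort.genes, config.case_samples, config.control_samples
    )
    retained = gene_cnv.frequency_filter(profiles)
    log2fc = diffexpr.compute_log2fc(cohort.expression)
    degs = {d.gene: d for d in diffexpr.screen_degs(log2fc)}
    candidates = [
        driver_integration.DriverCandidate(
            gene=p.gene,
            chromosome=p.chromosome,
            log2_copy_number=gene_cnv.summarize_gene_copy_number(p),
            log2_fc=degs[p.gene].log2_fc,
            cnv_state=p.recurrent_state,
            deg_direction=degs[p.gene].direction,
        )
        for p in retained
        if p.gene in degs
    ]
    driven = {d.gene for d in driver_integration.classify_driven(candidates)}

    truth = cohort.truth
    concordant = set(truth.loc[truth.concordant, "gene"])
    decoys = set(truth.loc[~truth.concordant, "gene"])
    return RecoveryResult(
        n_drivers=len(concordant),
        recovered=len(driven & concordant),
        decoys_driven=len(driven & decoys),
        false_driven=len(driven - concordant - decoys),
        driven_genes=sorted(driven),
    )
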