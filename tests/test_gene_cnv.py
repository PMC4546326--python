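"""Gene-level CNV calls: containment mapping, recurrence filter, summary."""

import numpy as np
import pytest

from cnvdrive.cnv_events import DELETION, DUPLICATION, segments_to_events
from cnvdrive.errors import DataError
from cnvdrive.formats_io import GeneModel
from cnvdrive.gene_cnv import (
    GeneCnvProfile,
    build_profiles,
    frequency_filter,
    map_events_to_genes,
    summarize_gene_copy_number,
)

from conftest import make_segment


def brute_force_calls(events, gene_models, containment="full"):
    """Quadratic oracle: per-gene, per-event containment scan."""
    calls = {}
    for gene in gene_models:
        per_sample = {}
        for e in events:
            if e.chromosome != gene.chromosome:
                continue
            if containment == "full":
                hit = e.start <= gene.start and e.end >= gene.end
            else:
                hit = e.start < gene.end and e.end > gene.start
            if not hit:
                continue
            call = (e.state, e.log2_copy_number)
            old = per_sample.get(e.sample)
            if old is not None:
                key = lambda c: (abs(c[1] - 1.0), c[1])
                call = old if key(old) >= key(call) else call
            per_sample[e.sample] = call
        calls[gene.symbol] = per_sample
    return calls


def random_instance(rng, n_genes=50, n_events=200):
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, 900_000))
        genes.append(
            GeneModel(f"G{i}", int(rng.integers(1, 4)), start,
                      start + int(rng.integers(200, 20_000)))
        )
    segments = []
    for _ in range(n_events):
        start = int(rng.integers(0, 900_000))
        segments.append(
            make_segment(
                sample=f"s{rng.integers(8)}",
                group="case",
                chromosome=int(rng.integers(1, 4)),
                start=start,
                end=start + int(rng.integers(1_000, 100_000)),
                segment_mean=float(rng.uniform(-1, 1)),
            )
        )
    return genes, segments_to_events(segments)


class TestMapping:
    def test_gene_inside_event_called(self):
        genes = [GeneModel("A", 1, 100, 200)]
        events = segments_to_events([make_segment(start=0, end=10_000, segment_mean=0.5)])
        calls = map_events_to_genes(events, genes)
        assert calls["A"] == {"s1": (DUPLICATION, 1.5)}

    def test_partial_overlap_semantics(self):
        genes = [GeneModel("A", 1, 100, 200)]
        events = segments_to_events(
            [make_segment(start=150, end=10_000, segment_mean=0.5)]
        )
        assert map_events_to_genes(events, genes, "full")["A"] == {}
        assert map_events_to_genes(events, genes, "any_overlap")["A"] != {}

    def test_conflicting_states_larger_magnitude_wins(self):
        genes = [GeneModel("A", 1, 100, 200)]
        events = segments_to_events(
            [
                make_segment(start=0, end=10_000, segment_mean=0.3),
                make_segment(start=0, end=50_000, segment_mean=-0.8),
            ]
        )
        calls = map_events_to_genes(events, genes)
        assert calls["A"]["s1"][0] == DELETION

    @pytest.mark.parametrize("containment", ["full", "any_overlap"])
    def test_matches_brute_force_oracle(self, containment):
        rng = np.random.default_rng(23)
        for _ in range(20):
            genes, events = random_instance(rng)
            assert map_events_to_genes(events, genes, containment) == brute_force_calls(
                events, genes, containment
            )


def make_profile(n_case_calls, n_control_calls, state=DUPLICATION, log2cn=1.5,
                 n_cases=10, n_controls=10):
    case_samples = tuple(f"c{i}" for i in range(n_cases))
    control_samples = tuple(f"n{i}" for i in range(n_controls))
    calls = {f"c{i}": (state, log2cn) for i in range(n_case_calls)}
    calls.update({f"n{i}": (state, log2cn) for i in range(n_control_calls)})
    return GeneCnvProfile("G", 1, calls, case_samples, control_samples)


class TestFrequencyFilter:
    def test_above_threshold_retained(self):
        assert frequency_filter([make_profile(9, 0)])  # 0.9 > 0.8

    def test_exact_threshold_rejected(self):
        # "more than 80%" is strict: 8/10 does not qualify
        assert frequency_filter([make_profile(8, 0)]) == []

    def test_any_control_call_rejected(self):
        assert frequency_filter([make_profile(10, 1)]) == []

    def test_mixed_states_not_recurrent(self):
        case_samples = tuple(f"c{i}" for i in range(10))
        calls = {f"c{i}": (DUPLICATION if i < 5 else DELETION, 1.5 if i < 5 else 0.5)
                 for i in range(10)}
        profile = GeneCnvProfile("G", 1, calls, case_samples, ("n0",))
        assert profile.case_frequency == 1.0
        assert frequency_filter([profile]) == []

    def test_monotone_in_min_case_fraction(self):
        profiles = [make_profile(k, 0) for k in range(11)]
        loose = frequency_filter(profiles, 0.5)
        strict = frequency_filter(profiles, 0.9)
        assert len(strict) <= len(loose)
        assert all(p in loose for p in strict)


class TestSummarize:
    def test_constant_carriers(self):
        assert summarize_gene_copy_number(make_profile(9, 0, log2cn=1.5)) == 1.5

    def test_mean_of_carriers(self):
        case_samples = ("c0", "c1", "c2")
        calls = {"c0": (DUPLICATION, 1.0 + 1e-6), "c1": (DUPLICATION, 2.0)}
        profile = GeneCnvProfile("G", 1, calls, case_samples, ("n0",))
        value = summarize_gene_copy_number(profile)
        assert value == pytest.approx((1.0 + 1e-6 + 2.0) / 2)

    def test_no_carriers_errors(self):
        profile = GeneCnvProfile("G", 1, {}, ("c0",), ("n0",))
        with pytest.raises(DataError):
            summarize_gene_copy_number(profile)

    def test_recovers_generator_copy_number(self):
        """Planted gains at log2CN 1.6 are recovered within +-0.1."""
        from cnvdrive.synthetic_data import SimulationConfig, simulate_cohort

        errors = []
        for seed in range(20):
            config = SimulationConfig(seed=seed)
            cohort = simulate_cohort(config)
            events = segments_to_events(cohort.case_segments + cohort.control_segments)
            profiles = {
                p.gene: p
                for p in build_profiles(
                    events, cohort.genes, config.case_samples, config.control_samples
                )
            }
            for driver in config.drivers:
                if driver.state != DUPLICATION:
                    continue
                gene = cohort.genes[driver.gene_index].symbol
                profile = profiles[gene]
                if profile.calls:
                    errors.append(
                        summarize_gene_copy_number(profile) - config.gain_log2cn
                    )
        assert errors and max(abs(e) for e in errors) < 0.1
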